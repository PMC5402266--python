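"""Tissue-specificity scoring and target-tissue gene selection.

The tissue-specificity index (TSI) of a per-tissue expression profile
``x_1..x_n`` is ``sum_i (1 - x_i / max(x)) / (n - 1)``: 0 for a uniformly
expressed gene, 1 for a gene expressed in a single tissue.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptySelectionError, UndefinedTSIError
from .io import as_float_array

logger = logging.getLogger(__name__)


def compute_tsi(profile_row: Sequence[float]) -> float:
    """Tissue-specificity index of one per-tissue expression vector.

    Requires n >= 2 nonnegative values with a positive maximum.
    """
    x = as_float_array(profile_row, "expression profile")
    if x.size < 2:
        raise UndefinedTSIError(f"TSI needs at least 2 tissues, got {x.size}")
    if (x < 0).any():
        raise UndefinedTSIError("expression values must be nonnegative")
    xmax = x.max()
    if xmax <= 0:
        raise UndefinedTSIError("TSI undefined for an all-zero profile")
    return float(np.sum(1.0 - x / xmax) / (x.size - 1))


def assign_max_tissue(profile: pd.DataFrame) -> pd.Series:
    """Per gene, the tissue with the highest mean expression.

    Ties break toward the first tissue in column order, with a warning.
    """
    values = profile.to_numpy()
    argmax = values.argmax(axis=1)
    row_max = values.max(axis=1)
    tie_mask = (values == row_max[:, None]).sum(axis=1) > 1
    if tie_mask.any():
        tied = profile.index[tie_mask].tolist()
        logger.warning(
            "max-tissue ties broken by tissue order for %d gene(s): %s",
            len(tied), tied[:10],
        )
    return pd.Series(
        np.asarray(profile.columns)[argmax], index=profile.index, name="max_tissue"
    )


def specificity_table(
    profile: pd.DataFrame,
    target_tissues: Iterable[str],
    fraction: float = 0.2,
) -> pd.DataFrame:
    """Score every gene and flag the selected target-tissue-specific set.

    Returns a frame indexed by gene id with columns ``tsi``, ``max_tissue``
    and ``selected``.  Genes whose profile is all zero have undefined TSI and
    are dropped with a warning.
    """
    if profile.shape[1] < 2:
        raise UndefinedTSIError(
            f"TSI needs at least 2 tissues, got {profile.shape[1]}"
        )
    values = profile.to_numpy()
    row_max = values.max(axis=1)
    zero = row_max <= 0
    if zero.any():
        dropped = profile.index[zero].tolist()
        logger.warning("dropping %d all-zero gene(s): %s", len(dropped), dropped[:10])
        profile = profile.loc[~zero]
        values = values[~zero]
        row_max = row_max[~zero]

    n = profile.shape[1]
    tsi = (1.0 - values / row_max[:, None]).sum(axis=1) / (n - 1)
    table = pd.DataFrame(
        {"tsi": tsi, "max_tissue": assign_max_tissue(profile)}, index=profile.index
    )
    table.index.name = "gene_id"
    selected = select_top_quantile(table, fraction, set(target_tissues))
    table["selected"] = table.index.isin(selected)
    return table


def select_top_quantile(
    table: pd.DataFrame, fraction: float, target_group: Iterable[str]
) -> list[str]:
    """The floor(fraction * N) highest-TSI genes among the N genes whose
    maximum expression falls in the target tissue group.

    Ordering is TSI descending, then gene id ascending (deterministic
    tie-break at the cut).
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    target_group = set(target_group)
    candidates = table[table["max_tissue"].isin(target_group)]
    n_candidates = len(candidates)
    if n_candidates == 0:
        raise EmptySelectionError(
            f"no genes have their maximum expression in {sorted(target_group)}"
        )
    k = math.floor(fraction * n_candidates)
    # sort on TSI desc then gene id asc without mutating the caller's frame
    ranked = candidates.assign(_gene=candidates.index.astype(str)).sort_values(
        ["tsi", "_gene"], ascending=[False, True]
    )
    return ranked.index[:k].tolist()
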
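"""Gene-set overrepresentation tests with multiple-testing adjustment.

The primary test is the one-sided hypergeometric upper tail: the probability
of drawing at least the observed overlap when a size-s selection is taken
uniformly from a universe of N genes containing K set members.  A permutation
alternative is provided for users who distrust the independence assumptions.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ("set_name", "k", "K", "s", "N", "p", "p_adj")


def benjamini_hochberg(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    Returns adjusted p-values in the input order:
    ``p_adj(i) = min_{j >= i} min(1, p(j) * m / j)`` over the ascending sort.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted


def hypergeom_enrichment(
    selected: Iterable[str],
    collection: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Test each gene set for overrepresentation in the selected genes.

    Set members are intersected with the universe before testing; sets that
    are empty after intersection are skipped with a warning.  Returns a frame
    with columns set_name, k, K, s, N, p, p_adj sorted by p ascending.
    """
    universe = set(universe)
    selected = set(selected)
    offenders = sorted(selected - universe)
    if offenders:
        raise ValueError(
            f"selected genes missing from the universe: {offenders[:10]}"
        )
    n_universe = len(universe)
    n_selected = len(selected)

    rows = []
    for name, members in collection.items():
        in_universe = set(members) & universe
        if not in_universe:
            logger.warning("gene set %r has no members in the universe; skipped", name)
            continue
        k = len(in_universe & selected)
        big_k = len(in_universe)
        p = float(stats.hypergeom.sf(k - 1, n_universe, big_k, n_selected))
        rows.append((name, k, big_k, n_selected, n_universe, min(p, 1.0)))

    result = pd.DataFrame(rows, columns=RESULT_COLUMNS[:-1])
    if result.empty:
        result["p_adj"] = pd.Series(dtype=float)
        return result
    result["p_adj"] = benjamini_hochberg(result["p"].to_numpy())
    return result.sort_values(["p", "set_name"]).reset_index(drop=True)


def permutation_enrichment(
    selected: Iterable[str],
    gene_set: Iterable[str],
    universe: Iterable[str],
    n_perm: int = 1000,
    seed: int | None = None,
) -> float:
    """Empirical overrepresentation p-value from random same-size selections.

    ``p = (1 + #{permuted overlap >= observed}) / (n_perm + 1)`` with
    permutations drawn as uniform size-s subsets of the universe.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    universe_list = sorted(set(universe))
    selected = set(selected) & set(universe_list)
    members = np.array(
        [gene in set(gene_set) for gene in universe_list], dtype=bool
    )
    observed = len(selected & set(np.asarray(universe_list)[members]))
    s = len(selected)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        draw = rng.choice(len(universe_list), size=s, replace=False)
        if members[draw].sum() >= observed:
            hits += 1
    return (1 + hits) / (n_perm + 1)
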
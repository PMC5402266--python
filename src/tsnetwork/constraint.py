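"""Derived-allele-frequency (DAF) comparison between gene sets.

Persistently low DAF is a signature of purifying selection, so comparing the
mean DAF of a candidate gene set against a background set — with
nonparametric bootstrap confidence intervals, since DAF distributions are far
from normal — indicates whether the candidate set sits under different
selective constraint.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Iterable
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class SetSummary:
    name: str
    n_snps: int
    mean: float
    ci_lo: float
    ci_hi: float


@dataclass
class DAFComparison:
    """Result of comparing mean DAF between two gene sets."""

    set_a: SetSummary
    set_b: SetSummary
    n_reps: int
    level: float
    seed: int | None
    significant: bool
    lower_set: str | None
    p_diff: float

    def to_dict(self) -> dict:
        return asdict(self)


def mean_daf(variants: pd.DataFrame, genes: Iterable[str], name: str = "gene set"):
    """(n SNPs, mean DAF) over SNPs whose gene belongs to the set."""
    mask = variants["gene_id"].isin(set(genes))
    values = variants.loc[mask, "daf"].to_numpy()
    if values.size == 0:
        raise ValueError(f"no SNPs map to {name}")
    return int(values.size), float(values.mean())


def bootstrap_ci(
    values,
    n_reps: int = 500,
    level: float = 0.95,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean.

    Resamples with replacement ``n_reps`` times and returns the
    ``(1-level)/2`` and ``1-(1-level)/2`` empirical quantiles of the
    replicate means.  Constant input yields the degenerate interval (c, c)
    with a warning.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError(f"bootstrap needs >= 2 values, got {v.size}")
    if n_reps < 100:
        raise ValueError(f"n_reps must be >= 100, got {n_reps}")
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if np.ptp(v) == 0:
        warnings.warn("constant input: degenerate bootstrap CI", stacklevel=2)
        c = float(v[0])
        return (c, c)
    if rng is None:
        rng = np.random.default_rng(seed)
    means = _replicate_means(v, n_reps, rng)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def _replicate_means(v: np.ndarray, n_reps: int, rng: np.random.Generator) -> np.ndarray:
    idx = rng.integers(0, v.size, size=(n_reps, v.size))
    return v[idx].mean(axis=1)


def _gene_replicate_means(
    variants: pd.DataFrame, genes: list[str], n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Replicate means when the resampling unit is the gene (SNPs pooled)."""
    by_gene = {
        g: grp["daf"].to_numpy()
        for g, grp in variants[variants["gene_id"].isin(genes)].groupby("gene_id")
    }
    pool = sorted(by_gene)
    means = np.empty(n_reps)
    for rep in range(n_reps):
        draw = rng.integers(0, len(pool), size=len(pool))
        pooled = np.concatenate([by_gene[pool[i]] for i in draw])
        means[rep] = pooled.mean()
    return means


def compare_daf(
    variants: pd.DataFrame,
    set_a: Iterable[str],
    set_b: Iterable[str],
    n_reps: int = 500,
    level: float = 0.95,
    seed: int | None = None,
    names: tuple[str, str] = ("set_a", "set_b"),
    resample: str = "snps",
) -> DAFComparison:
    """Compare mean DAF between two gene sets with bootstrap CIs.

    The verdict is "significant" iff the two percentile CIs are disjoint.
    Also reports a two-sided bootstrap p-value for the difference in means
    (fraction of replicate differences on either side of zero).  ``resample``
    chooses the resampling unit: individual SNPs (default) or whole genes
    with their SNPs pooled.
    """
    if resample not in {"snps", "genes"}:
        raise ValueError(f"resample must be 'snps' or 'genes', got {resample!r}")
    genes_a, genes_b = set(set_a), set(set_b)
    shared = genes_a & genes_b
    if shared:
        logger.warning(
            "gene sets overlap on %d gene(s); their SNPs count in both sets",
            len(shared),
        )

    rng = np.random.default_rng(seed)
    summaries = []
    replicate_means = []
    for name, genes in zip(names, (genes_a, genes_b)):
        n, mean = mean_daf(variants, genes, name=name)
        values = variants.loc[variants["gene_id"].isin(genes), "daf"].to_numpy()
        if np.ptp(values) == 0:
            warnings.warn(f"{name}: constant DAF, degenerate CI", stacklevel=2)
            means = np.full(n_reps, values[0], dtype=float)
        elif resample == "snps":
            means = _replicate_means(values, n_reps, rng)
        else:
            means = _gene_replicate_means(variants, sorted(genes), n_reps, rng)
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
        summaries.append(SetSummary(name, n, mean, float(lo), float(hi)))
        replicate_means.append(means)

    a, b = summaries
    significant = a.ci_hi < b.ci_lo or b.ci_hi < a.ci_lo
    lower = None
    if a.mean != b.mean:
        lower = a.name if a.mean < b.mean else b.name
    diffs = replicate_means[0] - replicate_means[1]
    p_low = (1 + int((diffs <= 0).sum())) / (n_reps + 1)
    p_high = (1 + int((diffs >= 0).sum())) / (n_reps + 1)
    p_diff = min(1.0, 2.0 * min(p_low, p_high))
    return DAFComparison(
        set_a=a, set_b=b, n_reps=n_reps, level=level, seed=seed,
        significant=bool(significant), lower_set=lower, p_diff=float(p_diff),
    )
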
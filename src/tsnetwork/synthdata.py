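"""Synthetic data with known ground truth for the whole pipeline.

Expression is generated on the log scale from a one-factor model: genes of a
planted module share a per-sample latent factor, module genes are boosted in
the target tissue group, and everything is exponentiated to linear-scale
intensities.  Under this model the expected Pearson correlation of two genes
from the same module on the log scale is ``loading^2 / (loading^2 +
noise_sd^2)``, which makes the network stage analytically testable.

Variant tables draw per-SNP derived allele frequencies from per-gene-set Beta
distributions, so a planted constraint shift between sets is exact:
``mean = alpha / (alpha + beta)``.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyDesignError
from .io import write_gmt, write_matrix, write_variants

logger = logging.getLogger(__name__)

DEFAULT_TARGET_TISSUES = tuple(f"heart{i:02d}" for i in range(1, 11))
DEFAULT_OTHER_TISSUES = ("brain", "liver", "kidney", "lung", "muscle")


@dataclass
class ExpressionGenConfig:
    """Design of a synthetic multi-tissue expression experiment.

    Log-scale model for a gene of module m in sample s:
    ``baseline + boost * [tissue(s) in targets] + loading * F_m(s) + eps``
    with F_m(s) ~ N(0,1) shared by the module and eps ~ N(0, noise_sd^2).
    Background genes omit boost and factor.  ``factor_in_target_only``
    restricts the latent factor to target-tissue samples.
    """

    n_tissues: int = 15
    replicates_per_tissue: int = 2
    target_tissues: tuple[str, ...] = DEFAULT_TARGET_TISSUES
    tissues: tuple[str, ...] | None = None
    module_sizes: tuple[int, ...] = (285, 15, 10, 6)
    n_background_genes: int = 2600
    baseline_log_expression: float = 3.0
    target_boost_log: float = 4.0
    factor_loading: float = 1.0
    noise_sd_log: float = 0.33
    factor_in_target_only: bool = False
    seed: int = 17

    def tissue_labels(self) -> tuple[str, ...]:
        if self.tissues is not None:
            return tuple(self.tissues)
        labels = list(self.target_tissues)
        extras = iter(DEFAULT_OTHER_TISSUES + tuple(
            f"other{i:02d}" for i in range(1, self.n_tissues + 1)
        ))
        while len(labels) < self.n_tissues:
            candidate = next(extras)
            if candidate not in labels:
                labels.append(candidate)
        return tuple(labels[: self.n_tissues])

    def validate(self) -> None:
        labels = self.tissue_labels()
        if self.n_tissues < 1 or len(labels) != self.n_tissues:
            raise ValueError(
                f"n_tissues={self.n_tissues} inconsistent with {len(labels)} labels"
            )
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tissue labels")
        if self.replicates_per_tissue < 1:
            raise ValueError("replicates_per_tissue must be >= 1")
        if any(size < 1 for size in self.module_sizes):
            raise ValueError("every module size must be >= 1")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be >= 0")
        if sum(self.module_sizes) + self.n_background_genes == 0:
            raise EmptyDesignError("design has zero genes")
        if self.noise_sd_log <= 0:
            raise ValueError("noise_sd_log must be > 0")
        if not self.target_tissues:
            raise ValueError("target_tissues must be nonempty")
        unknown = set(self.target_tissues) - set(labels)
        if unknown:
            raise ValueError(f"target tissues not in tissue labels: {sorted(unknown)}")


@dataclass
class VariantGenConfig:
    """Per-gene-set Beta(alpha, beta) DAF distributions.

    Defaults plant a downward shift in the constrained ("specific") set:
    Beta(0.3, 3.0) mean 0.091 versus background Beta(0.5, 3.0) mean 0.143.
    """

    set_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"specific": (0.3, 3.0), "background": (0.5, 3.0)}
    )
    snps_per_gene: int = 5
    background_set: str = "background"
    seed: int = 17

    def validate(self) -> None:
        if self.snps_per_gene < 1:
            raise ValueError("snps_per_gene must be >= 1")
        if self.background_set not in self.set_params:
            raise ValueError(
                f"background set {self.background_set!r} has no Beta parameters"
            )
        for name, (alpha, beta) in self.set_params.items():
            if alpha <= 0 or beta <= 0:
                raise ValueError(f"set {name!r}: Beta parameters must be > 0")


@dataclass
class TruthManifest:
    """Ground truth of a generated bundle."""

    gene_module: dict[str, str]
    specificity_class: dict[str, str]
    daf_params: dict[str, tuple[float, float]] = field(default_factory=dict)

    def module_genes(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for gene, module in self.gene_module.items():
            out.setdefault(module, []).append(gene)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": list(self.gene_module),
                "module": list(self.gene_module.values()),
                "specificity_class": [
                    self.specificity_class[g] for g in self.gene_module
                ],
            }
        )


def generate_expression(
    config: ExpressionGenConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthManifest]:
    """Generate (expression matrix, sample annotation, truth manifest).

    Rows: module genes (``modMM_gKKKK``) then background genes
    (``bg_gKKKKK``); columns: ``tissue_rN`` in tissue order.  Values are
    strictly positive linear-scale intensities; identical config and seed
    give identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tissues = config.tissue_labels()
    samples = [
        f"{tissue}_r{rep}"
        for tissue in tissues
        for rep in range(1, config.replicates_per_tissue + 1)
    ]
    sample_tissue = np.repeat(tissues, config.replicates_per_tissue)
    target_mask = np.isin(sample_tissue, config.target_tissues).astype(float)

    gene_ids: list[str] = []
    gene_module: dict[str, str] = {}
    spec_class: dict[str, str] = {}
    for m, size in enumerate(config.module_sizes, start=1):
        label = f"module{m}"
        for k in range(1, size + 1):
            gene = f"mod{m:02d}_g{k:04d}"
            gene_ids.append(gene)
            gene_module[gene] = label
            spec_class[gene] = "target_specific"
    for k in range(1, config.n_background_genes + 1):
        gene = f"bg_g{k:05d}"
        gene_ids.append(gene)
        gene_module[gene] = "background"
        spec_class[gene] = "background"

    n_samples = len(samples)
    n_modules = len(config.module_sizes)
    factors = rng.standard_normal((n_modules, n_samples))
    factor_mask = target_mask if config.factor_in_target_only else np.ones(n_samples)

    log_expr = np.empty((len(gene_ids), n_samples))
    row = 0
    for m, size in enumerate(config.module_sizes):
        signal = (
            config.baseline_log_expression
            + config.target_boost_log * target_mask
            + config.factor_loading * factors[m] * factor_mask
        )
        noise = rng.standard_normal((size, n_samples)) * config.noise_sd_log
        log_expr[row : row + size] = signal[None, :] + noise
        row += size
    if config.n_background_genes:
        noise = rng.standard_normal((config.n_background_genes, n_samples))
        log_expr[row:] = config.baseline_log_expression + noise * config.noise_sd_log

    matrix = pd.DataFrame(np.exp(log_expr), index=gene_ids, columns=samples)
    matrix.index.name = "gene_id"
    annotation = pd.DataFrame({"sample_id": samples, "tissue": sample_tissue})
    manifest = TruthManifest(gene_module=gene_module, specificity_class=spec_class)
    return matrix, annotation, manifest


def generate_variants(
    gene_sets: Mapping[str, Sequence[str]],
    config: VariantGenConfig,
) -> pd.DataFrame:
    """Generate a variant table: snps_per_gene SNPs per gene, DAF ~ set Beta.

    A gene in several sets takes the first set in mapping order; sets without
    Beta parameters fall back to the background set's parameters with a
    warning.
    """
    config.validate()
    assignment: dict[str, str] = {}
    for name, genes in gene_sets.items():
        for gene in genes:
            assignment.setdefault(gene, name)

    rng = np.random.default_rng(config.seed)
    rows: list[tuple[str, str, float]] = []
    for gene, set_name in assignment.items():
        if set_name not in config.set_params:
            logger.warning(
                "gene set %r has no DAF parameters; using background set %r",
                set_name, config.background_set,
            )
            set_name = config.background_set
        alpha, beta = config.set_params[set_name]
        daf = rng.beta(alpha, beta, size=config.snps_per_gene)
        rows.extend(
            (f"{gene}_snp{j}", gene, float(d))
            for j, d in enumerate(daf, start=1)
        )
    return pd.DataFrame(rows, columns=["snp_id", "gene_id", "daf"])


BUNDLE_FILES = (
    "expression.tsv",
    "samples.tsv",
    "gene_sets.gmt",
    "variants.tsv",
    "truth_manifest.tsv",
)


def write_fixture_bundle(
    outdir: str | Path,
    expr_config: ExpressionGenConfig | None = None,
    var_config: VariantGenConfig | None = None,
) -> dict[str, Path]:
    """Write a complete synthetic input bundle; returns name -> path.

    Files: expression.tsv, samples.tsv, gene_sets.gmt (per-module sets plus
    pooled "specific" and "background"), variants.tsv, truth_manifest.tsv.
    Re-running with the same configs reproduces byte-identical files.
    """
    expr_config = expr_config or ExpressionGenConfig()
    var_config = var_config or VariantGenConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    matrix, annotation, manifest = generate_expression(expr_config)
    modules = manifest.module_genes()
    background = modules.pop("background", [])
    specific = [g for genes in modules.values() for g in genes]

    gene_sets: dict[str, list[str]] = {"specific": specific}
    gene_sets.update(modules)
    if background:
        gene_sets["background"] = background

    variants = generate_variants(
        {"specific": specific, "background": background}, var_config
    )
    manifest.daf_params = {
        name: tuple(params) for name, params in var_config.set_params.items()
    }

    paths = {
        "expression": write_matrix(matrix, outdir / "expression.tsv"),
        "samples": outdir / "samples.tsv",
        "gene_sets": write_gmt(gene_sets, outdir / "gene_sets.gmt"),
        "variants": write_variants(variants, outdir / "variants.tsv"),
        "truth_manifest": outdir / "truth_manifest.tsv",
    }
    annotation.to_csv(paths["samples"], sep="\t", index=False)
    manifest.to_frame().to_csv(paths["truth_manifest"], sep="\t", index=False)
    return paths
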
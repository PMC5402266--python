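"""End-to-end orchestration: preprocess -> specificity -> network ->
enrichment -> constraint, driven by a single config with one global seed.

Every stage writes plain-text outputs into the configured output directory
and the run finishes with a ``manifest.json`` listing parameters and the
SHA-256 checksum of every file, so identical config + seed reproduces
identical checksums.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .constraint import compare_daf
from .enrichment import hypergeom_enrichment
from .errors import ConfigError, StageError
from .io import read_gmt, read_variants, sha256_file, write_gmt, write_matrix
from .network import build_network, export_network, mcl_cluster, pearson_matrix
from .preprocess import (
    average_replicates,
    collapse_transcripts,
    median_scale,
    read_expression,
    read_sample_annotation,
    read_transcript_annotation,
)
from .specificity import specificity_table

logger = logging.getLogger(__name__)

STAGES = ("preprocess", "specificity", "network", "enrichment", "constraint")


@dataclass
class PipelineConfig:
    """All inputs and parameters of a full run.

    Defaults mirror the analysis settings the package is built around:
    top fraction 0.2, correlation threshold 0.80, 500 bootstrap replicates
    at the 95% level.
    """

    expression: Path
    sample_annotation: Path
    target_tissues: list[str]
    outdir: Path = Path("results")
    transcript_annotation: Path | None = None
    gene_sets: Path | None = None
    variants: Path | None = None
    fraction: float = 0.2
    correlation_threshold: float = 0.80
    corr_samples: str = "target"  # "target" | "all"
    log_transform_correlation: bool = True
    mcl_inflation: float = 2.0
    mcl_expansion: int = 2
    mcl_prune_below: float = 1e-5
    mcl_max_iter: int = 100
    mcl_tol: float = 1e-6
    daf_reps: int = 500
    daf_level: float = 0.95
    daf_resample: str = "snps"
    seed: int = 17

    def __post_init__(self) -> None:
        self.expression = Path(self.expression)
        self.sample_annotation = Path(self.sample_annotation)
        self.outdir = Path(self.outdir)
        for name in ("transcript_annotation", "gene_sets", "variants"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))
        self.target_tissues = list(self.target_tissues)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config whose keys mirror :class:`PipelineConfig` fields."""
    with open(path, encoding="utf-8") as handle:
        raw = yaml.safe_load(handle) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"unknown config keys: {unknown}")
    missing = [k for k in ("expression", "sample_annotation", "target_tissues")
               if k not in raw]
    if missing:
        raise ConfigError(f"missing required config keys: {missing}")
    return PipelineConfig(**raw)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of human-readable violations; empty means valid."""
    errors: list[str] = []
    if not 0 < config.fraction <= 1:
        errors.append(f"fraction must be in (0, 1], got {config.fraction}")
    if not -1 <= config.correlation_threshold <= 1:
        errors.append(
            "correlation threshold must be in [-1, 1], "
            f"got {config.correlation_threshold}"
        )
    if config.corr_samples not in {"target", "all"}:
        errors.append(
            f"corr_samples must be 'target' or 'all', got {config.corr_samples!r}"
        )
    if config.mcl_inflation <= 1:
        errors.append(f"MCL inflation must exceed 1, got {config.mcl_inflation}")
    if config.mcl_expansion < 2:
        errors.append(f"MCL expansion must be >= 2, got {config.mcl_expansion}")
    if config.daf_reps < 100:
        errors.append(f"daf_reps must be >= 100, got {config.daf_reps}")
    if not 0 < config.daf_level < 1:
        errors.append(f"daf_level must be in (0, 1), got {config.daf_level}")
    if config.daf_resample not in {"snps", "genes"}:
        errors.append(
            f"daf_resample must be 'snps' or 'genes', got {config.daf_resample!r}"
        )
    if not config.target_tissues:
        errors.append("target_tissues must be nonempty")
    for name in ("expression", "sample_annotation", "transcript_annotation",
                 "gene_sets", "variants"):
        path = getattr(config, name)
        if path is not None and not Path(path).is_file():
            errors.append(f"{name} file not found: {path}")
    return errors


def _stage_seed(seed: int, stage_index: int) -> int:
    """Fan the global seed out to a per-stage seed (documented derivation)."""
    return int(
        np.random.SeedSequence(seed, spawn_key=(stage_index,)).generate_state(1)[0]
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns the manifest written to disk."""
    errors = validate_config(config)
    if errors:
        raise ConfigError("; ".join(errors))
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    stage_info: dict[str, dict] = {}

    def _run(stage: str, fn):
        start = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise StageError(stage, str(exc)) from exc
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - start)
        return result

    # --- preprocess ---------------------------------------------------
    def _preprocess():
        matrix = read_expression(config.expression)
        if config.transcript_annotation is not None:
            annotation = read_transcript_annotation(config.transcript_annotation)
            matrix = collapse_transcripts(matrix, annotation)
        matrix = median_scale(matrix)
        samples = read_sample_annotation(config.sample_annotation)
        profile = average_replicates(matrix, samples)
        files["normalized_expression"] = write_matrix(
            matrix, outdir / "normalized_expression.tsv"
        )
        files["tissue_profile"] = write_matrix(
            profile, outdir / "tissue_profile.tsv"
        )
        stage_info["preprocess"] = {
            "genes": int(matrix.shape[0]),
            "samples": int(matrix.shape[1]),
            "tissues": int(profile.shape[1]),
        }
        return matrix, samples, profile

    matrix, samples, profile = _run("preprocess", _preprocess)

    # --- specificity --------------------------------------------------
    def _specificity():
        table = specificity_table(profile, config.target_tissues, config.fraction)
        path = outdir / "specificity.tsv"
        table.to_csv(path, sep="\t", float_format="%.10g")
        files["specificity"] = path
        selected = table.index[table["selected"]].tolist()
        files["selected_genes"] = write_gmt(
            {"selected_tissue_specific": selected},
            outdir / "selected_genes.gmt",
            descriptions={"selected_tissue_specific":
                          f"top {config.fraction:g} by TSI in target tissues"},
        )
        stage_info["specificity"] = {
            "candidates": int(table["max_tissue"].isin(config.target_tissues).sum()),
            "selected": len(selected),
        }
        return selected

    selected = _run("specificity", _specificity)

    # --- network --------------------------------------------------------
    def _network():
        if config.corr_samples == "target":
            targets = set(config.target_tissues)
            corr_samples = samples.loc[
                samples["tissue"].isin(targets), "sample_id"
            ].tolist()
        else:
            corr_samples = matrix.columns.tolist()
        corr = pearson_matrix(
            matrix.loc[selected], corr_samples,
            log_transform=config.log_transform_correlation,
        )
        graph = build_network(corr, threshold=config.correlation_threshold)
        assignment = mcl_cluster(
            graph,
            inflation=config.mcl_inflation,
            expansion=config.mcl_expansion,
            prune_below=config.mcl_prune_below,
            max_iter=config.mcl_max_iter,
            tol=config.mcl_tol,
        )
        files["network_edges"] = export_network(
            graph, assignment, outdir / "network_edges.tsv", fmt="edgelist"
        )
        files["network_graphml"] = export_network(
            graph, assignment, outdir / "network.graphml", fmt="graphml"
        )
        path = outdir / "clusters.tsv"
        assignment.to_frame().to_csv(path, sep="\t", index=False)
        files["clusters"] = path
        stage_info["network"] = {
            "nodes": graph.number_of_nodes(),
            "edges": graph.number_of_edges(),
            "clusters": len(assignment.sizes),
            "multigene_clusters": sum(
                1 for size in assignment.sizes.values() if size >= 2
            ),
            "mcl_converged": assignment.converged,
            "mcl_iterations": assignment.n_iter,
        }
        return graph, assignment

    _run("network", _network)

    # --- enrichment -------------------------------------------------------
    if config.gene_sets is not None:
        def _enrichment():
            collection = read_gmt(config.gene_sets)
            universe = matrix.index.tolist()
            result = hypergeom_enrichment(
                set(selected) & set(universe), collection, universe
            )
            path = outdir / "enrichment.tsv"
            result.to_csv(path, sep="\t", index=False, float_format="%.6g")
            files["enrichment"] = path
            stage_info["enrichment"] = {"sets_tested": int(len(result))}

        _run("enrichment", _enrichment)

    # --- constraint -------------------------------------------------------
    if config.variants is not None:
        def _constraint():
            variants = read_variants(config.variants)
            universe = set(matrix.index) & set(variants["gene_id"])
            comparison = compare_daf(
                variants,
                set_a=set(selected) & universe,
                set_b=universe,
                n_reps=config.daf_reps,
                level=config.daf_level,
                seed=_stage_seed(config.seed, STAGES.index("constraint")),
                names=("tissue_specific", "all_genes"),
                resample=config.daf_resample,
            )
            path = outdir / "daf_comparison.json"
            with open(path, "w", encoding="utf-8") as handle:
                json.dump(comparison.to_dict(), handle, indent=2, sort_keys=True)
                handle.write("\n")
            files["daf_comparison"] = path
            stage_info["constraint"] = {
                "significant": comparison.significant,
                "lower_set": comparison.lower_set,
            }

        _run("constraint", _constraint)

    # --- manifest ------------------------------------------------------
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            key: (str(value) if isinstance(value, Path) else value)
            for key, value in dataclasses.asdict(config).items()
        },
        "stages": stage_info,
        "files": {
            name: {"path": path.name, "sha256": sha256_file(path)}
            for name, path in sorted(files.items())
        },
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return manifest
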
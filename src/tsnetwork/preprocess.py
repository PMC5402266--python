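"""Expression-matrix preprocessing.

Reads linear-scale expression matrices, normalizes between arrays by scaling
every column to a common median, collapses transcript-level rows to one row
per gene (smallest CDS-covering transcript wins), and averages replicate
samples into per-tissue mean profiles.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateArrayError, ParseError

logger = logging.getLogger(__name__)


def validate_expression(matrix: pd.DataFrame, source: str = "expression matrix") -> None:
    """Check the expression-matrix contract: unique ids, finite nonnegative values."""
    if matrix.index.has_duplicates:
        dups = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ParseError(f"{source}: duplicate row ids: {dups[:10]}")
    if matrix.columns.has_duplicates:
        dups = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise ParseError(f"{source}: duplicate column ids: {dups[:10]}")
    values = matrix.to_numpy()
    if not np.all(np.isfinite(values)):
        rows = matrix.index[~np.isfinite(values).all(axis=1)].tolist()
        raise ParseError(f"{source}: non-finite or missing values in rows {rows[:10]}")
    if (values < 0).any():
        rows = matrix.index[(values < 0).any(axis=1)].tolist()
        raise ParseError(f"{source}: negative values in rows {rows[:10]} "
                         "(linear-scale intensities must be >= 0)")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a gene/transcript x sample TSV (first column = row id, header = samples).

    Raises :class:`ParseError` for duplicate ids, ragged rows, missing or
    non-numeric cells, or negative values.
    """
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: ragged or malformed TSV: {exc}") from exc
    matrix = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = raw.index[converted.isna()]
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric or missing value in column {col!r}, "
                f"rows {bad.tolist()[:5]}"
            )
        matrix[col] = converted.astype(float)
    validate_expression(matrix, source=str(path))
    return matrix


def median_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale every column (array) to share a common median.

    The reference is the median of the per-column medians; column *j* is
    multiplied by ``reference / median_j``.  Idempotent up to floating point.
    """
    medians = matrix.median(axis=0)
    zero = medians.index[medians <= 0].tolist()
    if zero:
        raise DegenerateArrayError(
            f"columns with non-positive median cannot be scaled: {zero[:10]}"
        )
    reference = float(medians.median())
    return matrix * (reference / medians)


def read_transcript_annotation(path: str | Path) -> pd.DataFrame:
    """Read transcript_id / gene_id / length / covers_cds TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "gene_id": str})
    required = ["transcript_id", "gene_id", "length", "covers_cds"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    if df["transcript_id"].duplicated().any():
        dups = df["transcript_id"][df["transcript_id"].duplicated()].tolist()
        raise ParseError(f"{path}: duplicate transcript ids: {dups[:10]}")
    df["length"] = pd.to_numeric(df["length"], errors="raise")
    if (df["length"] <= 0).any():
        raise ParseError(f"{path}: transcript lengths must be > 0")
    df["covers_cds"] = df["covers_cds"].map(
        lambda v: str(v).strip().lower() in {"true", "1", "yes", "t"}
    )
    return df.loc[:, required]


def collapse_transcripts(
    matrix: pd.DataFrame, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Collapse transcript rows to one row per gene.

    Per gene, the retained row is the CDS-covering transcript of minimal
    length; ties break on lexicographically smaller transcript id.  Genes
    with no CDS-covering transcript fall back to the overall smallest
    transcript, with a logged warning.
    """
    annotated = set(annotation["transcript_id"])
    unknown = [t for t in matrix.index if t not in annotated]
    if unknown:
        raise ParseError(f"transcripts absent from annotation: {unknown[:10]}")

    ann = annotation[annotation["transcript_id"].isin(matrix.index)]
    chosen: dict[str, str] = {}
    for gene_id, group in ann.groupby("gene_id", sort=True):
        covering = group[group["covers_cds"]]
        pool = covering
        if pool.empty:
            pool = group
            logger.warning(
                "gene %s has no CDS-covering transcript; keeping overall smallest",
                gene_id,
            )
        pick = pool.sort_values(["length", "transcript_id"]).iloc[0]
        chosen[gene_id] = pick["transcript_id"]

    collapsed = matrix.loc[[chosen[g] for g in sorted(chosen)]].copy()
    collapsed.index = pd.Index(sorted(chosen), name="gene_id")
    return collapsed


def read_sample_annotation(path: str | Path) -> pd.DataFrame:
    """Read sample_id / tissue (/ optional time_point) TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "tissue"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    if df["sample_id"].duplicated().any():
        dups = df["sample_id"][df["sample_id"].duplicated()].tolist()
        raise ParseError(f"{path}: duplicate sample ids: {dups[:10]}")
    return df


def average_replicates(
    matrix: pd.DataFrame,
    sample_annotation: pd.DataFrame,
    per_time: bool = False,
) -> pd.DataFrame:
    """Average replicate samples into per-tissue mean profiles.

    When a ``time_point`` column is present, samples are first averaged
    within each (tissue, time point) group and those group means are then
    averaged per tissue, so no time point dominates through replicate count.
    With ``per_time=True`` the per-(tissue, time point) profile is returned
    instead, with columns labelled ``tissue|time``.

    Tissue column order follows first appearance in the annotation.
    """
    ann = sample_annotation
    unannotated = [s for s in matrix.columns if s not in set(ann["sample_id"])]
    if unannotated:
        raise ParseError(f"samples without tissue annotation: {unannotated[:10]}")
    ann = ann[ann["sample_id"].isin(matrix.columns)]
    tissues = list(dict.fromkeys(ann["tissue"]))
    empty = [t for t in dict.fromkeys(sample_annotation["tissue"]) if t not in tissues]
    if empty:
        raise ParseError(f"tissues with zero samples in the matrix: {empty[:10]}")

    has_time = "time_point" in ann.columns and ann["time_point"].notna().any()
    if has_time:
        groups = ann.groupby(["tissue", "time_point"], sort=False)["sample_id"]
        group_means = {
            (tissue, time): matrix[list(samples)].mean(axis=1)
            for (tissue, time), samples in groups
        }
        if per_time:
            profile = pd.DataFrame(
                {f"{t}|{tp}": vals for (t, tp), vals in group_means.items()}
            )
            return profile
        profile = pd.DataFrame(
            {
                tissue: pd.concat(
                    [v for (t, _), v in group_means.items() if t == tissue], axis=1
                ).mean(axis=1)
                for tissue in tissues
            }
        )
        return profile

    groups = ann.groupby("tissue", sort=False)["sample_id"]
    profile = pd.DataFrame(
        {tissue: matrix[list(samples)].mean(axis=1) for tissue, samples in groups}
    )
    return profile.loc[:, tissues]
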
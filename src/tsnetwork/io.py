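"""Readers and writers for the plain-text formats used across the pipeline.

Formats
-------
GMT
    One gene set per line: ``name<TAB>description<TAB>gene1<TAB>gene2...``.
Variant TSV
    Columns ``snp_id``, ``gene_id``, ``daf`` with ``daf`` in [0, 1].
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = ("snp_id", "gene_id", "daf")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into an ordered mapping ``set name -> member gene ids``.

    Duplicate members within a set are dropped (first occurrence kept);
    duplicate set names are an error.
    """
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT lines need at least "
                    f"name, description and one gene (got {len(fields)} fields)"
                )
            name = fields[0]
            if name in sets:
                raise ParseError(f"{path}: line {lineno}: duplicate set name {name!r}")
            members = [g for g in fields[2:] if g]
            if not members:
                raise ParseError(f"{path}: line {lineno}: set {name!r} has no members")
            sets[name] = list(dict.fromkeys(members))
    return sets


def write_gmt(
    sets: Mapping[str, Iterable[str]],
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> Path:
    """Write gene sets to a GMT file; returns the path written."""
    path = Path(path)
    descriptions = descriptions or {}
    with open(path, "w", encoding="utf-8") as handle:
        for name, members in sets.items():
            desc = descriptions.get(name, "na")
            handle.write("\t".join([name, desc, *members]) + "\n")
    return path


def read_variants(path: str | Path) -> pd.DataFrame:
    """Read a per-SNP table with columns snp_id, gene_id, daf.

    Validates that SNP ids are unique and every DAF lies in [0, 1].
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "gene_id": str})
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    df = df.loc[:, list(VARIANT_COLUMNS)]
    dup = df["snp_id"][df["snp_id"].duplicated()]
    if not dup.empty:
        raise ParseError(f"{path}: duplicate snp ids: {sorted(set(dup))[:10]}")
    daf = pd.to_numeric(df["daf"], errors="coerce")
    if daf.isna().any():
        bad = df.loc[daf.isna(), "snp_id"].tolist()[:10]
        raise ParseError(f"{path}: non-numeric daf values at snps {bad}")
    if ((daf < 0) | (daf > 1)).any():
        bad = df.loc[(daf < 0) | (daf > 1), "snp_id"].tolist()[:10]
        raise ParseError(f"{path}: daf outside [0, 1] at snps {bad}")
    df["daf"] = daf.astype(float)
    return df


def write_variants(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a variant table to TSV with a stable float format."""
    path = Path(path)
    df.loc[:, list(VARIANT_COLUMNS)].to_csv(
        path, sep="\t", index=False, float_format="%.8g"
    )
    return path


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "gene_id") -> Path:
    """Write a numeric matrix (rows = genes, columns = samples/tissues) to TSV."""
    path = Path(path)
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")
    return path


def sha256_file(path: str | Path) -> str:
    """Hex digest of a file's contents (used by the run manifest)."""
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def as_float_array(values, name: str = "values") -> np.ndarray:
    """Coerce to a 1-D float array, rejecting NaN/inf."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr
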
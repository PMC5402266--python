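"""Small gene-set fixtures shipped with the package."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .io import read_gmt


def chd_candidates_path() -> Path:
    """Path to the packaged CHD candidate gene-set GMT."""
    return Path(resources.files("tsnetwork.data") / "chd_candidates.gmt")


def load_chd_candidates() -> dict[str, list[str]]:
    """The packaged CHD (congenital heart disease) candidate gene set."""
    return read_gmt(chd_candidates_path())
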
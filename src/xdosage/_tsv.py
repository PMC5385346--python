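"""Shared TSV I/O with a commented provenance header line."""

from __future__ import annotations

import io
from pathlib import Path

import pandas as pd

from . import __version__


def format_params(params: dict | None) -> str:
    if not params:
        return ""
    return " ".join(f"{k}={v}" for k, v in sorted(params.items()))


def write_table(df: pd.DataFrame, path: str | Path, params: dict | None = None,
                index: bool = True) -> Path:
    """Write ``df`` as TSV preceded by a single ``#`` comment line recording
    the tool version and the parameters that produced the table."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = f"# xdosage {__version__} {format_params(params)}".rstrip()
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=index)
    path.write_text(header + "\n" + buf.getvalue())
    return path


def read_table(path: str | Path, index_col=0) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (comment lines skipped)."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
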
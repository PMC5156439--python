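"""Tab-separated table I/O with ``# key=value`` header metadata.

All pipeline artifacts are plain TSV: '.' decimal separator, one header
line of column names, optional leading comment lines of the form
``# key=value`` carrying provenance (seed, strain, stage parameters).
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path
from typing import Any

import pandas as pd

#: strains with a packaged phenotype table
PACKAGED_STRAINS = ("IL1403", "KF147", "SK11")

_SURVIVAL_COL = re.compile(r"^(?P<stress>[a-z]+)_(?P<minutes>\d+)min_pct$")


class MalformedTableError(ValueError):
    """Raised when a TSV cannot be parsed; message carries the line number."""


def write_tsv(df: pd.DataFrame, path: str | Path, meta: dict[str, Any] | None = None,
              index: bool = False) -> None:
    """Write *df* to *path*, preceded by ``# key=value`` metadata lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, index_col: str | int | None = None
             ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a TSV written by :func:`write_tsv`.

    Returns the data frame and the parsed metadata dict. Parse failures are
    reported as :class:`MalformedTableError` with the offending line number.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_meta = 0
    for line in lines:
        if not line.startswith("#"):
            break
        n_meta += 1
        body = line.lstrip("#").strip()
        if "=" in body:
            key, _, value = body.partition("=")
            meta[key.strip()] = value.strip()
    from io import StringIO

    try:
        df = pd.read_csv(StringIO("".join(lines[n_meta:])), sep="\t",
                         index_col=index_col)
    except pd.errors.EmptyDataError as exc:
        raise MalformedTableError(f"{path}: empty table") from exc
    except pd.errors.ParserError as exc:  # pragma: no cover - message shape
        msg = str(exc)
        m = re.search(r"line (\d+)", msg)
        line_no = int(m.group(1)) + n_meta if m else None
        raise MalformedTableError(
            f"{path}: malformed TSV"
            + (f" at line {line_no}" if line_no else "") + f": {msg}") from exc
    if df.empty and df.columns.size == 0:
        raise MalformedTableError(f"{path}: empty table")
    return df, meta


def survival_columns(df: pd.DataFrame) -> dict[tuple[str, int], str]:
    """Map ``(stress, minutes)`` to the matching ``<stress>_<t>min_pct`` column."""
    out: dict[tuple[str, int], str] = {}
    for col in df.columns:
        m = _SURVIVAL_COL.match(str(col))
        if m:
            out[(m.group("stress"), int(m.group("minutes")))] = col
    return out


def load_packaged_phenotypes(strain: str) -> pd.DataFrame:
    """Load the packaged per-strain phenotype table (13 fermentations).

    Columns: fermentation design factors, growth summary (``mu``,
    ``od_final``) and percent-survival columns per stress/timepoint.
    """
    if strain not in PACKAGED_STRAINS:
        raise KeyError(f"no packaged phenotype table for strain {strain!r}; "
                       f"choose one of {PACKAGED_STRAINS}")
    ref = resources.files("robustsig.data") / f"phenotypes_{strain}.tsv"
    with resources.as_file(ref) as path:
        df, _ = read_tsv(path)
    return df
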
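"""Readers and writers for wide-format longitudinal data.

CSV is the canonical interchange (comma, UTF-8, "." decimal, literal
``NA`` for missing); Excel ``.xlsx`` and Stata ``.dta`` are supported
as best-effort exports. Tri-state flag columns serialise as TRUE/FALSE/
NA (per-criterion) and 1/0/NA (combined), matching the flag-table
semantics.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .identify import DataError, WideDataset

__all__ = ["expand_columns", "read_table", "read_wide", "write_outputs", "to_long"]

_NA_STRINGS = ["", "NA", "NaN", "nan", "N/A", "na"]

_RANGE_RE = re.compile(r"^(?P<prefix>.*?)(?P<start>\d+)\s*:\s*(?P=prefix)?(?P<stop>\d+)$")


def expand_columns(spec: Union[str, Sequence[str]]) -> list:
    """Expand a session-column shorthand like ``"bdi_s1:bdi_s12"``.

    A list is passed through (with any range items expanded); a plain
    comma-separated string is split. The range endpoints must share the
    same prefix.
    """
    if isinstance(spec, str):
        items = [s.strip() for s in spec.split(",") if s.strip()]
    else:
        items = list(spec)
    out = []
    for item in items:
        if isinstance(item, str) and ":" in item:
            m = _RANGE_RE.match(item)
            if not m:
                raise DataError(f"cannot parse column range {item!r}")
            prefix = m.group("prefix")
            start, stop = int(m.group("start")), int(m.group("stop"))
            if stop < start:
                raise DataError(f"descending column range {item!r}")
            out.extend(f"{prefix}{k}" for k in range(start, stop + 1))
        else:
            out.append(item)
    return out


def _detect_format(path: Path, format: Optional[str]) -> str:
    if format:
        return format.lstrip(".").lower()
    suffix = path.suffix.lstrip(".").lower()
    if suffix in ("csv", "tsv", "txt", "xlsx", "dta"):
        return "tsv" if suffix == "txt" else suffix
    raise DataError(f"cannot infer file format from {path.name!r}; pass format=")


def read_table(path, format: Optional[str] = None) -> pd.DataFrame:
    """Read a delimited/Excel/Stata file into a DataFrame, NA-aware."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"file not found: {path}")
    fmt = _detect_format(path, format)
    if fmt == "csv":
        return pd.read_csv(path, na_values=_NA_STRINGS, keep_default_na=True)
    if fmt == "tsv":
        return pd.read_csv(path, sep="\t", na_values=_NA_STRINGS, keep_default_na=True)
    if fmt == "xlsx":
        return pd.read_excel(path, na_values=_NA_STRINGS)
    if fmt == "dta":
        return pd.read_stata(path)
    raise DataError(f"unsupported input format {fmt!r}")


def read_wide(
    path,
    id_column: str,
    session_columns: Union[str, Sequence[str]],
    secondary_columns: Union[str, Sequence[str], None] = None,
    measure_name: str = "score",
    format: Optional[str] = None,
) -> WideDataset:
    """Read a wide-format dataset and validate/coerce the score columns.

    Empty and NA-coded cells become missing values; any other cell that
    fails numeric coercion is reported with its subject id and column.
    """
    frame = read_table(path, format)
    session_columns = expand_columns(session_columns)
    if secondary_columns is not None:
        secondary_columns = expand_columns(secondary_columns)
    missing_cols = [
        c for c in [id_column] + session_columns + (secondary_columns or [])
        if c not in frame.columns
    ]
    if missing_cols:
        raise DataError(f"columns not found in {path}: {', '.join(missing_cols)}")
    bad_cells = []
    for col in session_columns + (secondary_columns or []):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        newly_na = coerced.isna() & frame[col].notna()
        for i in frame.index[newly_na]:
            bad_cells.append(f"{id_column}={frame.at[i, id_column]!r} "
                             f"{col}={frame.at[i, col]!r}")
        frame[col] = coerced
    if bad_cells:
        raise DataError(
            "non-numeric score cells: " + "; ".join(bad_cells[:20])
            + ("; ..." if len(bad_cells) > 20 else "")
        )
    return WideDataset(
        data=frame,
        id_column=id_column,
        session_columns=session_columns,
        secondary_columns=secondary_columns,
        measure_name=measure_name,
    )


def _serialise_tristate(frame: pd.DataFrame) -> pd.DataFrame:
    """Boolean criterion columns -> TRUE/FALSE/NA strings; Int64 stays 1/0/NA."""
    out = frame.copy()
    for col in out.columns:
        if pd.api.types.is_bool_dtype(out[col]):
            out[col] = out[col].map({True: "TRUE", False: "FALSE"}).astype(object)
    return out


def write_outputs(frame: pd.DataFrame, path, format: Optional[str] = None) -> None:
    """Write any of this package's tabular outputs to csv/tsv/xlsx/dta.

    Missing values are written as literal ``NA`` in delimited formats.
    An empty table still writes its header.
    """
    if frame is None:
        raise DataError("nothing to write")
    path = Path(path)
    fmt = _detect_format(path, format)
    frame = _serialise_tristate(frame)
    if fmt == "csv":
        frame.to_csv(path, index=False, na_rep="NA")
    elif fmt == "tsv":
        frame.to_csv(path, index=False, na_rep="NA", sep="\t")
    elif fmt == "xlsx":
        frame.to_excel(path, index=False, na_rep="NA")
    elif fmt == "dta":
        out = frame.copy()
        for col in out.columns:
            dt = out[col].dtype
            if isinstance(dt, (pd.Int64Dtype, pd.BooleanDtype)):
                out[col] = out[col].astype(float)
        out.columns = [re.sub(r"[^A-Za-z0-9_]", "_", str(c)) for c in out.columns]
        out.to_stata(path, write_index=False)
    else:
        raise DataError(f"unsupported output format {fmt!r}")


def to_long(dataset: WideDataset) -> pd.DataFrame:
    """Reshape helper: the primary measure as long-format (id, session, value)."""
    frame = dataset.data[[dataset.id_column] + list(dataset.session_columns)]
    long = frame.melt(id_vars=dataset.id_column, var_name="session_column",
                      value_name="value")
    order = {c: i + 1 for i, c in enumerate(dataset.session_columns)}
    long["session"] = long["session_column"].map(order)
    long = long.drop(columns="session_column").sort_values(
        [dataset.id_column, "session"], kind="stable"
    ).reset_index(drop=True)
    return long[[dataset.id_column, "session", "value"]]
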
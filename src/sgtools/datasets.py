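"""Analysis datasets built from identified gains.

Two shapes are produced: ``bysg`` has one row per identified sudden
gain (or loss) and ``byperson`` one row per subject, gainer or not.
Each gain row carries the pregain session number, the six scores around
the gain (x_{n-2} .. x_{n+3}), its raw magnitude, its share of the
total treatment change, and the 50%-loss reversal status: a gain is
counted as reversed if, at any session after the postgain measurement,
the score returns to or beyond the midpoint of the pregain and postgain
scores. The original session columns are carried along so secondary
measures and plots can be joined by id.
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .criteria import CriteriaConfig, TriState
from .identify import DataError, GainFlagTable, WideDataset, identify_sg, identify_sl

__all__ = [
    "reversal_value",
    "reversal_occurred",
    "create_bysg",
    "create_byperson",
    "extract_values",
]

logger = logging.getLogger("sgtools")

_POSITIONS = ("2n", "1n", "n", "n1", "n2", "n3")
SELECTORS = ("first", "last", "smallest", "largest")


def reversal_value(x_n: float, x_n1: float) -> float:
    """Score at or beyond which a gain from x_n to x_n1 counts as reversed.

    The 50%-loss rule puts the threshold at the arithmetic midpoint:
    x_{n+1} + 0.5 * (x_n - x_{n+1}). A 40-to-30 gain reverses at 35 or
    more.
    """
    if x_n is None or x_n1 is None or (
        isinstance(x_n, float) and math.isnan(x_n)
    ) or (isinstance(x_n1, float) and math.isnan(x_n1)):
        raise ValueError("reversal_value requires both pregain and postgain scores")
    return x_n1 + 0.5 * (x_n - x_n1)


def reversal_occurred(
    later_scores: Sequence, threshold: float, direction: str = "gain"
) -> bool:
    """Whether any later observed score crosses the reversal threshold.

    ``later_scores`` are the observed values at sessions n+2 onwards
    (missing values skipped). Inclusive: a score exactly at the
    threshold counts. For losses the comparison mirrors (at or below).
    """
    vals = [
        float(v) for v in later_scores
        if v is not None and not (isinstance(v, float) and math.isnan(v))
    ]
    if direction == "gain":
        return any(v >= threshold for v in vals)
    return any(v <= threshold for v in vals)


def _gain_records(
    data: WideDataset,
    config: CriteriaConfig,
    tx_start_var: str,
    tx_end_var: str,
    measure_name: str,
    flags: Optional[GainFlagTable],
) -> list:
    for col in (tx_start_var, tx_end_var):
        if col not in data.data.columns:
            raise DataError(f"treatment start/end column not found: {col!r}")
    if flags is None:
        flags = identify_sg(data, config) if config.direction == "gain" else identify_sl(data, config)
    flagged = flags.flagged()
    counts: dict = {}
    for sid, _ in flagged:
        counts[sid] = counts.get(sid, 0) + 1

    m = measure_name
    records = []
    for sid, n in flagged:
        series = data.series(sid)
        window = series.window(n)
        x_n, x_n1 = window[2], window[3]
        if config.direction == "gain":
            magnitude = x_n - x_n1
        else:
            magnitude = x_n1 - x_n
        row = data.data.loc[data.data[data.id_column] == sid].iloc[0]
        tx_start = pd.to_numeric(pd.Series([row[tx_start_var]]), errors="coerce").iloc[0]
        tx_end = pd.to_numeric(pd.Series([row[tx_end_var]]), errors="coerce").iloc[0]
        if pd.isna(tx_start) or pd.isna(tx_end):
            tx_change = np.nan
        elif config.direction == "gain":
            tx_change = float(tx_start) - float(tx_end)
        else:
            tx_change = float(tx_end) - float(tx_start)
        if not pd.isna(tx_change) and tx_change > 0:
            proportion = magnitude / tx_change
        else:
            proportion = np.nan
            if not pd.isna(tx_change):
                logger.warning(
                    "subject %s: total treatment change %.3g is not an "
                    "improvement; sg_change_proportion set to missing",
                    sid, tx_change,
                )
        rev_value = reversal_value(x_n, x_n1)
        later = [series.value_at(s) for s in range(n + 2, series.n_sessions + 1)]
        reversed_flag = reversal_occurred(later, rev_value, config.direction)
        rec = {
            data.id_column: sid,
            "id_sg": f"{sid}_sg{n}",
            "sg_crit123": 1,
            "sg_session_n": n,
            "sg_freq_byperson": counts[sid],
        }
        for pos, val in zip(_POSITIONS, window):
            rec[f"sg_{m}_{pos}"] = np.nan if val is None else val
        rec.update({
            "sg_magnitude": magnitude,
            f"sg_{m}_tx_change": tx_change,
            "sg_change_proportion": proportion,
            "sg_reversal_value": rev_value,
            "sg_reversal": int(reversed_flag),
        })
        records.append(rec)
    return records


def _schema_columns(id_column: str, measure_name: str) -> list:
    m = measure_name
    return (
        [id_column, "id_sg", "sg_crit123", "sg_session_n", "sg_freq_byperson"]
        + [f"sg_{m}_{pos}" for pos in _POSITIONS]
        + ["sg_magnitude", f"sg_{m}_tx_change", "sg_change_proportion",
           "sg_reversal_value", "sg_reversal"]
    )


_INT_FIELDS = ("sg_crit123", "sg_session_n", "sg_freq_byperson", "sg_reversal")


def _attach_metadata(df: pd.DataFrame, data: WideDataset, config: CriteriaConfig,
                     measure_name: str, shape: str, selector: Optional[str] = None) -> pd.DataFrame:
    for col in _INT_FIELDS:
        df[col] = df[col].astype("Int64")  # nullable: non-gainers have no session
    df.attrs.update({
        "measure_name": measure_name,
        "n_sessions": data.n_sessions,
        "session_columns": list(data.session_columns),
        "id_column": data.id_column,
        "direction": config.direction,
        "shape": shape,
    })
    if selector is not None:
        df.attrs["selector"] = selector
    return df


def create_bysg(
    data: WideDataset,
    config: CriteriaConfig,
    tx_start_var: str,
    tx_end_var: str,
    measure_name: str = "sg",
    flags: Optional[GainFlagTable] = None,
) -> pd.DataFrame:
    """One row per identified sudden gain (or loss), with the full variable set.

    Column names embed ``measure_name`` (``sg_bdi_n`` etc.); the
    original session columns are appended so downstream joins and plots
    need no second lookup. A dataset with no gains comes back empty but
    with the full schema.
    """
    records = _gain_records(data, config, tx_start_var, tx_end_var, measure_name, flags)
    cols = _schema_columns(data.id_column, measure_name)
    bysg = pd.DataFrame.from_records(records, columns=cols)
    bysg = bysg.sort_values(
        [data.id_column, "sg_session_n"], kind="stable"
    ).reset_index(drop=True)
    raw = data.data[[data.id_column] + list(data.session_columns)]
    bysg = bysg.merge(raw, on=data.id_column, how="left")
    return _attach_metadata(bysg, data, config, measure_name, "bysg")


def create_byperson(
    data: WideDataset,
    config: CriteriaConfig,
    tx_start_var: str,
    tx_end_var: str,
    measure_name: str = "sg",
    selector: str = "first",
    flags: Optional[GainFlagTable] = None,
) -> pd.DataFrame:
    """One row per subject; gain fields describe one selected gain.

    For subjects with several gains, ``selector`` picks which gain the
    row describes: ``first``/``last`` by pregain session, ``smallest``/
    ``largest`` by magnitude (ties broken by earlier session).
    Non-gainers keep the row with sg_crit123 = 0 and missing gain
    fields.
    """
    if selector not in SELECTORS:
        raise DataError(f"selector must be one of {SELECTORS}, got {selector!r}")
    records = _gain_records(data, config, tx_start_var, tx_end_var, measure_name, flags)
    cols = _schema_columns(data.id_column, measure_name)
    per_subject = {}
    for rec in records:
        per_subject.setdefault(rec[data.id_column], []).append(rec)

    def pick(recs: list) -> dict:
        if selector == "first":
            return min(recs, key=lambda r: r["sg_session_n"])
        if selector == "last":
            return max(recs, key=lambda r: r["sg_session_n"])
        if selector == "smallest":
            return min(recs, key=lambda r: (r["sg_magnitude"], r["sg_session_n"]))
        return max(recs, key=lambda r: (r["sg_magnitude"], -r["sg_session_n"]))

    rows = []
    for sid in data.subject_ids:
        if sid in per_subject:
            rows.append(pick(per_subject[sid]))
        else:
            row = {c: np.nan for c in cols}
            row[data.id_column] = sid
            row["sg_crit123"] = 0
            row["sg_freq_byperson"] = 0
            rows.append(row)
    byperson = pd.DataFrame.from_records(rows, columns=cols)
    raw = data.data[[data.id_column] + list(data.session_columns)]
    byperson = byperson.merge(raw, on=data.id_column, how="left")
    return _attach_metadata(byperson, data, config, measure_name, "byperson",
                            selector=selector)


def extract_values(
    target: pd.DataFrame,
    data: WideDataset,
    extract_columns: Sequence[str],
    extract_measure_name: str,
) -> pd.DataFrame:
    """Add a secondary measure's scores around each gain to a bysg/byperson table.

    ``extract_columns`` must parallel the primary session columns one to
    one — same count, same measurement occasions — so that position k is
    the secondary score at session k+1. For each row with a pregain
    session n, columns ``sg_<m>_2n .. sg_<m>_n3`` receive the secondary
    values at sessions n-2 .. n+3; sessions outside the series are
    missing, as are all six for rows without a gain.
    """
    extract_columns = list(extract_columns)
    if len(extract_columns) != data.n_sessions:
        raise DataError(
            f"extract_columns has {len(extract_columns)} entries but the primary "
            f"measure has {data.n_sessions} sessions; the two lists must align "
            "one to one at the same measurement occasions"
        )
    missing = [c for c in extract_columns if c not in data.data.columns]
    if missing:
        raise DataError(f"columns not found in data: {', '.join(map(str, missing))}")
    id_col = data.id_column
    if id_col not in target.columns or "sg_session_n" not in target.columns:
        raise DataError(
            f"target must carry {id_col!r} and 'sg_session_n' columns "
            "(a bysg or byperson dataset)"
        )
    m2 = extract_measure_name
    wide = data.data.set_index(id_col)
    out = target.copy()
    new_cols = {f"sg_{m2}_{pos}": [] for pos in _POSITIONS}
    for _, row in target.iterrows():
        n = row["sg_session_n"]
        if pd.isna(n):
            for pos in _POSITIONS:
                new_cols[f"sg_{m2}_{pos}"].append(np.nan)
            continue
        n = int(n)
        subj = wide.loc[row[id_col]]
        for pos, sess in zip(_POSITIONS, range(n - 2, n + 4)):
            if 1 <= sess <= data.n_sessions:
                val = pd.to_numeric(
                    pd.Series([subj[extract_columns[sess - 1]]]), errors="coerce"
                ).iloc[0]
            else:
                val = np.nan
            new_cols[f"sg_{m2}_{pos}"].append(val)
    for col, vals in new_cols.items():
        out[col] = vals
    out.attrs = dict(target.attrs)
    return out
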
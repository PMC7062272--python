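"""Descriptive statistics and plot-ready aggregates for gain datasets."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .identify import DataError, WideDataset

__all__ = ["GainSummary", "describe_sg", "average_gain_profile", "trajectory_data"]

_POSITIONS = ("2n", "1n", "n", "n1", "n2", "n3")


@dataclass(frozen=True)
class GainSummary:
    """Counts and moments summarising the gains in a dataset.

    Subject-level counts come from the byperson table, gain-level counts
    and moments from bysg. ``mean_magnitude`` and ``sd_magnitude`` are
    NaN when there are no gains.
    """

    n_subjects: int
    n_gainers: int
    pct_gainers: float
    n_multigainers: int
    total_gains: int
    mean_magnitude: float
    sd_magnitude: float
    n_reversed: int
    pct_reversed: float
    mean_session_n: float

    def to_dict(self) -> dict:
        return asdict(self)

    def __str__(self) -> str:
        what = "gain"
        lines = [
            f"subjects analysed:            {self.n_subjects}",
            f"subjects with a sudden {what}: {self.n_gainers} "
            f"({100 * self.pct_gainers:.1f}%)",
            f"subjects with multiple {what}s: {self.n_multigainers}",
            f"total sudden {what}s:          {self.total_gains}",
            f"mean {what} magnitude:         "
            + (f"{self.mean_magnitude:.2f} (SD {self.sd_magnitude:.2f})"
               if self.total_gains else "NA"),
            f"reversed {what}s:              {self.n_reversed} "
            + (f"({100 * self.pct_reversed:.1f}%)" if self.total_gains else ""),
            f"mean pregain session:         "
            + (f"{self.mean_session_n:.2f}" if self.total_gains else "NA"),
        ]
        return "\n".join(lines)


def describe_sg(bysg: pd.DataFrame, byperson: pd.DataFrame) -> GainSummary:
    """Summarise gains from matching bysg and byperson datasets."""
    m_b = bysg.attrs.get("measure_name")
    m_p = byperson.attrs.get("measure_name")
    if m_b is not None and m_p is not None and m_b != m_p:
        raise DataError(
            f"bysg measure {m_b!r} does not match byperson measure {m_p!r}"
        )
    n_subjects = len(byperson)
    gainers = byperson[byperson["sg_crit123"] == 1]
    n_gainers = int(len(gainers))
    total_gains = int(len(bysg))
    if total_gains:
        freq = bysg.groupby(bysg.columns[0])["sg_freq_byperson"].first()
        n_multi = int((freq > 1).sum())
        mean_mag = float(bysg["sg_magnitude"].mean())
        sd_mag = float(bysg["sg_magnitude"].std(ddof=1)) if total_gains > 1 else float("nan")
        n_rev = int((bysg["sg_reversal"] == 1).sum())
        pct_rev = n_rev / total_gains
        mean_n = float(bysg["sg_session_n"].mean())
    else:
        n_multi, n_rev = 0, 0
        mean_mag = sd_mag = mean_n = float("nan")
        pct_rev = float("nan")
    return GainSummary(
        n_subjects=n_subjects,
        n_gainers=n_gainers,
        pct_gainers=(n_gainers / n_subjects) if n_subjects else float("nan"),
        n_multigainers=n_multi,
        total_gains=total_gains,
        mean_magnitude=mean_mag,
        sd_magnitude=sd_mag,
        n_reversed=n_rev,
        pct_reversed=pct_rev,
        mean_session_n=mean_n,
    )


def average_gain_profile(
    bysg: pd.DataFrame,
    measure_name: Optional[str] = None,
    tx_start_var: Optional[str] = None,
    tx_end_var: Optional[str] = None,
) -> pd.DataFrame:
    """Per-position mean, SD and n of the six scores around the gain.

    Returns one row per position (2n, 1n, n, n1, n2, n3), with optional
    treatment-start and -end anchor rows when the bysg table carries the
    raw session columns. Missing values are excluded position-wise, so
    each position can have its own n. This is the data behind the
    average-gain plot.
    """
    if len(bysg) == 0:
        raise DataError("average_gain_profile needs at least one gain record")
    m = measure_name or bysg.attrs.get("measure_name")
    if m is None:
        raise DataError("measure_name not given and not recorded on the dataset")
    rows = []

    def stats_for(label: str, col: str) -> dict:
        vals = pd.to_numeric(bysg[col], errors="coerce").dropna()
        return {
            "position": label,
            "mean": float(vals.mean()) if len(vals) else float("nan"),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
            "n": int(len(vals)),
        }

    if tx_start_var is not None:
        if tx_start_var not in bysg.columns:
            raise DataError(f"column not found: {tx_start_var!r}")
        rows.append(stats_for("tx_start", tx_start_var))
    for pos in _POSITIONS:
        col = f"sg_{m}_{pos}"
        if col not in bysg.columns:
            raise DataError(f"column not found: {col!r}")
        rows.append(stats_for(pos, col))
    if tx_end_var is not None:
        if tx_end_var not in bysg.columns:
            raise DataError(f"column not found: {tx_end_var!r}")
        rows.append(stats_for("tx_end", tx_end_var))
    return pd.DataFrame(rows)


def trajectory_data(
    data: WideDataset,
    subject_ids: Optional[Sequence] = None,
    predicate: Optional[Callable] = None,
) -> pd.DataFrame:
    """Long-format (id, session, value) rows for trajectory plots.

    Select subjects by explicit id list and/or by a predicate over each
    subject's :class:`~sgtools.criteria.MeasurementSeries` (e.g. "has a
    gain between sessions 3 and 4", computed from a flag table). Rows
    are ordered by id (dataset order) then session; an empty selection
    yields an empty table with the schema intact.
    """
    if subject_ids is not None:
        known = set(data.subject_ids)
        unknown = [s for s in subject_ids if s not in known]
        if unknown:
            raise DataError(f"unknown subject ids: {unknown}")
        wanted = set(subject_ids)
    else:
        wanted = None
    rows = []
    for series in data.iter_series():
        if wanted is not None and series.subject_id not in wanted:
            continue
        if predicate is not None and not predicate(series):
            continue
        for sess in range(1, series.n_sessions + 1):
            v = series.value_at(sess)
            rows.append({
                "id": series.subject_id,
                "session": sess,
                "value": np.nan if v is None else v,
            })
    return pd.DataFrame(rows, columns=["id", "session", "value"])
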
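"""Sweep identification of sudden gains and losses across a wide dataset.

The input is wide-format: one row per subject, one ID column, and one
column per session of the outcome measure. Every session-to-session
interval that can structurally be evaluated (pregain session ``n`` from
2 to S-2 for S sessions) is checked against the three criteria, and the
result is a per-subject flag table with one tri-state column per
interval — TRUE/FALSE/NA for the individual criteria and 1/0/NA for the
combined sudden-gain flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .criteria import (
    CriteriaConfig,
    IntervalEvaluation,
    MeasurementSeries,
    TriState,
    check_interval,
    pattern_evaluable,
)

__all__ = ["DataError", "WideDataset", "GainFlagTable", "identify_sg",
           "identify_sl", "select_cases"]

logger = logging.getLogger("sgtools")


class DataError(ValueError):
    """Input data violates a structural requirement."""


@dataclass
class WideDataset:
    """Wide-format longitudinal dataset: one row per subject.

    ``session_columns`` are the ordered outcome columns (session 1
    first); ``secondary_columns``, if given, are a parallel measure at
    the same sessions. Non-numeric or empty cells are treated as
    missing.
    """

    data: pd.DataFrame
    id_column: str
    session_columns: list
    secondary_columns: Optional[list] = None
    measure_name: str = "score"

    def __post_init__(self) -> None:
        self.session_columns = list(self.session_columns)
        if self.secondary_columns is not None:
            self.secondary_columns = list(self.secondary_columns)
        wanted = [self.id_column] + self.session_columns + (self.secondary_columns or [])
        missing = [c for c in wanted if c not in self.data.columns]
        if missing:
            raise DataError(f"columns not found in data: {', '.join(map(str, missing))}")
        if len(self.session_columns) < 4:
            raise DataError(
                "at least 4 session columns are required for any interval to be "
                f"evaluable, got {len(self.session_columns)}"
            )
        ids = self.data[self.id_column]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].unique().tolist()
            raise DataError(f"duplicate subject ids: {dupes}")

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def n_sessions(self) -> int:
        return len(self.session_columns)

    @property
    def subject_ids(self) -> list:
        return self.data[self.id_column].tolist()

    def _row_values(self, row: pd.Series, columns: Sequence[str]) -> tuple:
        vals = pd.to_numeric(row[list(columns)], errors="coerce")
        return tuple(None if pd.isna(v) else float(v) for v in vals)

    def series(self, subject_id, secondary: bool = False) -> MeasurementSeries:
        """The outcome series for one subject (primary or secondary measure)."""
        mask = self.data[self.id_column] == subject_id
        if not mask.any():
            raise DataError(f"unknown subject id: {subject_id!r}")
        row = self.data.loc[mask].iloc[0]
        if secondary:
            if self.secondary_columns is None:
                raise DataError("dataset has no secondary measure columns")
            cols = self.secondary_columns
        else:
            cols = self.session_columns
        return MeasurementSeries(
            subject_id=subject_id,
            values=self._row_values(row, cols),
            measure_name=self.measure_name,
        )

    def iter_series(self) -> Iterator[MeasurementSeries]:
        # ids taken from the original column: .iterrows() would upcast them
        # to the row's common dtype
        ids = self.data[self.id_column].tolist()
        for sid, (_, row) in zip(ids, self.data.iterrows()):
            yield MeasurementSeries(
                subject_id=sid,
                values=self._row_values(row, self.session_columns),
                measure_name=self.measure_name,
            )


def _interval_label(n: int) -> str:
    return f"{n}to{n + 1}"


@dataclass
class GainFlagTable:
    """Per-subject, per-interval tri-state flags from an identification sweep.

    Interval columns are named ``sg_<n>to<n+1>`` (combined flag, 1/0/NA)
    and ``sg_crit<k>_<n>to<n+1>`` (per-criterion, TRUE/FALSE/NA) when
    details were requested. Intervals with pregain session 1 or S-1 are
    omitted: the minimum-data patterns make them structurally
    impossible.
    """

    table: pd.DataFrame
    id_column: str
    pregain_sessions: list
    config: CriteriaConfig
    details: bool
    evaluations: dict = field(repr=False, default_factory=dict)

    def flagged(self) -> list:
        """(subject_id, pregain_session) pairs whose combined flag is 1."""
        out = []
        for _, row in self.table.iterrows():
            for n in self.pregain_sessions:
                val = row[f"sg_{_interval_label(n)}"]
                if not pd.isna(val) and val == 1:
                    out.append((row[self.id_column], n))
        return out

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def _sweep(data: WideDataset, config: CriteriaConfig, details: bool) -> GainFlagTable:
    S = data.n_sessions
    pregain_sessions = list(range(2, S - 1))  # n in [2, S-2]
    records = []
    evaluations = {}
    for series in data.iter_series():
        rec = {data.id_column: series.subject_id}
        for n in pregain_sessions:
            ev = check_interval(series, n, config)
            evaluations[(series.subject_id, n)] = ev
            lab = _interval_label(n)
            if details:
                rec[f"sg_crit1_{lab}"] = ev.crit1.as_flag
                rec[f"sg_crit2_{lab}"] = ev.crit2.as_flag
                rec[f"sg_crit3_{lab}"] = ev.crit3.as_flag if config.crit3 else None
            flag = ev.is_gain.as_flag
            rec[f"sg_{lab}"] = None if flag is None else int(flag)
            if ev.is_gain is TriState.INDETERMINATE:
                missing = [
                    p for p, present in zip(
                        ("x_n", "x_n+1"),
                        (ev.n_pre_available > 0 and series.value_at(n) is not None,
                         series.value_at(n + 1) is not None),
                    ) if not present
                ]
                logger.info(
                    "subject %s interval %s indeterminate "
                    "(%d/3 pregain, %d/3 postgain points present%s)",
                    series.subject_id, lab, ev.n_pre_available, ev.n_post_available,
                    f"; mandatory {', '.join(missing)} missing" if missing else "",
                )
        records.append(rec)
    table = pd.DataFrame.from_records(records)
    for col in table.columns:
        if col == data.id_column:
            continue
        if col.startswith("sg_crit"):
            table[col] = table[col].astype("boolean")
        else:
            table[col] = table[col].astype("Int64")
    return GainFlagTable(
        table=table,
        id_column=data.id_column,
        pregain_sessions=pregain_sessions,
        config=config,
        details=details,
        evaluations=evaluations,
    )


def identify_sg(
    data: WideDataset, config: CriteriaConfig, details: bool = False
) -> GainFlagTable:
    """Apply the sudden-gains criteria to every interval of every subject.

    ``config.direction`` must be ``"gain"``; use :func:`identify_sl`
    for sudden losses. With ``details`` the table carries the three
    per-criterion columns alongside each combined flag.
    """
    if config.direction != "gain":
        raise DataError("identify_sg requires config.direction='gain'")
    return _sweep(data, config, details)


def identify_sl(
    data: WideDataset, config: CriteriaConfig, details: bool = False
) -> GainFlagTable:
    """Identify sudden losses: the criteria applied in the inverse direction."""
    if config.direction != "loss":
        raise DataError("identify_sl requires config.direction='loss'")
    return _sweep(data, config, details)


def select_cases(
    data: WideDataset,
    config: Optional[CriteriaConfig] = None,
    min_sessions: Optional[int] = None,
) -> pd.DataFrame:
    """Per-subject inclusion flags for a sudden-gains analysis.

    Default rule: include a subject iff at least one interval satisfies
    the minimum-data pattern (two of three points on each side of a
    present pregain/postgain pair). With ``min_sessions`` the rule is
    instead a minimum count of present measurements.
    """
    rows = []
    for series in data.iter_series():
        present = [v is not None for v in series.values]
        if min_sessions is not None:
            include = sum(present) >= min_sessions
        else:
            include = any(
                pattern_evaluable(
                    [series.value_at(s) is not None for s in range(n - 2, n + 4)]
                )
                for n in range(2, data.n_sessions - 1)
            )
        rows.append({data.id_column: series.subject_id, "sg_select": include})
    return pd.DataFrame(rows)
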
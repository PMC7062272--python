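"""Core sudden-gain criteria.

A sudden gain is a between-session improvement that is (1) large in
absolute terms, (2) large relative to the pregain score, and (3) large
relative to the symptom fluctuation in the three sessions on either side
of the change. This module implements the three criteria as pure
functions on scores, together with the missing-data rules that decide
whether an interval can be evaluated at all and the degrees-of-freedom
adjusted critical values used by criterion 3.

Sessions are named relative to the gain: the pregain session is ``n``,
the postgain session is ``n+1``, and the six-session window around a
candidate interval runs from ``n-2`` to ``n+3``. Missing scores are
represented as ``None`` (or NaN at the pandas boundary) and propagate to
an explicit *indeterminate* verdict rather than to False.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from scipy import stats as _scipy_stats

__all__ = [
    "TriState",
    "ConfigError",
    "MeasurementSeries",
    "CriteriaConfig",
    "WindowStats",
    "Crit3Result",
    "IntervalEvaluation",
    "crit1_met",
    "crit2_met",
    "critical_value",
    "crit3_met",
    "pattern_evaluable",
    "check_interval",
]

logger = logging.getLogger("sgtools")

Score = Optional[float]


class ConfigError(ValueError):
    """Invalid criteria configuration."""


class TriState(Enum):
    """Verdict of a criterion: met, not met, or untestable due to missing data."""

    MET = "met"
    NOT_MET = "not_met"
    INDETERMINATE = "indeterminate"

    def __bool__(self) -> bool:  # pragma: no cover - guard against misuse
        raise TypeError(
            "TriState cannot be coerced to bool; compare against TriState members"
        )

    @property
    def as_flag(self) -> Optional[bool]:
        """TRUE/FALSE/NA encoding used in flag tables (None for indeterminate)."""
        if self is TriState.MET:
            return True
        if self is TriState.NOT_MET:
            return False
        return None


def _is_missing(x: Score) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class MeasurementSeries:
    """One subject's ordered outcome scores with explicit missingness.

    Scores are indexed by session, 1-based and contiguous; position ``k``
    of ``values`` holds the score at session ``k + 1``. Missing
    measurements are ``None``.
    """

    subject_id: object
    values: tuple
    measure_name: str = "score"

    def __post_init__(self) -> None:
        if len(self.values) < 1:
            raise ValueError("MeasurementSeries needs at least one score slot")
        cleaned = tuple(
            None if _is_missing(v) else float(v) for v in self.values
        )
        object.__setattr__(self, "values", cleaned)

    @property
    def n_sessions(self) -> int:
        return len(self.values)

    def value_at(self, session: int) -> Score:
        """Score at a 1-based session; sessions outside the series are missing."""
        if 1 <= session <= self.n_sessions:
            return self.values[session - 1]
        return None

    def window(self, n: int) -> tuple:
        """The six scores x_{n-2} .. x_{n+3} around pregain session ``n``."""
        return tuple(self.value_at(s) for s in range(n - 2, n + 4))


@dataclass(frozen=True)
class CriteriaConfig:
    """Tunable parameters of the three criteria.

    Parameters
    ----------
    crit1_cutoff : float
        Minimum absolute between-session change, in score units
        (classically 7 points on the BDI; often derived from the RCI).
    crit2 : bool
        Whether to apply the relative-change criterion (default True;
        some studies omit it because of response-scale concerns).
    crit2_pct : float
        Minimum change as a fraction of the pregain score (default 0.25;
        0.33 is a published variant for sudden losses).
    crit3 : bool
        Whether to apply the fluctuation criterion (default True).
    crit3_alpha : float
        Two-tailed alpha for the criterion-3 critical value (default 0.05).
    crit3_adjust : bool
        Adjust the critical value to the available degrees of freedom
        around the gain (default True). When False,
        ``crit3_critical_value`` is applied to every interval.
    crit3_critical_value : float
        Fixed critical value used when ``crit3_adjust`` is False
        (default 2.776, the full-data t quantile).
    direction : str
        ``"gain"`` (improvement = decrease) or ``"loss"`` (deterioration
        = increase).
    """

    crit1_cutoff: float
    crit2: bool = True
    crit2_pct: float = 0.25
    crit3: bool = True
    crit3_alpha: float = 0.05
    crit3_adjust: bool = True
    crit3_critical_value: float = 2.776
    direction: str = "gain"

    def __post_init__(self) -> None:
        if not self.crit1_cutoff > 0:
            raise ConfigError(
                f"crit1_cutoff must be positive, got {self.crit1_cutoff!r}"
            )
        if not 0 <= self.crit2_pct < 1:
            raise ConfigError(f"crit2_pct must be in [0, 1), got {self.crit2_pct!r}")
        if not 0 < self.crit3_alpha < 1:
            raise ConfigError(
                f"crit3_alpha must be in (0, 1), got {self.crit3_alpha!r}"
            )
        if not self.crit3_adjust and not self.crit3_critical_value > 0:
            raise ConfigError("crit3_critical_value must be positive")
        if self.direction not in ("gain", "loss"):
            raise ConfigError(
                f"direction must be 'gain' or 'loss', got {self.direction!r}"
            )


@dataclass(frozen=True)
class WindowStats:
    """Summary statistics of the pre- and postgain windows (sample SDs, n-1)."""

    mean_pre: float
    mean_post: float
    sd_pre: float
    sd_post: float
    n_pre: int
    n_post: int

    @property
    def pooled_sd(self) -> float:
        num = (self.n_pre - 1) * self.sd_pre**2 + (self.n_post - 1) * self.sd_post**2
        return math.sqrt(num / (self.n_pre + self.n_post - 2))


@dataclass(frozen=True)
class Crit3Result:
    verdict: TriState
    window_stats: Optional[WindowStats] = None
    critical_value_used: Optional[float] = None


@dataclass(frozen=True)
class IntervalEvaluation:
    """Tri-state verdicts for one session-to-session interval.

    ``pregain_session`` is the session ``n`` immediately before the
    candidate change, so the interval runs from ``n`` to ``n+1``.
    """

    subject_id: object
    pregain_session: int
    crit1: TriState
    crit2: TriState
    crit3: TriState
    is_gain: TriState
    n_pre_available: int
    n_post_available: int
    critical_value_used: Optional[float] = None


def crit1_met(x_n: Score, x_n1: Score, cutoff: float, direction: str = "gain") -> TriState:
    """Criterion 1: the change is at least ``cutoff`` score points.

    Inclusive ("at least"): a drop exactly equal to the cutoff counts.
    Indeterminate when either the pregain or postgain score is missing.
    """
    if not cutoff > 0:
        raise ConfigError(f"crit1 cutoff must be positive, got {cutoff!r}")
    if _is_missing(x_n) or _is_missing(x_n1):
        return TriState.INDETERMINATE
    change = (x_n - x_n1) if direction == "gain" else (x_n1 - x_n)
    return TriState.MET if change >= cutoff else TriState.NOT_MET


def crit2_met(x_n: Score, x_n1: Score, pct: float, direction: str = "gain") -> TriState:
    """Criterion 2: the change is at least ``pct`` of the pregain score.

    A percentage drop from a non-positive score is undefined, so
    ``x_n <= 0`` yields not-met (with a logged warning) rather than an
    error; symptom scales are non-negative.
    """
    if _is_missing(x_n) or _is_missing(x_n1):
        return TriState.INDETERMINATE
    if x_n <= 0:
        logger.warning(
            "criterion 2 evaluated with non-positive pregain score %s; "
            "verdict not_met by convention", x_n,
        )
        return TriState.NOT_MET
    change = (x_n - x_n1) if direction == "gain" else (x_n1 - x_n)
    return TriState.MET if change >= pct * x_n else TriState.NOT_MET


def critical_value(n_pre: int, n_post: int, alpha: float = 0.05) -> float:
    """Two-tailed Student-t quantile at ``1 - alpha/2`` with df = n_pre + n_post - 2.

    With full three-session windows on both sides this is t(4; 97.5%) =
    2.776; one missing point on either side gives 3.182 (df 3), one
    missing on each side 4.303 (df 2).
    """
    if not 0 < alpha < 1:
        raise ConfigError(f"alpha must be in (0, 1), got {alpha!r}")
    df = n_pre + n_post - 2
    if df < 1:
        raise ConfigError(
            f"criterion 3 needs n_pre + n_post - 2 >= 1 degrees of freedom, "
            f"got n_pre={n_pre}, n_post={n_post}"
        )
    return float(_scipy_stats.t.ppf(1 - alpha / 2, df))


def _window_values(window: Sequence[Score]) -> list:
    return [float(v) for v in window if not _is_missing(v)]


def crit3_met(
    pre_window: Sequence[Score],
    post_window: Sequence[Score],
    config: CriteriaConfig,
) -> Crit3Result:
    """Criterion 3: mean change exceeds the critical multiple of the pooled SD.

    ``pre_window`` holds the available scores among x_{n-2}, x_{n-1},
    x_n and ``post_window`` those among x_{n+1}, x_{n+2}, x_{n+3}. The
    verdict is indeterminate with fewer than two scores on either side.
    Otherwise the change in window means must *strictly* exceed

        c * sqrt(((n_pre-1)*SD_pre^2 + (n_post-1)*SD_post^2) / (n_pre+n_post-2))

    where c is the df-adjusted t quantile (or the fixed critical value
    when adjustment is off). A zero pooled SD is legal: the test then
    reduces to a strict comparison of the two means.
    """
    pre = _window_values(pre_window)
    post = _window_values(post_window)
    if len(pre) < 2 or len(post) < 2:
        return Crit3Result(TriState.INDETERMINATE)
    n_pre, n_post = len(pre), len(post)
    mean_pre = sum(pre) / n_pre
    mean_post = sum(post) / n_post
    sd_pre = math.sqrt(sum((v - mean_pre) ** 2 for v in pre) / (n_pre - 1))
    sd_post = math.sqrt(sum((v - mean_post) ** 2 for v in post) / (n_post - 1))
    ws = WindowStats(mean_pre, mean_post, sd_pre, sd_post, n_pre, n_post)
    if config.crit3_adjust:
        c = critical_value(n_pre, n_post, config.crit3_alpha)
    else:
        c = config.crit3_critical_value
    diff = (mean_pre - mean_post) if config.direction == "gain" else (mean_post - mean_pre)
    verdict = TriState.MET if diff > c * ws.pooled_sd else TriState.NOT_MET
    return Crit3Result(verdict, ws, c)


def pattern_evaluable(availability: Sequence[bool]) -> bool:
    """Whether the six-session window allows the interval to be evaluated.

    ``availability`` flags presence of x_{n-2} .. x_{n+3}. The pregain
    and postgain points must be present, and at least two of the three
    points on each side of the interval — a minimum of four points
    overall, arranged in one of the four canonical patterns (or any
    superset of one).
    """
    a = [bool(v) for v in availability]
    if len(a) != 6:
        raise ValueError(f"availability must have six entries, got {len(a)}")
    pre, post = a[:3], a[3:]
    return pre[2] and post[0] and sum(pre) >= 2 and sum(post) >= 2


def check_interval(
    series: MeasurementSeries, n: int, config: CriteriaConfig
) -> IntervalEvaluation:
    """Evaluate the interval from session ``n`` to ``n+1`` of one series.

    Composes the three criteria and the evaluability pattern into a
    single tri-state result. The combined verdict is indeterminate
    whenever the window fails the minimum-data pattern (the interval
    cannot be fully tested), not-met as soon as any applied criterion is
    determinately not met, and met only when every applied criterion is
    met.
    """
    if not 1 <= n < series.n_sessions:
        raise ValueError(
            f"pregain session n={n} out of range; valid range for this series "
            f"is 1 <= n <= {series.n_sessions - 1}"
        )
    window = series.window(n)
    x_n, x_n1 = window[2], window[3]
    availability = [not _is_missing(v) for v in window]
    n_pre_avail = sum(availability[:3])
    n_post_avail = sum(availability[3:])

    c1 = crit1_met(x_n, x_n1, config.crit1_cutoff, config.direction)
    c2 = (crit2_met(x_n, x_n1, config.crit2_pct, config.direction)
          if config.crit2 else TriState.INDETERMINATE)
    if config.crit3:
        c3_res = crit3_met(window[:3], window[3:], config)
        c3 = c3_res.verdict
        cv_used = c3_res.critical_value_used
    else:
        c3 = TriState.INDETERMINATE
        cv_used = None

    applied = [c1] + ([c2] if config.crit2 else []) + ([c3] if config.crit3 else [])
    if config.crit3 and not pattern_evaluable(availability):
        combined = TriState.INDETERMINATE
    elif any(v is TriState.NOT_MET for v in applied):
        combined = TriState.NOT_MET
    elif any(v is TriState.INDETERMINATE for v in applied):
        combined = TriState.INDETERMINATE
    else:
        combined = TriState.MET

    if combined is TriState.INDETERMINATE:
        missing_mandatory = [
            name
            for name, ok in zip(("x_n", "x_n+1"), (availability[2], availability[3]))
            if not ok
        ]
        if missing_mandatory:
            logger.debug(
                "subject %s interval %d->%d indeterminate: mandatory point(s) "
                "%s missing", series.subject_id, n, n + 1,
                ", ".join(missing_mandatory),
            )

    return IntervalEvaluation(
        subject_id=series.subject_id,
        pregain_session=n,
        crit1=c1,
        crit2=c2,
        crit3=c3,
        is_gain=combined,
        n_pre_available=n_pre_avail,
        n_post_available=n_post_avail,
        critical_value_used=cv_used,
    )
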
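"""Seedable synthetic longitudinal datasets with planted sudden gains.

Real sudden-gains datasets are weekly bounded symptom questionnaires
(e.g. a 0-63 depression score) over a course of therapy. The generator
emulates that shape: each subject follows a gently improving linear
trend with AR(1) session-to-session noise, optionally rounded to
integers and clipped to the scale range; *planted* gains superimpose an
abrupt between-session drop, planted rebounds restore part or all of a
gain later (producing reversals), and missingness can be sprinkled at
random or as monotone dropout.

Plants are validated on the noise-free skeleton: construction
guarantees that with ``noise_sd = 0`` every planted interval meets all
three criteria (at the intended cutoff and percentage) and no other
interval of that subject does. Ground truth is returned alongside the
data so tests never re-derive it from generator internals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .criteria import CriteriaConfig, TriState, check_interval, MeasurementSeries
from .identify import WideDataset

__all__ = ["GenerationSpec", "generate", "default_demo", "DEMO_SEED"]

logger = logging.getLogger("sgtools")


@dataclass(frozen=True)
class GenerationSpec:
    """Recipe for one synthetic dataset.

    ``planted_gains`` are (subject_id, pregain_session, drop) triples;
    ``planted_rebounds`` are (subject_id, rebound_session, amount)
    triples adding ``amount`` back to every session from
    ``rebound_session`` on. ``dropout_after`` forces a subject's
    sessions after the given one to be missing regardless of
    ``missing_rate``. Cells inside a planted gain's six-session window
    are protected from random missingness so plants stay evaluable.
    """

    n_subjects: int = 43
    n_sessions: int = 12
    score_range: Tuple[int, int] = (0, 63)
    baseline_mean: float = 30.0
    baseline_sd: float = 5.0
    trend_per_session: float = -0.5
    noise_sd: float = 1.0
    noise_ar: float = 0.3
    planted_gains: tuple = ()
    planted_rebounds: tuple = ()
    baseline_overrides: Optional[Mapping] = None
    missing_rate: float = 0.0
    missing_pattern: str = "random"
    dropout_after: Optional[Mapping] = None
    secondary_measure: bool = False
    integer_scores: bool = True
    intended_cutoff: float = 7.0
    intended_pct: float = 0.25
    id_column: str = "id"
    primary_name: str = "bdi"
    secondary_name: str = "rq"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_sessions < 4:
            raise ValueError("need at least 1 subject and 4 sessions")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.missing_pattern not in ("random", "monotone_dropout"):
            raise ValueError(f"unknown missing_pattern {self.missing_pattern!r}")
        lo, hi = self.score_range
        if not lo < hi:
            raise ValueError("score_range must be (min, max) with min < max")
        for sid, n, drop in self.planted_gains:
            if not 2 <= n <= self.n_sessions - 2:
                raise ValueError(
                    f"planted gain for subject {sid}: pregain session {n} outside "
                    f"[2, {self.n_sessions - 2}]"
                )
            if not drop > 0:
                raise ValueError(f"planted drop must be positive, got {drop}")


def _skeleton(spec: GenerationSpec, baselines: Mapping) -> dict:
    """Noise-free trajectories per subject id."""
    S = spec.n_sessions
    gains_by_subject: dict = {}
    for sid, n, drop in spec.planted_gains:
        gains_by_subject.setdefault(sid, []).append((n, float(drop)))
    rebounds_by_subject: dict = {}
    for sid, r, amount in spec.planted_rebounds:
        rebounds_by_subject.setdefault(sid, []).append((int(r), float(amount)))
    out = {}
    lo, hi = spec.score_range
    for sid, b in baselines.items():
        y = b + spec.trend_per_session * np.arange(S, dtype=float)
        for n, drop in gains_by_subject.get(sid, ()):
            y[n:] -= drop  # sessions n+1 .. S (0-based index n is session n+1)
        for r, amount in rebounds_by_subject.get(sid, ()):
            y[r - 1:] += amount
        if y.min() < lo or y.max() > hi:
            raise ValueError(
                f"infeasible plant layout for subject {sid}: noise-free "
                f"trajectory spans [{y.min():.1f}, {y.max():.1f}], outside the "
                f"score range {spec.score_range}"
            )
        out[sid] = y
    return out


def _validate_plants(spec: GenerationSpec, skeleton: Mapping) -> None:
    config = CriteriaConfig(
        crit1_cutoff=spec.intended_cutoff, crit2_pct=spec.intended_pct
    )
    planted = {(sid, n) for sid, n, _ in spec.planted_gains}
    for sid, y in skeleton.items():
        series = MeasurementSeries(sid, tuple(y))
        for n in range(2, spec.n_sessions - 1):
            verdict = check_interval(series, n, config).is_gain
            if (sid, n) in planted and verdict is not TriState.MET:
                raise ValueError(
                    f"infeasible plant: subject {sid} interval {n}->{n + 1} does "
                    "not satisfy all criteria on the noise-free trajectory"
                )
            if (sid, n) not in planted and verdict is TriState.MET:
                raise ValueError(
                    f"plant layout for subject {sid} creates an unplanned gain at "
                    f"interval {n}->{n + 1} on the noise-free trajectory"
                )


def generate(spec: GenerationSpec) -> Tuple[WideDataset, pd.DataFrame]:
    """Generate a wide dataset and its ground-truth gain list.

    Returns ``(dataset, truth)`` where ``truth`` has one row per planted
    gain: subject id, pregain session, planted drop, and whether a
    rebound was planted for that subject. Identical specs (including
    the seed) yield identical output.
    """
    rng = np.random.default_rng(spec.seed)
    S, N = spec.n_sessions, spec.n_subjects
    ids = list(range(1, N + 1))
    known = set(ids)
    for sid, _, _ in spec.planted_gains:
        if sid not in known:
            raise ValueError(f"planted gain refers to unknown subject id {sid}")

    baselines = dict(zip(ids, rng.normal(spec.baseline_mean, spec.baseline_sd, N)))
    if spec.baseline_overrides:
        for sid, b in spec.baseline_overrides.items():
            baselines[sid] = float(b)
    skeleton = _skeleton(spec, baselines)
    _validate_plants(spec, skeleton)

    lo, hi = spec.score_range
    y = np.empty((N, S))
    for i, sid in enumerate(ids):
        e = np.empty(S)
        innov = rng.normal(0.0, spec.noise_sd, S)
        e[0] = innov[0]
        scale = np.sqrt(max(0.0, 1.0 - spec.noise_ar**2))
        for s in range(1, S):
            e[s] = spec.noise_ar * e[s - 1] + scale * innov[s]
        y[i] = skeleton[sid] + e
    n_clipped = int(((y < lo) | (y > hi)).sum())
    if n_clipped:
        logger.info("clipping %d generated scores to the range [%s, %s]",
                    n_clipped, lo, hi)
    y = np.clip(y, lo, hi)
    if spec.integer_scores:
        y = np.rint(y)

    rq = None
    if spec.secondary_measure:
        rq = 0.55 * y + 6.0 + rng.normal(0.0, 2.0, y.shape)
        rq = np.clip(rq, lo, hi)
        if spec.integer_scores:
            rq = np.rint(rq)

    # Missingness: protect the six-session window of every plant (and the
    # two sessions after a rebound) so planted structure stays observable.
    protected = np.zeros((N, S), dtype=bool)
    idx = {sid: i for i, sid in enumerate(ids)}
    for sid, n, _ in spec.planted_gains:
        protected[idx[sid], max(0, n - 3):min(S, n + 3)] = True
    for sid, r, _ in spec.planted_rebounds:
        protected[idx[sid], r - 1:min(S, r + 1)] = True

    missing = np.zeros((N, S), dtype=bool)
    if spec.missing_rate > 0:
        if spec.missing_pattern == "random":
            draw = rng.random((N, S)) < spec.missing_rate
            missing = draw & (~protected | (spec.missing_rate >= 1.0))
        else:  # monotone dropout: affected subjects stop attending
            affected = rng.random(N) < spec.missing_rate
            last = rng.integers(2, max(3, S - 1), N)
            for i, sid in enumerate(ids):
                if affected[i] and not protected[i].any():
                    missing[i, last[i]:] = True
    if spec.dropout_after:
        for sid, last_session in spec.dropout_after.items():
            missing[idx[sid], int(last_session):] = True

    y = y.astype(float)
    y[missing] = np.nan
    if rq is not None:
        rq = rq.astype(float)
        rq[missing] = np.nan

    cols = {spec.id_column: ids}
    p_cols = [f"{spec.primary_name}_s{s}" for s in range(1, S + 1)]
    for j, c in enumerate(p_cols):
        cols[c] = y[:, j]
    s_cols = None
    if rq is not None:
        s_cols = [f"{spec.secondary_name}_s{s}" for s in range(1, S + 1)]
        for j, c in enumerate(s_cols):
            cols[c] = rq[:, j]
    frame = pd.DataFrame(cols)
    dataset = WideDataset(
        data=frame,
        id_column=spec.id_column,
        session_columns=p_cols,
        secondary_columns=s_cols,
        measure_name=spec.primary_name,
    )

    rebound_subjects = {sid for sid, _, _ in spec.planted_rebounds}
    truth = pd.DataFrame(
        [
            {
                spec.id_column: sid,
                "sg_session_n": n,
                "planted_drop": float(drop),
                "rebound_planted": sid in rebound_subjects,
            }
            for sid, n, drop in sorted(spec.planted_gains)
        ],
        columns=[spec.id_column, "sg_session_n", "planted_drop", "rebound_planted"],
    )
    return dataset, truth


DEMO_SEED = 7

# Plant layout of the bundled demo: 16 of 43 subjects gain, of whom 8 have
# two gains and 1 has three (9 multi-gainers, 26 gains in total); three
# single-gain subjects fully relapse later, producing reversals. Drops are
# sized so that every criterion holds with several score points to spare on
# top of the session noise. This dataset is synthetic: it mimics the shape
# of a weekly-BDI therapy trial, not any real sample.
_DEMO_SINGLES = (
    (3, 5, 13), (7, 3, 13), (11, 8, 13), (15, 4, 13),
    (19, 6, 13), (23, 9, 13), (27, 7, 13),
)
_DEMO_DOUBLES = (
    (2, 3, 17), (2, 8, 12),
    (5, 4, 17), (5, 9, 12),
    (9, 2, 17), (9, 7, 12),
    (13, 3, 17), (13, 8, 12),
    (17, 4, 17), (17, 9, 12),
    (21, 2, 17), (21, 7, 12),
    (25, 3, 17), (25, 8, 12),
    (29, 4, 17), (29, 9, 12),
)
_DEMO_TRIPLE = ((31, 3, 20), (31, 6, 14), (31, 9, 11))
# Full relapses four sessions after the gain: (subject, rebound session, amount)
_DEMO_REBOUNDS = ((7, 7, 13.0), (15, 8, 13.0), (19, 10, 13.0))

DEMO_SPEC = GenerationSpec(
    n_subjects=43,
    n_sessions=12,
    baseline_mean=30.0,
    baseline_sd=4.0,
    trend_per_session=-0.5,
    noise_sd=1.0,
    noise_ar=0.3,
    planted_gains=_DEMO_SINGLES + _DEMO_DOUBLES + _DEMO_TRIPLE,
    planted_rebounds=_DEMO_REBOUNDS,
    baseline_overrides={
        **{sid: 33.0 for sid, _, _ in _DEMO_SINGLES},
        **{sid: 45.0 for sid, _, _ in _DEMO_DOUBLES},
        31: 58.0,
    },
    missing_rate=0.04,
    missing_pattern="random",
    dropout_after={38: 2, 41: 6},
    secondary_measure=True,
    seed=DEMO_SEED,
)


def default_demo(with_truth: bool = False):
    """The bundled 43-subject, 12-session demo dataset (fixed seed).

    Columns: ``id``, ``bdi_s1`` .. ``bdi_s12`` and the correlated
    secondary measure ``rq_s1`` .. ``rq_s12``. With ``with_truth`` the
    planted ground-truth table is returned alongside.
    """
    dataset, truth = generate(DEMO_SPEC)
    return (dataset, truth) if with_truth else dataset
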
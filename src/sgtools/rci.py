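"""Reliable-change-based cutoffs for criterion 1 (Jacobson–Truax chain).

The first sudden-gain criterion needs an absolute cutoff in score
units. Beyond the classic 7 BDI points, studies generally derive one
from the measure's reliability: the standard error of measurement

    S_E = SD * sqrt(1 - r)

(with SD the normal-population SD and r the test–retest reliability, or
— in the Martinovich adaptation — the clinical baseline SD and internal
consistency), the standard error of the difference between two
administrations

    S_diff = sqrt(2 * S_E^2),

and the reliable change value 1.96 * S_diff, the two-tailed 5% bound on
a pre–post difference under pure measurement error. Both S_diff and
1.96 * S_diff are used as cutoffs in the literature; the convention
flag selects between them and every intermediate is reported so the
choice is explicit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["ReliabilityInputs", "CutoffResult", "standard_error_measurement",
           "define_crit1_cutoff", "RCI_Z"]

RCI_Z = 1.96  # two-tailed z at alpha = 0.05; fixed by the reliable-change definition


@dataclass(frozen=True)
class ReliabilityInputs:
    """Reliability statistics a cutoff is derived from.

    ``which_sd`` records whether ``sd_baseline`` is the SD of a normal
    population (paired with test–retest reliability) or of the clinical
    sample at baseline (paired with internal consistency); the two
    formulas are numerically identical, so the flag is reporting
    metadata only.
    """

    sd_baseline: float
    reliability: float
    which_sd: str = "normal_population"

    def __post_init__(self) -> None:
        if not self.sd_baseline > 0:
            raise ValueError(f"sd_baseline must be positive, got {self.sd_baseline!r}")
        if not 0 <= self.reliability <= 1:
            raise ValueError(
                f"reliability must be in [0, 1], got {self.reliability!r}"
            )
        if self.which_sd not in ("normal_population", "clinical_baseline"):
            raise ValueError(f"unknown which_sd {self.which_sd!r}")


@dataclass(frozen=True)
class CutoffResult:
    """Full reliable-change chain: S_E, S_diff, 1.96*S_diff, and the pick."""

    s_e: float
    s_diff: float
    reliable_change: float
    recommended_cutoff: float
    convention: str

    def __str__(self) -> str:
        return (
            f"standard error of measurement (S_E):  {self.s_e:.4f}\n"
            f"standard error of difference (S_diff): {self.s_diff:.4f}\n"
            f"reliable change (1.96 x S_diff):       {self.reliable_change:.4f}\n"
            f"recommended criterion-1 cutoff:        {self.recommended_cutoff:.4f} "
            f"({self.convention} convention)"
        )


def standard_error_measurement(inputs: ReliabilityInputs) -> float:
    """S_E = sd_baseline * sqrt(1 - reliability)."""
    return inputs.sd_baseline * math.sqrt(1.0 - inputs.reliability)


def define_crit1_cutoff(
    inputs: ReliabilityInputs, convention: str = "reliable_change"
) -> CutoffResult:
    """Derive a criterion-1 cutoff from reliability statistics.

    ``convention`` is ``"reliable_change"`` (1.96 * S_diff, the default)
    or ``"s_diff"``; studies differ, so the full chain is returned.
    """
    if convention not in ("s_diff", "reliable_change"):
        raise ValueError(
            f"convention must be 's_diff' or 'reliable_change', got {convention!r}"
        )
    s_e = standard_error_measurement(inputs)
    s_diff = math.sqrt(2.0 * s_e**2)
    reliable_change = RCI_Z * s_diff
    recommended = reliable_change if convention == "reliable_change" else s_diff
    return CutoffResult(
        s_e=s_e,
        s_diff=s_diff,
        reliable_change=reliable_change,
        recommended_cutoff=recommended,
        convention=convention,
    )
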
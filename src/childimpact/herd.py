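"""Herd-effect adjustment for vaccines and bednets.

At high population coverage, transmission of an infectious agent is
disrupted enough that unvaccinated (or unprotected) children are also
shielded.  Rather than model transmission dynamics, the herd effect is a
phenomenological piecewise-linear function of coverage: zero below a
lower threshold, a maximum above an upper threshold, and linearly
interpolated in between.  For measles the established curve is zero
below 90% coverage, full protection (1.0) above 95%.

The incremental herd effect between a baseline and target coverage is
normalised by the protection headroom remaining at baseline, and the
herd increment then acts on the mortality left after the vaccine's
direct effect — structurally the same residual-mortality composition
used when combining interventions.
"""

from __future__ import annotations

from dataclasses import dataclass


class SaturatedBaselineError(ValueError):
    """Raised when the baseline state leaves no headroom for further effect."""


@dataclass(frozen=True)
class HerdCurve:
    """Piecewise-linear herd protection as a function of population coverage.

    Value is 0 below ``lower``, ``max_effect`` above ``upper``, and linear
    in between.  All three parameters are proportions.
    """

    lower: float
    upper: float
    max_effect: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower < self.upper <= 1.0):
            raise ValueError(
                f"herd thresholds must satisfy 0 <= lower < upper <= 1, "
                f"got lower={self.lower}, upper={self.upper}"
            )
        if not (0.0 <= self.max_effect <= 1.0):
            raise ValueError(f"max_effect must be in [0, 1], got {self.max_effect}")

    def value(self, coverage: float) -> float:
        return herd_value(self, coverage)


#: Default curve for herd-capable vaccines: no herd protection below 90%
#: coverage, complete protection above 95%, linear in between.
MEASLES_HERD_CURVE = HerdCurve(lower=0.90, upper=0.95, max_effect=1.0)


def herd_value(curve: HerdCurve, coverage: float) -> float:
    """Evaluate the herd-protection curve at a population coverage level."""
    if not (0.0 <= coverage <= 1.0):
        raise ValueError(f"coverage must be in [0, 1], got {coverage}")
    if coverage <= curve.lower:
        return 0.0
    if coverage >= curve.upper:
        return curve.max_effect
    return curve.max_effect * (coverage - curve.lower) / (curve.upper - curve.lower)


def incremental_herd(
    curve: HerdCurve, baseline_coverage: float, target_coverage: float
) -> float:
    """Additional herd protection gained moving from baseline to target coverage.

    Computed as (HE_t - HE_0) / (1 - HE_0): the gain in herd protection
    normalised by the protection not already realised at baseline.
    """
    he0 = herd_value(curve, baseline_coverage)
    het = herd_value(curve, target_coverage)
    if he0 >= 1.0:
        raise SaturatedBaselineError(
            "baseline coverage already confers full herd protection; "
            "no incremental effect is defined"
        )
    return (het - he0) / (1.0 - he0)


def total_with_herd(direct_reduction: float, herd_increment: float) -> float:
    """Total mortality reduction combining a direct effect with a herd increment.

    The herd increment acts on the mortality remaining after the direct
    effect: R + H * (1 - R).  Bounded by 1; equals 1 iff either input is 1.
    """
    if not (0.0 <= direct_reduction <= 1.0):
        raise ValueError(f"direct_reduction must be in [0, 1], got {direct_reduction}")
    if not (0.0 <= herd_increment <= 1.0):
        raise ValueError(f"herd_increment must be in [0, 1], got {herd_increment}")
    return direct_reduction + herd_increment * (1.0 - direct_reduction)
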
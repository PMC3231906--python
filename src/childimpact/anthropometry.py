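"""Anthropometric z-score bands and their link to cause-specific mortality.

Stunting (height-for-age) and wasting (weight-for-height) enter the
mortality calculus through four bands on the international growth
standard: below -3 SD, [-3, -2) SD, [-2, -1) SD, and at or above -1 SD
from the standard median.  The population's height-for-age distribution
is taken to be normal with unit standard deviation on the standard's
scale, shifted so that the observed prevalence below the anchoring cut
(-2 SD for stunting, -3 SD for severe wasting) is reproduced exactly.
Band occupancies are then successive differences of the normal CDF at
the shifted cut points.

Each band carries a relative risk of death for each cause and age band,
with the reference band (>= -1 SD, normal growth) fixed at RR = 1.  The
population-average relative risk (ARR) is the occupancy-weighted mean of
band RRs; the mortality reduction between two time points is one minus
the ratio of current to baseline ARR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

from scipy.stats import norm

#: Cut points on the international standard, in SD units, ordered left to right.
Z_CUTS = (-3.0, -2.0, -1.0)

#: Band labels, leftmost (most severe) first.
Z_BAND_LABELS = ("below_-3", "-3_to_-2", "-2_to_-1", "above_-1")

#: Index of the reference band (>= -1 SD).
REFERENCE_BAND = 3


@dataclass(frozen=True)
class ZBandDistribution:
    """Population fractions over the four z-score bands, most severe first."""

    fractions: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.fractions) != 4:
            raise ValueError("exactly four band fractions required")
        if any(f < -1e-12 for f in self.fractions):
            raise ValueError(f"band fractions must be non-negative, got {self.fractions}")
        total = sum(self.fractions)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"band fractions must sum to 1, got {total}")

    @property
    def below_minus3(self) -> float:
        return self.fractions[0]

    @property
    def below_minus2(self) -> float:
        return self.fractions[0] + self.fractions[1]


@dataclass
class RelativeRiskTable:
    """Relative risks of death by z-band, cause, and age band.

    Keys are ``(cause, age_band, z_band_index)``; the age-band component is
    any hashable identifier.  The reference band (index 3) is implicitly 1
    and need not be stored; storing a value other than 1 for it is an error.
    """

    rr: dict[tuple[str, Hashable, int], float]

    def __post_init__(self) -> None:
        for (cause, band, z), value in self.rr.items():
            if z == REFERENCE_BAND and value != 1.0:
                raise ValueError(
                    f"reference band RR must be 1, got {value} for ({cause}, {band})"
                )
            if value < 0:
                raise ValueError(f"RR must be non-negative, got {value}")

    def causes_for(self, age_band: Hashable) -> list[str]:
        """Causes with at least one stored RR for the given age band."""
        seen: dict[str, None] = {}
        for (cause, band, _z) in self.rr:
            if band == age_band:
                seen.setdefault(cause, None)
        return list(seen)

    def vector(self, cause: str, age_band: Hashable) -> tuple[float, float, float, float]:
        """RRs across the four bands for one (cause, age band); missing → 1."""
        return tuple(
            self.rr.get((cause, age_band, z), 1.0) for z in range(4)
        )  # type: ignore[return-value]


def prevalence_to_bands(prevalence: float, anchor_cut: float = -2.0) -> ZBandDistribution:
    """Place a population on the four z-score bands from a single prevalence.

    The population curve is a unit-SD normal shifted so that the mass
    below ``anchor_cut`` equals ``prevalence``.  For stunting the anchor
    is -2 SD (the stunting definition); for severe wasting it is -3 SD.

    Parameters
    ----------
    prevalence
        Fraction of children below the anchoring cut, strictly in (0, 1).
    anchor_cut
        The cut point, in SD units, whose cumulative mass the input
        prevalence refers to.  Must be one of the standard cuts.

    Returns
    -------
    ZBandDistribution whose cumulative mass below the anchor reproduces
    the input exactly.
    """
    if not (0.0 < prevalence < 1.0):
        raise ValueError(
            f"prevalence must be strictly between 0 and 1, got {prevalence}"
        )
    if anchor_cut not in Z_CUTS:
        raise ValueError(f"anchor_cut must be one of {Z_CUTS}, got {anchor_cut}")
    shift = anchor_cut - norm.ppf(prevalence)
    cdf = [norm.cdf(c - shift) for c in Z_CUTS]
    fractions = (cdf[0], cdf[1] - cdf[0], cdf[2] - cdf[1], 1.0 - cdf[2])
    return ZBandDistribution(fractions=fractions)


def average_relative_risk(
    bands: ZBandDistribution,
    rr: RelativeRiskTable | Sequence[float] | Mapping[int, float],
    cause: str | None = None,
    age_band: Hashable | None = None,
) -> float:
    """Occupancy-weighted mean relative risk across the four z-bands.

    ``rr`` may be a :class:`RelativeRiskTable` (then ``cause`` and
    ``age_band`` select the RR vector) or a 4-sequence of RRs ordered
    most-severe first.
    """
    if isinstance(rr, RelativeRiskTable):
        if cause is None or age_band is None:
            raise ValueError("cause and age_band required with a RelativeRiskTable")
        vec: Sequence[float] = rr.vector(cause, age_band)
    elif isinstance(rr, Mapping):
        vec = [rr.get(z, 1.0) for z in range(4)]
    else:
        vec = rr
        if len(vec) != 4:
            raise ValueError("rr sequence must have exactly four entries")
    return float(sum(z * r for z, r in zip(bands.fractions, vec)))


def mortality_reduction_from_arr(arr_t: float, arr_0: float) -> float:
    """Proportional mortality reduction, 1 - ARR_t / ARR_0.

    Positive when the current risk profile has improved relative to
    baseline; negative (a worsening) is passed through with its sign.
    """
    if arr_0 <= 0:
        raise ValueError(f"baseline ARR must be positive, got {arr_0}")
    return 1.0 - arr_t / arr_0


def apply_supplemental_feeding(
    wasting_bands: ZBandDistribution,
    coverage_change: float,
    destination_split: Sequence[float],
) -> ZBandDistribution:
    """Redistribute severely wasted children receiving supplemental feeding.

    Supplemental feeding is given only to severely wasted children (below
    -3 SD weight-for-height).  Of those newly covered, a configured split
    moves into the three better bands; the remainder ("stays") sees no
    effect.  ``destination_split`` is ordered (to >= -1, to [-2,-1), to
    [-3,-2), stays below -3) and must sum to 1.

    Mass is conserved exactly.
    """
    if not (0.0 <= coverage_change <= 1.0):
        raise ValueError(f"coverage_change must be in [0, 1], got {coverage_change}")
    split = tuple(float(s) for s in destination_split)
    if len(split) != 4:
        raise ValueError("destination_split needs four entries (>= -1, -1..-2, -2..-3, stays)")
    if any(s < 0 for s in split):
        raise ValueError(f"destination_split entries must be non-negative, got {split}")
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError(f"destination_split must sum to 1, got {sum(split)}")

    to_above1, to_21, to_32, _stays = split
    treated = wasting_bands.below_minus3 * coverage_change
    b3, b32, b21, ba1 = wasting_bands.fractions
    moved = treated * (1.0 - _stays)
    new = (
        b3 - moved,
        b32 + treated * to_32,
        b21 + treated * to_21,
        ba1 + treated * to_above1,
    )
    return ZBandDistribution(fractions=new)
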
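"""Direct mortality-reduction calculus and attribution by timing tier.

The proportional reduction in cause-specific mortality from scaling one
intervention is

    R = I * (C_t - C_0) / (1 - I * C_0) * AF

where I is effectiveness among the newly covered, C_0 and C_t baseline
and target coverage, and AF the affected fraction — the share of the
cause's deaths whose mechanism the intervention can touch.  The
denominator removes the impact already embedded in baseline mortality.

Several interventions acting on one cause compose on residual mortality,

    R_total = 1 - prod_i (1 - R_i),

which is order-free.  Credit for the combined reduction is NOT
order-free: interventions acting earlier in life (peri-conceptual →
pregnancy → childbirth → vaccines → preventive → curative) are credited
as if working on the full burden, later tiers only on what remains.
Within a tier, credit splits proportionally to isolated reductions.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Mapping

from .core import TimingTier
from .herd import SaturatedBaselineError

__all__ = [
    "single_reduction",
    "combine_reductions",
    "attribute_shares",
    "all_cause_reduction",
]


def single_reduction(
    effectiveness: float,
    affected_fraction: float,
    baseline_coverage: float,
    target_coverage: float,
) -> float:
    """Isolated proportional mortality reduction from one coverage change.

    May be negative when coverage declines (scale-down).  Raises
    :class:`SaturatedBaselineError` when effectiveness * baseline coverage
    equals 1, i.e. baseline mortality from the susceptible mechanism is
    already fully eliminated and no further reduction is defined.
    """
    for name, v in (
        ("effectiveness", effectiveness),
        ("affected_fraction", affected_fraction),
        ("baseline_coverage", baseline_coverage),
        ("target_coverage", target_coverage),
    ):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    denom = 1.0 - effectiveness * baseline_coverage
    if denom <= 0.0:
        raise SaturatedBaselineError(
            "effectiveness x baseline coverage = 1: the susceptible burden is "
            "already fully removed at baseline"
        )
    return effectiveness * (target_coverage - baseline_coverage) / denom * affected_fraction


def combine_reductions(reductions: Iterable[float]) -> float:
    """Compose isolated reductions on residual mortality: 1 - prod(1 - R_i).

    Permutation-invariant; the empty composition is 0.  Each element must
    lie in (-1, 1] (a reduction of exactly -1, a doubling, would make the
    residual product degenerate).
    """
    residual = 1.0
    for r in reductions:
        if not (-1.0 < r <= 1.0):
            raise ValueError(f"each reduction must lie in (-1, 1], got {r}")
        residual *= 1.0 - r
    return 1.0 - residual


def attribute_shares(
    reductions: Mapping[str, float],
    tiers: Mapping[str, TimingTier] | None = None,
) -> dict[str, float]:
    """Split credit for a combined reduction across interventions.

    Tiers are processed in rank order.  With T the combined reduction of
    all (positive) isolated reductions and U_g the combined reduction of
    all tiers up to and including tier g, tier g's block of credit is
    (U_g - U_{g-1}) / T — the fraction of the total contributed when that
    tier's interventions act on the mortality remaining after all earlier
    tiers.  Within a tier, credit splits proportionally to isolated
    reductions (R_i / sum R_i).  Shares over all interventions sum to 1.

    When all interventions share one tier this reduces exactly to the
    proportional rule R_i / sum_i R_i applied to the whole.

    Interventions with non-positive isolated reductions receive share 0
    (attribution of a mortality *increase* is undefined; a warning is
    emitted if any reduction is negative).  If no positive reductions
    exist, every share is 0.
    """
    if tiers is None:
        tiers = {}
    negatives = [k for k, r in reductions.items() if r < 0]
    if negatives:
        warnings.warn(
            f"negative reductions for {negatives}; attribution is computed on "
            "the positive reductions only",
            stacklevel=2,
        )
    positive = {k: r for k, r in reductions.items() if r > 0}
    shares = {k: 0.0 for k in reductions}
    if not positive:
        return shares

    total = combine_reductions(positive.values())
    if total <= 0:
        return shares

    default_tier = TimingTier.CURATIVE
    by_tier: dict[int, list[str]] = {}
    for k in positive:
        rank = tiers.get(k, default_tier).rank
        by_tier.setdefault(rank, []).append(k)

    cum_before = 0.0
    for rank in sorted(by_tier):
        members = by_tier[rank]
        cum_after = 1.0 - (1.0 - cum_before) * math.prod(1.0 - positive[k] for k in members)
        block = (cum_after - cum_before) / total
        tier_sum = sum(positive[k] for k in members)
        for k in members:
            shares[k] = block * positive[k] / tier_sum
        cum_before = cum_after
    return shares


def all_cause_reduction(
    cause_reductions: Mapping[str, float],
    cause_fractions: Mapping[str, float],
) -> float:
    """All-cause mortality reduction: sum of per-cause reductions weighted
    by the share of deaths each cause accounts for.

    Causes absent from ``cause_reductions`` contribute zero reduction.
    ``cause_fractions`` must sum to 1.
    """
    total = sum(cause_fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"cause fractions must sum to 1, got {total}")
    return float(
        sum(cause_reductions.get(c, 0.0) * f for c, f in cause_fractions.items())
    )
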
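"""Odds-ratio decomposition of risk-factor prevalence and cohort updates.

Nutrition-related interventions act on mortality through intermediate
outcomes — stunting, wasting, IUGR, diarrhoea incidence, breastfeeding —
rather than on a cause of death directly.  The central device is the
odds-ratio decomposition: given an overall prevalence P, the fractions
of children in a risky vs non-risky status (e.g. not receiving vs
receiving preventive zinc), and the odds ratio OR of the outcome between
the statuses,

    P_k = OR * P_1 / (1 - P_1 + OR * P_1)        (odds relation)
    P   = F_k * P_k + F_1 * P_1                  (mixture relation)

are two equations in the two status-specific prevalences (P_k risky,
P_1 non-risky), solved in closed form at baseline.  Shifting children
between statuses (coverage scale-up) then projects a new overall
prevalence holding the status-specific values fixed; the proportional
decline feeds the mortality side.  The odds-ratio formulation guarantees
projected prevalences never leave (0, 1).

Complementary feeding generalises this to four statuses (food secure /
insecure crossed with promotion), solved by a bracketed root-finder on
the reference-status prevalence.  Diarrhoea incidence enters through a
per-episode odds ratio raised to the mean episodes per year, with
incidence reductions recast as moving children from "i episodes" to
"none".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy.optimize import brentq

from .direct import combine_reductions, single_reduction

__all__ = [
    "TwoStateRiskModel",
    "FourStateFeedingModel",
    "solve_two_state",
    "project_prevalence",
    "prevalence_reduction",
    "two_state_prevalence_reduction",
    "solve_four_state",
    "diarrhoea_or_to_two_state",
    "reduce_diarrhoea_incidence",
    "update_stunting_cohort",
    "update_breastfeeding",
    "update_iugr",
]


@dataclass(frozen=True)
class TwoStateRiskModel:
    """Two-status odds-ratio model at baseline.

    ``odds_ratio`` compares the odds of the outcome in the risky status
    to the non-risky status; ``risky_fraction`` is the baseline share of
    children in the risky status; ``prevalence`` the baseline overall
    outcome prevalence.
    """

    odds_ratio: float
    risky_fraction: float
    prevalence: float | None = None

    def __post_init__(self) -> None:
        if self.odds_ratio <= 0:
            raise ValueError(f"odds ratio must be > 0, got {self.odds_ratio}")
        if not (0.0 <= self.risky_fraction <= 1.0):
            raise ValueError(f"risky fraction must be in [0, 1], got {self.risky_fraction}")
        if self.prevalence is not None and not (0.0 < self.prevalence < 1.0):
            raise ValueError(f"prevalence must be in (0, 1), got {self.prevalence}")


@dataclass(frozen=True)
class FourStateFeedingModel:
    """Four-status odds-ratio model (complementary feeding).

    ``fractions`` are the population shares of the four statuses with the
    least-risky (food secure with promotion) first; ``odds_ratios`` are
    for statuses 2-4 relative to the first; ``prevalence`` is the overall
    baseline stunting prevalence.
    """

    odds_ratios: tuple[float, float, float]
    fractions: tuple[float, float, float, float]
    prevalence: float

    def __post_init__(self) -> None:
        if any(o <= 0 for o in self.odds_ratios):
            raise ValueError(f"all odds ratios must be > 0, got {self.odds_ratios}")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"status fractions must sum to 1, got {self.fractions}")
        if any(f < 0 for f in self.fractions):
            raise ValueError(f"status fractions must be non-negative, got {self.fractions}")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError(f"prevalence must be in (0, 1), got {self.prevalence}")


def _odds_relation(odds_ratio: float, p_reference: float) -> float:
    """Prevalence in a status whose odds are ``odds_ratio`` times the
    reference status's odds."""
    return odds_ratio * p_reference / (1.0 - p_reference + odds_ratio * p_reference)


def solve_two_state(model: TwoStateRiskModel) -> tuple[float, float]:
    """Solve the baseline odds/mixture system for status-specific prevalences.

    Returns ``(p_risky, p_nonrisky)``.  Substituting the pair back into
    the odds relation and the mixture relation reproduces the inputs to
    better than 1e-10.  The mixture relation reduces the system to a
    quadratic in the non-risky prevalence; the root inside (0, 1) is the
    admissible one.
    """
    if model.prevalence is None:
        raise ValueError("model.prevalence is required to solve the system")
    odds, f_k, p = model.odds_ratio, model.risky_fraction, model.prevalence
    if odds == 1.0:
        return p, p
    a = (1.0 - f_k) * (odds - 1.0)
    b = f_k * odds + (1.0 - f_k) - p * (odds - 1.0)
    c = -p
    if a == 0.0:  # everyone risky: linear
        q = -c / b
    else:
        disc = b * b - 4.0 * a * c
        if disc < 0:
            raise ValueError("inconsistent inputs: no real status-specific prevalences")
        root = math.sqrt(disc)
        candidates = [(-b + root) / (2.0 * a), (-b - root) / (2.0 * a)]
        inside = [q for q in candidates if 0.0 < q < 1.0]
        if not inside:
            raise ValueError(
                f"inconsistent inputs: no root in (0, 1) for OR={odds}, "
                f"F_risky={f_k}, P={p}"
            )
        q = inside[0]
    return _odds_relation(odds, q), q


def project_prevalence(
    p_risky: float, p_nonrisky: float, new_risky_fraction: float
) -> float:
    """Overall prevalence after the risky-status share changes, holding the
    status-specific prevalences fixed (the mixture relation)."""
    for name, v in (("p_risky", p_risky), ("p_nonrisky", p_nonrisky),
                    ("new_risky_fraction", new_risky_fraction)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return new_risky_fraction * p_risky + (1.0 - new_risky_fraction) * p_nonrisky


def prevalence_reduction(p_baseline: float, p_target: float) -> float:
    """Proportional decline in prevalence, (P_0 - P_t) / P_0.

    Positive for declines; negative values signal a worsening.
    """
    if p_baseline <= 0:
        raise ValueError(f"baseline prevalence must be > 0, got {p_baseline}")
    return (p_baseline - p_target) / p_baseline


def two_state_prevalence_reduction(
    odds_ratio: float,
    baseline_risky_fraction: float,
    target_risky_fraction: float,
    baseline_prevalence: float,
) -> float:
    """Isolated prevalence reduction from one determinant's status shift.

    Convenience composition of the solve → project → reduction chain:
    solve at baseline, move the risky fraction, report the proportional
    decline.  Identical risky fractions give exactly 0.
    """
    if target_risky_fraction == baseline_risky_fraction or odds_ratio == 1.0:
        return 0.0
    p_risky, p_nonrisky = solve_two_state(
        TwoStateRiskModel(odds_ratio, baseline_risky_fraction, baseline_prevalence)
    )
    projected = project_prevalence(p_risky, p_nonrisky, target_risky_fraction)
    return prevalence_reduction(baseline_prevalence, projected)


def solve_four_state(model: FourStateFeedingModel) -> tuple[float, float, float, float]:
    """Status-specific prevalences for the four-status feeding system.

    The three odds relations express each status's prevalence in terms of
    the reference (least risky) status's prevalence q, so the four-term
    mixture relation becomes a single equation in q.  The left side is
    strictly increasing in q, so the root is unique and bracketed on
    (0, 1); it is found numerically and verified by residual
    substitution.  (Eliminating q algebraically yields a quartic — the
    bracketed root-finder locates the same admissible root without
    quartic branch selection.)
    """
    ors = (1.0,) + tuple(model.odds_ratios)

    def mixture(q: float) -> float:
        return sum(f * _odds_relation(o, q) for f, o in zip(model.fractions, ors)) - model.prevalence

    lo, hi = 1e-15, 1.0 - 1e-15
    if mixture(lo) > 0 or mixture(hi) < 0:
        raise ValueError("inconsistent inputs: no admissible root in (0, 1)")
    q = brentq(mixture, lo, hi, xtol=1e-15, rtol=8.9e-16)
    probs = tuple(_odds_relation(o, q) for o in ors)
    if any(not (0.0 < p < 1.0) for p in probs):
        raise ValueError("inconsistent inputs: a status-specific prevalence left (0, 1)")
    return probs  # type: ignore[return-value]


def diarrhoea_or_to_two_state(
    baseline_episodes: float,
    target_episodes: float,
    per_episode_or: float,
    prevalence: float | None = None,
) -> TwoStateRiskModel:
    """Recast an incidence decline as a two-status model for stunting.

    The population-average odds ratio for stunting is the per-episode
    odds ratio raised to the baseline mean episodes per year.  All
    children are taken to have the baseline number of episodes at
    baseline (risky fraction 1); an incidence decline moves a proportion
    of children to zero episodes, so the risky fraction at the target
    year is target/baseline.
    """
    if baseline_episodes <= 0:
        raise ValueError(f"baseline episodes must be > 0, got {baseline_episodes}")
    if target_episodes < 0:
        raise ValueError(f"target episodes must be >= 0, got {target_episodes}")
    if target_episodes > baseline_episodes:
        raise ValueError(
            "incidence increases are not modelled by the two-status mapping "
            f"(baseline {baseline_episodes}, target {target_episodes})"
        )
    if per_episode_or <= 0:
        raise ValueError(f"per-episode odds ratio must be > 0, got {per_episode_or}")
    population_or = per_episode_or**baseline_episodes
    return TwoStateRiskModel(
        odds_ratio=population_or,
        risky_fraction=target_episodes / baseline_episodes,
        prevalence=prevalence,
    )


def reduce_diarrhoea_incidence(
    baseline_episodes: float,
    interventions: Iterable[tuple[float, float, float, float]],
) -> float:
    """Episodes/year after water-and-sanitation scale-up.

    Each intervention is ``(effectiveness, affected_fraction,
    baseline_coverage, target_coverage)``; the same machinery used for
    mortality applies, with incidence in place of mortality: isolated
    reductions from coverage changes compose on residual incidence.
    """
    if baseline_episodes < 0:
        raise ValueError(f"episodes must be >= 0, got {baseline_episodes}")
    reductions = [single_reduction(*args) for args in interventions]
    return baseline_episodes * (1.0 - combine_reductions(reductions))


def update_iugr(
    baseline_iugr: float,
    interventions: Iterable[tuple[float, float, float, float]],
) -> float:
    """IUGR fraction after scale-up of interventions acting in pregnancy
    (IPT/bednets, balanced energy, micronutrients).

    The mortality-reduction machinery applies with the percentage
    reduction in children born with IUGR in place of mortality.
    """
    if not (0.0 <= baseline_iugr <= 1.0):
        raise ValueError(f"baseline IUGR must be in [0, 1], got {baseline_iugr}")
    reductions = [single_reduction(*args) for args in interventions]
    return baseline_iugr * (1.0 - combine_reductions(reductions))


def update_stunting_cohort(
    baseline_stunting: float,
    determinant_reductions: Iterable[float],
) -> float:
    """Stunting prevalence in a band after its determinants shift.

    Each determinant (carried risk — IUGR for the neonatal band,
    previous-band stunting for later bands — plus complementary feeding,
    diarrhoea episodes, zinc supplementation) contributes an isolated
    proportional prevalence reduction from the odds-ratio machinery;
    reductions compose on the stunting remaining after earlier ones, so
    composition is order-free.
    """
    if not (0.0 <= baseline_stunting <= 1.0):
        raise ValueError(f"baseline stunting must be in [0, 1], got {baseline_stunting}")
    return baseline_stunting * (1.0 - combine_reductions(determinant_reductions))


def update_breastfeeding(
    baseline_fractions: Mapping[str, float],
    promotion_odds_ratio: float,
    baseline_coverage: float,
    target_coverage: float,
    improved_category: str = "exclusive",
) -> dict[str, float]:
    """Category fractions after breastfeeding-promotion scale-up.

    The improved-vs-not dichotomy is solved with the two-status
    machinery: the outcome is practising the improved category, the risky
    status is *not* being reached by promotion, and
    ``promotion_odds_ratio`` is the odds of improved practice for
    promoted relative to un-promoted mothers (> 1 means promotion
    helps).  The non-improved remainder is redistributed over the other
    categories proportionally to their baseline fractions.  Output
    fractions sum to 1.
    """
    fractions = dict(baseline_fractions)
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"category fractions must sum to 1, got {total}")
    p0 = fractions.get(improved_category, 0.0)
    if promotion_odds_ratio == 1.0 or target_coverage == baseline_coverage or not (0.0 < p0 < 1.0):
        return fractions
    # risky = un-promoted; OR of improved practice risky vs non-risky is 1/OR_promotion
    p_risky, p_nonrisky = solve_two_state(
        TwoStateRiskModel(
            odds_ratio=1.0 / promotion_odds_ratio,
            risky_fraction=1.0 - baseline_coverage,
            prevalence=p0,
        )
    )
    p_improved = project_prevalence(p_risky, p_nonrisky, 1.0 - target_coverage)
    rest0 = 1.0 - p0
    out = {improved_category: p_improved}
    for cat, f in fractions.items():
        if cat != improved_category:
            out[cat] = f * (1.0 - p_improved) / rest0
    return out
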
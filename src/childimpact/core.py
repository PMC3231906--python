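"""Domain types shared by all computation modules.

A scenario bundles everything needed to project under-five deaths and
deaths averted: a baseline mortality profile (all-cause risk and cause-of-
death fractions per age band), a registry of interventions (effectiveness
and affected fraction per targeted cause, timing tier, optional herd
curve, optional risk-factor routes), per-intervention coverage
trajectories, an annual birth series, and a risk-factor configuration
(stunting/wasting prevalences, IUGR, diarrhoea incidence, breastfeeding
categories, odds ratios, and relative-risk tables).

All coverages, effectivenesses, affected fractions and prevalences are
dimensionless proportions in [0, 1]; percent appears only at I/O
boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

from .anthropometry import RelativeRiskTable
from .herd import HerdCurve

__all__ = [
    "AgeBand",
    "ALL_BANDS",
    "POSTNEONATAL_BANDS",
    "TimingTier",
    "BF_CATEGORIES",
    "Cause",
    "default_causes",
    "RESIDUAL_CAUSE",
    "Effect",
    "RiskFactorEffect",
    "InterventionSpec",
    "CoverageTrajectory",
    "MortalityProfile",
    "RiskFactorConfig",
    "FeedingConfig",
    "Scenario",
    "Diagnostic",
    "validate_scenario",
    "MissingYearError",
]


class AgeBand(Enum):
    """The five age bands partitioning [0, 60) months of life."""

    NEONATAL = ("0m", 0, 1)
    M1_5 = ("1-5m", 1, 6)
    M6_11 = ("6-11m", 6, 12)
    M12_23 = ("12-23m", 12, 24)
    M24_59 = ("24-59m", 24, 60)

    def __init__(self, label: str, start_months: int, end_months: int):
        self.label = label
        self.start_months = start_months
        self.end_months = end_months

    @property
    def duration_months(self) -> int:
        return self.end_months - self.start_months

    @property
    def duration_years(self) -> float:
        return self.duration_months / 12.0

    @property
    def start_years(self) -> float:
        """Age at band entry, in years."""
        return self.start_months / 12.0

    @classmethod
    def from_label(cls, label: str) -> "AgeBand":
        for band in cls:
            if band.label == label:
                return band
        raise KeyError(f"unknown age band label {label!r}")

    def __lt__(self, other: "AgeBand") -> bool:
        if not isinstance(other, AgeBand):
            return NotImplemented
        return self.start_months < other.start_months


ALL_BANDS: tuple[AgeBand, ...] = tuple(AgeBand)
POSTNEONATAL_BANDS: tuple[AgeBand, ...] = tuple(AgeBand)[1:]


class TimingTier(Enum):
    """Stage at which an intervention acts; rank governs attribution order."""

    PERI_CONCEPTUAL = 1
    PREGNANCY = 2
    CHILDBIRTH = 3
    VACCINES = 4
    PREVENTIVE = 5
    CURATIVE = 6

    @property
    def rank(self) -> int:
        return self.value


#: Breastfeeding practice categories, best first.  The exclusive category
#: is the reference for mortality relative risks.
BF_CATEGORIES = ("exclusive", "predominant", "partial", "none")

RESIDUAL_CAUSE = "other"

#: Risk-factor route identifiers an intervention may carry.
RISK_FACTORS = (
    "stunting",
    "wasting",
    "iugr",
    "diarrhoea_incidence",
    "breastfeeding",
    "complementary_feeding",
)


@dataclass(frozen=True)
class Cause:
    """A cause of death, with the age bands in which it is active.

    ``is_residual`` marks the "all other causes" bucket that absorbs the
    remainder of each band's cause fractions and is never targeted by an
    intervention.  ``active`` is False for causes carried for profile
    consistency but whose mortality is computed elsewhere (AIDS).
    """

    name: str
    age_bands: frozenset[AgeBand]
    is_residual: bool = False
    active: bool = True


def default_causes() -> dict[str, Cause]:
    """The standard cause-of-death registry.

    Neonatal-only causes act in band 0m; post-neonatal causes act in the
    four bands covering 1-59 months; diarrhoea and the residual act in
    all five.  AIDS is enumerated but inactive here (its mortality is
    driven by adult prevalence and modelled separately).
    """
    neonatal = frozenset({AgeBand.NEONATAL})
    post = frozenset(POSTNEONATAL_BANDS)
    every = frozenset(ALL_BANDS)
    causes = [
        Cause("birth asphyxia", neonatal),
        Cause("prematurity", neonatal),
        Cause("sepsis/pneumonia", neonatal),
        Cause("congenital anomalies", neonatal),
        Cause("tetanus", neonatal),
        Cause("diarrhoea", every),
        Cause("pneumonia", post),
        Cause("meningitis", post),
        Cause("measles", post),
        Cause("malaria", post),
        Cause("pertussis", post),
        Cause("injury", post),
        Cause("AIDS", post, active=False),
        Cause(RESIDUAL_CAUSE, every, is_residual=True),
    ]
    return {c.name: c for c in causes}


@dataclass(frozen=True)
class Effect:
    """Effectiveness and affected fraction of one intervention against one
    (cause, age band)."""

    effectiveness: float
    affected_fraction: float = 1.0


@dataclass(frozen=True)
class RiskFactorEffect:
    """An intervention's route through an intermediate outcome.

    ``factor`` is one of :data:`RISK_FACTORS`.  Odds-ratio routes
    (stunting, breastfeeding) carry ``odds_ratio``: the odds of the bad
    outcome for an *uncovered* child relative to a covered one (> 1 means
    coverage protects).  Incidence-style routes (iugr,
    diarrhoea_incidence) carry ``effectiveness`` and
    ``affected_fraction``, applied with the same machinery as direct
    mortality effects but to the risk-factor level.  The wasting and
    complementary_feeding routes are markers: their mechanics
    (redistribution split, four-state odds ratios) live in the scenario's
    risk-factor configuration.
    """

    factor: str
    odds_ratio: float | None = None
    effectiveness: float | None = None
    affected_fraction: float = 1.0


@dataclass
class InterventionSpec:
    """One intervention: timing tier, direct effects, herd curve, and
    risk-factor routes."""

    id: str
    tier: TimingTier
    effects: dict[tuple[str, AgeBand], Effect] = field(default_factory=dict)
    herd: HerdCurve | None = None
    risk_factor_effects: tuple[RiskFactorEffect, ...] = ()


class MissingYearError(KeyError):
    """A coverage trajectory has no value for a requested year."""


@dataclass
class CoverageTrajectory:
    """Per-year coverage of one intervention, as proportions."""

    intervention_id: str
    baseline_year: int
    coverage: dict[int, float]

    @property
    def baseline(self) -> float:
        return self.coverage[self.baseline_year]

    def at(self, year: int) -> float:
        try:
            return self.coverage[year]
        except KeyError:
            raise MissingYearError(
                f"trajectory for {self.intervention_id!r} has no coverage for "
                f"year {year} (years present: {sorted(self.coverage)})"
            ) from None


@dataclass
class MortalityProfile:
    """Baseline mortality: per-band all-cause risk per child entering the
    band, and the distribution of those deaths over causes."""

    band_risk: dict[AgeBand, float]
    cause_fractions: dict[AgeBand, dict[str, float]]


@dataclass
class FeedingConfig:
    """Complementary-feeding four-state system.

    States, least risky first: food secure with promotion, food secure
    without promotion, food insecure with promotion and supplementation,
    food insecure without either.  ``odds_ratios`` are for states 2-4
    relative to state 1.  ``food_secure_fraction`` (the share living
    above the poverty line) splits the population between secure and
    insecure; promotion coverage splits each of those between
    with/without promotion.
    """

    odds_ratios: tuple[float, float, float]
    food_secure_fraction: float


@dataclass
class RiskFactorConfig:
    """Baselines, odds ratios, and relative-risk tables for the
    intermediate-outcome pathways.

    Optional blocks switch their pathway off when absent.  The odds
    ratios the field literature does not pin down (previous-band
    stunting carry-over, IUGR to stunting) are deliberately required
    configuration with no package defaults.
    """

    stunting_prevalence: dict[AgeBand, float] = field(default_factory=dict)
    severe_wasting_prevalence: dict[AgeBand, float] = field(default_factory=dict)
    iugr_fraction: float | None = None
    diarrhoea_episodes: dict[AgeBand, float] = field(default_factory=dict)
    #: per-episode odds ratio for stunting; population OR is this to the
    #: power of mean episodes/year
    diarrhoea_episode_or: float | None = None
    #: previous-band stunting carry-over OR, per post-neonatal band
    carry_or: dict[AgeBand, float] = field(default_factory=dict)
    #: IUGR -> neonatal stunting OR
    iugr_stunting_or: float | None = None
    feeding: FeedingConfig | None = None
    stunting_rr: RelativeRiskTable | None = None
    wasting_rr: RelativeRiskTable | None = None
    #: neonatal cause -> RR of death for IUGR vs non-IUGR newborns
    iugr_rr: dict[str, float] = field(default_factory=dict)
    breastfeeding_fractions: dict[AgeBand, dict[str, float]] = field(default_factory=dict)
    #: (cause, band, category) -> RR of death vs exclusive breastfeeding
    breastfeeding_rr: dict[tuple[str, AgeBand, str], float] = field(default_factory=dict)
    #: supplemental feeding destination split (to >=-1, to -1..-2, to -2..-3, stays)
    supplemental_feeding_split: tuple[float, float, float, float] | None = None


@dataclass
class Scenario:
    """A complete, self-contained input bundle for one projection."""

    name: str
    baseline_year: int
    births: dict[int, float]
    mortality: MortalityProfile
    interventions: dict[str, InterventionSpec] = field(default_factory=dict)
    coverage: dict[str, CoverageTrajectory] = field(default_factory=dict)
    risk_factors: RiskFactorConfig = field(default_factory=RiskFactorConfig)
    causes: dict[str, Cause] = field(default_factory=default_causes)


@dataclass(frozen=True)
class Diagnostic:
    """One validation finding: the offending field and the violated
    constraint."""

    field: str
    message: str

    def __str__(self) -> str:
        return f"{self.field}: {self.message}"


def _check_proportion(value: float, name: str, out: list[Diagnostic]) -> None:
    if not (0.0 <= value <= 1.0):
        out.append(Diagnostic(name, f"must be a proportion in [0, 1], got {value}"))


def validate_scenario(scenario: Scenario) -> list[Diagnostic]:
    """Check every scenario invariant; return diagnostics, not exceptions.

    An empty list means the bundle is well formed.  Each diagnostic names
    the offending field and the constraint it violates.  The function is
    pure: repeated calls on the same scenario give identical results.
    """
    out: list[Diagnostic] = []
    causes = scenario.causes

    # --- interventions ---
    for iid, spec in scenario.interventions.items():
        if spec.id != iid:
            out.append(Diagnostic(f"interventions[{iid}].id", f"key/id mismatch ({spec.id!r})"))
        for (cause_name, band), eff in spec.effects.items():
            prefix = f"interventions[{iid}].effects[{cause_name},{band.label}]"
            _check_proportion(eff.effectiveness, prefix + ".effectiveness", out)
            _check_proportion(eff.affected_fraction, prefix + ".affected_fraction", out)
            cause = causes.get(cause_name)
            if cause is None:
                out.append(Diagnostic(prefix, f"unknown cause {cause_name!r}"))
            else:
                if cause.is_residual:
                    out.append(Diagnostic(prefix, "the residual cause cannot be targeted"))
                elif band not in cause.age_bands:
                    out.append(Diagnostic(prefix, f"cause {cause_name!r} is not active in band {band.label}"))
                elif not cause.active:
                    out.append(Diagnostic(prefix, f"cause {cause_name!r} is inactive in this model"))
        for rfe in spec.risk_factor_effects:
            prefix = f"interventions[{iid}].risk_factor_effects[{rfe.factor}]"
            if rfe.factor not in RISK_FACTORS:
                out.append(Diagnostic(prefix, f"unknown risk factor {rfe.factor!r}"))
            if rfe.odds_ratio is not None and rfe.odds_ratio <= 0:
                out.append(Diagnostic(prefix + ".odds_ratio", f"must be > 0, got {rfe.odds_ratio}"))
            if rfe.effectiveness is not None:
                _check_proportion(rfe.effectiveness, prefix + ".effectiveness", out)
            _check_proportion(rfe.affected_fraction, prefix + ".affected_fraction", out)
        if iid not in scenario.coverage:
            out.append(Diagnostic(f"coverage[{iid}]", "no coverage trajectory for this intervention"))

    # --- coverage trajectories ---
    for iid, traj in scenario.coverage.items():
        prefix = f"coverage[{iid}]"
        if traj.intervention_id != iid:
            out.append(Diagnostic(prefix, f"key/intervention_id mismatch ({traj.intervention_id!r})"))
        if iid not in scenario.interventions:
            out.append(Diagnostic(prefix, "trajectory for unknown intervention"))
        if traj.baseline_year not in traj.coverage:
            out.append(Diagnostic(prefix + ".baseline_year", f"baseline year {traj.baseline_year} missing from trajectory"))
        for year, c in traj.coverage.items():
            if not (0.0 <= c <= 1.0):
                out.append(Diagnostic(f"{prefix}.coverage[{year}]", f"must be a proportion in [0, 1], got {c}"))

    # --- mortality profile ---
    for band in ALL_BANDS:
        risk = scenario.mortality.band_risk.get(band)
        if risk is None:
            out.append(Diagnostic(f"mortality.band_risk[{band.label}]", "missing"))
        else:
            _check_proportion(risk, f"mortality.band_risk[{band.label}]", out)
        fractions = scenario.mortality.cause_fractions.get(band)
        if fractions is None:
            out.append(Diagnostic(f"mortality.cause_fractions[{band.label}]", "missing"))
            continue
        total = sum(fractions.values())
        if abs(total - 1.0) > 1e-9:
            out.append(Diagnostic(
                f"mortality.cause_fractions[{band.label}]",
                f"fractions must sum to 1 within 1e-9, got {total}",
            ))
        for cause_name, frac in fractions.items():
            prefix = f"mortality.cause_fractions[{band.label}][{cause_name}]"
            _check_proportion(frac, prefix, out)
            cause = causes.get(cause_name)
            if cause is None:
                out.append(Diagnostic(prefix, f"unknown cause {cause_name!r}"))
            elif band not in cause.age_bands:
                out.append(Diagnostic(prefix, f"cause {cause_name!r} is not active in band {band.label}"))

    # --- births ---
    if not scenario.births:
        out.append(Diagnostic("births", "empty birth series"))
    for year, n in scenario.births.items():
        if n < 0:
            out.append(Diagnostic(f"births[{year}]", f"must be non-negative, got {n}"))

    # --- risk factors ---
    rf = scenario.risk_factors
    for band, p in rf.stunting_prevalence.items():
        if not (0.0 < p < 1.0):
            out.append(Diagnostic(f"risk_factors.stunting_prevalence[{band.label}]",
                                  f"must be strictly inside (0, 1), got {p}"))
    for band, p in rf.severe_wasting_prevalence.items():
        if not (0.0 < p < 1.0):
            out.append(Diagnostic(f"risk_factors.severe_wasting_prevalence[{band.label}]",
                                  f"must be strictly inside (0, 1), got {p}"))
    if rf.iugr_fraction is not None:
        _check_proportion(rf.iugr_fraction, "risk_factors.iugr_fraction", out)
    for band, eps in rf.diarrhoea_episodes.items():
        if eps < 0:
            out.append(Diagnostic(f"risk_factors.diarrhoea_episodes[{band.label}]",
                                  f"must be non-negative, got {eps}"))
    if rf.diarrhoea_episode_or is not None and rf.diarrhoea_episode_or <= 0:
        out.append(Diagnostic("risk_factors.diarrhoea_episode_or",
                              f"must be > 0, got {rf.diarrhoea_episode_or}"))
    for band, odds in rf.carry_or.items():
        if odds <= 0:
            out.append(Diagnostic(f"risk_factors.carry_or[{band.label}]", f"must be > 0, got {odds}"))
    if rf.iugr_stunting_or is not None and rf.iugr_stunting_or <= 0:
        out.append(Diagnostic("risk_factors.iugr_stunting_or",
                              f"must be > 0, got {rf.iugr_stunting_or}"))
    if rf.feeding is not None:
        for i, odds in enumerate(rf.feeding.odds_ratios):
            if odds <= 0:
                out.append(Diagnostic(f"risk_factors.feeding.odds_ratios[{i}]", f"must be > 0, got {odds}"))
        _check_proportion(rf.feeding.food_secure_fraction, "risk_factors.feeding.food_secure_fraction", out)
    for band, fractions in rf.breastfeeding_fractions.items():
        prefix = f"risk_factors.breastfeeding_fractions[{band.label}]"
        unknown = set(fractions) - set(BF_CATEGORIES)
        if unknown:
            out.append(Diagnostic(prefix, f"unknown categories {sorted(unknown)}"))
        total = sum(fractions.values())
        if abs(total - 1.0) > 1e-9:
            out.append(Diagnostic(prefix, f"category fractions must sum to 1, got {total}"))
    if rf.supplemental_feeding_split is not None:
        split = rf.supplemental_feeding_split
        if len(split) != 4 or any(s < 0 for s in split) or abs(sum(split) - 1.0) > 1e-9:
            out.append(Diagnostic("risk_factors.supplemental_feeding_split",
                                  f"must be four non-negative fractions summing to 1, got {split}"))
    return out
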
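"""End-to-end scenario evaluation.

Glue that turns a validated scenario into per-year, per-band, per-cause
combined mortality reductions and attribution shares, feeds them to the
cohort engine, and assembles tidy output tables.

Two kinds of unit enter the composition for a (cause, band, year) cell:
direct interventions (their isolated reductions, herd-adjusted where a
herd curve is present) and pseudo-interventions for the
intermediate-outcome routes (stunting, wasting, IUGR, breastfeeding).
Pseudo-units participate in tiered attribution like any intervention —
the IUGR route at the pregnancy tier, the nutrition routes at the
preventive tier — and their credited share is then expanded recursively
onto the real interventions that moved the risk factor, in proportion to
each one's isolated contribution.  Carried determinants (IUGR for the
neonatal band, previous-band stunting later) inherit the upstream
factor's weights, so credit flows through the cohort chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from . import anthropometry as anthro
from . import riskfactors as rf
from .cohort import CohortLedger, project, summarize_rates
from .core import (
    ALL_BANDS,
    BF_CATEGORIES,
    AgeBand,
    Diagnostic,
    Scenario,
    TimingTier,
    validate_scenario,
)
from .direct import attribute_shares, combine_reductions, single_reduction
from .herd import incremental_herd

__all__ = ["ScenarioValidationError", "RiskFactorYearState", "Results", "run_scenario"]

#: Attribution tier of each pseudo-intervention route.
PSEUDO_TIERS = {
    "~stunting": TimingTier.PREVENTIVE,
    "~wasting": TimingTier.PREVENTIVE,
    "~breastfeeding": TimingTier.PREVENTIVE,
    "~iugr": TimingTier.PREGNANCY,
}


class ScenarioValidationError(ValueError):
    """Raised when a scenario fails validation; carries the diagnostics."""

    def __init__(self, diagnostics: list[Diagnostic]):
        self.diagnostics = diagnostics
        lines = "\n".join(f"  - {d}" for d in diagnostics)
        super().__init__(f"scenario failed validation:\n{lines}")


# ---------------------------------------------------------------------------
# risk-factor state per year
# ---------------------------------------------------------------------------


@dataclass
class RiskFactorYearState:
    """Intermediate-outcome levels for one projection year, plus the
    per-intervention weights used to expand pseudo-attribution."""

    year: int
    stunting: dict[AgeBand, float] = field(default_factory=dict)
    stunting_weights: dict[AgeBand, dict[str, float]] = field(default_factory=dict)
    wasting_dist: dict[AgeBand, anthro.ZBandDistribution] = field(default_factory=dict)
    severe_wasting: dict[AgeBand, float] = field(default_factory=dict)
    wasting_weights: dict[AgeBand, dict[str, float]] = field(default_factory=dict)
    iugr: float | None = None
    iugr_weights: dict[str, float] = field(default_factory=dict)
    episodes: dict[AgeBand, float] = field(default_factory=dict)
    episode_weights: dict[str, float] = field(default_factory=dict)
    bf_fractions: dict[AgeBand, dict[str, float]] = field(default_factory=dict)
    bf_weights: dict[AgeBand, dict[str, float]] = field(default_factory=dict)


def _coverage_pair(scenario: Scenario, iid: str, year: int) -> tuple[float, float]:
    traj = scenario.coverage[iid]
    return traj.baseline, traj.at(year)


def _rf_interventions(scenario: Scenario, factor: str):
    for iid, spec in scenario.interventions.items():
        for eff in spec.risk_factor_effects:
            if eff.factor == factor:
                yield iid, eff


def _merge_weights(
    determinants: list[tuple[float, dict[str, float]]]
) -> dict[str, float]:
    """Combine per-determinant (reduction, sub-weights) into one weight
    dict: each determinant contributes its positive reduction, split over
    interventions by its normalised sub-weights."""
    out: dict[str, float] = {}
    for r, weights in determinants:
        if r <= 0:
            continue
        total = sum(w for w in weights.values() if w > 0)
        if total <= 0:
            continue
        for iid, w in weights.items():
            if w > 0:
                out[iid] = out.get(iid, 0.0) + r * w / total
    return out


def compute_risk_factor_state(scenario: Scenario, year: int) -> RiskFactorYearState:
    """Update every intermediate outcome for one projection year.

    Bands are swept youngest to oldest so the carried determinant
    (previous-band stunting) for a band uses the already-updated value of
    the band before it, mirroring cohort progression at the prevalence
    level.
    """
    cfg = scenario.risk_factors
    state = RiskFactorYearState(year=year)

    # --- IUGR (pregnancy-stage interventions) ---
    if cfg.iugr_fraction is not None:
        args, weights = [], {}
        for iid, eff in _rf_interventions(scenario, "iugr"):
            c0, ct = _coverage_pair(scenario, iid, year)
            r = single_reduction(eff.effectiveness or 0.0, eff.affected_fraction, c0, ct)
            args.append(r)
            weights[iid] = max(r, 0.0)
        state.iugr = cfg.iugr_fraction * (1.0 - combine_reductions(args))
        state.iugr_weights = weights

    # --- diarrhoea incidence (water & sanitation) ---
    wash = []
    for iid, eff in _rf_interventions(scenario, "diarrhoea_incidence"):
        c0, ct = _coverage_pair(scenario, iid, year)
        r = single_reduction(eff.effectiveness or 0.0, eff.affected_fraction, c0, ct)
        wash.append((iid, r))
    incidence_factor = 1.0 - combine_reductions([r for _i, r in wash])
    state.episode_weights = {iid: max(r, 0.0) for iid, r in wash}
    for band, e0 in cfg.diarrhoea_episodes.items():
        state.episodes[band] = e0 * incidence_factor

    # --- stunting, band by band ---
    prev_band: AgeBand | None = None
    for band in ALL_BANDS:
        p0 = cfg.stunting_prevalence.get(band)
        if p0 is None:
            prev_band = None
            continue
        determinants: list[tuple[float, dict[str, float]]] = []

        # carried risk: IUGR for the neonatal band, previous-band stunting after
        if band is AgeBand.NEONATAL:
            if (
                cfg.iugr_stunting_or is not None
                and cfg.iugr_fraction is not None
                and state.iugr is not None
            ):
                r = rf.two_state_prevalence_reduction(
                    cfg.iugr_stunting_or, cfg.iugr_fraction, state.iugr, p0
                )
                determinants.append((r, dict(state.iugr_weights)))
        elif prev_band is not None and band in cfg.carry_or:
            p_prev0 = cfg.stunting_prevalence[prev_band]
            p_prev_t = state.stunting[prev_band]
            r = rf.two_state_prevalence_reduction(
                cfg.carry_or[band], p_prev0, p_prev_t, p0
            )
            determinants.append((r, dict(state.stunting_weights.get(prev_band, {}))))

        # direct odds-ratio determinants (e.g. preventive zinc)
        for iid, eff in _rf_interventions(scenario, "stunting"):
            if eff.odds_ratio is None:
                continue
            c0, ct = _coverage_pair(scenario, iid, year)
            r = rf.two_state_prevalence_reduction(eff.odds_ratio, 1.0 - c0, 1.0 - ct, p0)
            determinants.append((r, {iid: 1.0}))

        # complementary feeding (four-status system)
        if cfg.feeding is not None:
            s = cfg.feeding.food_secure_fraction
            for iid, _eff in _rf_interventions(scenario, "complementary_feeding"):
                c0, ct = _coverage_pair(scenario, iid, year)
                if ct == c0:
                    continue
                fractions0 = (s * c0, s * (1 - c0), (1 - s) * c0, (1 - s) * (1 - c0))
                model = rf.FourStateFeedingModel(
                    odds_ratios=cfg.feeding.odds_ratios,
                    fractions=fractions0,
                    prevalence=p0,
                )
                probs = rf.solve_four_state(model)
                fractions_t = (s * ct, s * (1 - ct), (1 - s) * ct, (1 - s) * (1 - ct))
                projected = sum(f * q for f, q in zip(fractions_t, probs))
                determinants.append((rf.prevalence_reduction(p0, projected), {iid: 1.0}))

        # diarrhoea episodes
        if (
            cfg.diarrhoea_episode_or is not None
            and band in cfg.diarrhoea_episodes
            and cfg.diarrhoea_episodes[band] > 0
            and state.episodes[band] < cfg.diarrhoea_episodes[band]
        ):
            e0, et = cfg.diarrhoea_episodes[band], state.episodes[band]
            model = rf.diarrhoea_or_to_two_state(e0, et, cfg.diarrhoea_episode_or, p0)
            # at baseline every child has e0 episodes (risky fraction 1);
            # the decline moves the complement of target/baseline to zero
            p_risky, p_non = rf.solve_two_state(
                rf.TwoStateRiskModel(model.odds_ratio, 1.0, p0)
            )
            projected = rf.project_prevalence(p_risky, p_non, model.risky_fraction)
            determinants.append(
                (rf.prevalence_reduction(p0, projected), dict(state.episode_weights))
            )

        state.stunting[band] = rf.update_stunting_cohort(
            p0, [r for r, _w in determinants]
        )
        state.stunting_weights[band] = _merge_weights(determinants)
        prev_band = band

    # --- wasting (supplemental feeding) ---
    if cfg.supplemental_feeding_split is not None:
        for band, w0 in cfg.severe_wasting_prevalence.items():
            dist = anthro.prevalence_to_bands(w0, anchor_cut=-3.0)
            weights: dict[str, float] = {}
            for iid, _eff in _rf_interventions(scenario, "wasting"):
                c0, ct = _coverage_pair(scenario, iid, year)
                delta = max(ct - c0, 0.0)
                if delta > 0:
                    dist = anthro.apply_supplemental_feeding(
                        dist, delta, cfg.supplemental_feeding_split
                    )
                    weights[iid] = weights.get(iid, 0.0) + delta
            state.wasting_dist[band] = dist
            state.severe_wasting[band] = dist.below_minus3
            state.wasting_weights[band] = weights

    # --- breastfeeding categories ---
    for band, fractions0 in cfg.breastfeeding_fractions.items():
        fractions = dict(fractions0)
        weights = {}
        for iid, eff in _rf_interventions(scenario, "breastfeeding"):
            if eff.odds_ratio is None:
                continue
            c0, ct = _coverage_pair(scenario, iid, year)
            fractions = rf.update_breastfeeding(fractions, eff.odds_ratio, c0, ct)
            weights[iid] = weights.get(iid, 0.0) + max(ct - c0, 0.0)
        state.bf_fractions[band] = fractions
        state.bf_weights[band] = weights

    return state


# ---------------------------------------------------------------------------
# per-cell reduction assembly
# ---------------------------------------------------------------------------


def _direct_units(
    scenario: Scenario, year: int
) -> dict[tuple[AgeBand, str], dict[str, float]]:
    """Isolated (herd-adjusted) direct reductions per (band, cause) cell."""
    cells: dict[tuple[AgeBand, str], dict[str, float]] = {}
    for iid, spec in scenario.interventions.items():
        if not spec.effects:
            continue
        c0, ct = _coverage_pair(scenario, iid, year)
        herd_increment = (
            incremental_herd(spec.herd, c0, ct) if spec.herd is not None else 0.0
        )
        for (cause, band), eff in spec.effects.items():
            r = single_reduction(eff.effectiveness, eff.affected_fraction, c0, ct)
            if herd_increment != 0.0:
                # herd acts on the mortality the direct effect leaves behind
                r = 1.0 - (1.0 - r) * (1.0 - herd_increment)
            cells.setdefault((band, cause), {})[iid] = r
    return cells


def _arr_reduction_from_bands(
    dist0: anthro.ZBandDistribution,
    dist_t: anthro.ZBandDistribution,
    table: anthro.RelativeRiskTable,
    cause: str,
    band: AgeBand,
) -> float:
    arr0 = anthro.average_relative_risk(dist0, table, cause, band)
    arrt = anthro.average_relative_risk(dist_t, table, cause, band)
    return anthro.mortality_reduction_from_arr(arrt, arr0)


def assemble_year(
    scenario: Scenario, year: int, state: RiskFactorYearState
) -> tuple[
    dict[tuple[AgeBand, str], float],
    dict[tuple[AgeBand, str], dict[str, float]],
]:
    """Combined reductions and expanded attribution shares for one year.

    Returns ``(reductions, shares)`` keyed by (band, cause).  Shares are
    expanded: pseudo-route credit is redistributed to the interventions
    that moved the underlying risk factor; credit that cannot be traced
    to an intervention keeps the pseudo label.
    """
    cfg = scenario.risk_factors
    cells = _direct_units(scenario, year)
    pseudo_weights: dict[tuple[str, AgeBand], dict[str, float]] = {}

    # stunting route
    if cfg.stunting_rr is not None:
        for band, p_t in state.stunting.items():
            p0 = cfg.stunting_prevalence[band]
            if p_t == p0:
                continue
            dist0 = anthro.prevalence_to_bands(p0)
            dist_t = anthro.prevalence_to_bands(p_t)
            for cause in cfg.stunting_rr.causes_for(band):
                r = _arr_reduction_from_bands(dist0, dist_t, cfg.stunting_rr, cause, band)
                if r != 0.0:
                    cells.setdefault((band, cause), {})["~stunting"] = r
                    pseudo_weights[("~stunting", band)] = state.stunting_weights.get(band, {})

    # wasting route
    if cfg.wasting_rr is not None:
        for band, dist_t in state.wasting_dist.items():
            w0 = cfg.severe_wasting_prevalence[band]
            dist0 = anthro.prevalence_to_bands(w0, anchor_cut=-3.0)
            if dist_t.fractions == dist0.fractions:
                continue
            for cause in cfg.wasting_rr.causes_for(band):
                r = _arr_reduction_from_bands(dist0, dist_t, cfg.wasting_rr, cause, band)
                if r != 0.0:
                    cells.setdefault((band, cause), {})["~wasting"] = r
                    pseudo_weights[("~wasting", band)] = state.wasting_weights.get(band, {})

    # IUGR route (neonatal, two statuses)
    if cfg.iugr_rr and cfg.iugr_fraction is not None and state.iugr is not None:
        p0, p_t = cfg.iugr_fraction, state.iugr
        if p_t != p0:
            band = AgeBand.NEONATAL
            for cause, risk_ratio in cfg.iugr_rr.items():
                arr0 = p0 * risk_ratio + (1.0 - p0)
                arrt = p_t * risk_ratio + (1.0 - p_t)
                r = anthro.mortality_reduction_from_arr(arrt, arr0)
                if r != 0.0:
                    cells.setdefault((band, cause), {})["~iugr"] = r
                    pseudo_weights[("~iugr", band)] = dict(state.iugr_weights)

    # breastfeeding route (category relative risks, exclusive as reference)
    if cfg.breastfeeding_rr:
        for band, fractions_t in state.bf_fractions.items():
            fractions0 = cfg.breastfeeding_fractions[band]
            if fractions_t == fractions0:
                continue
            causes = sorted({c for (c, b, _cat) in cfg.breastfeeding_rr if b == band})
            for cause in causes:
                def arr(fracs: Mapping[str, float]) -> float:
                    return sum(
                        fracs.get(cat, 0.0)
                        * cfg.breastfeeding_rr.get((cause, band, cat), 1.0)
                        for cat in BF_CATEGORIES
                    )

                r = anthro.mortality_reduction_from_arr(arr(fractions_t), arr(fractions0))
                if r != 0.0:
                    cells.setdefault((band, cause), {})["~breastfeeding"] = r
                    pseudo_weights[("~breastfeeding", band)] = state.bf_weights.get(band, {})

    reductions: dict[tuple[AgeBand, str], float] = {}
    shares: dict[tuple[AgeBand, str], dict[str, float]] = {}
    tiers = {iid: spec.tier for iid, spec in scenario.interventions.items()}
    tiers.update(PSEUDO_TIERS)

    for (band, cause), units in cells.items():
        combined = combine_reductions(units.values())
        if combined == 0.0 and all(r == 0.0 for r in units.values()):
            continue
        reductions[(band, cause)] = combined
        raw = attribute_shares(units, tiers)
        expanded: dict[str, float] = {}
        for name, share in raw.items():
            if share == 0.0:
                continue
            if name.startswith("~"):
                weights = pseudo_weights.get((name, band), {})
                wsum = sum(weights.values())
                if wsum > 0:
                    for iid, w in weights.items():
                        expanded[iid] = expanded.get(iid, 0.0) + share * w / wsum
                else:
                    expanded[name] = expanded.get(name, 0.0) + share
            else:
                expanded[name] = expanded.get(name, 0.0) + share
        shares[(band, cause)] = expanded
    return reductions, shares


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------


@dataclass
class Results:
    """Everything a scenario run produces."""

    scenario: Scenario
    ledger: CohortLedger
    rates: pd.DataFrame
    deaths: pd.DataFrame
    averted_by_intervention: pd.DataFrame
    nutrition: pd.DataFrame
    reductions: dict[tuple[int, AgeBand, str], float]
    shares: dict[tuple[int, AgeBand, str], dict[str, float]]

    def write(self, outdir, fmt: str = "csv") -> list[str]:
        """Write the output tables; returns the file paths written.

        CSV floats use a fixed repr so re-running on identical inputs
        yields byte-identical files.
        """
        import os

        os.makedirs(outdir, exist_ok=True)
        tables = {
            "rates": self.rates,
            "deaths": self.deaths,
            "deaths_averted_by_intervention": self.averted_by_intervention,
            "nutrition": self.nutrition,
        }
        written = []
        for name, table in tables.items():
            if fmt == "csv":
                path = os.path.join(outdir, f"{name}.csv")
                table.to_csv(path, index=False, float_format="%.10g")
            elif fmt == "json":
                path = os.path.join(outdir, f"{name}.json")
                table.to_json(path, orient="records", indent=2)
            else:
                raise ValueError(f"unknown format {fmt!r}")
            written.append(path)
        return written


def _nutrition_table(
    scenario: Scenario, states: dict[int, RiskFactorYearState]
) -> pd.DataFrame:
    cfg = scenario.risk_factors
    rows = []
    for year, state in states.items():
        for band in ALL_BANDS:
            row = {"year": year, "band": band.label}
            row["stunting"] = state.stunting.get(band, cfg.stunting_prevalence.get(band))
            row["severe_wasting"] = state.severe_wasting.get(
                band, cfg.severe_wasting_prevalence.get(band)
            )
            row["diarrhoea_episodes"] = state.episodes.get(
                band, cfg.diarrhoea_episodes.get(band)
            )
            bf = state.bf_fractions.get(band, cfg.breastfeeding_fractions.get(band, {}))
            row["exclusive_bf"] = bf.get("exclusive")
            row["iugr"] = (
                state.iugr if band is AgeBand.NEONATAL and state.iugr is not None else None
            )
            rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["year", "band", "stunting", "severe_wasting", "diarrhoea_episodes", "exclusive_bf", "iugr"],
    )


def run_scenario(
    scenario: Scenario,
    start_year: int | None = None,
    end_year: int | None = None,
) -> Results:
    """Validate, compute reductions and attribution, project, summarise.

    ``start_year`` defaults to the scenario baseline year; ``end_year``
    to the last year every coverage trajectory covers.  Raises
    :class:`ScenarioValidationError` on a malformed bundle and
    :class:`~childimpact.core.MissingYearError` when a trajectory has a
    gap inside the projection window.
    """
    diagnostics = validate_scenario(scenario)
    if diagnostics:
        raise ScenarioValidationError(diagnostics)

    if start_year is None:
        start_year = scenario.baseline_year
    if end_year is None:
        if scenario.coverage:
            end_year = min(max(t.coverage) for t in scenario.coverage.values())
        else:
            end_year = max(scenario.births, default=start_year)
        end_year = max(end_year, start_year)

    reductions: dict[tuple[int, AgeBand, str], float] = {}
    shares: dict[tuple[int, AgeBand, str], dict[str, float]] = {}
    states: dict[int, RiskFactorYearState] = {}
    for year in range(start_year, end_year + 1):
        state = compute_risk_factor_state(scenario, year)
        states[year] = state
        year_reductions, year_shares = assemble_year(scenario, year, state)
        for (band, cause), r in year_reductions.items():
            reductions[(year, band, cause)] = r
        for (band, cause), s in year_shares.items():
            shares[(year, band, cause)] = s

    ledger = project(scenario, reductions, shares, start_year, end_year)
    return Results(
        scenario=scenario,
        ledger=ledger,
        rates=summarize_rates(ledger),
        deaths=ledger.deaths_table(),
        averted_by_intervention=ledger.averted_table(),
        nutrition=_nutrition_table(scenario, states),
        reductions=reductions,
        shares=shares,
    )
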
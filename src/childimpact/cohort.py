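"""Simplified cohort-component projection of deaths and deaths averted.

Annual birth cohorts are carried through the five age bands.  Each band
has a per-child all-cause mortality risk over the band's duration,
distributed over causes by the baseline cause-of-death fractions;
scenario runs multiply each cause's deaths by (1 - R) with R the
combined cause-specific reduction for that band and calendar year.

Births within a year are taken as uniform, so a cohort born in year t
enters band b at calendar time t + (band entry age); the entrants split
between the two calendar years the entry window overlaps, in proportion
to the overlap.  Survivors age into the next band, which produces the
spillover the calculus requires: averting neonatal deaths increases the
number of children exposed to post-neonatal mortality.

Deaths averted per (cause, band, year) are baseline deaths minus
scenario deaths; they are apportioned to interventions by the supplied
attribution shares and summed across causes per intervention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .core import ALL_BANDS, AgeBand, Scenario

__all__ = ["CohortLedger", "project", "summarize_rates"]

#: Years of pre-baseline simulation needed so every band is populated by
#: cohorts in steady state when reporting starts (the oldest band is
#: entered two years after birth and lasts three).
WARMUP_YEARS = 5


@dataclass
class CohortLedger:
    """Projection bookkeeping for a baseline/scenario pair of runs."""

    years: list[int]
    entrants: dict[tuple[int, AgeBand], float] = field(default_factory=dict)
    baseline_entrants: dict[tuple[int, AgeBand], float] = field(default_factory=dict)
    deaths: dict[tuple[int, AgeBand, str], float] = field(default_factory=dict)
    baseline_deaths: dict[tuple[int, AgeBand, str], float] = field(default_factory=dict)
    #: attributed deaths averted per (year, band, cause, intervention)
    attributed: dict[tuple[int, AgeBand, str, str], float] = field(default_factory=dict)

    def averted(self, year: int, band: AgeBand, cause: str) -> float:
        return (
            self.baseline_deaths.get((year, band, cause), 0.0)
            - self.deaths.get((year, band, cause), 0.0)
        )

    def total_deaths(self, year: int, band: AgeBand) -> float:
        return sum(
            d for (y, b, _c), d in self.deaths.items() if y == year and b == band
        )

    def averted_by_intervention(self) -> dict[tuple[int, str], float]:
        """Deaths averted per (year, intervention), summed across causes
        and bands."""
        out: dict[tuple[int, str], float] = {}
        for (year, _band, _cause, iid), d in self.attributed.items():
            out[(year, iid)] = out.get((year, iid), 0.0) + d
        return out

    # ---- tidy tables ----

    def deaths_table(self) -> pd.DataFrame:
        rows = [
            {
                "year": y,
                "band": b.label,
                "cause": c,
                "deaths": self.deaths.get((y, b, c), 0.0),
                "baseline_deaths": self.baseline_deaths.get((y, b, c), 0.0),
                "deaths_averted": self.averted(y, b, c),
            }
            for y in self.years
            for b in ALL_BANDS
            for c in sorted({k[2] for k in self.baseline_deaths if k[0] == y and k[1] == b})
        ]
        return pd.DataFrame(rows, columns=["year", "band", "cause", "deaths", "baseline_deaths", "deaths_averted"])

    def averted_table(self) -> pd.DataFrame:
        by_int = self.averted_by_intervention()
        interventions = sorted({iid for (_y, iid) in by_int})
        rows = [
            {"year": y, "intervention": iid, "deaths_averted": by_int.get((y, iid), 0.0)}
            for y in self.years
            for iid in interventions
        ]
        return pd.DataFrame(rows, columns=["year", "intervention", "deaths_averted"])


def _births_at(births: Mapping[int, float], year: int) -> float:
    """Birth series clamped to its first/last value outside its range."""
    if year in births:
        return births[year]
    lo, hi = min(births), max(births)
    if year < lo:
        return births[lo]
    return births[hi]


def project(
    scenario: Scenario,
    reductions: Mapping[tuple[int, AgeBand, str], float] | None = None,
    shares: Mapping[tuple[int, AgeBand, str], Mapping[str, float]] | None = None,
    start_year: int | None = None,
    end_year: int | None = None,
) -> CohortLedger:
    """Run the baseline and scenario cohort projections.

    ``reductions`` maps (year, band, cause) to the combined proportional
    mortality reduction; missing keys mean no change.  ``shares`` carries
    the attribution of each (year, band, cause) reduction over
    interventions; attributed deaths averted sum to the total averted for
    that cell by construction.  Years before the scenario baseline use
    baseline mortality.

    A baseline run (empty ``reductions``) reproduces baseline mortality
    exactly, so deaths averted are zero everywhere.
    """
    reductions = reductions or {}
    shares = shares or {}
    if start_year is None:
        start_year = scenario.baseline_year
    if end_year is None:
        end_year = max(start_year, max(scenario.births, default=start_year))
    if end_year < start_year:
        raise ValueError(f"end_year {end_year} before start_year {start_year}")

    years = list(range(start_year, end_year + 1))
    ledger = CohortLedger(years=years)
    profile = scenario.mortality

    for birth_year in range(start_year - WARMUP_YEARS, end_year + 1):
        n_base = _births_at(scenario.births, birth_year)
        n_scen = n_base
        for band in ALL_BANDS:
            risk = profile.band_risk[band]
            fractions = profile.cause_fractions[band]
            entry = birth_year + band.start_years
            y0 = math.floor(entry)
            frac = entry - y0
            weights = [(y0, 1.0 - frac)]
            if frac > 0:
                weights.append((y0 + 1, frac))

            surv_base = 0.0
            surv_scen = 0.0
            for year, w in weights:
                in_range = start_year <= year <= end_year
                portion_base = w * n_base
                portion_scen = w * n_scen
                if in_range:
                    key = (year, band)
                    ledger.baseline_entrants[key] = ledger.baseline_entrants.get(key, 0.0) + portion_base
                    ledger.entrants[key] = ledger.entrants.get(key, 0.0) + portion_scen
                d_base_total = 0.0
                d_scen_total = 0.0
                for cause, f in fractions.items():
                    d_base = portion_base * risk * f
                    r = reductions.get((year, band, cause), 0.0) if year >= start_year else 0.0
                    d_scen = portion_scen * risk * f * (1.0 - r)
                    d_base_total += d_base
                    d_scen_total += d_scen
                    if in_range:
                        ck = (year, band, cause)
                        ledger.baseline_deaths[ck] = ledger.baseline_deaths.get(ck, 0.0) + d_base
                        ledger.deaths[ck] = ledger.deaths.get(ck, 0.0) + d_scen
                surv_base += portion_base - d_base_total
                surv_scen += portion_scen - d_scen_total
            n_base = surv_base
            n_scen = surv_scen

    for (year, band, cause), base_d in ledger.baseline_deaths.items():
        averted = base_d - ledger.deaths.get((year, band, cause), 0.0)
        if averted == 0.0:
            continue
        cell_shares = shares.get((year, band, cause), {})
        for iid, s in cell_shares.items():
            if s == 0.0:
                continue
            ak = (year, band, cause, iid)
            ledger.attributed[ak] = ledger.attributed.get(ak, 0.0) + averted * s
    return ledger


def summarize_rates(ledger: CohortLedger) -> pd.DataFrame:
    """Neonatal, infant, and under-five mortality rates per 1000 births.

    Per-year band risks are deaths over entrants for that calendar year;
    the summary rates are cumulative cohort death risks over the
    constituent bands, 1 - prod(1 - risk_b), scaled per 1000 births.
    """
    rows = []
    for year in ledger.years:
        risks = {}
        for band in ALL_BANDS:
            entrants = ledger.entrants.get((year, band), 0.0)
            deaths = ledger.total_deaths(year, band)
            risks[band] = deaths / entrants if entrants > 0 else 0.0
        nmr = 1000.0 * risks[AgeBand.NEONATAL]
        infant_bands = (AgeBand.NEONATAL, AgeBand.M1_5, AgeBand.M6_11)
        imr = 1000.0 * (1.0 - math.prod(1.0 - risks[b] for b in infant_bands))
        u5mr = 1000.0 * (1.0 - math.prod(1.0 - risks[b] for b in ALL_BANDS))
        rows.append({"year": year, "nmr": nmr, "imr": imr, "u5mr": u5mr})
    return pd.DataFrame(rows, columns=["year", "nmr", "imr", "u5mr"])
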
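"""Cohort projection: closed-form death counts, spillover, and rates."""

import math

import pytest

import childimpact as ci
from childimpact.cohort import project, summarize_rates
from childimpact.core import ALL_BANDS, AgeBand, MortalityProfile, Scenario


def _single_cause_scenario(
    neonatal_risk=0.03,
    post_risk=0.01,
    diarrhoea_fraction=0.2,
    births=1000.0,
    years=(2020, 2024),
) -> Scenario:
    """Minimal profile: diarrhoea plus the residual in every band."""
    profile = MortalityProfile(
        band_risk={
            band: (neonatal_risk if band is AgeBand.NEONATAL else post_risk)
            for band in ALL_BANDS
        },
        cause_fractions={
            band: {"diarrhoea": diarrhoea_fraction, "other": 1 - diarrhoea_fraction}
            for band in ALL_BANDS
        },
    )
    return Scenario(
        name="single-cause",
        baseline_year=years[0],
        births={y: births for y in range(years[0], years[1] + 1)},
        mortality=profile,
    )


class TestProject:
    def test_no_reductions_avert_nothing(self):
        scenario = _single_cause_scenario()
        ledger = project(scenario)
        for (year, band, cause) in ledger.baseline_deaths:
            assert ledger.averted(year, band, cause) == 0.0

    def test_single_band_closed_form(self):
        scenario = _single_cause_scenario()
        reductions = {
            (year, AgeBand.NEONATAL, "diarrhoea"): 0.466 for year in range(2020, 2025)
        }
        shares = {k: {"ors": 1.0} for k in reductions}
        ledger = project(scenario, reductions, shares)
        key = (2020, AgeBand.NEONATAL, "diarrhoea")
        assert ledger.baseline_deaths[key] == pytest.approx(6.0)
        assert ledger.deaths[key] == pytest.approx(6.0 * (1 - 0.466))  # 3.204
        assert ledger.averted(*key) == pytest.approx(2.796)
        assert ledger.attributed[(*key, "ors")] == pytest.approx(2.796)

    def test_neonatal_reduction_spills_into_next_band(self):
        scenario = _single_cause_scenario()
        reductions = {
            (year, AgeBand.NEONATAL, "diarrhoea"): 0.466 for year in range(2015, 2025)
        }
        ledger = project(scenario, reductions)
        # steady state: extra entrants to 1-5m equal the neonatal deaths averted
        year = 2023
        extra = (
            ledger.entrants[(year, AgeBand.M1_5)]
            - ledger.baseline_entrants[(year, AgeBand.M1_5)]
        )
        averted = ledger.averted(year, AgeBand.NEONATAL, "diarrhoea")
        assert extra == pytest.approx(averted, rel=1e-9)
        assert averted == pytest.approx(1000 * 0.03 * 0.2 * 0.466)

    def test_cause_deaths_sum_to_all_cause(self):
        scenario = _single_cause_scenario()
        reductions = {(2021, AgeBand.M1_5, "diarrhoea"): 0.3}
        ledger = project(scenario, reductions)
        for year in ledger.years:
            for band in ALL_BANDS:
                total = ledger.total_deaths(year, band)
                risk = scenario.mortality.band_risk[band]
                entrants = ledger.entrants.get((year, band), 0.0)
                assert total <= entrants + 1e-9
        assert ledger.total_deaths(2020, AgeBand.NEONATAL) == pytest.approx(
            1000 * 0.03
        )

    def test_scenario_deaths_never_exceed_baseline_in_total(self):
        scenario = _single_cause_scenario()
        reductions = {
            (y, b, "diarrhoea"): 0.4 for y in range(2020, 2025) for b in ALL_BANDS
        }
        ledger = project(scenario, reductions)
        assert sum(ledger.deaths.values()) <= sum(ledger.baseline_deaths.values())


class TestSummarizeRates:
    def test_zero_mortality_gives_zero_rates(self):
        scenario = _single_cause_scenario(neonatal_risk=0.0, post_risk=0.0)
        rates = summarize_rates(project(scenario))
        assert (rates[["nmr", "imr", "u5mr"]] == 0).all().all()

    def test_survival_product_for_infant_rate(self):
        # neonatal risk 0.03, infant bands 0.01 each: survival-product oracle
        scenario = _single_cause_scenario(neonatal_risk=0.03, post_risk=0.01)
        rates = summarize_rates(project(scenario))
        steady = rates[rates.year >= 2022]
        expected_imr = (1 - 0.97 * 0.99 * 0.99) * 1000  # 49.303
        assert steady["nmr"].iloc[0] == pytest.approx(30.0, abs=1e-9)
        assert steady["imr"].iloc[0] == pytest.approx(expected_imr, abs=1e-9)

    def test_constant_conditions_give_constant_rates(self):
        scenario = _single_cause_scenario()
        rates = summarize_rates(project(scenario))
        for column in ("nmr", "imr", "u5mr"):
            assert rates[column].nunique() == 1
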
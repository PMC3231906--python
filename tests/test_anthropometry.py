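"""Shifted-normal z-band placement and relative-risk mortality reductions."""

import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from childimpact import (
    RelativeRiskTable,
    ZBandDistribution,
    apply_supplemental_feeding,
    average_relative_risk,
    mortality_reduction_from_arr,
    prevalence_to_bands,
)

prevalences = st.floats(min_value=1e-3, max_value=1 - 1e-3, allow_nan=False)


class TestPrevalenceToBands:
    @given(prevalences)
    def test_recovers_input_prevalence(self, p):
        bands = prevalence_to_bands(p)
        assert bands.below_minus2 == pytest.approx(p, abs=1e-12)
        assert sum(bands.fractions) == pytest.approx(1.0, abs=1e-12)

    def test_half_stunted_distribution(self):
        bands = prevalence_to_bands(0.50)
        # shift of -2: mass below -3 is Phi(-1)
        assert bands.below_minus3 == pytest.approx(norm.cdf(-1.0), abs=1e-12)

    def test_standard_population_is_nearly_unshifted(self):
        bands = prevalence_to_bands(norm.cdf(-2.0))
        for frac, expected in zip(
            bands.fractions,
            (norm.cdf(-3), norm.cdf(-2) - norm.cdf(-3), norm.cdf(-1) - norm.cdf(-2), 1 - norm.cdf(-1)),
        ):
            assert frac == pytest.approx(expected, abs=1e-12)

    @given(prevalences, prevalences)
    def test_monotone_leftward_shift(self, a, b):
        lo, hi = min(a, b), max(a, b)
        lo_bands, hi_bands = prevalence_to_bands(lo), prevalence_to_bands(hi)
        # every cumulative band gains mass as prevalence rises
        assert hi_bands.below_minus3 >= lo_bands.below_minus3 - 1e-12
        assert hi_bands.below_minus2 >= lo_bands.below_minus2 - 1e-12

    def test_severe_wasting_anchor(self):
        bands = prevalence_to_bands(0.05, anchor_cut=-3.0)
        assert bands.below_minus3 == pytest.approx(0.05, abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_prevalence_rejected(self, bad):
        with pytest.raises(ValueError):
            prevalence_to_bands(bad)


class TestAverageRelativeRisk:
    def test_dot_product(self):
        bands = ZBandDistribution((0.1, 0.2, 0.3, 0.4))
        assert average_relative_risk(bands, (4.6, 2.1, 1.4, 1.0)) == pytest.approx(1.70)

    def test_reference_mass_only(self):
        bands = ZBandDistribution((0.0, 0.0, 0.0, 1.0))
        assert average_relative_risk(bands, (4.6, 2.1, 1.4, 1.0)) == 1.0

    @given(st.tuples(prevalences, prevalences, prevalences, prevalences))
    def test_unit_risks_always_give_one(self, raw):
        total = sum(raw)
        bands = ZBandDistribution(tuple(x / total for x in raw))
        assert average_relative_risk(bands, (1.0, 1.0, 1.0, 1.0)) == pytest.approx(1.0)

    def test_table_lookup(self):
        table = RelativeRiskTable(
            rr={("diarrhoea", "1-5m", 0): 4.6, ("diarrhoea", "1-5m", 1): 2.1,
                ("diarrhoea", "1-5m", 2): 1.4}
        )
        bands = ZBandDistribution((0.1, 0.2, 0.3, 0.4))
        assert average_relative_risk(bands, table, "diarrhoea", "1-5m") == pytest.approx(1.70)

    def test_reference_band_must_be_one(self):
        with pytest.raises(ValueError):
            RelativeRiskTable(rr={("x", "0m", 3): 2.0})


class TestMortalityReductionFromArr:
    @pytest.mark.parametrize(
        "arr_t, arr_0, expected",
        [(1.5, 1.5, 0.0), (1.36, 1.70, 0.20), (2.0, 1.0, -1.0)],
    )
    def test_values_and_sign_convention(self, arr_t, arr_0, expected):
        assert mortality_reduction_from_arr(arr_t, arr_0) == pytest.approx(expected)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            mortality_reduction_from_arr(1.0, 0.0)

    def test_unchanged_band_distribution_gives_zero(self):
        bands = prevalence_to_bands(0.3)
        rr = (4.6, 2.1, 1.4, 1.0)
        arr = average_relative_risk(bands, rr)
        assert mortality_reduction_from_arr(arr, arr) == 0.0


class TestSupplementalFeeding:
    SPLIT = (0.2, 0.3, 0.3, 0.2)

    def test_zero_coverage_change_is_identity(self):
        bands = prevalence_to_bands(0.08, anchor_cut=-3.0)
        assert apply_supplemental_feeding(bands, 0.0, self.SPLIT).fractions == bands.fractions

    def test_fully_ineffective_split_is_identity(self):
        bands = prevalence_to_bands(0.08, anchor_cut=-3.0)
        out = apply_supplemental_feeding(bands, 0.7, (0.0, 0.0, 0.0, 1.0))
        assert out.fractions == pytest.approx(bands.fractions, abs=1e-15)

    def test_mass_bookkeeping(self):
        bands = ZBandDistribution((0.10, 0.15, 0.25, 0.50))
        out = apply_supplemental_feeding(bands, 1.0, self.SPLIT)
        assert out.below_minus3 == pytest.approx(0.10 - 0.10 * 0.8)
        assert out.fractions[1] == pytest.approx(0.15 + 0.10 * 0.3)
        assert out.fractions[2] == pytest.approx(0.25 + 0.10 * 0.3)
        assert out.fractions[3] == pytest.approx(0.50 + 0.10 * 0.2)

    @given(
        prevalences,
        st.floats(min_value=0.0, max_value=1.0),
        st.tuples(prevalences, prevalences, prevalences, prevalences),
    )
    def test_conserves_mass(self, severe, coverage, raw_split):
        total = sum(raw_split)
        split = tuple(x / total for x in raw_split)
        bands = prevalence_to_bands(severe, anchor_cut=-3.0)
        out = apply_supplemental_feeding(bands, coverage, split)
        assert sum(out.fractions) == pytest.approx(1.0, abs=1e-12)

    def test_bad_split_rejected(self):
        bands = prevalence_to_bands(0.05, anchor_cut=-3.0)
        with pytest.raises(ValueError):
            apply_supplemental_feeding(bands, 0.5, (0.5, 0.5, 0.5, 0.5))
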
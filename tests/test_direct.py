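"""Direct-effect calculus: isolated reductions, composition, attribution."""

import math
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from childimpact import (
    TimingTier,
    all_cause_reduction,
    attribute_shares,
    combine_reductions,
    single_reduction,
)
from childimpact.herd import SaturatedBaselineError

reductions_in_unit = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


class TestSingleReduction:
    @pytest.mark.parametrize(
        "effectiveness, affected, c0, ct, expected",
        [
            (0.93, 0.95, 0.25, 0.50, 0.288),  # ORS scale-up
            (0.85, 1.00, 0.75, 0.97, 0.516),  # measles vaccine direct effect
        ],
    )
    def test_worked_values(self, effectiveness, affected, c0, ct, expected):
        r = single_reduction(effectiveness, affected, c0, ct)
        assert round(r, 3) == expected

    @given(
        effectiveness=reductions_in_unit,
        affected=reductions_in_unit,
        c=reductions_in_unit,
    )
    def test_no_coverage_change_gives_zero(self, effectiveness, affected, c):
        if effectiveness * c < 1.0:
            assert single_reduction(effectiveness, affected, c, c) == 0.0

    def test_coverage_decline_gives_negative(self):
        assert single_reduction(0.5, 1.0, 0.6, 0.3) < 0

    def test_saturated_baseline_raises(self):
        with pytest.raises(SaturatedBaselineError):
            single_reduction(1.0, 1.0, 1.0, 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            single_reduction(1.2, 1.0, 0.0, 0.5)


class TestCombineReductions:
    @pytest.mark.parametrize(
        "rs, expected, digits",
        [
            ([0.288, 0.25], 0.466, 3),
            ([0.306, 0.288, 0.25], 0.629, 3),
            ([], 0.0, 12),
        ],
    )
    def test_worked_values(self, rs, expected, digits):
        assert round(combine_reductions(rs), digits) == expected

    @given(st.lists(reductions_in_unit, max_size=6), st.randoms(use_true_random=False))
    def test_permutation_invariant(self, rs, rnd):
        shuffled = list(rs)
        rnd.shuffle(shuffled)
        assert math.isclose(
            combine_reductions(rs), combine_reductions(shuffled), abs_tol=1e-12
        )

    @given(reductions_in_unit)
    def test_single_element_identity(self, r):
        assert combine_reductions([r]) == pytest.approx(r, abs=1e-15)

    @given(reductions_in_unit, reductions_in_unit, reductions_in_unit)
    def test_monotone_in_each_argument(self, a, b, delta):
        bigger = min(1.0, a + delta)
        assert combine_reductions([bigger, b]) >= combine_reductions([a, b]) - 1e-12

    def test_rejects_doubling(self):
        with pytest.raises(ValueError):
            combine_reductions([-1.0])


class TestAttributeShares:
    def test_single_tier_worked_values(self):
        shares = attribute_shares({"ors": 0.288, "zinc": 0.250})
        assert round(shares["ors"], 3) == 0.535
        assert round(shares["zinc"], 3) == 0.465

    def test_tiered_worked_values(self):
        tiers = {
            "rota": TimingTier.VACCINES,
            "ors": TimingTier.CURATIVE,
            "zinc": TimingTier.CURATIVE,
        }
        shares = attribute_shares({"rota": 0.306, "ors": 0.288, "zinc": 0.250}, tiers)
        assert round(100 * shares["rota"], 1) == 48.6
        assert round(100 * shares["ors"], 1) == 27.5
        assert round(100 * shares["zinc"], 1) == 23.9

    def test_sole_contributor_gets_everything(self):
        assert attribute_shares({"only": 0.4}) == {"only": 1.0}

    def test_zero_total_gives_zero_shares(self):
        assert attribute_shares({"a": 0.0, "b": 0.0}) == {"a": 0.0, "b": 0.0}

    def test_negative_reduction_warns_and_gets_zero(self):
        with pytest.warns(UserWarning):
            shares = attribute_shares({"up": 0.3, "down": -0.2})
        assert shares["down"] == 0.0
        assert shares["up"] == 1.0

    @given(
        rs=st.lists(
            st.floats(min_value=0.01, max_value=0.95), min_size=1, max_size=8
        ),
        tier_seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_shares_sum_to_one_for_random_tiers(self, rs, tier_seed):
        rnd = random.Random(tier_seed)
        names = [f"i{k}" for k in range(len(rs))]
        tiers = {n: rnd.choice(list(TimingTier)) for n in names}
        shares = attribute_shares(dict(zip(names, rs)), tiers)
        assert math.isclose(sum(shares.values()), 1.0, abs_tol=1e-9)

    @given(
        rs=st.lists(st.floats(min_value=0.01, max_value=0.95), min_size=1, max_size=8)
    )
    def test_single_tier_matches_proportional_formula(self, rs):
        """With every intervention in one tier, shares reduce to R_i / sum R_i."""
        names = [f"i{k}" for k in range(len(rs))]
        shares = attribute_shares(dict(zip(names, rs)))
        total = sum(rs)
        for name, r in zip(names, rs):
            assert shares[name] == pytest.approx(r / total, abs=1e-12)


class TestAllCauseReduction:
    def test_worked_value(self):
        fractions = {"diarrhoea": 0.20, "other": 0.80}
        assert all_cause_reduction({"diarrhoea": 0.46}, fractions) == pytest.approx(0.092)

    def test_conservation_limits(self):
        fractions = {"a": 0.3, "b": 0.7}
        assert all_cause_reduction({}, fractions) == 0.0
        assert all_cause_reduction({"a": 1.0, "b": 1.0}, fractions) == pytest.approx(1.0)

    def test_rejects_unnormalised_fractions(self):
        with pytest.raises(ValueError):
            all_cause_reduction({}, {"a": 0.5})
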
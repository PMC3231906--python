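"""Odds-ratio risk-factor machinery: two-state and four-state solves,
diarrhoea incidence mapping, cohort stunting updates, breastfeeding."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from childimpact import (
    FourStateFeedingModel,
    TwoStateRiskModel,
    diarrhoea_or_to_two_state,
    prevalence_reduction,
    project_prevalence,
    reduce_diarrhoea_incidence,
    solve_four_state,
    solve_two_state,
    two_state_prevalence_reduction,
    update_breastfeeding,
    update_iugr,
    update_stunting_cohort,
)

odds_ratios = st.floats(min_value=0.2, max_value=5.0, allow_nan=False)
fractions = st.floats(min_value=0.05, max_value=0.95, allow_nan=False)
prevalences = st.floats(min_value=0.05, max_value=0.95, allow_nan=False)


def _odds_relation(odds, q):
    return odds * q / (1 - q + odds * q)


def _bisect_nonrisky(odds, f_k, p, tol=1e-13):
    """Independent oracle: bisection on the non-risky prevalence."""

    def mixture(q):
        return f_k * _odds_relation(odds, q) + (1 - f_k) * q - p

    lo, hi = 1e-12, 1 - 1e-12
    assert mixture(lo) < 0 < mixture(hi)
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if mixture(mid) < 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


class TestSolveTwoState:
    def test_zinc_worked_values(self):
        p_risky, p_nonrisky = solve_two_state(TwoStateRiskModel(1.18, 0.75, 0.35))
        assert round(100 * p_risky, 1) == 35.9
        assert round(100 * p_nonrisky, 1) == 32.2

    @given(fractions, prevalences)
    def test_unit_odds_ratio_gives_no_differential(self, f, p):
        assert solve_two_state(TwoStateRiskModel(1.0, f, p)) == (p, p)

    @given(odds_ratios, fractions, prevalences)
    def test_residuals_and_bisection_oracle(self, odds, f, p):
        p_risky, p_nonrisky = solve_two_state(TwoStateRiskModel(odds, f, p))
        # odds relation residual
        assert abs(p_risky - _odds_relation(odds, p_nonrisky)) < 1e-10
        # mixture relation residual
        assert abs(f * p_risky + (1 - f) * p_nonrisky - p) < 1e-10
        assert abs(p_nonrisky - _bisect_nonrisky(odds, f, p)) < 1e-8

    @given(
        st.floats(min_value=1.01, max_value=5.0),
        fractions,
        prevalences,
    )
    def test_risky_exceeds_overall_exceeds_nonrisky(self, odds, f, p):
        p_risky, p_nonrisky = solve_two_state(TwoStateRiskModel(odds, f, p))
        assert p_risky > p > p_nonrisky

    def test_requires_prevalence(self):
        with pytest.raises(ValueError):
            solve_two_state(TwoStateRiskModel(1.5, 0.5))


class TestProjectAndReduce:
    def test_zinc_scale_up_chain(self):
        p_risky, p_nonrisky = solve_two_state(TwoStateRiskModel(1.18, 0.75, 0.35))
        projected = project_prevalence(p_risky, p_nonrisky, 0.50)
        assert round(100 * projected, 1) == 34.1
        assert round(100 * prevalence_reduction(0.35, projected), 1) == 2.7
        # baseline risky fraction recovers the baseline prevalence
        assert project_prevalence(p_risky, p_nonrisky, 0.75) == pytest.approx(0.35, abs=1e-12)

    @given(prevalences, fractions)
    def test_equal_status_probabilities_are_inert(self, p, f):
        assert project_prevalence(p, p, f) == pytest.approx(p)

    @pytest.mark.parametrize(
        "p0, pt, expected",
        [(0.350, 0.341, 0.0257), (0.4, 0.4, 0.0), (0.4, 0.2, 0.5)],
    )
    def test_prevalence_reduction(self, p0, pt, expected):
        assert prevalence_reduction(p0, pt) == pytest.approx(expected, abs=5e-5)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            prevalence_reduction(0.0, 0.1)


class TestSolveFourState:
    def test_unit_odds_degenerate_to_uniform(self):
        model = FourStateFeedingModel((1.0, 1.0, 1.0), (0.4, 0.2, 0.2, 0.2), 0.35)
        probs = solve_four_state(model)
        assert all(q == pytest.approx(0.35, abs=1e-12) for q in probs)

    @given(
        o1=st.floats(min_value=1.0, max_value=3.0),
        o2=st.floats(min_value=1.0, max_value=3.0),
        o3=st.floats(min_value=1.0, max_value=3.0),
        p=prevalences,
        w=st.tuples(fractions, fractions, fractions, fractions),
    )
    def test_residuals(self, o1, o2, o3, p, w):
        total = sum(w)
        fr = tuple(x / total for x in w)
        probs = solve_four_state(FourStateFeedingModel((o1, o2, o3), fr, p))
        q = probs[0]
        for odds, prob in zip((1.0, o1, o2, o3), probs):
            assert abs(prob - _odds_relation(odds, q)) < 1e-10
        assert abs(sum(f * prob for f, prob in zip(fr, probs)) - p) < 1e-10

    def test_single_population_limit(self):
        probs = solve_four_state(
            FourStateFeedingModel((1.3, 1.6, 2.2), (1.0, 0.0, 0.0, 0.0), 0.35)
        )
        assert probs[0] == pytest.approx(0.35, abs=1e-10)

    @given(odds_ratios, fractions, prevalences)
    def test_degenerates_to_two_state(self, odds, f, p):
        """With two statuses empty, the four-state solve must agree with the
        two-state closed form (risky status carries the odds ratio)."""
        probs = solve_four_state(
            FourStateFeedingModel((odds, 1.0, 1.0), (1 - f, f, 0.0, 0.0), p)
        )
        p_risky, p_nonrisky = solve_two_state(TwoStateRiskModel(odds, f, p))
        assert probs[0] == pytest.approx(p_nonrisky, abs=1e-9)
        assert probs[1] == pytest.approx(p_risky, abs=1e-9)


class TestDiarrhoeaIncidence:
    def test_episode_drop_mapping(self):
        model = diarrhoea_or_to_two_state(3.0, 2.0, 1.05)
        assert round(100 * model.risky_fraction, 1) == 66.7
        assert model.odds_ratio == pytest.approx(1.05**3)

    @pytest.mark.parametrize("target, expected", [(3.0, 1.0), (0.0, 0.0)])
    def test_boundary_targets(self, target, expected):
        assert diarrhoea_or_to_two_state(3.0, target, 1.1).risky_fraction == expected

    def test_incidence_increase_rejected(self):
        with pytest.raises(ValueError):
            diarrhoea_or_to_two_state(2.0, 3.0, 1.1)

    @given(st.floats(min_value=1.01, max_value=1.2))
    def test_population_or_monotone_in_episodes(self, per_episode):
        ors = [
            diarrhoea_or_to_two_state(e, e, per_episode).odds_ratio
            for e in (1.0, 2.0, 3.0, 5.0)
        ]
        assert ors == sorted(ors)

    def test_reduce_incidence(self):
        assert reduce_diarrhoea_incidence(3.0, []) == 3.0
        assert reduce_diarrhoea_incidence(3.0, [(0.3, 1.0, 0.0, 1.0)]) == pytest.approx(2.1)
        # two interventions compose on residual incidence
        two = reduce_diarrhoea_incidence(3.0, [(0.3, 1.0, 0.0, 1.0), (0.2, 1.0, 0.0, 1.0)])
        assert two == pytest.approx(3.0 * 0.7 * 0.8)


class TestStuntingCohort:
    def test_no_determinants_is_identity(self):
        assert update_stunting_cohort(0.35, []) == 0.35

    def test_zinc_only_worked_chain(self):
        r = two_state_prevalence_reduction(1.18, 0.75, 0.50, 0.35)
        assert round(100 * update_stunting_cohort(0.35, [r]), 1) == 34.1

    def test_two_determinants_compose_residually(self):
        out = update_stunting_cohort(0.40, [0.027, 0.05])
        assert out == pytest.approx(0.40 * (1 - 0.027) * (1 - 0.05))

    @given(
        p=prevalences,
        r1=st.floats(min_value=0.0, max_value=0.5),
        r2=st.floats(min_value=0.0, max_value=0.5),
    )
    def test_improving_a_determinant_never_increases_stunting(self, p, r1, r2):
        assert update_stunting_cohort(p, [r1, r2]) <= update_stunting_cohort(p, [r1]) + 1e-12


class TestUpdateIugr:
    def test_no_scale_up_is_identity(self):
        assert update_iugr(0.15, []) == 0.15

    def test_single_intervention(self):
        assert update_iugr(0.15, [(0.2, 1.0, 0.0, 0.5)]) == pytest.approx(0.135)

    def test_pair_composes_residually(self):
        pair = update_iugr(0.15, [(0.2, 1.0, 0.0, 1.0), (0.1, 1.0, 0.0, 1.0)])
        assert pair == pytest.approx(0.15 * 0.8 * 0.9)


class TestUpdateBreastfeeding:
    BASE = {"exclusive": 0.3, "predominant": 0.3, "partial": 0.25, "none": 0.15}

    def test_no_coverage_change_is_identity(self):
        assert update_breastfeeding(self.BASE, 1.5, 0.2, 0.2) == self.BASE

    def test_unit_odds_ratio_is_identity(self):
        assert update_breastfeeding(self.BASE, 1.0, 0.2, 0.9) == self.BASE

    def test_promotion_shifts_towards_exclusive_and_sums_to_one(self):
        out = update_breastfeeding(self.BASE, 1.5, 0.2, 0.6)
        assert out["exclusive"] > self.BASE["exclusive"]
        assert sum(out.values()) == pytest.approx(1.0, abs=1e-12)
        # non-exclusive categories keep their relative proportions
        assert out["predominant"] / out["partial"] == pytest.approx(0.3 / 0.25)

    def test_solution_satisfies_odds_and_mixture_relations(self):
        odds_promotion = 1.5
        c0, ct = 0.2, 0.6
        out = update_breastfeeding(self.BASE, odds_promotion, c0, ct)
        p_risky, p_nonrisky = solve_two_state(
            TwoStateRiskModel(1.0 / odds_promotion, 1.0 - c0, self.BASE["exclusive"])
        )
        assert abs(p_risky - _odds_relation(1.0 / odds_promotion, p_nonrisky)) < 1e-10
        expected = project_prevalence(p_risky, p_nonrisky, 1.0 - ct)
        assert out["exclusive"] == pytest.approx(expected, abs=1e-12)
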
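"""Value models, probability weighting, and the softmax choice rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foragefit import (
    MODELS,
    OutcomeDistribution,
    TrialArrays,
    WalkSpec,
    choice_prob,
    compute_stats,
    enumerate_walk,
    model_by_name,
    model_values,
    option_value,
    power_utility,
    prelec_weight,
    rdu_value,
)
from foragefit.inference import _cached_features


def features_for(x0, n, gA, pA, gB, pB, frame=1):
    return _cached_features(x0, n, gA, pA, gB, pB, frame)


@pytest.fixture(scope="module")
def trial_block(small_gamble_set=None):
    from foragefit import GambleSetConfig, generate_gamble_set

    pairs = generate_gamble_set(GambleSetConfig(pairs_per_combo=10), seed=2)
    feats = [
        features_for(p.x0, p.n, p.gA, p.pA, p.gB, p.pB, frame)
        for frame in (0, 1)
        for p in pairs
    ]
    return TrialArrays(feats)


class TestRegistry:
    def test_parameter_counts_per_model(self):
        expected = {1: 1, 2: 2, 3: 2, 4: 3, 5: 3, 6: 4, 7: 2, 8: 3, 9: 4,
                    10: 3, 11: 1, 12: 4}
        assert {m: MODELS[m].k for m in MODELS} == expected

    def test_beta_always_first_and_positive(self):
        for spec in MODELS.values():
            assert spec.param_names[0] == "beta"
            assert spec.positive[0] is True

    def test_lookup_by_name(self):
        assert model_by_name("EV+pstarve").model_id == 7
        with pytest.raises(KeyError):
            model_by_name("nope")


class TestPowerUtility:
    def test_zero_maps_to_zero(self):
        for mu in (0.2, 1.0, 2.5):
            assert power_utility(0.0, mu) == 0.0

    def test_identity_and_square_root(self):
        assert power_utility(3.7, 1.0) == pytest.approx(3.7)
        assert power_utility(4.0, 0.5) == pytest.approx(2.0)

    def test_invalid_exponent_rejected(self):
        with pytest.raises(ValueError):
            power_utility(1.0, 0.0)
        with pytest.raises(ValueError):
            power_utility(1.0, -1.0)


class TestPrelecWeight:
    @given(p=st.floats(1e-6, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_alpha_one_is_identity(self, p):
        assert prelec_weight(p, alpha=1.0) == pytest.approx(p, abs=1e-12)

    def test_fixed_point_at_one_over_e(self):
        for alpha in (0.3, 0.7, 1.5):
            assert prelec_weight(np.exp(-1), alpha) == pytest.approx(
                np.exp(-1), abs=1e-12
            )

    @given(p=st.floats(1e-6, 1.0), alpha=st.floats(0.2, 3.0))
    @settings(max_examples=50, deadline=None)
    def test_two_parameter_form_reduces_to_one_parameter(self, p, alpha):
        assert prelec_weight(p, alpha, beta_w=1.0) == pytest.approx(
            prelec_weight(p, alpha), abs=1e-14
        )

    def test_boundary_conventions(self):
        assert prelec_weight(0.0, 0.5) == 0.0
        assert prelec_weight(1.0, 0.5) == 1.0

    def test_monotone_increasing(self):
        grid = np.linspace(0.01, 1.0, 50)
        w = prelec_weight(grid, alpha=0.4, beta_w=1.7)
        assert np.all(np.diff(w) > 0)


class TestRduValue:
    @given(spec=st.builds(WalkSpec, x0=st.integers(1, 3), n=st.integers(1, 3),
                          g=st.integers(2, 6), p=st.floats(0.05, 0.95)))
    @settings(max_examples=50, deadline=None)
    def test_reduces_to_expected_value_under_identity_weights(self, spec):
        d = enumerate_walk(spec)
        assert rdu_value(d, mu=1.0, alpha=1.0, beta_w=1.0) == pytest.approx(
            compute_stats(d).ev, abs=1e-10
        )

    def test_two_outcome_hand_computation(self):
        # best-ranked-first: V = w(0.4) * u(8) with Prelec-I alpha = 0.5
        d = OutcomeDistribution((0, 8), (0.6, 0.4))
        w = np.exp(-((-np.log(0.4)) ** 0.5))
        assert rdu_value(d, mu=1.0, alpha=0.5) == pytest.approx(8 * w, abs=1e-12)

    def test_constant_distribution_value_is_its_utility(self):
        # decision weights sum to one, so a sure outcome v is worth v**mu
        d = OutcomeDistribution((4,), (1.0,))
        for alpha in (0.3, 1.0, 2.0):
            assert rdu_value(d, mu=0.5, alpha=alpha) == pytest.approx(2.0, abs=1e-12)

    def test_vectorised_path_agrees_with_scalar(self, trial_block):
        ta = trial_block
        params = {"mu": 0.8, "alpha": 0.6, "beta_w": 1.3}
        v = model_values(6, params, ta)
        for i in (0, 5, 17, ta.n - 1):
            for col in (0, 1):
                sup = ta.sup[i, col]
                prb = ta.prb[i, col]
                keep = prb > 0
                d = _sorted_dist(sup[keep], prb[keep])
                assert v[i, col] == pytest.approx(
                    rdu_value(d, **params), abs=1e-10
                )


def _sorted_dist(sup, prb):
    order = np.argsort(sup)
    return OutcomeDistribution(
        tuple(int(x) for x in sup[order]), tuple(float(q) for q in prb[order])
    )


class TestChoiceProb:
    def test_indifference_gives_half(self):
        assert choice_prob(2.0, 2.0, beta=0.7) == 0.5

    def test_unit_value_gap_in_noise_units(self):
        assert choice_prob(1.0, 0.0, beta=1.0) == pytest.approx(
            1 / (1 + np.exp(-1)), abs=1e-9
        )

    def test_noise_dominates_in_large_beta_limit(self):
        assert choice_prob(3.0, 1.0, beta=1e8) == pytest.approx(0.5, abs=1e-6)

    @given(v1=st.floats(-20, 20), v2=st.floats(-20, 20),
           beta=st.floats(0.01, 10))
    @settings(max_examples=50, deadline=None)
    def test_complementarity(self, v1, v2, beta):
        assert choice_prob(v1, v2, beta) + choice_prob(v2, v1, beta) == (
            pytest.approx(1.0, abs=1e-12)
        )

    def test_nonpositive_beta_rejected(self):
        with pytest.raises(ValueError):
            choice_prob(1.0, 0.0, beta=0.0)


class TestOptionValue:
    def test_homeostatic_value_arithmetic(self):
        feat = features_for(2, 3, 3, 0.4, 4, 0.5, frame=1)
        # option A: EV = 2.528, p_starve = 0.36
        v = option_value(7, {"xi": -2.0}, feat, "A")
        assert v == pytest.approx(2.528 - 2.0 * 0.36, abs=1e-12)

    def test_zero_starvation_weight_reduces_to_pure_ev(self):
        feat = features_for(1, 2, 5, 0.3, 2, 0.8, frame=0)
        for opt in ("A", "B"):
            assert option_value(7, {"xi": 0.0}, feat, opt) == pytest.approx(
                option_value(1, {}, feat, opt), abs=1e-14
            )

    def test_frame_specific_weights_select_by_frame(self):
        params = {"xi_foraging": -4.0, "xi_casino": -1.0}
        f_forage = features_for(2, 2, 3, 0.4, 4, 0.6, frame=1)
        f_casino = features_for(2, 2, 3, 0.4, 4, 0.6, frame=0)
        va_f = option_value(10, params, f_forage, "A")
        va_c = option_value(10, params, f_casino, "A")
        ps = f_forage.stats_a.p_starve
        assert va_f == pytest.approx(f_forage.stats_a.ev - 4.0 * ps, abs=1e-12)
        assert va_c == pytest.approx(f_casino.stats_a.ev - 1.0 * ps, abs=1e-12)

    def test_unknown_model_rejected(self):
        feat = features_for(1, 1, 3, 0.5, 4, 0.5)
        with pytest.raises(KeyError):
            option_value(99, {}, feat, "A")


class TestNesting:
    def test_frame_model_with_equal_weights_reproduces_base(self, trial_block):
        ta = trial_block
        xi = -2.3
        v10 = model_values(10, {"xi_foraging": xi, "xi_casino": xi}, ta)
        v7 = model_values(7, {"xi": xi}, ta)
        assert np.max(np.abs(v10 - v7)) < 1e-10

    def test_day_model_with_equal_weights_reproduces_base(self, trial_block):
        ta = trial_block
        xi = -1.4
        v12 = model_values(
            12, {"xi_d1": xi, "xi_d2": xi, "xi_d3": xi}, ta
        )
        v7 = model_values(7, {"xi": xi}, ta)
        assert np.max(np.abs(v12 - v7)) < 1e-10

    def test_moment_models_nest_at_zero_weights(self, trial_block):
        ta = trial_block
        v1 = model_values(1, {}, ta)
        assert np.allclose(model_values(4, {"rho": 0, "lam": 0}, ta), v1)
        assert np.allclose(model_values(9, {"rho": 0, "lam": 0, "xi": 0}, ta), v1)
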
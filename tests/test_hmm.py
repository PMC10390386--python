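import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from revlearn.fitting import no_reversal_predictive
from revlearn.hmm import (
    HMMParams,
    binary_entropy,
    c0_correction,
    exact_posterior,
    filter_step,
    init_particles,
    predict_next,
    run_filter,
    state_change_probability,
)


def truncated_mean_p(alpha_p, beta_p):
    """Numerical-integration oracle: E[p] under Beta(a,b) truncated to [0.5, 1]."""
    dens = lambda p: stats.beta.pdf(p, alpha_p, beta_p)
    num, _ = integrate.quad(lambda p: p * dens(p), 0.5, 1.0)
    den, _ = integrate.quad(dens, 0.5, 1.0)
    return num / den


class TestC0:
    def test_uniform_prior_value(self):
        assert c0_correction(HMMParams(1, 1, 1, 1)) == pytest.approx(0.5)

    def test_first_trial_match_probability_equals_truncated_mean(self):
        # (alpha_p + c0) / (alpha_p + beta_p) must equal E[p | truncation]
        params = HMMParams(1, 1, 1, 1)
        c0 = c0_correction(params)
        assert (1 + c0) / 2 == pytest.approx(truncated_mean_p(1, 1))
        assert 0.5 * (1 + c0) / 2 == pytest.approx(0.375)

    @pytest.mark.parametrize("a,b", [(2.0, 3.0), (0.5, 0.5), (7.0, 1.5), (1.0, 10.0)])
    def test_match_probability_general_params(self, a, b):
        c0 = c0_correction(HMMParams(a, b, 1, 1))
        assert (a + c0) / (a + b) == pytest.approx(truncated_mean_p(a, b), rel=1e-8)

    def test_first_trial_probabilities_normalize(self):
        params = HMMParams(2.5, 0.8, 1, 1)
        c0 = c0_correction(params)
        total = 2 * (0.5 * (params.alpha_p + c0) / 3.3) + 2 * (0.5 * (params.beta_p - c0) / 3.3)
        assert total == pytest.approx(1.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            HMMParams(0.0, 1, 1, 1)
        with pytest.raises(ValueError):
            HMMParams(1, 1, -1, 1)


class TestInitAndPrimitives:
    def test_uniform_weights(self, default_params):
        ps = init_particles(default_params, 100)
        np.testing.assert_allclose(ps.weights, 0.01)
        assert ps.t == 0

    def test_single_particle_allowed(self, default_params):
        assert init_particles(default_params, 1).n_particles == 1

    def test_invalid_count(self, default_params):
        with pytest.raises(ValueError):
            init_particles(default_params, 0)

    def test_prior_predictive_is_symmetric(self, default_params):
        p0, p1 = predict_next(init_particles(default_params, 10))
        assert p0 == pytest.approx(0.5)
        assert p1 == pytest.approx(0.5)

    def test_first_transition_change_probability(self, default_params):
        # alpha_a = beta_a = 1, r = 0: flip probability (1+0)/(1+1+0) = 0.5
        ps = init_particles(default_params, 10)
        rng = np.random.default_rng(0)
        ps, _ = filter_step(ps, 1, rng)
        from revlearn.hmm import _branch

        _, p_trans, _, _, _ = _branch(ps)
        np.testing.assert_allclose(p_trans, 0.5)


class TestBinaryEntropy:
    def test_half_is_one_bit(self):
        assert binary_entropy(0.5) == 1.0

    def test_degenerate_is_zero(self):
        assert binary_entropy(0.0) == 0.0
        assert binary_entropy(1.0) == 0.0

    def test_quarter(self):
        assert binary_entropy(0.25) == pytest.approx(0.8113, abs=1e-4)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            binary_entropy(1.5)

    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_symmetry_and_bounds(self, q):
        h = binary_entropy(q)
        assert 0.0 <= h <= 1.0
        assert h == pytest.approx(binary_entropy(1.0 - q), abs=1e-12)


class TestStateChangeProbability:
    @pytest.mark.parametrize("pz0,pz1,y,expected", [
        (0.9, 0.1, 0, 0.1),
        (0.5, 0.5, 0, 0.5),
        (0.5, 0.5, 1, 0.5),
        (0.2, 0.8, 0, 0.8),
    ])
    def test_examples(self, pz0, pz1, y, expected):
        assert state_change_probability(pz0, pz1, y) == pytest.approx(expected)

    def test_missing_choice_propagates_nan(self):
        assert math.isnan(state_change_probability(0.7, 0.3, -1))
        assert math.isnan(state_change_probability(0.7, 0.3, float("nan")))


class TestExactPosterior:
    def test_first_trial_posterior_symmetric(self, default_params):
        df = exact_posterior(default_params, [1])
        # posterior after one observation favors the observed side under the
        # truncated prior, and the marginal over x is symmetric
        assert df.loc[0, "predictive_x1"] == pytest.approx(0.5)
        assert df.loc[0, "posterior_z1"] == pytest.approx(0.75)

    def test_evidence_normalizes_over_all_sequences(self, default_params):
        import itertools

        total = sum(
            math.exp(exact_posterior(default_params, list(xs))["log_evidence"].iloc[-1])
            for xs in itertools.product((0, 1), repeat=4)
        )
        assert total == pytest.approx(1.0)

    def test_too_long_rejected(self, default_params):
        with pytest.raises(ValueError):
            exact_posterior(default_params, [0] * 15)

    def test_complement_sequence_mirrors_posterior(self):
        params = HMMParams(2.0, 1.5, 1.0, 4.0)
        x = [1, 1, 0, 1, 0]
        a = exact_posterior(params, x)
        b = exact_posterior(params, [1 - v for v in x])
        np.testing.assert_allclose(a["posterior_z1"], b["posterior_z0"], atol=1e-12)
        np.testing.assert_allclose(a["predictive_x1"], b["predictive_x0"], atol=1e-12)

    def test_monotone_evidence_accumulation(self, default_params):
        # consecutive confirming observations monotonically sharpen the posterior
        df = exact_posterior(HMMParams(1, 1, 1, 10), [1, 1, 1, 1, 1])
        assert (np.diff(df["posterior_z1"]) > 0).all()


class TestParticleFilterAgainstOracle:
    @pytest.mark.parametrize("params,x,seed", [
        (HMMParams(1, 1, 1, 1), [1, 1, 0], 0),
        (HMMParams(1, 1, 1, 1), [1, 1, 0, 0, 1, 1, 1, 0, 1, 1], 1),
        (HMMParams(2.0, 3.0, 0.5, 5.0), [0, 1, 1, 1, 0, 0, 1, 0, 1, 0], 2),
        (HMMParams(0.8, 0.8, 2.0, 20.0), [1, 0, 1, 1, 1, 1, 0, 0, 1, 1], 3),
    ])
    def test_posterior_agreement(self, params, x, seed):
        exact = exact_posterior(params, x)
        est = run_filter(params, x, n_particles=100_000, seed=seed)
        err = np.max(np.abs(est["posterior_z1"].to_numpy()
                            - exact["posterior_z1"].to_numpy()))
        assert err <= 0.01
        err_pred = np.max(np.abs(est["predictive_x1"].to_numpy()
                                 - exact["predictive_x1"].to_numpy()))
        assert err_pred <= 0.01

    def test_multinomial_resampler_also_agrees(self, default_params):
        x = [1, 1, 0, 1, 1]
        exact = exact_posterior(default_params, x)
        est = run_filter(default_params, x, n_particles=100_000, seed=4,
                         resampler="multinomial")
        err = np.max(np.abs(est["posterior_z1"].to_numpy()
                            - exact["posterior_z1"].to_numpy()))
        assert err <= 0.01

    def test_unknown_resampler_rejected(self, default_params):
        with pytest.raises(ValueError):
            run_filter(default_params, [1], n_particles=10, seed=0, resampler="bogus")

    def test_monotone_posterior_all_confirming(self):
        est = run_filter(HMMParams(1, 1, 1, 10), [1] * 5, n_particles=50_000, seed=5)
        assert (np.diff(est["posterior_z1"]) > 0).all()


class TestRunFilter:
    def test_identical_seeds_bit_identical(self, default_params):
        x = [1, 0, 1, 1, 0, 1]
        a = run_filter(default_params, x, n_particles=5000, seed=7)
        b = run_filter(default_params, x, n_particles=5000, seed=7)
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())

    def test_posterior_sums_to_one_and_entropy_consistent(self):
        params = HMMParams(1.5, 2.0, 1.0, 8.0)
        x = np.random.default_rng(0).integers(0, 2, 30)
        y = np.random.default_rng(1).integers(0, 2, 30)
        est = run_filter(params, x, y, n_particles=3000, seed=2)
        np.testing.assert_allclose(est["posterior_z0"] + est["posterior_z1"], 1.0,
                                   atol=1e-12)
        np.testing.assert_allclose(
            est["state_entropy"],
            [binary_entropy(q) for q in est["state_change_probability"]],
            atol=1e-12,
        )

    def test_label_symmetry_of_uncertainty_measures(self):
        params = HMMParams(1.0, 1.0, 1.0, 6.0)
        rng = np.random.default_rng(3)
        x = rng.integers(0, 2, 20)
        y = rng.integers(0, 2, 20)
        # exact in the math (see the enumeration mirror test); Monte Carlo
        # tolerance here because complementing permutes the resampling order
        a = run_filter(params, x, y, n_particles=50_000, seed=9)
        b = run_filter(params, 1 - x, 1 - y, n_particles=50_000, seed=9)
        np.testing.assert_allclose(a["state_change_probability"],
                                   b["state_change_probability"], atol=0.01)
        np.testing.assert_allclose(a["state_entropy"], b["state_entropy"], atol=0.02)

    def test_negative_feedback_raises_uncertainty(self):
        # long run of confirmations then one disconfirmation
        params = HMMParams(1, 1, 1, 30)
        x = [1] * 10 + [0]
        y = [1] * 11
        est = run_filter(params, x, y, n_particles=20_000, seed=1)
        q = est["state_change_probability"].to_numpy()
        h = est["state_entropy"].to_numpy()
        assert q[10] > q[9]
        assert h[10] > h[9]

    def test_no_reversal_limit_matches_closed_form(self):
        # alpha_a -> 0, beta_a -> inf: switching impossible; the filter must
        # reduce to the closed-form beta-Bernoulli predictive recursion
        params = HMMParams(2.0, 2.0, 1e-6, 1e6)
        rng = np.random.default_rng(12)
        x = rng.integers(0, 2, 10)
        exact = exact_posterior(params, x)
        closed = no_reversal_predictive(4.0, x)
        np.testing.assert_allclose(exact["predictive_x1"], closed, atol=1e-3)
        est = run_filter(params, x, n_particles=100_000, seed=6)
        np.testing.assert_allclose(est["predictive_x1"], closed, atol=1e-3)

    def test_missing_choice_gives_nan_estimates(self, default_params):
        est = run_filter(default_params, [1, 0, 1], [1, -1, 0], n_particles=1000, seed=0)
        assert math.isnan(est.loc[1, "state_change_probability"])
        assert not math.isnan(est.loc[0, "state_change_probability"])


class TestMonotoneEvidenceProperty:
    @settings(max_examples=10, deadline=None)
    @given(st.integers(min_value=2, max_value=6))
    def test_change_probability_non_increasing_without_negative_feedback(self, t):
        # choices track the confirmed side; every feedback is positive
        params = HMMParams(1, 1, 1, 10)
        x = [1] * t
        y = [1] * t
        exact = exact_posterior(params, x)
        q = [state_change_probability(row.posterior_z0, row.posterior_z1, 1)
             for row in exact.itertuples()]
        assert all(q[i + 1] <= q[i] + 1e-12 for i in range(len(q) - 1))
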
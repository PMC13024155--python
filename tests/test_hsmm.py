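import numpy as np
import pytest

from brainstates import (
    EMConfig,
    HSMMParams,
    em_fit,
    init_params,
    loglikelihood,
    match_states,
    posterior_marginals,
    viterbi_decode,
)
from brainstates.durations import ShiftedPoissonDwell, TabularDwell
from brainstates.synthetic import generate_params, sample_observations, sample_path

from oracles import brute_force_hsmm, random_hsmm_params


class TestLoglikelihood:
    def test_single_state_closed_form(self, rng):
        params = random_hsmm_params(K=1, R=3, seed=1)
        Y = rng.normal(size=(25, 3))
        from scipy.stats import multivariate_normal
        expected = multivariate_normal.logpdf(Y, params.means[0], params.covs[0]).sum()
        assert loglikelihood(params, Y) == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_exhaustive_enumeration(self, trial, rng):
        params = random_hsmm_params(K=2, R=2, D=5, seed=trial)
        Y = np.random.default_rng(100 + trial).normal(size=(5, 2))
        bf_ll, _, _ = brute_force_hsmm(params, Y)
        assert loglikelihood(params, Y) == pytest.approx(bf_ll, abs=1e-8)

    def test_scaling_change_of_variables(self, rng):
        """Scaling Y and mu by c with Sigma by c^2 shifts loglik by -T R log c."""
        params = random_hsmm_params(K=2, R=3, D=8, seed=3)
        Y = rng.normal(size=(20, 3))
        c = 2.5
        scaled = HSMMParams(
            means=c * params.means, covs=c ** 2 * params.covs, trans=params.trans,
            dwell=params.dwell, init=params.init, max_dwell=params.max_dwell)
        ll = loglikelihood(params, Y)
        ll_scaled = loglikelihood(scaled, c * Y)
        assert ll_scaled == pytest.approx(ll - 20 * 3 * np.log(c), abs=1e-8)

    def test_region_mismatch_rejected(self, rng):
        params = random_hsmm_params(K=2, R=2, seed=0)
        with pytest.raises(ValueError, match="regions"):
            loglikelihood(params, rng.normal(size=(10, 5)))

    def test_singular_covariance_names_numerical_error(self, rng):
        params = random_hsmm_params(K=2, R=2, seed=0)
        covs = params.covs.copy()
        covs[1] = np.ones((2, 2))  # rank 1
        bad = HSMMParams(means=params.means, covs=covs, trans=params.trans,
                         dwell=params.dwell, init=params.init, max_dwell=6)
        with pytest.raises(np.linalg.LinAlgError, match="state 1"):
            loglikelihood(bad, rng.normal(size=(5, 2)))


class TestViterbi:
    def test_single_state_forced(self, rng):
        params = random_hsmm_params(K=1, R=2, seed=2)
        seq = viterbi_decode(params, rng.normal(size=(17, 2)))
        assert (seq.labels == 0).all()

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_exhaustive_argmax(self, trial):
        params = random_hsmm_params(K=2, R=2, D=6, seed=200 + trial)
        Y = np.random.default_rng(300 + trial).normal(size=(6, 2))
        _, bf_lp, bf_path = brute_force_hsmm(params, Y)
        seq = viterbi_decode(params, Y)
        assert seq.log_joint == pytest.approx(bf_lp, abs=1e-8)
        np.testing.assert_array_equal(seq.labels, bf_path)

    def test_noiseless_separation_recovers_true_path(self, rng):
        truth = generate_params(R=4, K=3, separation=8.0, seed=9, max_dwell=20)
        path = sample_path(truth, 120, rng)
        Y = truth.means[path.labels] + 1e-6 * rng.normal(size=(120, 4))
        seq = viterbi_decode(truth, Y)
        np.testing.assert_array_equal(seq.labels, path.labels)

    def test_decoded_joint_never_exceeds_marginal(self, rng):
        params = random_hsmm_params(K=3, R=2, D=10, seed=4)
        Y = rng.normal(size=(40, 2))
        assert viterbi_decode(params, Y).log_joint <= loglikelihood(params, Y) + 1e-10

    def test_invariant_to_state_relabelling(self, rng):
        params = random_hsmm_params(K=3, R=2, D=8, seed=8)
        Y = rng.normal(size=(30, 2))
        perm = np.array([2, 0, 1])
        seq = viterbi_decode(params, Y)
        seq_p = viterbi_decode(params.permuted(perm), Y)
        # permuted(perm) state k holds old state perm[k]
        np.testing.assert_array_equal(perm[seq_p.labels], seq.labels)
        assert seq_p.log_joint == pytest.approx(seq.log_joint, abs=1e-9)


class TestPosteriors:
    def test_marginals_normalise(self, rng):
        params = random_hsmm_params(K=3, R=2, D=8, seed=42)
        g = posterior_marginals(params, rng.normal(size=(35, 2)))
        np.testing.assert_allclose(g.sum(axis=1), 1.0, atol=1e-10)


class TestHMMEquivalence:
    def test_dwell_mass_at_one_matches_hmmlearn(self, rng):
        """All dwell mass at 1 reduces the model to a standard HMM."""
        from hmmlearn.hmm import GaussianHMM

        K, R, T = 3, 2, 50
        base = random_hsmm_params(K=K, R=R, seed=5)
        params = HSMMParams(
            means=base.means, covs=base.covs, trans=base.trans,
            dwell=tuple(TabularDwell.from_array([1.0]) for _ in range(K)),
            init=base.init, max_dwell=10)
        Y = rng.normal(size=(T, R))
        h = GaussianHMM(n_components=K, covariance_type="full", init_params="")
        h.startprob_, h.transmat_ = base.init, base.trans
        h.means_, h.covars_ = base.means, base.covs
        assert loglikelihood(params, Y) == pytest.approx(h.score(Y), abs=1e-8)
        np.testing.assert_array_equal(viterbi_decode(params, Y).labels, h.predict(Y))


class TestInit:
    def test_single_state_grand_moments(self, rng):
        Y = rng.normal(size=(100, 3))
        p = init_params([Y], K=1)
        np.testing.assert_allclose(p.means[0], Y.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(p.covs[0], np.cov(Y.T), atol=1e-4)

    def test_two_separated_clouds(self, rng):
        a = rng.normal(size=(80, 2)) + np.array([10.0, 0.0])
        b = rng.normal(size=(80, 2)) - np.array([10.0, 0.0])
        p = init_params([np.vstack([a, b])], K=2, seed=0)
        centers = p.means[np.argsort(p.means[:, 0])]
        np.testing.assert_allclose(centers[0], b.mean(axis=0), atol=0.5)
        np.testing.assert_allclose(centers[1], a.mean(axis=0), atol=0.5)

    def test_deterministic_given_seed(self, rng):
        Y = rng.normal(size=(60, 3))
        p1 = init_params([Y], K=3, seed=11)
        p2 = init_params([Y], K=3, seed=11)
        np.testing.assert_array_equal(p1.means, p2.means)

    def test_k_exceeding_pool_rejected(self, rng):
        with pytest.raises(ValueError):
            init_params([rng.normal(size=(4, 2))], K=10)


class TestEM:
    def test_single_state_one_step_moments(self, rng):
        Ys = [rng.normal(size=(50, 3)) for _ in range(2)]
        fit = em_fit(Ys, K=1, config=EMConfig(n_starts=1))
        pooled = np.vstack(Ys)
        np.testing.assert_allclose(fit.params.means[0], pooled.mean(axis=0), atol=1e-10)
        assert fit.n_iter == 1 and fit.converged

    def test_trace_monotone_on_generic_data(self, rng):
        Ys = [rng.normal(size=(60, 2)) + np.array([s, 0]) for s in (0, 3)]
        fit = em_fit(Ys, K=2, config=EMConfig(max_iter=15, tol=0.0, n_starts=1,
                                              max_dwell=15, seed=1))
        d = np.diff(fit.loglik_trace)
        assert (d >= -1e-6 * np.abs(fit.loglik_trace[:-1])).all()

    def test_recovers_known_parameters(self, rng):
        truth = generate_params(R=4, K=3, separation=6.0, seed=21,
                                dwell_mean=5.0, max_dwell=25)
        r = np.random.default_rng(22)
        scans = [sample_observations(truth, sample_path(truth, 150, r), r)
                 for _ in range(8)]
        fit = em_fit(scans, K=3, config=EMConfig(max_iter=40, tol=1e-6,
                                                 n_starts=2, max_dwell=25, seed=0))
        perm = match_states(fit.params.means, truth.means)
        err = max(np.linalg.norm(fit.params.means[k] - truth.means[perm[k]])
                  for k in range(3))
        assert err < 0.6   # 10% of the separation

    def test_mismatched_regions_rejected(self, rng):
        with pytest.raises(ValueError, match="regions"):
            em_fit([rng.normal(size=(20, 2)), rng.normal(size=(20, 3))], K=2)
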
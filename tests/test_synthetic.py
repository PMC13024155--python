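import numpy as np
import pytest
from scipy.stats import chisquare

from brainstates import (
    CohortDesign,
    generate_cohort,
    generate_params,
    generate_stress,
    sample_observations,
    sample_path,
    stationary_occupancy,
)
from brainstates.durations import ShiftedPoissonDwell, TabularDwell
from brainstates.hsmm import HSMMParams, StateSequence
from brainstates.synthetic import GroundTruth, StressModel


class TestGenerateParams:
    def test_study_scale_shapes(self):
        p = generate_params(R=36, K=6, separation=4.0, seed=0)
        assert p.means.shape == (6, 36)
        assert p.covs.shape == (6, 36, 36)
        d = np.linalg.norm(p.means[:, None] - p.means[None], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 4.0

    def test_single_state_degenerate(self):
        p = generate_params(R=4, K=1, seed=0)
        assert p.trans.shape == (1, 1) and p.trans[0, 0] == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_separation_postcondition(self, seed):
        p = generate_params(R=5, K=3, separation=3.0, seed=seed)
        d = np.linalg.norm(p.means[:, None] - p.means[None], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 3.0

    def test_valid_stochastic_structure(self):
        p = generate_params(R=4, K=4, seed=3)
        assert np.allclose(p.trans.sum(axis=1), 1.0)
        assert np.all(np.diag(p.trans) == 0)
        for k in range(4):
            assert np.linalg.eigvalsh(p.covs[k]).min() > 0
        assert all(d.mean >= 3.0 for d in p.dwell)

    def test_simplex_geometry_equidistant(self):
        p = generate_params(R=6, K=4, separation=5.0, seed=1, geometry="simplex")
        d = np.linalg.norm(p.means[:, None] - p.means[None], axis=2)
        off = d[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 5.0, atol=1e-9)


class TestSamplePath:
    def test_single_state_forced(self):
        p = generate_params(R=4, K=1, seed=0)
        seq = sample_path(p, 50, 0)
        assert (seq.labels == 0).all() and len(seq) == 50

    def test_deterministic_alternating_blocks(self):
        """Point-mass dwell at 5 with forced alternation gives exact 5-blocks."""
        p = generate_params(R=4, K=2, seed=0)
        pm = TabularDwell.from_array([0, 0, 0, 0, 1.0])  # all mass at d=5
        p = HSMMParams(means=p.means, covs=p.covs,
                       trans=np.array([[0.0, 1.0], [1.0, 0.0]]),
                       dwell=(pm, pm), init=np.array([1.0, 0.0]), max_dwell=10)
        seq = sample_path(p, 20, 3)
        expected = np.repeat([0, 1, 0, 1], 5)
        np.testing.assert_array_equal(seq.labels, expected)

    def test_dwell_histogram_matches_pmf(self):
        """Chi-square GOF of 1e5 sampled dwells against the shifted-Poisson pmf."""
        dw = ShiftedPoissonDwell(3.0)
        rng = np.random.default_rng(99)
        draws = dw.sample(rng, size=100_000)
        grid_max = 20
        obs = np.bincount(np.clip(draws, 1, grid_max), minlength=grid_max + 1)[1:]
        pmf = np.exp(dw.log_pmf(60))
        exp = np.concatenate([pmf[: grid_max - 1], [pmf[grid_max - 1:].sum()]])
        stat, p = chisquare(obs, exp * obs.sum())
        assert p > 0.01


class TestSampleObservations:
    def test_noiseless_limit_hits_means(self):
        p = generate_params(R=3, K=2, separation=5.0, seed=4)
        tiny = np.stack([1e-12 * np.eye(3)] * 2)
        p = HSMMParams(means=p.means, covs=tiny, trans=p.trans,
                       dwell=p.dwell, init=p.init, max_dwell=p.max_dwell)
        path = StateSequence(labels=np.array([0, 0, 1, 1, 1]))
        Y = sample_observations(p, path, 0)
        np.testing.assert_allclose(Y, p.means[path.labels], atol=1e-4)

    def test_moments_converge(self):
        p = generate_params(R=3, K=2, separation=5.0, seed=5)
        n = 10_000
        path = StateSequence(labels=np.zeros(n, dtype=int))
        Y = sample_observations(p, path, 1)
        se = np.sqrt(np.diag(p.covs[0]) / n)
        assert (np.abs(Y.mean(axis=0) - p.means[0]) < 3 * se).all()
        err_small = np.linalg.norm(np.cov(Y.T) - p.covs[0])
        err_big = np.linalg.norm(np.cov(Y[:500].T) - p.covs[0])
        assert err_small < err_big  # Frobenius error shrinks with n


class TestCohort:
    def test_study_design_counts(self):
        design = CohortDesign(T=60, R=4, K=3)  # small T/R, study-sized cohort
        manifest, scans, truth = generate_cohort(design, seed=0)
        assert len(scans) == (15 + 17) * 2
        groups = manifest.rows.groupby("participant_id")["group"].first()
        assert (groups == "mindfulness").sum() == 15
        assert (groups == "control").sum() == 17

    def test_minimal_cohort(self):
        design = CohortDesign(n_group1=1, n_group2=1, scans_per_participant=1,
                              T=40, R=4, K=2)
        manifest, scans, truth = generate_cohort(design, seed=1)
        assert len(scans) == 2
        assert {s.group for s in scans} == {"mindfulness", "control"}

    def test_same_seed_identical(self):
        design = CohortDesign(n_group1=2, n_group2=2, T=50, R=4, K=3)
        m1, s1, t1 = generate_cohort(design, seed=5)
        m2, s2, t2 = generate_cohort(design, seed=5)
        assert m1.rows.equals(m2.rows)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_true_paths_cover_every_scan(self):
        design = CohortDesign(n_group1=2, n_group2=2, T=50, R=4, K=3)
        _, scans, truth = generate_cohort(design, seed=2)
        for s in scans:
            assert len(truth.true_paths[(s.participant_id, s.scan_id)]) == 50

    def test_emissions_shared_across_groups(self):
        design = CohortDesign(n_group1=2, n_group2=2, T=50, R=4, K=3)
        _, _, truth = generate_cohort(design, seed=3)
        np.testing.assert_array_equal(
            truth.params_by_group["mindfulness"].means,
            truth.params_by_group["control"].means)

    def test_dwell_contrast_raises_designated_occupancy(self):
        """Longer designated-state dwell in group 1 raises its stationary occupancy."""
        design = CohortDesign(n_group1=2, n_group2=2, T=50, R=4, K=4)
        _, _, truth = generate_cohort(design, seed=4)
        occ1 = stationary_occupancy(truth.params_by_group["mindfulness"])
        occ2 = stationary_occupancy(truth.params_by_group["control"])
        assert occ1[design.designated_state] > occ2[design.designated_state]

    def test_empirical_occupancy_matches_stationary_closed_form(self):
        """Long-run occupancy ~ embedded-chain stationary weights x mean dwells."""
        p = generate_params(R=4, K=3, separation=5.0, seed=6, dwell_mean=4.0)
        rng = np.random.default_rng(7)
        counts = np.zeros(3)
        for _ in range(40):
            counts += np.bincount(sample_path(p, 600, rng).labels, minlength=3)
        emp = counts / counts.sum()
        np.testing.assert_allclose(emp, stationary_occupancy(p), atol=0.02)


class TestStress:
    def _truth(self, slopes, noise_sd=0.0, ri_sd=0.0):
        p = generate_params(R=4, K=len(slopes), seed=0)
        return GroundTruth(
            params_by_group={"mindfulness": p, "control": p}, true_paths={},
            stress_model=StressModel(intercept=3.0, slope_per_state=tuple(slopes),
                                     noise_sd=noise_sd, random_intercept_sd=ri_sd))

    def test_constant_when_everything_zero(self):
        truth = self._truth([0.0, 0.0])
        occ = np.array([[50.0, 50.0], [10.0, 90.0]])
        scores = generate_stress(truth, occ, ["a", "b"], 0)
        np.testing.assert_allclose(scores, 3.0)

    def test_monotone_in_negative_slope_state(self):
        truth = self._truth([-0.05, 0.0])
        occ = np.array([[10.0, 90.0], [30.0, 70.0], [60.0, 40.0]])
        scores = generate_stress(truth, occ, ["a", "b", "c"], 0)
        assert scores[0] > scores[1] > scores[2]

    def test_clipped_to_instrument_scale(self):
        truth = self._truth([-1.0, 0.0])
        occ = np.array([[100.0, 0.0]])
        scores = generate_stress(truth, occ, ["a"], 0)
        assert scores[0] == 1.0
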
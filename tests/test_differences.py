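"""Bhattacharyya distances and the four per-pair difference metrics."""

import dataclasses

import numpy as np
import pytest
from scipy import integrate, stats

from paintransfer import (
    bhattacharyya_gaussian,
    bhattacharyya_histogram,
    compute_difference_metrics,
    diff_bold_map,
    diff_pain,
    dist_bold_map,
    dist_pain,
    generate_cohort,
)
from paintransfer.exceptions import AlignmentError


def bhattacharyya_quadrature(m1, v1, m2, v2):
    """Independent oracle: DB = -ln integral sqrt(p(x) q(x)) dx."""
    p = stats.norm(m1, np.sqrt(v1))
    q = stats.norm(m2, np.sqrt(v2))
    bc, _ = integrate.quad(
        lambda x: np.sqrt(p.pdf(x) * q.pdf(x)), -np.inf, np.inf, limit=200
    )
    return -np.log(bc)


class TestBhattacharyyaGaussian:
    def test_identity_and_closed_form(self):
        assert bhattacharyya_gaussian(3.0, 2.0, 3.0, 2.0) == 0.0
        # means two apart, unit variances: 0.25 * 4 / 2 + 0.5 ln 1 = 0.5
        assert bhattacharyya_gaussian(0.0, 1.0, 2.0, 1.0) == pytest.approx(0.5)

    def test_against_quadrature_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m1, m2 = rng.normal(0, 3, size=2)
            v1, v2 = rng.uniform(0.2, 4.0, size=2)
            assert bhattacharyya_gaussian(m1, v1, m2, v2) == pytest.approx(
                bhattacharyya_quadrature(m1, v1, m2, v2), abs=1e-6
            )

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            bhattacharyya_gaussian(0.0, -1.0, 0.0, 1.0)

    def test_non_negative(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=(4, 50))
        v = rng.uniform(0.1, 2, size=(4, 50))
        d = bhattacharyya_gaussian(m[0], v[0], m[1], v[1])
        assert np.all(d >= 0)


class TestPainMetrics:
    def test_dist_pain_identity_and_symmetry(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 10, size=20)
        b = rng.uniform(0, 10, size=20)
        assert dist_pain(a, a) == 0.0
        assert dist_pain(a, b) == pytest.approx(dist_pain(b, a))
        assert dist_pain(a, b) >= 0

    def test_diff_pain_orientation(self):
        test_r = np.full(10, 7.0)
        train_r = np.full(10, 3.0)
        assert diff_pain(test_r, train_r) == pytest.approx(4.0)
        assert diff_pain(train_r, test_r) == pytest.approx(-4.0)
        assert diff_pain(test_r, test_r) == 0.0

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            dist_pain([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            diff_pain([], [1.0])


class TestBoldMetrics:
    def test_identical_matrices_zero(self):
        F = np.random.default_rng(3).normal(size=(10, 5))
        assert np.allclose(dist_bold_map(F, F), 0.0)
        assert np.allclose(diff_bold_map(F, F), 0.0)

    def test_single_voxel_shift_closed_form(self):
        rng = np.random.default_rng(4)
        F = rng.normal(size=(200, 5))
        G = F.copy()
        shift = 1.5
        G[:, 2] += shift
        d = dist_bold_map(G, F)
        v = F[:, 2].var(ddof=1)
        assert d[2] == pytest.approx(0.25 * shift**2 / (2 * v), rel=1e-10)
        assert np.allclose(np.delete(d, 2), 0.0)

    def test_quadrature_oracle_per_voxel(self):
        rng = np.random.default_rng(5)
        Ft = rng.normal(1.0, 1.2, size=(60, 5))
        Fs = rng.normal(0.0, 0.8, size=(60, 5))
        d = dist_bold_map(Ft, Fs)
        for v in range(5):
            expected = bhattacharyya_quadrature(
                Ft[:, v].mean(), Ft[:, v].var(ddof=1),
                Fs[:, v].mean(), Fs[:, v].var(ddof=1),
            )
            assert d[v] == pytest.approx(expected, abs=1e-6)

    def test_diff_bold_brute_force(self):
        rng = np.random.default_rng(6)
        Ft = rng.normal(size=(6, 4))
        Fs = rng.normal(size=(6, 4))
        expected = [Ft[:, v].mean() - Fs[:, v].mean() for v in range(4)]
        assert np.allclose(diff_bold_map(Ft, Fs), expected, atol=1e-12)
        assert np.allclose(diff_bold_map(Fs, Ft), -diff_bold_map(Ft, Fs))

    def test_mismatched_voxel_counts_rejected(self):
        with pytest.raises(AlignmentError):
            dist_bold_map(np.ones((5, 3)), np.ones((5, 4)))
        with pytest.raises(AlignmentError):
            diff_bold_map(np.ones((5, 3)), np.ones((5, 4)))


class TestHistogramEstimator:
    def test_identical_samples_zero(self):
        x = np.random.default_rng(7).uniform(0, 10, size=40)
        assert bhattacharyya_histogram(x, x) == pytest.approx(0.0)

    def test_separated_samples_positive(self):
        rng = np.random.default_rng(8)
        a = rng.normal(2, 0.5, size=100)
        b = rng.normal(7, 0.5, size=100)
        assert bhattacharyya_histogram(a, b, value_range=(0, 10)) > 1.0

    def test_cohort_metrics_run_with_histogram(self, small_cfg):
        datasets, _ = generate_cohort(small_cfg)
        metrics = compute_difference_metrics(datasets, estimator="histogram")
        assert np.allclose(metrics.dist_pain, metrics.dist_pain.T)
        assert np.all(metrics.dist_bold >= 0)


class TestCohortMetrics:
    def test_structural_identities(self, small_cfg):
        datasets, _ = generate_cohort(small_cfg)
        m = compute_difference_metrics(datasets)
        assert np.allclose(m.dist_pain, m.dist_pain.T)
        assert np.allclose(m.diff_pain, -m.diff_pain.T)
        assert np.allclose(m.dist_bold, m.dist_bold.transpose(1, 0, 2))
        assert np.allclose(m.diff_bold, -m.diff_bold.transpose(1, 0, 2))
        assert np.allclose(np.diagonal(m.dist_pain), 0.0)
        assert np.all(m.dist_pain >= 0) and np.all(m.dist_bold >= 0)

    def test_matches_pairwise_functions(self, small_cfg):
        datasets, _ = generate_cohort(small_cfg)
        m = compute_difference_metrics(datasets)
        s, t = 1, 4
        assert m.dist_pain[s, t] == pytest.approx(
            dist_pain(datasets[t].ratings, datasets[s].ratings)
        )
        assert m.diff_pain[s, t] == pytest.approx(
            diff_pain(datasets[t].ratings, datasets[s].ratings)
        )
        assert np.allclose(
            m.diff_bold[s, t], diff_bold_map(datasets[t].features, datasets[s].features)
        )

    def test_homogeneous_cohort_all_zero(self, homogeneous_cfg):
        datasets, _ = generate_cohort(homogeneous_cfg)
        m = compute_difference_metrics(datasets)
        assert np.allclose(m.dist_pain, 0.0, atol=1e-8)
        assert np.allclose(m.diff_pain, 0.0, atol=1e-8)
        assert np.allclose(m.diff_bold, 0.0, atol=1e-8)

    def test_diff_pain_recovers_planted_sensitivity(self):
        """With slope heterogeneity off and low rating noise, the pairwise
        mean-rating difference tracks the planted offset difference."""
        from paintransfer import CohortConfig

        cfg = CohortConfig(
            n_individuals=20, slope_mean_sd=(1.6, 0.0), rating_noise_sd=0.2, seed=17
        )
        datasets, truth = generate_cohort(cfg)
        m = compute_difference_metrics(datasets)
        iu = np.triu_indices(20, k=1)
        planted = truth.alpha[iu[1]] - truth.alpha[iu[0]]
        observed = m.diff_pain[iu]
        r = np.corrcoef(planted, observed)[0, 1]
        assert r > 0.9
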
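"""SIMPLS regression: oracle equivalences, component selection, group maps."""

import dataclasses

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from paintransfer import (
    CohortConfig,
    PLSRModel,
    SIMPLSRegression,
    analyze_cohort,
    fit_simpls,
    generate_cohort,
    group_predictive_map,
    select_n_components,
)
from paintransfer import PipelineConfig
from paintransfer.exceptions import DegenerateResponseError, RankError


def random_problem(rng, n=5, p=3):
    X = rng.normal(size=(n, p))
    y = rng.normal(size=n)
    return X, y


class TestSIMPLSOracles:
    def test_full_rank_equals_ols(self):
        """At full rank SIMPLS reproduces the normal-equations solution."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            X, y = random_problem(rng)
            est = SIMPLSRegression(n_components=3).fit(X, y)
            Xd = np.column_stack([X, np.ones(len(y))])
            beta = np.linalg.lstsq(Xd, y, rcond=None)[0]
            assert np.max(np.abs(est.coef_ - beta[:3])) < 1e-8
            assert est.intercept_ == pytest.approx(beta[3], abs=1e-8)

    def test_matches_nipals_at_reduced_rank(self):
        """For a univariate response SIMPLS and NIPALS extract the same
        components; cross-check against sklearn at k < rank."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 12))
        y = X[:, 0] + 0.5 * X[:, 3] + 0.1 * rng.normal(size=30)
        for k in (1, 2, 4):
            ours = SIMPLSRegression(n_components=k).fit(X, y)
            ref = PLSRegression(n_components=k, scale=False).fit(X, y)
            assert np.allclose(ours.coef_, ref.coef_.ravel(), atol=1e-8)

    def test_exact_single_voxel_recovery(self):
        ratings = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        X = np.zeros((5, 4))
        X[:, 2] = ratings / 2.0
        est = SIMPLSRegression(n_components=1).fit(X, ratings)
        assert est.coef_[2] == pytest.approx(2.0, abs=1e-10)
        assert np.allclose(np.delete(est.coef_, 2), 0.0, atol=1e-10)

    def test_trial_duplication_invariance(self):
        rng = np.random.default_rng(3)
        X, y = random_problem(rng, n=8, p=5)
        one = SIMPLSRegression(n_components=2).fit(X, y)
        two = SIMPLSRegression(n_components=2).fit(
            np.vstack([X, X]), np.concatenate([y, y])
        )
        assert np.allclose(one.coef_, two.coef_, atol=1e-10)
        assert one.intercept_ == pytest.approx(two.intercept_, abs=1e-10)

    def test_column_scaling_equivariance_at_full_rank(self):
        rng = np.random.default_rng(11)
        X, y = random_problem(rng, n=10, p=4)
        base = SIMPLSRegression(n_components=4).fit(X, y)
        scale = np.array([1.0, 2.5, 0.5, 10.0])
        scaled = SIMPLSRegression(n_components=4).fit(X * scale, y)
        assert np.allclose(scaled.coef_, base.coef_ / scale, atol=1e-8)


class TestFitValidation:
    def test_constant_ratings_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        with pytest.raises(DegenerateResponseError):
            SIMPLSRegression(n_components=1).fit(X, np.full(6, 5.0))

    def test_components_beyond_rank_rejected(self):
        rng = np.random.default_rng(1)
        X = np.tile(rng.normal(size=(5, 1)), (1, 4))  # rank 1
        y = rng.normal(size=5)
        with pytest.raises(RankError):
            SIMPLSRegression(n_components=3).fit(X, y)
        with pytest.raises(RankError):
            SIMPLSRegression(n_components=9).fit(rng.normal(size=(5, 4)), y)

    def test_predict_identities(self):
        rng = np.random.default_rng(5)
        X, y = random_problem(rng, n=12, p=6)
        model = fit_simpls(X, y, n_components=3, individual_id="s0")
        assert model.predict(np.zeros((1, 6)))[0] == pytest.approx(model.intercept)
        assert model.predict(X).mean() == pytest.approx(y.mean())
        with pytest.raises(ValueError):
            model.predict(np.zeros((1, 5)))


class TestComponentSelection:
    def test_noise_free_rank_one_signal(self):
        # orthogonal columns: the response direction is itself a latent
        # component, so one component explains everything
        rng = np.random.default_rng(2)
        X = np.linalg.qr(rng.normal(size=(20, 6)))[0]
        y = X @ np.array([1.0, 0, 0, 0, 0, 0])
        assert select_n_components(X, y, r2_threshold=0.95) == 1

    def test_pure_noise_hits_cap_with_warning(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 30))
        y = rng.normal(size=40)
        with pytest.warns(UserWarning, match="unreachable"):
            k = select_n_components(X, y, r2_threshold=0.999999, max_components=10)
        assert k == 10

    def test_two_factor_response_needs_two_components(self):
        """Response spanned by two orthogonal score directions with the first
        SIMPLS component capturing < 95% of its variance. Oracle: the first
        score is t1 = Xc Xc' yc, so R^2_1 = cos^2(yc, t1) in closed form."""
        n = 40
        rng = np.random.default_rng(8)
        z = np.linalg.qr(rng.normal(size=(n, 2)))[0]  # two orthonormal scores
        X = np.column_stack([z[:, 0], 2.0 * z[:, 1]])
        y = z[:, 0] + z[:, 1]
        yc = y - y.mean()
        Xc = X - X.mean(axis=0)
        t1 = Xc @ (Xc.T @ yc)
        r2_first = float((yc @ t1) ** 2 / ((yc @ yc) * (t1 @ t1)))
        assert r2_first < 0.95  # construction guarantee, computed independently
        assert select_n_components(X, y, r2_threshold=0.95) == 2


class TestGroupMap:
    def test_degenerate_variance_path(self):
        coef = np.array([1.0, 0.0, -2.0])
        models = [PLSRModel(coef.copy(), 0.0, 1, f"s{i}") for i in range(4)]
        gmap = group_predictive_map(models, alpha=0.05)
        assert gmap.p_value[0] == 0.0 and gmap.p_value[2] == 0.0
        assert gmap.p_value[1] == 1.0
        assert not gmap.significant[1]

    def test_region_recovery_with_polarity(self, default_run):
        """Planted consistent regions are flagged with the right sign; the
        sign-heterogeneous region is not flagged."""
        truth = default_run.ground_truth
        gmap = default_run.group_map
        pos = truth.region_voxels("positive")
        neg = truth.region_voxels("negative")
        het = truth.region_voxels("sign_heterogeneous")
        assert gmap.significant[pos].mean() > 0.9
        assert np.all(gmap.polarity[pos][gmap.significant[pos]] == 1)
        assert gmap.significant[neg].mean() > 0.9
        assert np.all(gmap.polarity[neg][gmap.significant[neg]] == -1)
        assert not gmap.significant[het].any()

    def test_requires_three_models(self):
        models = [PLSRModel(np.ones(3), 0.0, 1, f"s{i}") for i in range(2)]
        with pytest.raises(ValueError):
            group_predictive_map(models)


def test_fitted_mean_equals_rating_mean_across_cohort(default_run):
    """Centering identity for every individual's model."""
    for model, ds in zip(default_run.models, default_run.datasets):
        assert model.predict(ds.features).mean() == pytest.approx(
            ds.ratings.mean(), abs=1e-8
        )
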
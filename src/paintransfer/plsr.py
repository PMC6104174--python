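"""Partial least squares regression via SIMPLS, and group-level coefficient maps.

The decoding model for individual ``j`` is linear in the trial-by-voxel
feature matrix B:  R_i = B_i a + b,  with the coefficient vector ``a``
estimated by the SIMPLS algorithm (de Jong 1993, Chemometr. Intell. Lab. 18).
SIMPLS extracts mutually orthogonal score vectors that maximize covariance
with the (centered) response and regresses the response on them; with as many
components as the rank of the centered feature matrix it reproduces the
ordinary-least-squares solution.

Both blocks are centered, so the returned intercept makes the mean fitted
value on the training trials equal the mean training rating — the identity
that forces resubstitution mean prediction bias to zero downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .exceptions import DegenerateResponseError, RankError

logger = logging.getLogger(__name__)

_RANK_TOL = 1e-12


def _simpls_path(X: np.ndarray, y: np.ndarray, max_components: int):
    """Run the SIMPLS recursion and return the per-component path.

    Returns (R, Q, ss_y) where the coefficient vector using the first k
    components is ``R[:, :k] @ Q[:k]`` (on centered data) and the cumulative
    response variance explained is ``cumsum(Q**2) / ss_y`` (scores are
    orthonormal, so explained sums of squares add).
    """
    n, p = X.shape
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    ss_y = float(yc @ yc)
    if ss_y <= _RANK_TOL:
        raise DegenerateResponseError("ratings are constant; nothing to regress on")

    s = Xc.T @ yc                       # covariance direction (univariate response)
    scale = float(np.linalg.norm(s))    # reference magnitude for rank decisions
    R = np.zeros((p, max_components))
    Q = np.zeros(max_components)
    V = np.zeros((p, max_components))
    reached = 0
    for a in range(max_components):
        r = s.copy()
        t = Xc @ r
        norm_t = float(np.linalg.norm(t))
        if norm_t <= _RANK_TOL * max(scale, 1.0):
            break                       # rank exhausted
        t /= norm_t
        r /= norm_t
        p_load = Xc.T @ t
        q = float(yc @ t)
        v = p_load.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ p_load)
        norm_v = float(np.linalg.norm(v))
        if norm_v <= _RANK_TOL * max(scale, 1.0):
            break
        v /= norm_v
        s = s - v * (v @ s)
        R[:, a] = r
        Q[a] = q
        V[:, a] = v
        reached = a + 1
    return R[:, :reached], Q[:reached], ss_y, x_mean, y_mean


class SIMPLSRegression(RegressorMixin, BaseEstimator):
    """Univariate-response PLSR fitted with SIMPLS.

    Parameters
    ----------
    n_components : int or None
        Number of latent components. ``None`` selects the smallest count whose
        cumulative coefficient of determination on the training response
        reaches ``r2_threshold``, capped at ``max_components``.
    r2_threshold : float
        Fitted-variance / total-variance ratio used for automatic selection.
    max_components : int
        Cap on the selected component count. If the threshold is unreachable
        at the cap (or at the data rank), the cap is used and a warning issued.

    Attributes
    ----------
    coef_ : (n_features,) coefficients on the original feature scale.
    intercept_ : float
    n_components_ : int, components actually used.
    r2_path_ : cumulative training R^2 per component, length = path length.
    """

    def __init__(self, n_components: int | None = None, r2_threshold: float = 0.95,
                 max_components: int = 10):
        self.n_components = n_components
        self.r2_threshold = r2_threshold
        self.max_components = max_components

    def fit(self, X, y):
        X, y = validate_data(self, X, y, ensure_min_samples=2, y_numeric=True)
        n, p = X.shape
        hard_cap = min(n - 1, p)
        if self.n_components is not None:
            if not 1 <= self.n_components <= hard_cap:
                raise RankError(
                    f"n_components={self.n_components} outside [1, {hard_cap}] "
                    f"for {n} trials x {p} voxels"
                )
            budget = self.n_components
        else:
            if not 0.0 < self.r2_threshold < 1.0:
                raise ValueError("r2_threshold must lie in (0, 1)")
            budget = min(self.max_components, hard_cap)

        R, Q, ss_y, x_mean, y_mean = _simpls_path(X, y, budget)
        if self.n_components is not None and R.shape[1] < self.n_components:
            raise RankError(
                f"data rank {R.shape[1]} cannot support n_components={self.n_components}"
            )
        r2_path = np.cumsum(Q**2) / ss_y
        if self.n_components is not None:
            k = self.n_components
        else:
            hit = np.nonzero(r2_path >= self.r2_threshold)[0]
            if hit.size:
                k = int(hit[0]) + 1
            else:
                k = R.shape[1]
                warnings.warn(
                    f"R^2 threshold {self.r2_threshold} unreachable within "
                    f"{k} components (best {r2_path[-1] if k else 0.0:.3f}); using the cap",
                    stacklevel=2,
                )
        self.coef_ = R[:, :k] @ Q[:k]
        self.intercept_ = float(y_mean - x_mean @ self.coef_)
        self.n_components_ = k
        self.r2_path_ = r2_path
        self.x_mean_ = x_mean
        self.y_mean_ = float(y_mean)
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return X @ self.coef_ + self.intercept_


# -- module-level conveniences ----------------------------------------------

@dataclass
class PLSRModel:
    """Serialized form of one individual's fitted decoding model."""

    coefficients: np.ndarray
    intercept: float
    n_components: int
    individual_id: str

    def predict(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        if features.shape[-1] != self.coefficients.shape[0]:
            raise ValueError(
                f"{features.shape[-1]} feature columns vs "
                f"{self.coefficients.shape[0]} coefficients"
            )
        return features @ self.coefficients + self.intercept


def fit_simpls(features, ratings, n_components: int, individual_id: str = "") -> PLSRModel:
    """Fit a fixed-size SIMPLS model and return its portable form."""
    est = SIMPLSRegression(n_components=n_components).fit(features, ratings)
    return PLSRModel(est.coef_, est.intercept_, est.n_components_, individual_id)


def select_n_components(features, ratings, r2_threshold: float = 0.95,
                        max_components: int = 10) -> int:
    """Smallest component count reaching the training-R^2 threshold (capped)."""
    est = SIMPLSRegression(
        n_components=None, r2_threshold=r2_threshold, max_components=max_components
    ).fit(features, ratings)
    return est.n_components_


def fit_individual(dataset, r2_threshold: float = 0.95, max_components: int = 10) -> PLSRModel:
    """Fit one individual's model with automatic component selection."""
    est = SIMPLSRegression(
        n_components=None, r2_threshold=r2_threshold, max_components=max_components
    ).fit(dataset.features, dataset.ratings)
    return PLSRModel(est.coef_, est.intercept_, est.n_components_, dataset.individual_id)


# -- group-level predictive map ----------------------------------------------

@dataclass
class VoxelStatMap:
    """A per-voxel statistic with uncorrected p-values and an FWE mask.

    ``p_value`` is the uncorrected two-sided p unless ``correction`` says
    otherwise (the permutation path stores FWE-adjusted p-values directly).
    ``polarity`` is the sign of the statistic at significant voxels, 0
    elsewhere.
    """

    statistic: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray
    correction: str
    alpha: float
    polarity: np.ndarray = field(default=None)
    n_tests: int = 0

    def __post_init__(self):
        if self.polarity is None:
            self.polarity = np.where(self.significant, np.sign(self.statistic), 0.0)

    def threshold(self, alpha: float) -> np.ndarray:
        """Recompute the significance mask at another FWE level."""
        if self.correction == "bonferroni":
            sig = self.p_value * self.n_tests <= alpha
        else:
            sig = self.p_value <= alpha
        return sig & np.isfinite(self.statistic)


def group_predictive_map(models: list[PLSRModel], alpha: float = 0.05) -> VoxelStatMap:
    """One-sample t-test of model coefficients against zero across individuals.

    Bonferroni FWE correction over in-mask voxels. Voxels with zero
    across-individual variance take p = 0 (constant nonzero coefficient) or
    p = 1 (all-zero) by sign convention and are logged.
    """
    if len(models) < 3:
        raise ValueError("need at least 3 models for a group map")
    coefs = np.vstack([m.coefficients for m in models])
    n, p = coefs.shape
    mean = coefs.mean(axis=0)
    sd = coefs.std(axis=0, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = mean / (sd / np.sqrt(n))
    pval = 2.0 * stats.t.sf(np.abs(tstat), df=n - 1)
    if degenerate.any():
        logger.info("group map: %d zero-variance voxels handled by sign convention",
                    int(degenerate.sum()))
        pval[degenerate & (mean != 0)] = 0.0
        tstat[degenerate & (mean != 0)] = np.sign(mean[degenerate & (mean != 0)]) * np.inf
        pval[degenerate & (mean == 0)] = 1.0
        tstat[degenerate & (mean == 0)] = 0.0
    significant = pval * p <= alpha
    return VoxelStatMap(tstat, pval, significant, "bonferroni", alpha, n_tests=p)
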
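"""Individual-by-individual transfer prediction and its error metrics.

Every individual's model is applied to every individual's trials, giving n^2
ordered (training, test) prediction pairs: the off-diagonal cells are
between-individual transfer, the diagonal is within-individual prediction.
Two error metrics summarize each pair:

    MAE_{t,s} = mean_i |Rhat_i(t;s) - R_i(t)|   (unsigned overall error)
    MPB_{t,s} = mean_i (Rhat_i(t;s) - R_i(t))   (signed bias; positive =
                                                 over-prediction)

Predictions are deliberately not clipped to the rating scale — clipping would
bias MPB. Within-individual prediction defaults to resubstitution, under
which the centering identity of the fitted models forces MPB = 0 on the
diagonal; a k-fold mode is available for a cross-validated diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from .exceptions import AlignmentError
from .pairs import flatten_offdiag, pair_index_frame
from .plsr import PLSRModel, SIMPLSRegression
from .simulate import IndividualDataset


def mae(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Mean absolute error between predicted and actual ratings."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape or predicted.size == 0:
        raise ValueError("predicted and actual must be equal-length, non-empty")
    return float(np.mean(np.abs(predicted - actual)))


def mpb(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Mean prediction bias (predicted minus actual); sign carries direction."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape or predicted.size == 0:
        raise ValueError("predicted and actual must be equal-length, non-empty")
    return float(np.mean(predicted - actual))


@dataclass
class PairwiseErrorMatrix:
    """MAE and MPB over all ordered (training, test) pairs.

    Matrices are indexed ``[train_idx, test_idx]``. The diagonal holds
    within-individual prediction, everything else between-individual.
    """

    mae: np.ndarray
    mpb: np.ndarray
    ids: list[str]

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def pair_index(self) -> pd.DataFrame:
        return pair_index_frame(self.ids)

    def between(self, metric: str = "mae") -> np.ndarray:
        """Off-diagonal values in canonical pair order."""
        return flatten_offdiag(getattr(self, metric), self.pair_index)

    def within(self, metric: str = "mae") -> np.ndarray:
        return np.diag(getattr(self, metric)).copy()


def _kfold_diagonal(dataset: IndividualDataset, n_components: int, n_splits: int):
    """Cross-validated within-individual predictions (optional diagonal mode)."""
    preds = np.empty_like(dataset.ratings)
    for train, test in KFold(n_splits=n_splits).split(dataset.features):
        est = SIMPLSRegression(
            n_components=None, r2_threshold=0.95,
            max_components=min(n_components, len(train) - 1),
        ).fit(dataset.features[train], dataset.ratings[train])
        preds[test] = est.predict(dataset.features[test])
    return preds


def pairwise_predict(
    models: list[PLSRModel],
    datasets: list[IndividualDataset],
    within_mode: str = "resubstitution",
    n_splits: int = 5,
) -> PairwiseErrorMatrix:
    """Fill the full n x n error matrices from per-individual models.

    ``models`` and ``datasets`` must be aligned by individual id (order
    included); a mismatch raises rather than silently mispairing.
    """
    if [m.individual_id for m in models] != [d.individual_id for d in datasets]:
        raise AlignmentError("models and datasets are not aligned by individual id")
    if within_mode not in ("resubstitution", "kfold"):
        raise ValueError(f"unknown within_mode {within_mode!r}")
    n = len(models)
    coefs = np.column_stack([m.coefficients for m in models])  # (n_vox, n)
    intercepts = np.array([m.intercept for m in models])
    mae_mat = np.empty((n, n))
    mpb_mat = np.empty((n, n))
    for t, ds in enumerate(datasets):
        preds = ds.features @ coefs + intercepts[None, :]       # (trials, n_models)
        resid = preds - ds.ratings[:, None]
        mae_mat[:, t] = np.abs(resid).mean(axis=0)
        mpb_mat[:, t] = resid.mean(axis=0)
        if within_mode == "kfold":
            cv_pred = _kfold_diagonal(ds, models[t].n_components, n_splits)
            mae_mat[t, t] = mae(cv_pred, ds.ratings)
            mpb_mat[t, t] = mpb(cv_pred, ds.ratings)
    return PairwiseErrorMatrix(mae_mat, mpb_mat, [d.individual_id for d in datasets])


@dataclass
class GroupDensity:
    """Kernel density estimate of one group's error distribution."""

    grid: np.ndarray
    density: np.ndarray


@dataclass
class MetricComparison:
    between_mean: float
    between_sd: float
    within_mean: float
    within_sd: float
    t_statistic: float
    p_value: float
    between_density: GroupDensity
    within_density: GroupDensity


@dataclass
class WithinBetweenReport:
    mae: MetricComparison
    mpb: MetricComparison
    n_between: int
    n_within: int
    test_variant: str


def _kde(values: np.ndarray, n_grid: int = 256) -> GroupDensity:
    """Gaussian KDE with Silverman's bandwidth; degenerate samples collapse to
    a point mass marker at the common value."""
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0:
        grid = np.array([values[0]])
        return GroupDensity(grid, np.array([np.inf]))
    kde = stats.gaussian_kde(values, bw_method="silverman")
    bw = kde.factor * values.std(ddof=1)
    grid = np.linspace(values.min() - 3 * bw, values.max() + 3 * bw, n_grid)
    return GroupDensity(grid, kde(grid))


def compare_within_between(
    errors: PairwiseErrorMatrix, test_variant: str = "welch"
) -> WithinBetweenReport:
    """Two-sample t-test (Welch by default) of between vs within prediction
    error, for MAE and MPB, plus KDE approximations of each distribution."""
    if errors.n_individuals < 3:
        raise ValueError("need at least 3 individuals to compare groups")
    if test_variant not in ("welch", "student"):
        raise ValueError(f"unknown test_variant {test_variant!r}")
    equal_var = test_variant == "student"
    out = {}
    for metric in ("mae", "mpb"):
        between = errors.between(metric)
        within = errors.within(metric)
        t, p = stats.ttest_ind(between, within, equal_var=equal_var)
        out[metric] = MetricComparison(
            float(between.mean()), float(between.std(ddof=1)),
            float(within.mean()), float(within.std(ddof=1)),
            float(t), float(p),
            _kde(between), _kde(within),
        )
    return WithinBetweenReport(
        out["mae"], out["mpb"],
        n_between=errors.n_individuals * (errors.n_individuals - 1),
        n_within=errors.n_individuals,
        test_variant=test_variant,
    )
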
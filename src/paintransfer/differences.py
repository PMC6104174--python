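"""Per-pair individual-difference metrics.

For each ordered (training s, test t) pair, four metrics quantify how the two
individuals' data differ:

* DIST_PAIN  — Bhattacharyya distance between the two trial-wise rating
  samples (unsigned, symmetric);
* DIFF_PAIN  — difference of across-trial mean ratings, test minus training
  (signed, antisymmetric);
* DIST_BOLD  — per-voxel Bhattacharyya distance between feature samples;
* DIFF_BOLD  — per-voxel difference of mean features, test minus training.

The Bhattacharyya distance between two empirical samples is evaluated, by
default, through the Gaussian closed form on the sample moments

    DB = (m1 - m2)^2 / (4 (v1 + v2)) + 1/2 ln[ (v1 + v2) / (2 sqrt(v1 v2)) ]

with unbiased sample variances floored at a small epsilon. A shared-bin
histogram estimator (DB = -ln sum_b sqrt(p_b q_b)) is available for
sensitivity analysis via ``estimator="histogram"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import AlignmentError
from .pairs import pair_index_frame
from .simulate import IndividualDataset

VAR_FLOOR = 1e-9


def bhattacharyya_gaussian(mean1, var1, mean2, var2, var_floor: float = VAR_FLOOR):
    """Closed-form Bhattacharyya distance between two Gaussians.

    Accepts scalars or broadcastable arrays. Variances are floored at
    ``var_floor``; negative variances are rejected.
    """
    mean1, var1 = np.asarray(mean1, dtype=float), np.asarray(var1, dtype=float)
    mean2, var2 = np.asarray(mean2, dtype=float), np.asarray(var2, dtype=float)
    if np.any(var1 < 0) or np.any(var2 < 0):
        raise ValueError("variances must be non-negative")
    v1 = np.maximum(var1, var_floor)
    v2 = np.maximum(var2, var_floor)
    vsum = v1 + v2
    out = 0.25 * (mean1 - mean2) ** 2 / vsum + 0.5 * np.log(vsum / (2.0 * np.sqrt(v1 * v2)))
    return out if out.ndim else float(out)


def bhattacharyya_histogram(x, y, bins: int = 20, value_range=None) -> float:
    """Histogram Bhattacharyya distance over shared bin edges.

    ``value_range`` defaults to the pooled min/max; for ratings pass (0, 10).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if value_range is None:
        lo = min(x.min(), y.min())
        hi = max(x.max(), y.max())
        if lo == hi:
            return 0.0
        value_range = (lo, hi)
    p, edges = np.histogram(x, bins=bins, range=value_range, density=False)
    q, _ = np.histogram(y, bins=edges, density=False)
    p = p / p.sum()
    q = q / q.sum()
    bc = float(np.sqrt(p * q).sum())
    return -np.log(max(bc, np.finfo(float).tiny))


def _moments(values: np.ndarray, axis: int = 0):
    if values.shape[axis] < 2:
        raise ValueError("need at least 2 trials for a distance")
    return values.mean(axis=axis), values.var(axis=axis, ddof=1)


def dist_pain(ratings_t, ratings_s, estimator: str = "gaussian", bins: int = 20) -> float:
    """Bhattacharyya distance between two individuals' rating samples."""
    ratings_t = np.asarray(ratings_t, dtype=float)
    ratings_s = np.asarray(ratings_s, dtype=float)
    if estimator == "histogram":
        return bhattacharyya_histogram(ratings_t, ratings_s, bins=bins, value_range=(0, 10))
    mt, vt = _moments(ratings_t)
    ms, vs = _moments(ratings_s)
    return bhattacharyya_gaussian(mt, vt, ms, vs)


def diff_pain(ratings_t, ratings_s) -> float:
    """Mean rating of the test individual minus that of the training one."""
    ratings_t = np.asarray(ratings_t, dtype=float)
    ratings_s = np.asarray(ratings_s, dtype=float)
    if ratings_t.size == 0 or ratings_s.size == 0:
        raise ValueError("empty rating vector")
    return float(ratings_t.mean() - ratings_s.mean())


def dist_bold_map(features_t, features_s, estimator: str = "gaussian", bins: int = 20):
    """Per-voxel Bhattacharyya distance between two feature matrices."""
    features_t = np.asarray(features_t, dtype=float)
    features_s = np.asarray(features_s, dtype=float)
    if features_t.shape[1] != features_s.shape[1]:
        raise AlignmentError("feature matrices have different voxel counts")
    if estimator == "histogram":
        return np.array([
            bhattacharyya_histogram(features_t[:, v], features_s[:, v], bins=bins)
            for v in range(features_t.shape[1])
        ])
    mt, vt = _moments(features_t)
    ms, vs = _moments(features_s)
    return bhattacharyya_gaussian(mt, vt, ms, vs)


def diff_bold_map(features_t, features_s):
    """Per-voxel mean feature of the test individual minus the training one."""
    features_t = np.asarray(features_t, dtype=float)
    features_s = np.asarray(features_s, dtype=float)
    if features_t.shape[1] != features_s.shape[1]:
        raise AlignmentError("feature matrices have different voxel counts")
    return features_t.mean(axis=0) - features_s.mean(axis=0)


@dataclass
class DifferenceMetrics:
    """All four metrics over every ordered (training, test) pair.

    Square arrays are indexed ``[train_idx, test_idx]``; the voxel-wise arrays
    have shape (n, n, n_voxels). dist_* are symmetric with zero diagonal,
    diff_* antisymmetric.
    """

    dist_pain: np.ndarray
    diff_pain: np.ndarray
    dist_bold: np.ndarray
    diff_bold: np.ndarray
    ids: list[str]

    @property
    def pair_index(self) -> pd.DataFrame:
        return pair_index_frame(self.ids)


def compute_difference_metrics(
    datasets: list[IndividualDataset],
    estimator: str = "gaussian",
    bins: int = 20,
) -> DifferenceMetrics:
    """Vectorized computation of all four metrics for a cohort."""
    if estimator not in ("gaussian", "histogram"):
        raise ValueError(f"unknown estimator {estimator!r}")
    n = len(datasets)
    ids = [d.individual_id for d in datasets]
    rating_mean = np.array([d.ratings.mean() for d in datasets])
    # diff: [s, t] = mean_t - mean_s  (test minus training)
    diff_pain_mat = rating_mean[None, :] - rating_mean[:, None]

    feat_mean = np.stack([d.features.mean(axis=0) for d in datasets])  # (n, p)
    diff_bold_mat = feat_mean[None, :, :] - feat_mean[:, None, :]

    if estimator == "gaussian":
        rating_var = np.array([d.ratings.var(ddof=1) for d in datasets])
        dist_pain_mat = bhattacharyya_gaussian(
            rating_mean[None, :], rating_var[None, :],
            rating_mean[:, None], rating_var[:, None],
        )
        feat_var = np.stack([d.features.var(axis=0, ddof=1) for d in datasets])
        dist_bold_mat = bhattacharyya_gaussian(
            feat_mean[None, :, :], feat_var[None, :, :],
            feat_mean[:, None, :], feat_var[:, None, :],
        )
    else:
        dist_pain_mat = np.zeros((n, n))
        for s in range(n):
            for t in range(s + 1, n):
                d = dist_pain(datasets[t].ratings, datasets[s].ratings,
                              estimator="histogram", bins=bins)
                dist_pain_mat[s, t] = dist_pain_mat[t, s] = d
        p = datasets[0].features.shape[1]
        dist_bold_mat = np.zeros((n, n, p))
        # shared edges per voxel from the pooled cohort range
        stacked = np.stack([d.features for d in datasets])  # (n, trials, p)
        lo = stacked.min(axis=(0, 1))
        hi = stacked.max(axis=(0, 1))
        same = lo == hi
        hi = np.where(same, hi + 1.0, hi)
        sqrt_hist = np.empty((n, p, bins))
        for j, ds in enumerate(datasets):
            for v in range(p):
                counts, _ = np.histogram(ds.features[:, v], bins=bins, range=(lo[v], hi[v]))
                sqrt_hist[j, v] = np.sqrt(counts / counts.sum())
        for v in range(p):
            bc = sqrt_hist[:, v, :] @ sqrt_hist[:, v, :].T
            dist_bold_mat[:, :, v] = -np.log(np.maximum(bc, np.finfo(float).tiny))

    # exact structural identities, up to floating round-off
    np.fill_diagonal(dist_pain_mat, 0.0)
    np.fill_diagonal(diff_pain_mat, 0.0)
    for j in range(n):
        dist_bold_mat[j, j, :] = 0.0
        diff_bold_mat[j, j, :] = 0.0
    return DifferenceMetrics(dist_pain_mat, diff_pain_mat, dist_bold_mat, diff_bold_mat, ids)
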
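"""Correlating individual-difference metrics with prediction error across pairs.

Unsigned metrics (DIST_PAIN, per-voxel DIST_BOLD) are correlated with MAE and
signed metrics (DIFF_PAIN, per-voxel DIFF_BOLD) with MPB, across the
n(n-1) ordered between-individual pairs, by Pearson correlation. Voxel-wise
maps are FWE-corrected by Bonferroni over in-mask voxels (the default,
matching common practice for such maps) — note the pairs are not independent
(each individual appears in 2(n-1) ordered pairs), which the parametric
p-values deliberately ignore. For calibrated inference an individual-label
permutation scheme with max-statistic FWE control is available via
``inference="permutation"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differences import DifferenceMetrics
from .exceptions import AlignmentError, ConstantInputError
from .pairs import flatten_offdiag
from .plsr import VoxelStatMap
from .transfer import PairwiseErrorMatrix

logger = logging.getLogger(__name__)


@dataclass
class PairVectors:
    """Error and difference metrics flattened over between-individual pairs,
    all aligned on one canonical pair index."""

    mae: np.ndarray        # (n_pairs,)
    mpb: np.ndarray
    dist_pain: np.ndarray
    diff_pain: np.ndarray
    dist_bold: np.ndarray  # (n_pairs, n_voxels)
    diff_bold: np.ndarray
    pair_index: pd.DataFrame


def build_pair_vectors(errors: PairwiseErrorMatrix, diffs: DifferenceMetrics) -> PairVectors:
    """Flatten off-diagonal cells of both structures in canonical pair order.

    Alignment is by individual id: if the two objects list the same ids in a
    different order, the difference metrics are re-indexed to the error
    matrix's order before flattening.
    """
    if set(errors.ids) != set(diffs.ids):
        raise AlignmentError("error matrix and difference metrics cover different individuals")
    if errors.ids == diffs.ids:
        reorder = None
    else:
        reorder = np.array([diffs.ids.index(i) for i in errors.ids])
    pair_index = errors.pair_index

    def aligned(arr):
        if reorder is None:
            return arr
        return arr[np.ix_(reorder, reorder)]

    return PairVectors(
        mae=flatten_offdiag(errors.mae, pair_index),
        mpb=flatten_offdiag(errors.mpb, pair_index),
        dist_pain=flatten_offdiag(aligned(diffs.dist_pain), pair_index),
        diff_pain=flatten_offdiag(aligned(diffs.diff_pain), pair_index),
        dist_bold=flatten_offdiag(aligned(diffs.dist_bold), pair_index),
        diff_bold=flatten_offdiag(aligned(diffs.diff_bold), pair_index),
        pair_index=pair_index,
    )


def correlate_scalar(metric: np.ndarray, error: np.ndarray,
                     names: tuple[str, str] = ("metric", "error")) -> tuple[float, float]:
    """Pearson r and two-sided p between two pair vectors."""
    metric = np.asarray(metric, dtype=float)
    error = np.asarray(error, dtype=float)
    if metric.shape != error.shape or metric.size < 3:
        raise ValueError("vectors must be equal-length with at least 3 entries")
    for vec, name in zip((metric, error), names):
        if np.ptp(vec) == 0:
            raise ConstantInputError(f"{name} vector is constant; correlation undefined")
    r, p = stats.pearsonr(metric, error)
    return float(r), float(p)


def _columnwise_pearson(metric_matrix: np.ndarray, error: np.ndarray):
    """Vectorized per-voxel Pearson r of each metric column with the error
    vector; constant columns return nan."""
    ez = error - error.mean()
    e_ss = float(ez @ ez)
    constant = np.ptp(metric_matrix, axis=0) == 0
    mc = metric_matrix - metric_matrix.mean(axis=0)
    m_ss = np.einsum("ij,ij->j", mc, mc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (mc.T @ ez) / np.sqrt(m_ss * e_ss)
    r[constant | (m_ss == 0)] = np.nan
    return np.clip(r, -1.0, 1.0)


def _permute_error(error_matrix: np.ndarray, perm: np.ndarray,
                   s_idx: np.ndarray, t_idx: np.ndarray) -> np.ndarray:
    """Error vector after relabeling individuals by ``perm``."""
    return error_matrix[perm[s_idx], perm[t_idx]]


def correlate_voxelwise(
    metric_matrix: np.ndarray,
    error: np.ndarray,
    alpha: float = 0.05,
    *,
    inference: str = "parametric",
    error_matrix: np.ndarray | None = None,
    pair_index: pd.DataFrame | None = None,
    n_permutations: int = 499,
    seed: int = 0,
) -> VoxelStatMap:
    """Per-voxel Pearson correlation map with FWE-corrected significance.

    Parameters
    ----------
    metric_matrix : (n_pairs, n_voxels)
        A voxel-wise difference metric flattened over pairs.
    error : (n_pairs,)
        The matching error metric (MAE for DIST_BOLD, MPB for DIFF_BOLD).
    inference : "parametric" or "permutation"
        Parametric: t-transform p-values, Bonferroni over non-constant voxels.
        Permutation: individual labels are permuted (relabeling the error
        matrix), and FWE-adjusted p-values come from the permutation
        distribution of the maximum |r| over voxels; requires
        ``error_matrix`` and ``pair_index``.
    """
    metric_matrix = np.asarray(metric_matrix, dtype=float)
    error = np.asarray(error, dtype=float)
    if metric_matrix.shape[0] != error.shape[0]:
        raise AlignmentError(
            f"{metric_matrix.shape[0]} metric rows vs {error.shape[0]} error entries"
        )
    if np.ptp(error) == 0:
        raise ConstantInputError("error vector is constant; correlation undefined")

    n_pairs, n_vox = metric_matrix.shape
    r = _columnwise_pearson(metric_matrix, error)
    valid = np.isfinite(r)
    n_valid = int(valid.sum())
    if n_valid < n_vox:
        logger.info("correlation map: %d constant voxels excluded", n_vox - n_valid)

    if inference == "parametric":
        df = n_pairs - 2
        with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
            t = r * np.sqrt(df / np.maximum(1.0 - r**2, np.finfo(float).tiny))
        p = np.where(valid, 2.0 * stats.t.sf(np.abs(t), df=df), 1.0)
        significant = valid & (p * n_valid <= alpha)
        return VoxelStatMap(r, p, significant, "bonferroni", alpha, n_tests=n_valid)

    if inference != "permutation":
        raise ValueError(f"unknown inference {inference!r}")
    if error_matrix is None or pair_index is None:
        raise ValueError("permutation inference needs error_matrix and pair_index")
    n = error_matrix.shape[0]
    s_idx = pair_index["train_idx"].to_numpy()
    t_idx = pair_index["test_idx"].to_numpy()
    rng = np.random.default_rng(seed)
    # all permuted error vectors at once, then one BLAS call for all voxels
    perms = np.stack([rng.permutation(n) for _ in range(n_permutations)])
    E = np.stack([_permute_error(error_matrix, perm, s_idx, t_idx) for perm in perms],
                 axis=1)                                     # (n_pairs, n_perm)
    Ez = E - E.mean(axis=0)
    e_ss = np.einsum("ij,ij->j", Ez, Ez)
    mc = metric_matrix - metric_matrix.mean(axis=0)
    m_ss = np.einsum("ij,ij->j", mc, mc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_perm = (mc.T @ Ez) / np.sqrt(np.outer(m_ss, e_ss))  # (n_vox, n_perm)
    max_abs = np.nanmax(np.abs(r_perm), axis=0)               # (n_perm,)
    obs = np.abs(np.where(valid, r, 0.0))
    exceed = (max_abs[None, :] >= obs[:, None]).sum(axis=1)
    p_fwe = (1.0 + exceed) / (1.0 + n_permutations)
    p_fwe = np.where(valid, p_fwe, 1.0)
    significant = valid & (p_fwe <= alpha)
    return VoxelStatMap(r, p_fwe, significant, "permutation-maxstat", alpha,
                        n_tests=n_valid)


@dataclass
class CorrelationReport:
    """Scalar correlations plus the two voxel-wise maps at each alpha."""

    r_dist_pain_mae: float
    p_dist_pain_mae: float
    r_diff_pain_mpb: float
    p_diff_pain_mpb: float
    dist_bold_mae_maps: dict[float, VoxelStatMap]
    diff_bold_mpb_maps: dict[float, VoxelStatMap]


def correlate_all(pairs: PairVectors, alphas=(0.05, 1e-20),
                  inference: str = "parametric",
                  error_matrices: dict[str, np.ndarray] | None = None,
                  n_permutations: int = 499, seed: int = 0) -> CorrelationReport:
    """The four correlation analyses: DIST_PAIN-MAE, DIFF_PAIN-MPB, and the
    voxel-wise DIST_BOLD-MAE and DIFF_BOLD-MPB maps at each threshold."""
    r_dist, p_dist = correlate_scalar(pairs.dist_pain, pairs.mae, ("DIST_PAIN", "MAE"))
    r_diff, p_diff = correlate_scalar(pairs.diff_pain, pairs.mpb, ("DIFF_PAIN", "MPB"))
    kw: dict = {"inference": inference, "n_permutations": n_permutations, "seed": seed}
    dist_maps, diff_maps = {}, {}
    for a in alphas:
        if inference == "permutation":
            kw["pair_index"] = pairs.pair_index
            kw["error_matrix"] = error_matrices["mae"]
        dist_maps[a] = correlate_voxelwise(pairs.dist_bold, pairs.mae, a, **kw)
        if inference == "permutation":
            kw["error_matrix"] = error_matrices["mpb"]
        diff_maps[a] = correlate_voxelwise(pairs.diff_bold, pairs.mpb, a, **kw)
    return CorrelationReport(r_dist, p_dist, r_diff, p_diff, dist_maps, diff_maps)
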
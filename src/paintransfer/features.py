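"""Trial-level feature extraction from evoked scan series.

The single scalar feature per trial and voxel is the baseline-normalized
signal at the 4th scan after stimulus onset — the scan at which the evoked
response peaks at TR = 1.5 s. Indexing convention, stated once and asserted
everywhere: the onset scan is index 0, so "the 4th scan after onset" is
index ``onset_index + 4``. The feature is the value at that scan, not a
maximum over a window (a max operator would be noise-biased).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import DegenerateBaselineError

PEAK_OFFSET = 4  # scans after onset


def normalize_series(values: np.ndarray, onset_index: int = 0) -> np.ndarray:
    """Percent-signal-change normalization against the onset-scan baseline.

    Computes ``(value - baseline) / baseline`` per scan, where the baseline is
    the raw value at ``onset_index``. The onset scan itself maps to 0. Works on
    any array whose last axis is scans (trial x voxel x scan stacks included).

    Raises
    ------
    DegenerateBaselineError
        If any baseline value is zero; the message names the offending
        (trial, voxel) position.
    """
    values = np.asarray(values, dtype=float)
    if not 0 <= onset_index < values.shape[-1]:
        raise IndexError(f"onset_index {onset_index} outside series of length {values.shape[-1]}")
    baseline = values[..., onset_index]
    zero = baseline == 0
    if np.any(zero):
        where = np.argwhere(np.atleast_1d(zero))[0]
        raise DegenerateBaselineError(
            f"zero baseline at onset (position {tuple(int(i) for i in where)}); "
            "percent signal change is undefined"
        )
    return (values - baseline[..., None]) / baseline[..., None]


def extract_feature(normalized: np.ndarray, onset_index: int = 0) -> np.ndarray:
    """Value of the normalized series at exactly the 4th post-onset scan."""
    normalized = np.asarray(normalized, dtype=float)
    peak = onset_index + PEAK_OFFSET
    if peak >= normalized.shape[-1]:
        raise IndexError(
            f"series of length {normalized.shape[-1]} has no 4th post-onset scan "
            f"(onset {onset_index})"
        )
    return normalized[..., peak]


def extract_features(series: np.ndarray, onset_index: int = 0) -> np.ndarray:
    """Normalize and reduce a (n_trials, n_voxels, n_scans) stack to a
    trial-by-voxel feature matrix."""
    return extract_feature(normalize_series(series, onset_index), onset_index)


class TrialFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transformer form of the feature extraction for pipeline composition.

    ``transform`` maps a (n_trials, n_voxels, n_scans) stack to the
    (n_trials, n_voxels) peak-feature matrix. Stateless; ``fit`` only records
    the input scan count.
    """

    def __init__(self, onset_index: int = 0):
        self.onset_index = onset_index

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError(f"expected (trials, voxels, scans) stack, got ndim={X.ndim}")
        if X.shape[-1] < self.onset_index + PEAK_OFFSET + 1:
            raise ValueError(
                f"{X.shape[-1]} scans cannot contain the 4th post-onset scan"
            )
        self.n_scans_ = X.shape[-1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        return extract_features(X, self.onset_index)
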
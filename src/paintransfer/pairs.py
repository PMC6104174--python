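"""Canonical ordering of ordered (training, test) individual pairs.

The pair enumeration is training-major, test-minor, diagonal excluded:
for n individuals the k-th row of the pair index is
(s = k // (n-1), t skipping s). This fixed order makes pair tables joinable
across the error, difference, and correlation stages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def pair_index_frame(ids: list[str]) -> pd.DataFrame:
    """DataFrame with one row per ordered between-individual pair.

    Columns: ``row`` (0..n(n-1)-1), ``train_idx``, ``test_idx``,
    ``train_id``, ``test_id``.
    """
    n = len(ids)
    s_idx, t_idx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    keep = s_idx != t_idx
    s_idx, t_idx = s_idx[keep], t_idx[keep]
    return pd.DataFrame(
        {
            "row": np.arange(s_idx.size),
            "train_idx": s_idx,
            "test_idx": t_idx,
            "train_id": [ids[i] for i in s_idx],
            "test_id": [ids[i] for i in t_idx],
        }
    )


def flatten_offdiag(matrix: np.ndarray, pair_index: pd.DataFrame) -> np.ndarray:
    """Off-diagonal cells of a (train, test)-indexed square (or square-by-voxel)
    array, in pair_index order."""
    return matrix[pair_index["train_idx"].to_numpy(), pair_index["test_idx"].to_numpy()]
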
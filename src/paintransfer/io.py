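"""File formats: ratings tables (CSV), NIfTI volumes, matrices, configs.

Conventions, asserted at every read:
* voxel coordinates are 0-based C-order indices into the grid;
* all volumes of a run share one affine (3 mm isotropic, identity rotation);
* ratings tables are comma-delimited with header ``trial,level,rating`` and
  ratings must lie on the 0-10 scale.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .config import CohortConfig, PipelineConfig
from .exceptions import ConfigurationError
from .plsr import PLSRModel
from .simulate import IndividualDataset

AFFINE = np.diag([3.0, 3.0, 3.0, 1.0])


# -- tabular -----------------------------------------------------------------

def write_ratings_table(dataset: IndividualDataset, path) -> None:
    pd.DataFrame(
        {
            "trial": np.arange(dataset.n_trials),
            "level": dataset.energy_levels,
            "rating": dataset.ratings,
        }
    ).to_csv(path, index=False)


def read_ratings_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"trial", "level", "rating"} - set(df.columns)
    if missing:
        raise ConfigurationError(f"{path}: missing columns {sorted(missing)}")
    bad = df.index[(df["rating"] < 0) | (df["rating"] > 10)]
    if len(bad):
        raise ConfigurationError(
            f"{path}: rating outside [0, 10] at line {int(bad[0]) + 2}"
        )
    return df


def write_matrix(matrix: np.ndarray, ids: list[str], path) -> None:
    """Square pair matrix as CSV with individual-id row/column labels."""
    pd.DataFrame(matrix, index=ids, columns=ids).to_csv(path)


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ConfigurationError(f"{path}: row and column ids disagree")
    return df.to_numpy(dtype=float), list(df.index)


# -- NIfTI -------------------------------------------------------------------

def save_volume(data: np.ndarray, path, grid_shape=None) -> None:
    """Write a voxel vector (reshaped to the grid) or an already-3D/4D array."""
    data = np.asarray(data)
    if grid_shape is not None:
        data = data.reshape(grid_shape if data.ndim == 1 else (*grid_shape, -1))
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), AFFINE), str(path))


def load_volume(path) -> np.ndarray:
    img = nib.load(str(path))
    if not np.allclose(img.affine, AFFINE):
        raise ConfigurationError(f"{path}: affine differs from the pipeline convention")
    return np.asarray(img.dataobj, dtype=np.float64)


def save_mask(mask: np.ndarray, path) -> None:
    if not mask.any():
        raise ConfigurationError("mask with 0 voxels")
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), AFFINE), str(path))


def load_mask(path) -> np.ndarray:
    mask = np.asarray(nib.load(str(path)).dataobj) > 0
    if not mask.any():
        raise ConfigurationError(f"{path}: mask with 0 voxels")
    return mask


def save_feature_stack(features: np.ndarray, grid_shape, path) -> None:
    """Trial-by-voxel matrix as a 4D stack (x, y, z, trial)."""
    vols = features.T.reshape(*grid_shape, features.shape[0])
    save_volume(vols, path)


def load_feature_stack(path) -> np.ndarray:
    vols = load_volume(path)
    if vols.ndim != 4:
        raise ConfigurationError(f"{path}: expected a 4D trial stack")
    return vols.reshape(-1, vols.shape[-1]).T


# -- models ------------------------------------------------------------------

def save_model(model: PLSRModel, grid_shape, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_volume(model.coefficients, directory / f"{model.individual_id}_coef.nii",
                grid_shape=grid_shape)
    meta = {
        "individual_id": model.individual_id,
        "intercept": model.intercept,
        "n_components": model.n_components,
    }
    (directory / f"{model.individual_id}_model.json").write_text(json.dumps(meta, indent=2))


def load_model(individual_id: str, directory) -> PLSRModel:
    directory = Path(directory)
    coef = load_volume(directory / f"{individual_id}_coef.nii").ravel()
    meta = json.loads((directory / f"{individual_id}_model.json").read_text())
    if meta["individual_id"] != individual_id:
        raise ConfigurationError(f"model sidecar id mismatch for {individual_id}")
    return PLSRModel(coef, meta["intercept"], meta["n_components"], individual_id)


# -- config ------------------------------------------------------------------

def write_config(config: PipelineConfig | CohortConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def read_pipeline_config(path) -> PipelineConfig:
    return PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def read_cohort_config(path) -> CohortConfig:
    return CohortConfig.from_dict(yaml.safe_load(Path(path).read_text()))


# -- manifests ---------------------------------------------------------------

def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(paths: list[Path], out_path) -> dict:
    manifest = {str(Path(p).name): sha256_of(p) for p in sorted(paths)}
    Path(out_path).write_text(json.dumps(manifest, indent=2))
    return manifest
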
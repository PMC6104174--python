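"""Cohort and pipeline configuration.

The synthetic cohort emulates a laser-evoked pain experiment: each individual
receives ``trials_per_level`` stimuli at each of ``n_levels`` energies in random
order and rates every stimulus on a 0-10 visual analog scale, while a
trial-by-voxel matrix of evoked BOLD amplitude features is recorded on a small
3-D grid. Individuals differ in rating sensitivity (mean offset), stimulus
slope, and per-region BOLD amplitude offsets; a set of planted regions carries
the predictive signal.

Region polarities
-----------------
``positive``            voxel weights > 0, consistent across individuals
``negative``            voxel weights < 0, consistent across individuals
``sign_heterogeneous``  per-individual random sign (group mean zero) — the
                        precuneus-like modulator region
``null``                weights exactly zero
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .exceptions import ConfigurationError

POLARITIES = ("positive", "negative", "sign_heterogeneous", "null")


@dataclass(frozen=True)
class Region:
    """A labelled voxel set with one predictive polarity.

    ``voxels`` holds flat (C-order) indices into the voxel grid.
    """

    label: str
    voxels: np.ndarray
    polarity: str

    def __post_init__(self):
        object.__setattr__(self, "voxels", np.asarray(self.voxels, dtype=np.intp))
        if self.polarity not in POLARITIES:
            raise ConfigurationError(
                f"region {self.label!r}: polarity {self.polarity!r} not in {POLARITIES}"
            )


def _block_indices(grid_shape, x0, y0, z0, size=3):
    """Flat indices of a cubic block of side ``size`` at the given corner."""
    ix, iy, iz = np.meshgrid(
        np.arange(x0, x0 + size),
        np.arange(y0, y0 + size),
        np.arange(z0, z0 + size),
        indexing="ij",
    )
    return np.ravel_multi_index(
        (ix.ravel(), iy.ravel(), iz.ravel()), grid_shape
    )


def default_regions(grid_shape=(12, 12, 12)) -> list[Region]:
    """Four disjoint 27-voxel blocks: two positive, one negative, one
    sign-heterogeneous. Everything else on the grid is null background."""
    if any(s < 10 for s in grid_shape):
        raise ConfigurationError(
            f"default regions need a grid of at least 10 per axis, got {grid_shape}"
        )
    return [
        Region("S1-like", _block_indices(grid_shape, 1, 1, 1), "positive"),
        Region("insula-like", _block_indices(grid_shape, 7, 1, 2), "positive"),
        Region("mPFC-like", _block_indices(grid_shape, 1, 7, 5), "negative"),
        Region("precuneus-like", _block_indices(grid_shape, 7, 7, 7), "sign_heterogeneous"),
    ]


@dataclass(frozen=True)
class CohortConfig:
    """Generative settings for one synthetic cohort.

    Defaults follow the emulated study design (30 individuals, 4 stimulus
    energies x 10 trials, ratings on [0, 10]) with heterogeneity magnitudes
    chosen to mirror its behavioral statistics; see docs/methods.md for the
    rationale behind each number.

    Parameters
    ----------
    sensitivity_mean_sd : (mean, sd) of the per-individual rating offset
        alpha_j (units: rating points).
    slope_mean_sd : (mean, sd) of the per-individual stimulus-to-rating slope
        beta_j (rating points per energy level).
    gain_sd : SD of the per-individual, per-region additive BOLD amplitude
        offset delta (fractional signal-change units).
    weight_scale : |w| of planted generative voxel weights (signal-change units
        per rating point).
    rating_noise_sd : trial-wise rating noise SD (rating points).
    bold_noise_sd : trial-wise voxel noise SD (signal-change units).
    adaptation_slope : optional per-trial rating drift (rating points per
        trial index); affects ratings only.
    """

    n_individuals: int = 30
    n_levels: int = 4
    trials_per_level: int = 10
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    regions: Sequence[Region] | None = None
    sensitivity_mean_sd: tuple[float, float] = (1.0, 1.3)
    slope_mean_sd: tuple[float, float] = (1.6, 0.3)
    gain_sd: float = 0.1
    weight_scale: float = 0.03
    rating_noise_sd: float = 1.0
    bold_noise_sd: float = 0.05
    rating_scale: tuple[float, float] = (0.0, 10.0)
    adaptation_slope: float = 0.0
    seed: int = 0

    @property
    def n_trials(self) -> int:
        return self.n_levels * self.trials_per_level

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))

    def resolved_regions(self) -> list[Region]:
        if self.regions is None:
            return default_regions(self.grid_shape)
        return list(self.regions)

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ConfigurationError("n_individuals must be >= 1")
        if self.n_levels < 1 or self.trials_per_level < 1:
            raise ConfigurationError("n_levels and trials_per_level must be >= 1")
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ConfigurationError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        if self.n_voxels == 0:
            raise ConfigurationError("voxel grid is empty")
        lo, hi = self.rating_scale
        if not (lo, hi) == (0.0, 10.0):
            raise ConfigurationError("rating scale is fixed to [0, 10]")
        if self.rating_noise_sd < 0 or self.bold_noise_sd < 0 or self.gain_sd < 0:
            raise ConfigurationError("noise SDs must be non-negative")
        seen = np.zeros(self.n_voxels, dtype=bool)
        for reg in self.resolved_regions():
            v = reg.voxels
            if v.min(initial=0) < 0 or v.max(initial=-1) >= self.n_voxels:
                raise ConfigurationError(f"region {reg.label!r} has voxels outside the grid")
            if seen[v].any():
                raise ConfigurationError(f"region {reg.label!r} overlaps another region")
            seen[v] = True

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "n_individuals": self.n_individuals,
            "n_levels": self.n_levels,
            "trials_per_level": self.trials_per_level,
            "grid_shape": list(self.grid_shape),
            "sensitivity_mean_sd": list(self.sensitivity_mean_sd),
            "slope_mean_sd": list(self.slope_mean_sd),
            "gain_sd": self.gain_sd,
            "weight_scale": self.weight_scale,
            "rating_noise_sd": self.rating_noise_sd,
            "bold_noise_sd": self.bold_noise_sd,
            "rating_scale": list(self.rating_scale),
            "adaptation_slope": self.adaptation_slope,
            "seed": self.seed,
        }
        if self.regions is not None:
            d["regions"] = [
                {"label": r.label, "voxels": r.voxels.tolist(), "polarity": r.polarity}
                for r in self.regions
            ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        for key in ("sensitivity_mean_sd", "slope_mean_sd", "rating_scale"):
            if key in d:
                d[key] = tuple(d[key])
        if "regions" in d and d["regions"] is not None:
            d["regions"] = [
                Region(r["label"], np.asarray(r["voxels"]), r["polarity"])
                for r in d["regions"]
            ]
        return cls(**d)

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run settings: cohort generation, model fitting, analysis."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    r2_threshold: float = 0.95
    max_components: int = 10
    alphas: tuple[float, ...] = (0.05, 1e-20)
    estimator: str = "gaussian"           # Bhattacharyya estimator
    within_mode: str = "resubstitution"   # or "kfold"
    test_variant: str = "welch"           # or "student"
    seed: int | None = None               # overrides cohort.seed when set

    def validate(self) -> None:
        self.resolved_cohort().validate()
        if not (0.0 < self.r2_threshold < 1.0):
            raise ConfigurationError("r2_threshold must lie in (0, 1)")
        if self.max_components < 1:
            raise ConfigurationError("max_components must be >= 1")
        if self.estimator not in ("gaussian", "histogram"):
            raise ConfigurationError(f"unknown estimator {self.estimator!r}")
        if self.within_mode not in ("resubstitution", "kfold"):
            raise ConfigurationError(f"unknown within_mode {self.within_mode!r}")
        if self.test_variant not in ("welch", "student"):
            raise ConfigurationError(f"unknown test_variant {self.test_variant!r}")
        for a in self.alphas:
            if not (0.0 < a < 1.0):
                raise ConfigurationError(f"alpha {a} outside (0, 1)")

    def resolved_cohort(self) -> CohortConfig:
        if self.seed is None:
            return self.cohort
        return self.cohort.with_seed(self.seed)

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort.to_dict(),
            "r2_threshold": self.r2_threshold,
            "max_components": self.max_components,
            "alphas": list(self.alphas),
            "estimator": self.estimator,
            "within_mode": self.within_mode,
            "test_variant": self.test_variant,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        if "alphas" in d:
            d["alphas"] = tuple(d["alphas"])
        return cls(**d)
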
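"""Synthetic evoked-response cohort generator.

Generative model, for individual ``j``, trial ``i`` at energy level ``e``
(levels are 1-based and map to equally spaced latent drives ``d = e``):

    rating      R_i = clip(alpha_j + beta_j * d_i + adaptation_slope * i + eps_i, 0, 10)
    feature     B_iv = w_jv * (R_i - Rbar_j + mu0) + delta_jv + eta_iv

where ``Rbar_j`` is individual j's mean rating and ``mu0`` the cohort-design
anchor level (mean offset + slope x mean drive), so the evoked response
tracks the *stimulus-driven fluctuation* of perceived pain around each
individual's own level. Between-individual differences in feature means are
therefore carried entirely by the amplitude offsets ``delta_jv``, independent
of differences in rating level — the two channels whose separate influence on
transfer error the analysis is designed to measure. (Coupling weights to the
raw rating instead would tie the feature-mean channel to the rating-mean
channel and the two would partially cancel in the prediction bias.)

``w_jv`` is +weight_scale in positive regions, -weight_scale in the negative
region, a per-individual random sign times weight_scale in the
sign-heterogeneous region, and exactly zero elsewhere. ``delta_jv`` is a
per-individual amplitude offset shared by all voxels of a planted region
(regional gain differences) and drawn per voxel in the null background.
Ratings are clipped to the 0-10 visual analog scale after noise.

All randomness derives from ``config.seed`` through named sub-streams, so any
individual's data can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import CohortConfig, Region
from .exceptions import ConfigurationError

# named RNG sub-streams (spawn keys under the cohort seed)
_STIM, _SUBJECT, _SIGNS, _DELTA, _RATING_NOISE, _BOLD_NOISE = range(6)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


@dataclass
class IndividualDataset:
    """One individual's trial-level data: ratings and evoked BOLD features."""

    individual_id: str
    ratings: np.ndarray        # (n_trials,)
    features: np.ndarray       # (n_trials, n_voxels)
    energy_levels: np.ndarray  # (n_trials,) 1-based level indices

    def __post_init__(self):
        self.ratings = np.asarray(self.ratings, dtype=float)
        self.features = np.asarray(self.features, dtype=float)
        self.energy_levels = np.asarray(self.energy_levels)
        if self.ratings.shape[0] != self.features.shape[0]:
            raise ConfigurationError(
                f"{self.individual_id}: {self.ratings.shape[0]} ratings vs "
                f"{self.features.shape[0]} feature rows"
            )
        if self.ratings.size and (self.ratings.min() < 0 or self.ratings.max() > 10):
            raise ConfigurationError(f"{self.individual_id}: ratings outside [0, 10]")

    @property
    def n_trials(self) -> int:
        return self.ratings.shape[0]


@dataclass
class GroundTruth:
    """Generative parameters recorded for recovery tests."""

    true_weight_map: np.ndarray   # (n_individuals, n_voxels)
    alpha: np.ndarray             # (n_individuals,) rating offsets
    beta: np.ndarray              # (n_individuals,) stimulus slopes
    delta: np.ndarray             # (n_individuals, n_voxels) amplitude offsets
    region_labels: np.ndarray     # (n_voxels,) region index, -1 = null background
    regions: list[Region]
    het_signs: np.ndarray         # (n_individuals, n_regions) +/-1 where sign_heterogeneous

    def region_voxels(self, polarity: str) -> np.ndarray:
        """Flat voxel indices of all regions with the given polarity."""
        sets = [r.voxels for r in self.regions if r.polarity == polarity]
        if not sets:
            return np.empty(0, dtype=np.intp)
        return np.concatenate(sets)


def generate_stimulus_sequence(config: CohortConfig, individual_index: int) -> np.ndarray:
    """Randomly ordered energy levels for one individual.

    Returns a permutation with exactly ``trials_per_level`` occurrences of each
    of the 1-based levels ``1..n_levels``; deterministic given the cohort seed
    and the individual index.
    """
    config.validate()
    if not 0 <= individual_index:
        raise ConfigurationError("individual_index must be non-negative")
    rng = _rng(config.seed, _STIM, individual_index)
    levels = np.repeat(np.arange(1, config.n_levels + 1), config.trials_per_level)
    return rng.permutation(levels)


def _draw_individual_params(config: CohortConfig):
    rng = _rng(config.seed, _SUBJECT)
    a_mean, a_sd = config.sensitivity_mean_sd
    b_mean, b_sd = config.slope_mean_sd
    alpha = a_mean + a_sd * rng.standard_normal(config.n_individuals)
    beta = b_mean + b_sd * rng.standard_normal(config.n_individuals)
    return alpha, beta


def _build_weights_and_offsets(config: CohortConfig, regions: list[Region]):
    n, p = config.n_individuals, config.n_voxels
    weights = np.zeros((n, p))
    delta = np.zeros((n, p))
    het_signs = np.zeros((n, len(regions)))
    sign_rng = _rng(config.seed, _SIGNS)
    delta_rng = _rng(config.seed, _DELTA)

    region_labels = np.full(p, -1, dtype=int)
    in_region = np.zeros(p, dtype=bool)
    for k, reg in enumerate(regions):
        region_labels[reg.voxels] = k
        in_region[reg.voxels] = True
        if reg.polarity == "positive":
            weights[:, reg.voxels] = config.weight_scale
        elif reg.polarity == "negative":
            weights[:, reg.voxels] = -config.weight_scale
        elif reg.polarity == "sign_heterogeneous":
            s = sign_rng.choice([-1.0, 1.0], size=n)
            het_signs[:, k] = s
            weights[:, reg.voxels] = s[:, None] * config.weight_scale
        # "null": weights stay exactly zero
        # regional amplitude offset, shared across the region's voxels
        delta[:, reg.voxels] = (config.gain_sd * delta_rng.standard_normal(n))[:, None]
    # background voxels: independent per-voxel offsets at the same scale
    n_bg = int((~in_region).sum())
    if n_bg:
        delta[:, ~in_region] = config.gain_sd * delta_rng.standard_normal((n, n_bg))
    return weights, delta, region_labels, het_signs


def generate_cohort(config: CohortConfig) -> tuple[list[IndividualDataset], GroundTruth]:
    """Draw a full cohort and record its generative ground truth."""
    config.validate()
    regions = config.resolved_regions()
    alpha, beta = _draw_individual_params(config)
    weights, delta, region_labels, het_signs = _build_weights_and_offsets(config, regions)

    lo, hi = config.rating_scale
    datasets = []
    for j in range(config.n_individuals):
        levels = generate_stimulus_sequence(config, j)
        drive = levels.astype(float)
        eps = _rng(config.seed, _RATING_NOISE, j).standard_normal(config.n_trials)
        raw = (
            alpha[j]
            + beta[j] * drive
            + config.adaptation_slope * np.arange(config.n_trials)
            + config.rating_noise_sd * eps
        )
        ratings = np.clip(raw, lo, hi)
        eta = _rng(config.seed, _BOLD_NOISE, j).standard_normal(
            (config.n_trials, config.n_voxels)
        )
        # anchor: the rating level implied by the cohort-design means, so the
        # evoked drive is the within-individual fluctuation around a common level
        mu0 = config.sensitivity_mean_sd[0] \
            + config.slope_mean_sd[0] * (config.n_levels + 1) / 2.0
        drive_signal = ratings - ratings.mean() + mu0
        features = drive_signal[:, None] * weights[j][None, :] + delta[j][None, :] \
            + config.bold_noise_sd * eta
        datasets.append(
            IndividualDataset(f"sub-{j:02d}", ratings, features, levels)
        )

    truth = GroundTruth(weights, alpha, beta, delta, region_labels, regions, het_signs)
    return datasets, truth


# -- trial-level scan series -------------------------------------------------

#: canonical evoked-response shape: zero at onset, unique peak at the 4th
#: post-onset scan, smooth decay afterwards
def _response_profile(scans_per_trial: int) -> np.ndarray:
    k = np.arange(scans_per_trial, dtype=float)
    return (k / 4.0) ** 2 * np.exp(2.0 - k / 2.0)


@dataclass
class TimecourseCohort:
    """Per-trial per-voxel scan series for a whole cohort.

    ``series[j]`` has shape (n_trials, n_voxels, scans_per_trial); the stimulus
    onset is scan index 0 and the per-trial response extremum falls on scan 4.
    Applying the features module (baseline-normalize, take the 4th post-onset
    scan) recovers exactly the cohort's feature matrices.
    """

    series: list[np.ndarray]
    onset_index: int
    baseline: float
    datasets: list[IndividualDataset]
    ground_truth: GroundTruth


def generate_trial_timecourses(
    config: CohortConfig, scans_per_trial: int = 8, baseline: float = 100.0
) -> TimecourseCohort:
    """Expand cohort features into raw-signal scan series.

    Each series is ``baseline * (1 + feature * h(k))`` where the profile
    ``h`` is 0 at onset and peaks (h = 1) at the 4th post-onset scan, so the
    percent-signal-change value at scan 4 equals the feature itself.
    """
    if scans_per_trial < 5:
        raise ConfigurationError(
            f"scans_per_trial must be >= 5 to contain the 4th post-onset scan, "
            f"got {scans_per_trial}"
        )
    if baseline == 0:
        raise ConfigurationError("baseline must be nonzero")
    datasets, truth = generate_cohort(config)
    h = _response_profile(scans_per_trial)
    series = [
        baseline * (1.0 + ds.features[:, :, None] * h[None, None, :])
        for ds in datasets
    ]
    return TimecourseCohort(series, 0, baseline, datasets, truth)
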
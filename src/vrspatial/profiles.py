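"""Occupancy-normalized spatial response profiles and their reliability.

A unit's response profile is the ratio of its smoothed spike-count map to
the smoothed occupancy map over 100 one-centimeter position bins. Traces
are smoothed in time with a 250 ms Gaussian before binning; both maps are
smoothed in space with a 5 cm Gaussian ("window" is taken as the kernel's
standard deviation, truncated at +/-3 sigma with edge renormalization so
constants are preserved at the corridor ends).

Reliability is the fivefold cross-validated fraction of variance in the
smoothed activity explained by the position-based profile; units with
reliability >= 5% pass the responsiveness filter. Folds are contiguous
blocks of trials, which keeps temporally smoothed samples from leaking
across the train/test boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d

from .session import (RUNNING_SPEED_CMS, STATIONARY_SPEED_CMS, SessionBundle,
                      build_trial_table, included_trials)

N_BINS = 100
TEMPORAL_SIGMA_S = 0.25
SPATIAL_SIGMA_CM = 5.0
MIN_OCCUPANCY_S = 1e-9
RELIABILITY_THRESHOLD = 0.05
N_FOLDS = 5


@dataclass
class ResponseProfile:
    """100-bin spatial tuning curve with its source maps."""

    values: np.ndarray          # rate-like; NaN where occupancy ~ 0
    spike_count_map: np.ndarray
    occupancy_map: np.ndarray   # seconds
    n_trials_used: int
    trial_subset: str = "all"


@dataclass
class ReliabilityResult:
    reliability: float
    per_fold: np.ndarray
    responsive: bool


# ---------------------------------------------------------------------------
# Smoothing

def gaussian_smooth(series: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing on a uniform grid with edge renormalization.

    The kernel has standard deviation ``sigma`` (in grid units), is
    truncated at +/-3 sigma, and near the edges the effective weights are
    renormalized to sum to one, so constant inputs come back unchanged.
    Works on 1-D series or on (units, timepoints) stacks along the last axis.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[-1] == 0:
        raise ValueError("cannot smooth an empty series")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    radius = int(np.ceil(3.0 * sigma))
    lags = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (lags / sigma) ** 2)
    kernel /= kernel.sum()
    num = convolve1d(series, kernel, axis=-1, mode="constant", cval=0.0)
    den = convolve1d(np.ones(series.shape[-1]), kernel, mode="constant", cval=0.0)
    return num / den


def smoothed_activity(bundle: SessionBundle) -> np.ndarray:
    """Deconvolved traces smoothed in time with the 250 ms Gaussian."""
    return gaussian_smooth(bundle.activity, TEMPORAL_SIGMA_S * bundle.meta.fs)


# ---------------------------------------------------------------------------
# Timepoint selection

def speed_gate(bundle: SessionBundle) -> np.ndarray:
    """Per-timepoint speed criterion for the session's condition.

    VR and running replay keep timepoints with speed > 1 cm/s; stationary
    replay keeps timepoints with speed < 5 cm/s (passive-viewing rest).
    """
    if bundle.meta.condition == "replay" and bundle.meta.replay_mode == "stationary":
        return bundle.speed < STATIONARY_SPEED_CMS
    return bundle.speed > RUNNING_SPEED_CMS


def resolve_trials(bundle: SessionBundle, trial_subset) -> np.ndarray:
    """Map a subset label (odd|even|all) or an explicit id list to trial ids.

    Odd/even parity is taken on the 1-based trial id; timed-out trials are
    always removed first.
    """
    kept = included_trials(build_trial_table(bundle))
    if isinstance(trial_subset, str):
        if trial_subset == "all":
            return kept
        if trial_subset == "odd":
            return kept[kept % 2 == 1]
        if trial_subset == "even":
            return kept[kept % 2 == 0]
        raise ValueError(f"unknown trial subset: {trial_subset!r}")
    requested = np.asarray(trial_subset, dtype=int)
    return kept[np.isin(kept, requested)]


def kept_mask(bundle: SessionBundle, trial_ids: np.ndarray) -> np.ndarray:
    """Timepoints with valid position, passing the speed gate, in the trials."""
    mask = bundle.valid & speed_gate(bundle)
    mask &= np.isin(bundle.trial_id, np.asarray(trial_ids, dtype=float))
    return mask


def position_bins(position: np.ndarray) -> np.ndarray:
    """0-based 1 cm bins, half-open [i, i+1); exactly 100 cm maps to bin 99."""
    return np.minimum(np.floor(position).astype(int), N_BINS - 1)


# ---------------------------------------------------------------------------
# Profiles

def profiles_from_samples(positions: np.ndarray, activity: np.ndarray,
                          dt: float, n_trials: int,
                          subset_label: str = "all") -> list[ResponseProfile]:
    """Bin, smooth, and normalize kept samples into per-unit profiles.

    ``activity`` is (units, kept timepoints) of temporally smoothed traces
    aligned with ``positions``.
    """
    if positions.size == 0:
        raise ValueError("no usable samples")
    activity = np.atleast_2d(activity)
    bins = position_bins(positions)
    occupancy = np.bincount(bins, minlength=N_BINS) * dt
    spike_counts = np.stack([
        np.bincount(bins, weights=row, minlength=N_BINS) * dt
        for row in activity])
    occ_s = gaussian_smooth(occupancy, SPATIAL_SIGMA_CM)
    spk_s = gaussian_smooth(spike_counts, SPATIAL_SIGMA_CM)
    defined = occ_s > MIN_OCCUPANCY_S
    values = np.full(spk_s.shape, np.nan)
    values[:, defined] = spk_s[:, defined] / occ_s[defined]
    return [ResponseProfile(values=values[u], spike_count_map=spk_s[u],
                            occupancy_map=occ_s, n_trials_used=n_trials,
                            trial_subset=subset_label)
            for u in range(activity.shape[0])]


def compute_profiles(bundle: SessionBundle, trial_subset="all",
                     smoothed: np.ndarray | None = None) -> list[ResponseProfile]:
    """Response profiles for every unit over the given trial subset."""
    trials = resolve_trials(bundle, trial_subset)
    mask = kept_mask(bundle, trials)
    if not mask.any():
        raise ValueError("no usable samples")
    if smoothed is None:
        smoothed = smoothed_activity(bundle)
    label = trial_subset if isinstance(trial_subset, str) else "custom"
    return profiles_from_samples(bundle.position[mask], smoothed[:, mask],
                                 bundle.dt, len(trials), label)


def compute_profile(bundle: SessionBundle, unit: int,
                    trial_subset="all") -> ResponseProfile:
    """Response profile of one unit (see :func:`compute_profiles`)."""
    trials = resolve_trials(bundle, trial_subset)
    mask = kept_mask(bundle, trials)
    if not mask.any():
        raise ValueError("no usable samples")
    smoothed = gaussian_smooth(bundle.activity[unit],
                               TEMPORAL_SIGMA_S * bundle.meta.fs)
    label = trial_subset if isinstance(trial_subset, str) else "custom"
    return profiles_from_samples(bundle.position[mask], smoothed[mask],
                                 bundle.dt, len(trials), label)[0]


def predict_trace(profile: ResponseProfile, positions: np.ndarray,
                  fill_value: float = np.nan) -> np.ndarray:
    """Predicted activity: profile value at each timepoint's position bin.

    Bins with undefined profile values take ``fill_value`` (the training-set
    mean in cross-validation).
    """
    pred = profile.values[position_bins(positions)]
    return np.where(np.isnan(pred), fill_value, pred)


# ---------------------------------------------------------------------------
# Reliability (cross-validated variance explained)

def trial_folds(trial_ids: np.ndarray, n_folds: int = N_FOLDS) -> list[np.ndarray]:
    """Contiguous blocks of trials used for every cross-validation here."""
    return [f for f in np.array_split(np.asarray(trial_ids), n_folds) if f.size]


def reliability_all(bundle: SessionBundle,
                    smoothed: np.ndarray | None = None) -> list[ReliabilityResult]:
    """Fivefold cross-validated reliability of every unit's profile.

    Per fold, the held-out smoothed activity y is predicted by the profile
    estimated from the training folds; the fold's score is
    ``1 - sum((y - y')^2) / sum((y - mu)^2)`` with mu the training-fold mean.
    A degenerate denominator scores 0.
    """
    trials = resolve_trials(bundle, "all")
    if trials.size < N_FOLDS:
        raise ValueError(f"need at least {N_FOLDS} non-timed-out trials")
    if smoothed is None:
        smoothed = smoothed_activity(bundle)
    folds = trial_folds(trials)
    n_units = bundle.n_units
    per_fold = np.zeros((n_units, len(folds)))
    for k, test_trials in enumerate(folds):
        train_trials = np.setdiff1d(trials, test_trials)
        train_mask = kept_mask(bundle, train_trials)
        test_mask = kept_mask(bundle, test_trials)
        if not train_mask.any() or not test_mask.any():
            continue  # fold contributes 0
        train_profiles = profiles_from_samples(
            bundle.position[train_mask], smoothed[:, train_mask],
            bundle.dt, len(train_trials), f"fold-{k}")
        mu = smoothed[:, train_mask].mean(axis=1)
        y = smoothed[:, test_mask]
        test_pos = bundle.position[test_mask]
        for u in range(n_units):
            y_hat = predict_trace(train_profiles[u], test_pos, fill_value=mu[u])
            denom = np.sum((y[u] - mu[u]) ** 2)
            if denom <= 0:
                per_fold[u, k] = 0.0
            else:
                per_fold[u, k] = 1.0 - np.sum((y[u] - y_hat) ** 2) / denom
    rel = per_fold.mean(axis=1)
    return [ReliabilityResult(reliability=float(rel[u]), per_fold=per_fold[u],
                              responsive=bool(rel[u] >= RELIABILITY_THRESHOLD))
            for u in range(n_units)]


def reliability(bundle: SessionBundle, unit: int) -> ReliabilityResult:
    """Reliability of a single unit (see :func:`reliability_all`)."""
    sub = SessionBundle(
        time=bundle.time, position=bundle.position, speed=bundle.speed,
        trial_id=bundle.trial_id, activity=bundle.activity[unit:unit + 1],
        meta=bundle.meta, reward_times=bundle.reward_times,
        pupil_size=bundle.pupil_size, pupil_x=bundle.pupil_x,
        pupil_y=bundle.pupil_y)
    return reliability_all(sub)[0]
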
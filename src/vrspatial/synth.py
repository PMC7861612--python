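"""Synthetic VR / replay sessions with known ground-truth spatial modulation.

The generative model mirrors the experimental protocol: a 100 cm corridor
whose landmarks at 20, 40, 60 and 80 cm make the segments [10, 50) and
[50, 90) cm visually identical; trial-structured traversals with 3-5 s
gray inter-trial periods and a 30 s timeout; and per-unit landmark-driven
visual tuning multiplied by a segment-specific spatial gain.

Each unit's expected rate is ``lambda(x) = V(x) * g(x)`` where the visual
template V repeats with period 40 cm inside the matching segments and the
gain g equals ``2a`` on [10, 50), ``2(1-a)`` on [50, 90) and 1 elsewhere,
for a gain parameter ``a`` in [0.5, 1]. The noise-free spatial modulation
index of such a unit is exactly ``2a - 1``: a = 0.5 is a purely visual
unit (SMI 0), a = 1 responds only in the first segment (SMI 1).

Activity is drawn Poisson per sample on the expected event count
``lambda * dt`` and divided by dt, giving a nonnegative rate-like trace
akin to a deconvolved calcium signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .session import (CORRIDOR_LENGTH_CM, TRIAL_TIMEOUT_S, SessionBundle,
                      SessionMeta)

LANDMARK_CENTERS_CM = np.array([20.0, 40.0, 60.0, 80.0])
SEGMENT_A = (10.0, 50.0)   # first visually matching segment
SEGMENT_B = (50.0, 90.0)   # second, identical to the first shifted by +40 cm


@dataclass
class GroundTruthUnit:
    """Generative parameters of one synthetic unit."""

    landmark_amplitudes: tuple[float, float] = (1.0, 0.6)  # grating, plaid
    tuning_width_cm: float = 6.0
    baseline_rate: float = 0.5     # events/s
    peak_rate: float = 8.0         # events/s, scales the landmark bumps
    spatial_gain_a: float = 0.5    # in [0.5, 1]; true SMI = 2a - 1

    @property
    def true_smi(self) -> float:
        return 2.0 * self.spatial_gain_a - 1.0

    def validate(self) -> "GroundTruthUnit":
        if not (0.0 <= self.spatial_gain_a <= 1.0):
            raise ValueError("spatial_gain_a must lie in [0, 1]")
        if self.tuning_width_cm <= 0 or self.peak_rate <= 0 or self.baseline_rate < 0:
            raise ValueError("rates must be nonnegative and widths positive")
        if any(a < 0 for a in self.landmark_amplitudes):
            raise ValueError("landmark amplitudes must be nonnegative")
        return self


@dataclass
class SimConfig:
    """Session-level simulation parameters.

    Corridor geometry and trial rules follow the experimental protocol;
    behavioral distributions (speed process, pauses, pupil) are not
    constrained by it and use the stated defaults.
    """

    n_units: int = 50
    n_trials: int = 60
    fs: float = 7.5                     # Hz (two-photon per-plane rate)
    mean_speed_cms: float = 15.0
    speed_relaxation_s: float = 2.0
    speed_sd_cms: float = 5.0
    intertrial_range_s: tuple[float, float] = (3.0, 5.0)
    replay_attenuation: float = 1.0     # rho: a' = 0.5 + rho * (a - 0.5)
    replay_activity_scale: float = 0.5  # rate scale in stationary replay
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.n_trials < 1:
            raise ValueError("at least one trial is required")
        if self.fs <= 0 or self.mean_speed_cms <= 0:
            raise ValueError("fs and mean speed must be positive")
        if not (0.0 <= self.replay_attenuation <= 1.0):
            raise ValueError("replay_attenuation must lie in [0, 1]")
        return self


# ---------------------------------------------------------------------------
# Visual template and expected rate

def make_visual_template(unit: GroundTruthUnit):
    """Return V(x): baseline plus Gaussian landmark bumps, periodic over 40 cm.

    Landmarks alternate grating-plaid-grating-plaid at 20/40/60/80 cm, so
    amplitudes repeat with period 40 cm. The bumps are placed on the full
    40 cm-periodic landmark lattice (gratings at 20 + 40n cm, plaids at
    40 + 40n cm), making V(x) = V(x + 40) hold to machine precision: the
    corridor's two halves are exactly visually indistinguishable, as they
    are on the physical corridor walls.
    """
    unit.validate()
    # lattice wide enough that truncation error is far below 1e-12
    grating_centers = 20.0 + 40.0 * np.arange(-3, 5)
    plaid_centers = 40.0 + 40.0 * np.arange(-3, 5)
    amp0, amp1 = (a * unit.peak_rate for a in unit.landmark_amplitudes)

    def template(x):
        x = np.asarray(x, dtype=float)
        v = np.full(x.shape, unit.baseline_rate)
        two_s2 = 2.0 * unit.tuning_width_cm ** 2
        for c in grating_centers:
            v = v + amp0 * np.exp(-((x - c) ** 2) / two_s2)
        for c in plaid_centers:
            v = v + amp1 * np.exp(-((x - c) ** 2) / two_s2)
        return v

    return template


def segment_gain(x, a: float):
    """Piecewise-constant spatial gain: 2a on [10,50), 2(1-a) on [50,90), 1 elsewhere."""
    x = np.asarray(x, dtype=float)
    g = np.ones(x.shape)
    g[(x >= SEGMENT_A[0]) & (x < SEGMENT_A[1])] = 2.0 * a
    g[(x >= SEGMENT_B[0]) & (x < SEGMENT_B[1])] = 2.0 * (1.0 - a)
    return g


def expected_rate(unit: GroundTruthUnit, x) -> np.ndarray:
    """Noise-free expected rate lambda(x) * g(x) for valid positions x."""
    return make_visual_template(unit)(x) * segment_gain(x, unit.spatial_gain_a)


def default_units(n: int, gain_a, rng: np.random.Generator) -> list[GroundTruthUnit]:
    """n units with randomized landmark amplitudes and a common or per-unit gain."""
    gains = np.broadcast_to(np.asarray(gain_a, dtype=float), (n,))
    units = []
    for i in range(n):
        amp0 = rng.uniform(0.5, 1.5)
        amp1 = rng.uniform(0.2, 1.0)
        units.append(GroundTruthUnit(
            landmark_amplitudes=(amp0, amp1),
            tuning_width_cm=rng.uniform(4.0, 8.0),
            baseline_rate=rng.uniform(0.2, 0.8),
            peak_rate=rng.uniform(5.0, 12.0),
            spatial_gain_a=float(gains[i]),
        ).validate())
    return units


# ---------------------------------------------------------------------------
# Behavior

def _ou_speed(n: int, dt: float, cfg: SimConfig, rng: np.random.Generator,
              start: float | None = None) -> np.ndarray:
    """Rectified Ornstein-Uhlenbeck running speed sampled at fs."""
    tau = cfg.speed_relaxation_s
    mu = cfg.mean_speed_cms
    sd = cfg.speed_sd_cms
    s = np.empty(n)
    s[0] = mu if start is None else start
    noise = rng.standard_normal(n) * sd * np.sqrt(2.0 * dt / tau)
    for i in range(1, n):
        s[i] = s[i - 1] + (mu - s[i - 1]) * dt / tau + noise[i]
    return np.maximum(s, 0.0)


def _simulate_behavior(cfg: SimConfig, rng: np.random.Generator):
    """Trial-structured trajectory: position, speed, trial ids, reward times."""
    dt = 1.0 / cfg.fs
    max_trial_samples = int(np.ceil((TRIAL_TIMEOUT_S + 5.0) / dt))
    pos_parts, spd_parts, tid_parts = [], [], []
    reward_times = []
    t_cursor = 0.0
    last_speed = cfg.mean_speed_cms
    for trial in range(1, cfg.n_trials + 1):
        speed = _ou_speed(max_trial_samples, dt, cfg, rng, start=last_speed)
        pos = np.cumsum(speed * dt)  # position at the *end* of each sample
        crossed = np.nonzero(pos >= CORRIDOR_LENGTH_CM)[0]
        end = min(crossed[0] if crossed.size else max_trial_samples - 1,
                  int(np.floor(TRIAL_TIMEOUT_S / dt)))
        n_t = end + 1
        pos = np.minimum(pos[:n_t], CORRIDOR_LENGTH_CM)
        speed = speed[:n_t]
        last_speed = speed[-1]
        pos_parts.append(pos)
        spd_parts.append(speed)
        tid_parts.append(np.full(n_t, float(trial)))
        t_cursor += n_t * dt
        if pos[-1] >= CORRIDOR_LENGTH_CM - 1e-9:
            reward_times.append(t_cursor - dt)
        if trial < cfg.n_trials:
            gray_s = rng.uniform(*cfg.intertrial_range_s)
            n_g = max(1, int(round(gray_s / dt)))
            gray_speed = _ou_speed(n_g, dt, cfg, rng, start=last_speed)
            last_speed = gray_speed[-1]
            pos_parts.append(np.full(n_g, np.nan))
            spd_parts.append(gray_speed)
            tid_parts.append(np.full(n_g, np.nan))
            t_cursor += n_g * dt
    position = np.concatenate(pos_parts)
    speed = np.concatenate(spd_parts)
    trial_id = np.concatenate(tid_parts)
    time = np.arange(position.size) * dt
    return time, position, speed, trial_id, np.array(reward_times)


def _pupil(speed: np.ndarray, dt: float, rng: np.random.Generator):
    """Pupil covariates: smoothed noise weakly correlated with running speed."""
    n = speed.size
    k = np.exp(-0.5 * (np.arange(-15, 16) / 5.0) ** 2)
    k /= k.sum()

    def smooth_noise(scale):
        return np.convolve(rng.standard_normal(n) * scale, k, mode="same")

    s_norm = (speed - speed.mean()) / (speed.std() + 1e-12)
    size = 1.0 + 0.3 * s_norm + smooth_noise(1.0)
    return size, smooth_noise(1.0), smooth_noise(1.0)


# ---------------------------------------------------------------------------
# Activity and sessions

def _draw_activity(units: list[GroundTruthUnit], position: np.ndarray,
                   dt: float, rng: np.random.Generator,
                   gains: np.ndarray | None = None,
                   rate_scale: float = 1.0) -> np.ndarray:
    """Poisson rate-like traces; gray-screen timepoints see baseline only."""
    n_t = position.size
    valid = ~np.isnan(position)
    activity = np.empty((len(units), n_t))
    for i, unit in enumerate(units):
        a = unit.spatial_gain_a if gains is None else float(gains[i])
        lam = np.full(n_t, unit.baseline_rate)
        lam[valid] = make_visual_template(unit)(position[valid]) * \
            segment_gain(position[valid], a)
        lam = lam * rate_scale
        activity[i] = rng.poisson(lam * dt) / dt
    return activity


def simulate_session(cfg: SimConfig, units: list[GroundTruthUnit] | None = None,
                     session_id: str = "sim", area: str = "V1",
                     gain_a=0.5) -> tuple[SessionBundle, list[GroundTruthUnit]]:
    """Simulate one closed-loop VR session; deterministic under cfg.seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    if units is None:
        units = default_units(cfg.n_units, gain_a, rng)
    time, position, speed, trial_id, rewards = _simulate_behavior(cfg, rng)
    activity = _draw_activity(units, position, 1.0 / cfg.fs, rng)
    pupil_size, pupil_x, pupil_y = _pupil(speed, 1.0 / cfg.fs, rng)
    bundle = SessionBundle(
        time=time, position=position, speed=speed, trial_id=trial_id,
        activity=activity, reward_times=rewards,
        pupil_size=pupil_size, pupil_x=pupil_x, pupil_y=pupil_y,
        meta=SessionMeta(fs=cfg.fs, area=area, condition="vr",
                         session_id=session_id),
    ).validate()
    return bundle, units


def simulate_replay(vr: SessionBundle, units: list[GroundTruthUnit],
                    mode: str, cfg: SimConfig,
                    seed: int | None = None) -> tuple[SessionBundle, list[GroundTruthUnit]]:
    """Open-loop playback of a VR session's visual sequence.

    The stimulus position trace is copied from the VR session; treadmill
    speed is generated independently (a fresh OU process when ``mode`` is
    "running", near-zero jitter when "stationary"). Activity is regenerated
    with the spatial gain attenuated toward 0.5 by ``cfg.replay_attenuation``
    (a' = 0.5 + rho * (a - 0.5)) and, in stationary replay, rates scaled by
    ``cfg.replay_activity_scale``.
    """
    if mode not in ("running", "stationary"):
        raise ValueError(f"unknown replay mode: {mode!r}")
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 7_654_321 if seed is None else seed)
    n = vr.n_timepoints
    dt = vr.dt
    if mode == "running":
        speed = _ou_speed(n, dt, cfg, rng)
        rate_scale = 1.0
    else:
        speed = np.abs(rng.normal(0.0, 0.25, n))
        speed = np.minimum(speed, 0.99)  # stays below the 1 cm/s running gate
        rate_scale = cfg.replay_activity_scale

    rho = cfg.replay_attenuation
    gains = np.array([0.5 + rho * (u.spatial_gain_a - 0.5) for u in units])
    activity = _draw_activity(units, vr.position, dt, rng,
                              gains=gains, rate_scale=rate_scale)
    pupil_size, pupil_x, pupil_y = _pupil(speed, dt, rng)
    truth = [replace(u, spatial_gain_a=float(g)) for u, g in zip(units, gains)]
    bundle = SessionBundle(
        time=vr.time.copy(), position=vr.position.copy(), speed=speed,
        trial_id=vr.trial_id.copy(), activity=activity,
        reward_times=vr.reward_times.copy(),
        pupil_size=pupil_size, pupil_x=pupil_x, pupil_y=pupil_y,
        meta=SessionMeta(fs=vr.meta.fs, area=vr.meta.area, condition="replay",
                         mouse=vr.meta.mouse, day=vr.meta.day,
                         session_id=f"{vr.meta.session_id}-replay-{mode}",
                         source_session=vr.meta.session_id, replay_mode=mode),
    ).validate()
    return bundle, truth


def ground_truth_frame(units: list[GroundTruthUnit]):
    """Tabulate ground truth (unit_id, a, true_smi, amplitudes, rates)."""
    import pandas as pd
    return pd.DataFrame({
        "unit_id": np.arange(len(units)),
        "a": [u.spatial_gain_a for u in units],
        "true_smi": [u.true_smi for u in units],
        "amp_grating": [u.landmark_amplitudes[0] for u in units],
        "amp_plaid": [u.landmark_amplitudes[1] for u in units],
        "baseline_rate": [u.baseline_rate for u in units],
        "peak_rate": [u.peak_rate for u in units],
        "tuning_width_cm": [u.tuning_width_cm for u in units],
    })
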
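import numpy as np
import pytest

from vrspatial import SessionBundle, SessionMeta, SimConfig, simulate_session


def make_bundle(position, speed, trial_id, activity, fs=7.5, condition="vr",
                replay_mode=None, rewards=(), pupil=False):
    """Hand-built session from explicit per-timepoint arrays."""
    position = np.asarray(position, dtype=float)
    n = position.size
    time = np.arange(n) / fs
    kwargs = {}
    if pupil:
        kwargs = dict(pupil_size=np.linspace(0.5, 1.5, n),
                      pupil_x=np.sin(np.arange(n)),
                      pupil_y=np.cos(np.arange(n)))
    return SessionBundle(
        time=time, position=position,
        speed=np.asarray(speed, dtype=float),
        trial_id=np.asarray(trial_id, dtype=float),
        activity=np.atleast_2d(np.asarray(activity, dtype=float)),
        reward_times=np.asarray(rewards, dtype=float),
        meta=SessionMeta(fs=fs, condition=condition, replay_mode=replay_mode),
        **kwargs,
    ).validate()


def corridor_traversals(n_trials, fs=7.5, speed_cms=20.0, gray_samples=10):
    """Constant-speed trajectory: position, speed, trial_id arrays."""
    dt = 1.0 / fs
    pos_parts, spd_parts, tid_parts = [], [], []
    for t in range(1, n_trials + 1):
        pos = np.arange(1, int(np.ceil(100.0 / (speed_cms * dt))) + 1) * speed_cms * dt
        pos = np.minimum(pos, 100.0)
        pos_parts.append(pos)
        spd_parts.append(np.full(pos.size, speed_cms))
        tid_parts.append(np.full(pos.size, float(t)))
        if t < n_trials:
            pos_parts.append(np.full(gray_samples, np.nan))
            spd_parts.append(np.full(gray_samples, speed_cms))
            tid_parts.append(np.full(gray_samples, np.nan))
    return (np.concatenate(pos_parts), np.concatenate(spd_parts),
            np.concatenate(tid_parts))


@pytest.fixture(scope="session")
def small_session():
    """A modest simulated VR session shared by read-only tests."""
    cfg = SimConfig(n_units=8, n_trials=30, seed=42)
    bundle, units = simulate_session(cfg, gain_a=0.75)
    return bundle, units, cfg


# ---------------------------------------------------------------------------
# Independent loop-based oracles

def smooth_oracle(series, sigma):
    """Edge-renormalized Gaussian smoothing by explicit loops."""
    series = np.asarray(series, dtype=float)
    n = series.size
    radius = int(np.ceil(3 * sigma))
    out = np.zeros(n)
    for i in range(n):
        wsum = 0.0
        acc = 0.0
        for j in range(max(0, i - radius), min(n, i + radius + 1)):
            w = np.exp(-0.5 * ((i - j) / sigma) ** 2)
            acc += w * series[j]
            wsum += w
        out[i] = acc / wsum
    return out


def profile_oracle(bundle, unit, trial_ids):
    """Brute-force response profile: loops over timepoints and bins."""
    fs = bundle.meta.fs
    dt = 1.0 / fs
    trace = smooth_oracle(bundle.activity[unit], 0.25 * fs)
    if bundle.meta.condition == "replay" and bundle.meta.replay_mode == "stationary":
        gate = bundle.speed < 5.0
    else:
        gate = bundle.speed > 1.0
    spike = np.zeros(100)
    occ = np.zeros(100)
    for t in range(bundle.n_timepoints):
        if np.isnan(bundle.position[t]) or not gate[t]:
            continue
        if bundle.trial_id[t] not in trial_ids:
            continue
        b = min(int(np.floor(bundle.position[t])), 99)
        spike[b] += trace[t] * dt
        occ[b] += dt
    spike_s = smooth_oracle(spike, 5.0)
    occ_s = smooth_oracle(occ, 5.0)
    values = np.full(100, np.nan)
    ok = occ_s > 1e-9
    values[ok] = spike_s[ok] / occ_s[ok]
    return values, spike_s, occ_s


def ridge_oracle(X, y, lam):
    """Ridge coefficients by explicit matrix inversion."""
    X = np.asarray(X, dtype=float)
    return np.linalg.inv(X.T @ X + lam * np.eye(X.shape[1])) @ X.T @ y


def random_session(rng, max_timepoints=500, n_units=2):
    """Random small session for property tests: irregular trials and gaps."""
    n_trials = rng.integers(2, 6)
    fs = 7.5
    parts_p, parts_s, parts_t = [], [], []
    for t in range(1, n_trials + 1):
        n = int(rng.integers(10, 40))
        pos = np.sort(rng.uniform(0, 100, n))
        parts_p.append(pos)
        parts_s.append(rng.uniform(0, 30, n))
        parts_t.append(np.full(n, float(t)))
        if t < n_trials:
            g = int(rng.integers(1, 8))
            parts_p.append(np.full(g, np.nan))
            parts_s.append(rng.uniform(0, 30, g))
            parts_t.append(np.full(g, np.nan))
    position = np.concatenate(parts_p)[:max_timepoints]
    speed = np.concatenate(parts_s)[:max_timepoints]
    trial_id = np.concatenate(parts_t)[:max_timepoints]
    activity = rng.exponential(2.0, (n_units, position.size))
    return make_bundle(position, speed, trial_id, activity, fs=fs)
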
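"""Session data model: behavioral time series plus deconvolved activity.

A session is one recording in the 100 cm virtual corridor, either in
closed loop ("vr": running updates the scene) or open loop ("replay":
a previous session's visual sequence is played back). Position is the
corridor position driving the screen; during inter-trial gray screens
it is marked invalid (NaN) and those timepoints are excluded from all
spatial computations. Replay bundles keep the *stimulus* position in
``position`` and the animal's own treadmill speed in ``speed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

CORRIDOR_LENGTH_CM = 100.0
TRIAL_TIMEOUT_S = 30.0
RUNNING_SPEED_CMS = 1.0
STATIONARY_SPEED_CMS = 5.0
MIN_REPLAY_TRIALS = 10

AREAS = ("LGN", "V1", "LM", "AL", "RL", "A", "AM", "PM")


class SessionValidationError(ValueError):
    """A session bundle violates one of its invariants."""


@dataclass
class SessionMeta:
    fs: float
    area: str = "V1"
    condition: str = "vr"  # "vr" | "replay"
    mouse: str = "synthetic"
    day: int = 1
    session_id: str = "session"
    source_session: str | None = None  # VR session a replay was taken from
    replay_mode: str | None = None  # "running" | "stationary" for replays


@dataclass
class SessionBundle:
    """One session: uniform time base, behavior, and units x timepoints activity."""

    time: np.ndarray           # seconds, uniformly sampled at meta.fs
    position: np.ndarray       # cm in [0, 100]; NaN during inter-trial gray
    speed: np.ndarray          # cm/s, >= 0
    trial_id: np.ndarray       # float array; integer >= 1 in-corridor, NaN in gray
    activity: np.ndarray       # (n_units, n_timepoints), nonnegative deconvolved rates
    meta: SessionMeta
    reward_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    pupil_size: np.ndarray | None = None
    pupil_x: np.ndarray | None = None
    pupil_y: np.ndarray | None = None
    unit_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        self.trial_id = np.asarray(self.trial_id, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        self.reward_times = np.asarray(self.reward_times, dtype=float)
        if self.unit_ids is None:
            self.unit_ids = np.arange(self.activity.shape[0])

    @property
    def n_units(self) -> int:
        return self.activity.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.time.size

    @property
    def dt(self) -> float:
        return 1.0 / self.meta.fs

    @property
    def valid(self) -> np.ndarray:
        """Timepoints with a valid corridor position (in-trial, not gray screen)."""
        return ~np.isnan(self.position)

    def validate(self) -> "SessionBundle":
        n = self.n_timepoints
        for name, arr in (("position", self.position), ("speed", self.speed),
                          ("trial_id", self.trial_id)):
            if arr.shape != (n,):
                raise SessionValidationError(
                    f"{name} has shape {arr.shape}, expected ({n},)")
        if self.activity.ndim != 2 or self.activity.shape[1] != n:
            raise SessionValidationError(
                f"activity has shape {self.activity.shape}, expected (n_units, {n})")
        if n >= 2:
            diffs = np.diff(self.time)
            if np.any(diffs <= 0):
                raise SessionValidationError("time is not strictly increasing")
            if np.max(np.abs(diffs - self.dt)) > 1e-6 * self.dt:
                raise SessionValidationError(
                    "time is not uniformly sampled at fs within tolerance")
        if np.any(self.activity < 0):
            raise SessionValidationError("activity contains negative values")
        pos = self.position[self.valid]
        if pos.size and (pos.min() < 0 or pos.max() > CORRIDOR_LENGTH_CM):
            raise SessionValidationError(
                f"position outside [0, {CORRIDOR_LENGTH_CM}] cm: "
                f"range [{pos.min()}, {pos.max()}]")
        if np.any(self.speed < 0):
            raise SessionValidationError("speed contains negative values")
        tid = self.trial_id[self.valid]
        if tid.size:
            if np.any(tid < 1) or np.any(tid != np.round(tid)):
                raise SessionValidationError("trial_id must be integer >= 1")
            if np.any(np.diff(tid) < 0):
                raise SessionValidationError("trial_id decreases over valid timepoints")
        if np.any(self.valid != ~np.isnan(self.trial_id)):
            raise SessionValidationError(
                "position and trial_id validity masks disagree")
        return self


# ---------------------------------------------------------------------------
# Trial table

def build_trial_table(bundle: SessionBundle) -> pd.DataFrame:
    """One row per trial with timeout/running/stationary classification.

    Trials lasting more than 30 s without reaching the corridor end are
    timed out and excluded from every downstream computation. Running /
    stationary flags (speed > 1 cm/s at >= 1 timepoint; speed < 5 cm/s at
    >= 1 timepoint) classify replay trials.
    """
    dt = bundle.dt
    valid = bundle.valid
    rows = []
    tids = bundle.trial_id[valid]
    if tids.size:
        for tid in np.unique(tids).astype(int):
            mask = valid & (bundle.trial_id == tid)
            t = bundle.time[mask]
            sp = bundle.speed[mask]
            pos = bundle.position[mask]
            duration = (t[-1] - t[0]) + dt
            rows.append({
                "trial_id": tid,
                "start_time": t[0],
                "end_time": t[-1],
                "duration_s": duration,
                "timed_out": duration > TRIAL_TIMEOUT_S,
                "reached_end": bool(pos.max() >= CORRIDOR_LENGTH_CM - 1e-9),
                "running_fraction": float(np.mean(sp > RUNNING_SPEED_CMS)),
                "is_running_trial": bool(np.any(sp > RUNNING_SPEED_CMS)),
                "is_stationary_trial": bool(np.any(sp < STATIONARY_SPEED_CMS)),
            })
    table = pd.DataFrame(rows, columns=[
        "trial_id", "start_time", "end_time", "duration_s", "timed_out",
        "reached_end", "running_fraction", "is_running_trial",
        "is_stationary_trial"])
    return table


def included_trials(table: pd.DataFrame) -> np.ndarray:
    """Trial ids that survive the 30 s timeout exclusion, in session order."""
    if table.empty:
        return np.empty(0, dtype=int)
    return table.loc[~table["timed_out"], "trial_id"].to_numpy(dtype=int)


def session_passes_replay_inclusion(table: pd.DataFrame, mode: str) -> bool:
    """True iff >= 10 non-timed-out trials carry the replay mode's flag."""
    if mode not in ("running", "stationary"):
        raise ValueError(f"unknown replay mode: {mode!r}")
    if table.empty:
        return False
    kept = table[~table["timed_out"]]
    col = "is_running_trial" if mode == "running" else "is_stationary_trial"
    return int(kept[col].sum()) >= MIN_REPLAY_TRIALS


# ---------------------------------------------------------------------------
# On-disk format: directory with meta.json + CSVs

_TS_COLS = ["time_s", "position_cm", "speed_cms", "trial_id",
            "pupil_size", "pupil_x", "pupil_y"]


def write_session(bundle: SessionBundle, path: str | Path) -> None:
    """Write a bundle to ``path`` (a directory), losslessly at double precision."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = bundle.meta
    (path / "meta.json").write_text(json.dumps({
        "fs": meta.fs, "area": meta.area, "condition": meta.condition,
        "mouse": meta.mouse, "day": meta.day, "session_id": meta.session_id,
        "source_session": meta.source_session, "replay_mode": meta.replay_mode,
    }, indent=2))

    n = bundle.n_timepoints
    ts = pd.DataFrame({
        "time_s": bundle.time,
        "position_cm": bundle.position,
        "speed_cms": bundle.speed,
        "trial_id": bundle.trial_id,
        "pupil_size": bundle.pupil_size if bundle.pupil_size is not None else np.full(n, np.nan),
        "pupil_x": bundle.pupil_x if bundle.pupil_x is not None else np.full(n, np.nan),
        "pupil_y": bundle.pupil_y if bundle.pupil_y is not None else np.full(n, np.nan),
    })
    # str(float) round-trips exactly in Python 3; NaN -> empty cell
    ts.to_csv(path / "timeseries.csv", index=False)

    act = pd.DataFrame(bundle.activity, columns=[str(i) for i in range(n)])
    act.to_csv(path / "activity.csv", index=False)

    pd.DataFrame({"time_s": bundle.reward_times}).to_csv(
        path / "rewards.csv", index=False)
    pd.DataFrame({"unit_id": bundle.unit_ids,
                  "area": [meta.area] * bundle.n_units}).to_csv(
        path / "units.csv", index=False)


def load_session(path: str | Path) -> SessionBundle:
    """Load and validate a bundle written by :func:`write_session`."""
    path = Path(path)
    meta_file = path / "meta.json"
    if not meta_file.exists():
        raise FileNotFoundError(f"no session bundle at {path}")
    raw = json.loads(meta_file.read_text())
    meta = SessionMeta(
        fs=float(raw["fs"]), area=raw.get("area", "V1"),
        condition=raw.get("condition", "vr"), mouse=raw.get("mouse", "?"),
        day=int(raw.get("day", 1)), session_id=raw.get("session_id", path.name),
        source_session=raw.get("source_session"),
        replay_mode=raw.get("replay_mode"))

    ts = pd.read_csv(path / "timeseries.csv", dtype=float)
    act = pd.read_csv(path / "activity.csv", dtype=float).to_numpy()
    rewards = pd.read_csv(path / "rewards.csv")
    reward_times = rewards["time_s"].to_numpy(dtype=float) if len(rewards) else np.empty(0)
    units = pd.read_csv(path / "units.csv")

    def _opt(col: str) -> np.ndarray | None:
        arr = ts[col].to_numpy()
        return None if np.all(np.isnan(arr)) else arr

    bundle = SessionBundle(
        time=ts["time_s"].to_numpy(),
        position=ts["position_cm"].to_numpy(),
        speed=ts["speed_cms"].to_numpy(),
        trial_id=ts["trial_id"].to_numpy(),
        activity=act,
        meta=meta,
        reward_times=reward_times,
        pupil_size=_opt("pupil_size"),
        pupil_x=_opt("pupil_x"),
        pupil_y=_opt("pupil_y"),
        unit_ids=units["unit_id"].to_numpy(),
    )
    return bundle.validate()


def as_replay(bundle: SessionBundle, **meta_updates) -> SessionBundle:
    """Shallow copy with updated metadata (used when deriving replay bundles)."""
    return replace(bundle, meta=replace(bundle.meta, **meta_updates))
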
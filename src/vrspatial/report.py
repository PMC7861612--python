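"""Session-level summaries, condition/area comparisons, and the pipeline.

Per-session statistics are medians over units included in the SMI analysis
(responsive, peak inside the matching segments, nonzero paired response);
dispersion is the unnormalized median absolute deviation from the median,
and comparisons across paired conditions (VR vs replay) use the Wilcoxon
signed-rank test on per-session medians while independent groups (areas,
training days) use the rank-sum test.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import kept_mask, reliability_all, resolve_trials, smoothed_activity
from .session import (SessionBundle, build_trial_table, load_session,
                      session_passes_replay_inclusion)
from .smi import smi_for_session


@dataclass
class SessionSummary:
    session_id: str
    area: str
    condition: str
    n_units_total: int
    n_responsive: int
    n_smi_included: int
    median_smi: float
    mad_smi: float
    fraction_smi_gt_0p5: float
    mean_activity: float
    unit_smis: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))


@dataclass
class ComparisonResult:
    test: str            # wilcoxon_signed_rank | wilcoxon_rank_sum | paired_t
    sidedness: str       # two-sided | greater | less
    n: tuple
    statistic: float
    p_value: float
    group_medians: tuple


def mad(x: np.ndarray) -> float:
    """Unnormalized median absolute deviation from the median."""
    x = np.asarray(x, dtype=float)
    return float(np.median(np.abs(x - np.median(x))))


def summarize_session(smi_results, reliabilities,
                      bundle: SessionBundle) -> SessionSummary:
    """Aggregate unit-level SMIs and reliabilities into one session row."""
    responsive = np.array([r.responsive for r in reliabilities])
    included = np.array([s.included for s in smi_results])
    smis = np.array([s.smi for s in smi_results])[included]
    if smis.size:
        median_smi, mad_smi = float(np.median(smis)), mad(smis)
        frac = float(np.mean(smis > 0.5))
    else:
        median_smi = mad_smi = frac = np.nan
    mask = kept_mask(bundle, resolve_trials(bundle, "all"))
    if responsive.any() and mask.any():
        mean_act = float(smoothed_activity(bundle)[responsive][:, mask].mean())
    else:
        mean_act = np.nan
    return SessionSummary(
        session_id=bundle.meta.session_id, area=bundle.meta.area,
        condition=bundle.meta.condition,
        n_units_total=bundle.n_units,
        n_responsive=int(responsive.sum()),
        n_smi_included=int(included.sum()),
        median_smi=median_smi, mad_smi=mad_smi,
        fraction_smi_gt_0p5=frac, mean_activity=mean_act,
        unit_smis=smis)


# ---------------------------------------------------------------------------
# Statistical comparisons

def _signed_rank(x: np.ndarray, y: np.ndarray, alternative: str):
    """Wilcoxon signed-rank: exact null for n <= 25 without ties/zeros,
    otherwise normal approximation with continuity correction."""
    d = x - y
    n = d.size
    use_exact = n <= 25 and not np.any(d == 0) and \
        np.unique(np.abs(d)).size == n
    if np.all(d == 0):
        return 0.0, 1.0
    method = "exact" if use_exact else "approx"
    res = stats.wilcoxon(x, y, alternative=alternative, method=method,
                         correction=(method == "approx"))
    return float(res.statistic), float(res.pvalue)


def compare_conditions(summaries_a: list[SessionSummary],
                       summaries_b: list[SessionSummary],
                       sidedness: str = "two-sided",
                       statistic: str = "median_smi") -> ComparisonResult:
    """Paired comparison of per-session statistics across two conditions.

    Sessions are matched by id (a replay is matched to its source VR
    session). ``statistic`` 'median_smi' uses the signed-rank test;
    'mean_activity' uses the paired t test.
    """
    def _key(s: SessionSummary) -> str:
        return s.session_id.split("-replay-")[0]

    ids_a = [_key(s) for s in summaries_a]
    ids_b = [_key(s) for s in summaries_b]
    if ids_a != ids_b:
        raise ValueError("session ids of the two conditions do not match")
    x = np.array([getattr(s, statistic) for s in summaries_a])
    y = np.array([getattr(s, statistic) for s in summaries_b])
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if statistic == "mean_activity":
        res = stats.ttest_rel(x, y, alternative=sidedness)
        return ComparisonResult("paired_t", sidedness, (x.size, y.size),
                                float(res.statistic), float(res.pvalue),
                                (float(np.median(x)), float(np.median(y))))
    stat, p = _signed_rank(x, y, sidedness)
    return ComparisonResult("wilcoxon_signed_rank", sidedness,
                            (x.size, y.size), stat, p,
                            (float(np.median(x)), float(np.median(y))))


def compare_areas(group_a, group_b,
                  sidedness: str = "two-sided") -> ComparisonResult:
    """Rank-sum comparison of two independent groups.

    Groups may be lists of :class:`SessionSummary` (per-session medians,
    the default reporting unit) or plain arrays of unit-level SMIs (used
    for the day-over-day experience comparison).
    """
    def _values(group):
        if len(group) and isinstance(group[0], SessionSummary):
            return np.array([s.median_smi for s in group])
        return np.asarray(group, dtype=float)

    x, y = _values(group_a), _values(group_b)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    res = stats.ranksums(x, y, alternative=sidedness)
    return ComparisonResult("wilcoxon_rank_sum", sidedness, (x.size, y.size),
                            float(res.statistic), float(res.pvalue),
                            (float(np.median(x)), float(np.median(y))))


# ---------------------------------------------------------------------------
# Pipeline

def analyze_session(bundle: SessionBundle,
                    vr_bundle: SessionBundle | None = None) -> SessionSummary:
    """Reliability -> SMI -> summary for one session.

    For replay sessions pass the source VR bundle: preferred positions and
    the responsiveness filter are always taken from VR.
    """
    if bundle.meta.condition == "replay":
        if vr_bundle is None:
            raise ValueError("replay analysis needs the source VR session")
        rel = reliability_all(vr_bundle)
        smis = smi_for_session(vr_bundle, eval_bundle=bundle,
                               reliabilities=rel)
    else:
        rel = reliability_all(bundle)
        smis = smi_for_session(bundle, reliabilities=rel)
    return summarize_session(smis, rel, bundle)


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run profiles -> reliability -> SMI -> summaries -> comparisons.

    ``config`` lists sessions as {"path": dir, "role": "vr"|"replay",
    "source": vr session path for replays}. Writes summaries.csv,
    comparisons.csv and run.log to ``out_dir``; deterministic for fixed
    inputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"config_hash: "
                 f"{hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()}"]

    vr_bundles: dict[str, SessionBundle] = {}
    summaries: list[SessionSummary] = []
    excluded: list[str] = []
    for entry in config["sessions"]:
        if entry.get("role", "vr") != "vr":
            continue
        b = load_session(entry["path"])
        vr_bundles[entry["path"]] = b
        summaries.append(analyze_session(b))
        log_lines.append(f"vr session {b.meta.session_id}: "
                         f"{summaries[-1].n_smi_included} units in SMI")

    replay_summaries: list[SessionSummary] = []
    for entry in config["sessions"]:
        if entry.get("role", "vr") != "replay":
            continue
        b = load_session(entry["path"])
        mode = b.meta.replay_mode or "running"
        table = build_trial_table(b)
        if not session_passes_replay_inclusion(table, mode):
            excluded.append(b.meta.session_id)
            log_lines.append(f"replay session {b.meta.session_id} excluded: "
                             f"fewer than 10 {mode} trials")
            continue
        vr = vr_bundles.get(entry["source"]) or load_session(entry["source"])
        replay_summaries.append(analyze_session(b, vr_bundle=vr))
        log_lines.append(f"replay session {b.meta.session_id}: included")

    rows = [{k: getattr(s, k) for k in (
        "session_id", "area", "condition", "n_units_total", "n_responsive",
        "n_smi_included", "median_smi", "mad_smi", "fraction_smi_gt_0p5",
        "mean_activity")} for s in summaries + replay_summaries]
    pd.DataFrame(rows).to_csv(out_dir / "summaries.csv", index=False)

    comp_rows = []
    if replay_summaries:
        by_source = {s.session_id.split("-replay-")[0]: s
                     for s in replay_summaries}
        paired_vr = [s for s in summaries if s.session_id in by_source]
        paired_rp = [by_source[s.session_id] for s in paired_vr]
        if paired_vr:
            c = compare_conditions(paired_vr, paired_rp, "greater")
            comp_rows.append({
                "comparison": "vr_vs_replay_median_smi", "test": c.test,
                "sidedness": c.sidedness, "n": c.n[0],
                "statistic": c.statistic, "p_value": c.p_value,
                "median_a": c.group_medians[0],
                "median_b": c.group_medians[1]})
    pd.DataFrame(comp_rows, columns=[
        "comparison", "test", "sidedness", "n", "statistic", "p_value",
        "median_a", "median_b"]).to_csv(out_dir / "comparisons.csv",
                                        index=False)
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return {"summaries": summaries + replay_summaries,
            "excluded": excluded}
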
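"""Cross-validated spatial modulation index and the purely-visual fit.

The corridor's segments [10, 50) and [50, 90) cm are visually identical,
so a purely visual unit must respond equally at any position x and at
x + 40 cm. The spatial modulation index quantifies the departure from
that symmetry: the preferred position p is the peak of the odd-trial
profile, the non-preferred position is the visually identical bin 40 cm
away, and

    SMI = (Rp - Rn) / (Rp + Rn)

with Rp, Rn read from an independent evaluation profile (even trials in
VR; all qualifying replay trials for replay conditions, still trained on
the VR odd trials). SMI is 0 for a response with two equal peaks, 1 for
a single-segment response, and negative when the segment preference is
inconsistent between the train and evaluation splits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .profiles import (RELIABILITY_THRESHOLD, ResponseProfile,
                       compute_profiles, reliability_all)
from .session import SessionBundle

MATCH_LOW_BIN = 15   # peaks in [0,15) or [85,100) fall outside the matching pairing
MATCH_HIGH_BIN = 85
SEGMENT_SHIFT = 40


@dataclass
class SMIResult:
    preferred_pos_bin: int | None
    nonpreferred_pos_bin: int | None
    rp: float
    rn: float
    smi: float
    included: bool
    exclusion_reason: str | None  # None | peak_outside_matching_segments |
                                  # zero_response | not_responsive


@dataclass
class VisualPrediction:
    """Two half-Gaussians meeting at the peak, duplicated at +/-40 cm."""

    peak_position_cm: float
    peak_height: float
    sigma_left_cm: float
    sigma_right_cm: float
    baseline: float
    predicted_profile: np.ndarray  # 100 bins
    residual_rms: float


def preferred_position(profile_odd: ResponseProfile) -> tuple[int | None, str | None]:
    """Peak bin of the odd-trial profile, or an exclusion reason.

    Ties are broken by the lowest bin index; peaks near the corridor start
    or end (0-15 cm or 85-100 cm) are excluded because their visually
    matching counterpart would fall outside the corridor's paired segments.
    """
    values = profile_odd.values
    if np.all(np.isnan(values)):
        return None, "zero_response"
    peak = int(np.nanargmax(values))  # argmax returns the first (lowest) maximum
    if peak < MATCH_LOW_BIN or peak >= MATCH_HIGH_BIN:
        return None, "peak_outside_matching_segments"
    return peak, None


def smi_from_profiles(profile_odd: ResponseProfile,
                      profile_eval: ResponseProfile,
                      responsive: bool = True) -> SMIResult:
    """SMI from a train (odd-trial) and an evaluation profile."""
    if not responsive:
        return SMIResult(None, None, np.nan, np.nan, np.nan, False,
                         "not_responsive")
    peak, reason = preferred_position(profile_odd)
    if peak is None:
        return SMIResult(None, None, np.nan, np.nan, np.nan, False, reason)
    nonpref = peak + SEGMENT_SHIFT if peak < 50 else peak - SEGMENT_SHIFT
    rp = float(profile_eval.values[peak])
    rn = float(profile_eval.values[nonpref])
    if not np.isfinite(rp) or not np.isfinite(rn) or (rp + rn) == 0:
        return SMIResult(peak, nonpref, rp, rn, np.nan, False, "zero_response")
    return SMIResult(peak, nonpref, rp, rn, (rp - rn) / (rp + rn), True, None)


def smi_for_session(vr: SessionBundle,
                    eval_bundle: SessionBundle | None = None,
                    reliabilities=None,
                    apply_responsiveness: bool = True) -> list[SMIResult]:
    """SMI of every unit in a session.

    Preferred positions always come from the VR odd-trial profiles; the
    evaluation profile comes from VR even trials, or from all qualifying
    trials of ``eval_bundle`` for replay conditions. The responsiveness
    filter (reliability >= 5% in VR) is applied before SMI.
    """
    odd = compute_profiles(vr, "odd")
    if eval_bundle is None:
        ev = compute_profiles(vr, "even")
    else:
        ev = compute_profiles(eval_bundle, "all")
    if apply_responsiveness:
        if reliabilities is None:
            reliabilities = reliability_all(vr)
        responsive = [r.responsive for r in reliabilities]
    else:
        responsive = [True] * vr.n_units
    return [smi_from_profiles(odd[u], ev[u], responsive[u])
            for u in range(vr.n_units)]


# ---------------------------------------------------------------------------
# Purely visual prediction

def _segment_bins(peak: int) -> np.ndarray:
    """The 40 bins of the visually matching segment containing the peak."""
    return np.arange(10, 50) if peak < 50 else np.arange(50, 90)


def _two_gaussian(x: np.ndarray, c: float, h: float, sl: float, sr: float,
                  b: float) -> np.ndarray:
    sigma = np.where(x < c, sl, sr)
    return b + h * np.exp(-((x - c) ** 2) / (2.0 * sigma ** 2))


def fit_visual_prediction(profile: ResponseProfile) -> VisualPrediction:
    """Least-squares fit of the purely visual model to one segment.

    A sum of two Gaussians meeting at the peak (shared position and height,
    independent left/right widths, additive baseline) is fit to the 40 bins
    of the segment where the unit peaked; the fitted curve duplicated at
    +/-40 cm is the response the unit would show if it were purely visual.
    Bins outside the matching segments ([0,10) and [90,100)) take the
    fitted baseline.
    """
    peak, reason = preferred_position(profile)
    if peak is None:
        raise ValueError(f"cannot fit visual prediction: {reason}")
    bins = _segment_bins(peak)
    y = profile.values[bins]
    ok = np.isfinite(y)
    if ok.sum() < 6:
        raise ValueError("fewer than 6 defined bins in the peak's segment")
    x = bins[ok] + 0.5
    y = y[ok]
    lo, hi = x.min(), x.max()
    c0 = peak + 0.5
    b0 = float(y.min())
    h0 = max(float(y.max() - y.min()), 1e-6)
    res = least_squares(
        lambda p: _two_gaussian(x, *p) - y,
        x0=[c0, h0, 5.0, 5.0, b0],
        bounds=([lo, 0.0, 0.5, 0.5, 0.0],
                [hi, np.inf, 60.0, 60.0, np.inf]),
        max_nfev=2000)
    if not res.success:
        raise RuntimeError(f"visual-prediction fit did not converge: {res.message}")
    c, h, sl, sr, b = res.x

    centers = np.arange(40) + bins[0] + 0.5
    segment_curve = _two_gaussian(centers, c, h, sl, sr, b)
    predicted = np.full(100, b)
    predicted[10:50] = segment_curve
    predicted[50:90] = segment_curve
    return VisualPrediction(
        peak_position_cm=float(c), peak_height=float(h),
        sigma_left_cm=float(sl), sigma_right_cm=float(sr), baseline=float(b),
        predicted_profile=predicted,
        residual_rms=float(np.sqrt(np.mean(res.fun ** 2))))
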
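"""Ridge-regression encoding models of deconvolved activity.

Three linear models predict a unit's activity from a common square-basis
description of the corridor plus behavioral covariates:

* ``visual`` — 5 trial-onset squares (0-10 cm, 2 cm wide), 5 trial-offset
  squares (90-100 cm), and 20 matched-segment predictors whose two square
  functions sit 40 cm apart (unit height), so any position in [10, 50) cm
  activates the same column as the visually identical position 40 cm away.
  30 predictors plus a constant.
* ``non_spatial`` — visual plus behavior: running speed at time shifts
  {-1000, -500, 0, +500, +1000} ms, pupil size, horizontal and vertical
  pupil position, and a reward impulse. 39 predictors plus a constant.
* ``spatial`` — non_spatial, but each matched-segment predictor's two
  squares take heights (h1, h2) = (alpha, 1-alpha) / sqrt(alpha^2 +
  (1-alpha)^2) for a single per-unit alpha in [0, 1]: alpha = 0.5 is a
  purely visual response, alpha = 0 or 1 a single-segment response.

Coefficients solve the ridge normal equations beta = (X'X + lambda I)^-1
X'y, with the constant column penalized exactly as the closed form states.
lambda (grid {0.01, 0.05, 0.1, 0.5, 1}) and alpha (step 0.1) are selected
by fivefold trial-blocked cross-validated variance explained, the same
folds and score as the reliability filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .profiles import (kept_mask, position_bins, profiles_from_samples,
                       resolve_trials, smoothed_activity, trial_folds)
from .session import SessionBundle
from .smi import SMIResult, smi_from_profiles

LAMBDA_GRID = (0.01, 0.05, 0.1, 0.5, 1.0)
ALPHA_GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.1), 1))
SPEED_SHIFTS_MS = (-1000.0, -500.0, 0.0, 500.0, 1000.0)
MODEL_KINDS = ("visual", "non_spatial", "spatial")


@dataclass
class GLMFit:
    model_kind: str
    beta: np.ndarray
    lambda_selected: float
    alpha_selected: float | None
    cv_variance_explained: float
    predicted_trace: np.ndarray      # at kept timepoints, clipped at 0
    predicted_smi: SMIResult | None = None


def segment_heights(alpha: float) -> tuple[float, float]:
    """Unit-norm heights of the paired squares: (alpha, 1-alpha)/||.||_2."""
    norm = np.sqrt(alpha ** 2 + (1.0 - alpha) ** 2)
    return alpha / norm, (1.0 - alpha) / norm


def _minmax(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    vmin, vmax = np.nanmin(v), np.nanmax(v)
    if vmax == vmin:
        return np.full_like(v, lo)
    return lo + (hi - lo) * (v - vmin) / (vmax - vmin)


def _shifted(series: np.ndarray, shift: int) -> np.ndarray:
    """Shift with edge padding (first/last value repeated)."""
    if shift == 0:
        return series
    out = np.empty_like(series)
    if shift > 0:
        out[shift:] = series[:-shift]
        out[:shift] = series[0]
    else:
        out[:shift] = series[-shift:]
        out[shift:] = series[-1]
    return out


class DesignBuilder:
    """Builds design matrices over a session's kept timepoints.

    The position-basis and behavioral blocks are assembled once; only the
    matched-segment heights change with alpha, so spatial-model designs at
    many alphas are cheap.
    """

    def __init__(self, bundle: SessionBundle, model_kind: str):
        if model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind: {model_kind!r}")
        self.model_kind = model_kind
        self.bundle = bundle
        trials = resolve_trials(bundle, "all")
        self.trials = trials
        self.mask = kept_mask(bundle, trials)
        if not self.mask.any():
            raise ValueError("no usable samples")
        self.kept_trial_id = bundle.trial_id[self.mask]
        self.kept_position = bundle.position[self.mask]
        bins = position_bins(self.kept_position)
        n = bins.size

        # onset: [0,2),...,[8,10); offset: [90,92),...,[98,100)
        onset = np.zeros((n, 5))
        offset = np.zeros((n, 5))
        for j in range(5):
            onset[:, j] = (bins >= 2 * j) & (bins < 2 * j + 2)
            offset[:, j] = (bins >= 90 + 2 * j) & (bins < 92 + 2 * j)
        # matched-segment pairs: [10+2j,12+2j) with [50+2j,52+2j)
        self._seg1 = np.zeros((n, 20))
        self._seg2 = np.zeros((n, 20))
        for j in range(20):
            self._seg1[:, j] = (bins >= 10 + 2 * j) & (bins < 12 + 2 * j)
            self._seg2[:, j] = (bins >= 50 + 2 * j) & (bins < 52 + 2 * j)
        self._onoff = np.hstack([onset, offset])

        if model_kind == "visual":
            self._behav = np.empty((n, 0))
        else:
            if bundle.pupil_size is None or bundle.pupil_x is None \
                    or bundle.pupil_y is None:
                raise ValueError(
                    f"{model_kind} model requires pupil covariates")
            fs = bundle.meta.fs
            speed01 = _minmax(bundle.speed, 0.0, 1.0)
            cols = [_shifted(speed01, int(round(ms / 1000.0 * fs)))[self.mask]
                    for ms in SPEED_SHIFTS_MS]
            cols.append(_minmax(bundle.pupil_size, 0.0, 1.0)[self.mask])
            cols.append(_minmax(bundle.pupil_x, -1.0, 1.0)[self.mask])
            cols.append(_minmax(bundle.pupil_y, -1.0, 1.0)[self.mask])
            reward = np.zeros(bundle.n_timepoints)
            if bundle.reward_times.size:
                idx = np.clip(
                    np.floor((bundle.reward_times - bundle.time[0]) *
                             fs).astype(int),
                    0, bundle.n_timepoints - 1)
                reward[idx] = 1.0
            cols.append(reward[self.mask])
            self._behav = np.column_stack(cols)

    @property
    def n_predictors(self) -> int:
        """Predictor count excluding the constant."""
        return 30 + self._behav.shape[1]

    def matrix(self, alpha: float | None = None) -> np.ndarray:
        """Design matrix (kept timepoints x predictors+1, constant last)."""
        if self.model_kind == "spatial":
            if alpha is None:
                raise ValueError("spatial model requires alpha")
            h1, h2 = segment_heights(alpha)
        else:
            h1 = h2 = 1.0
        segments = h1 * self._seg1 + h2 * self._seg2
        n = segments.shape[0]
        return np.hstack([self._onoff, segments, self._behav,
                          np.ones((n, 1))])


def build_design(bundle: SessionBundle, model_kind: str,
                 alpha: float | None = None) -> np.ndarray:
    """One-shot design matrix (see :class:`DesignBuilder`)."""
    return DesignBuilder(bundle, model_kind).matrix(alpha)


def ridge_solve(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Ridge coefficients solving (X'X + lambda I) beta = X'y.

    All coefficients, including the constant, are penalized. Solved by a
    Cholesky factorization of the regularized Gram matrix; ``y`` may be a
    matrix of traces (one column per unit).
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    X = np.asarray(X, dtype=float)
    gram = X.T @ X + lam * np.eye(X.shape[1])
    try:
        return scipy.linalg.solve(gram, X.T @ y, assume_a="pos")
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular normal equations (lambda={lam}); use lambda > 0"
        ) from exc


# ---------------------------------------------------------------------------
# Cross-validated fitting

def fit_models(bundle: SessionBundle, model_kind: str,
               smoothed: np.ndarray | None = None,
               with_predicted_smi: bool = True) -> list[GLMFit]:
    """Fit one encoding model to every unit with joint (lambda, alpha) CV.

    The design matrix is shared across units, so Gram matrices per
    (alpha, fold) are factored once and reused for every unit and lambda.
    """
    builder = DesignBuilder(bundle, model_kind)
    if smoothed is None:
        smoothed = smoothed_activity(bundle)
    y_all = smoothed[:, builder.mask].T  # kept timepoints x units
    n_units = y_all.shape[1]

    folds = trial_folds(builder.trials)
    if len(folds) < 5:
        raise ValueError("fewer than 5 usable trials for cross-validation")
    test_masks = [np.isin(builder.kept_trial_id, f.astype(float))
                  for f in folds]
    alphas = ALPHA_GRID if model_kind == "spatial" else (None,)
    scores = np.zeros((len(alphas), len(LAMBDA_GRID), n_units))

    for ia, alpha in enumerate(alphas):
        X = builder.matrix(alpha)
        for test in test_masks:
            train = ~test
            Xtr, Xte = X[train], X[test]
            ytr, yte = y_all[train], y_all[test]
            mu = ytr.mean(axis=0)
            denom = ((yte - mu) ** 2).sum(axis=0)
            denom = np.where(denom > 0, denom, np.inf)
            gram = Xtr.T @ Xtr
            xty = Xtr.T @ ytr
            for il, lam in enumerate(LAMBDA_GRID):
                beta = scipy.linalg.solve(
                    gram + lam * np.eye(gram.shape[0]), xty, assume_a="pos")
                resid = ((yte - Xte @ beta) ** 2).sum(axis=0)
                scores[ia, il] += 1.0 - resid / denom
    scores /= len(test_masks)

    flat = scores.reshape(-1, n_units)
    best = np.argmax(flat, axis=0)
    best_ia, best_il = np.unravel_index(best, scores.shape[:2])

    fits: list[GLMFit | None] = [None] * n_units
    for ia in np.unique(best_ia):
        X = builder.matrix(alphas[ia])
        gram = X.T @ X
        for il in np.unique(best_il[best_ia == ia]):
            sel = np.nonzero((best_ia == ia) & (best_il == il))[0]
            beta = scipy.linalg.solve(
                gram + LAMBDA_GRID[il] * np.eye(gram.shape[0]),
                X.T @ y_all[:, sel], assume_a="pos")
            pred = np.maximum(X @ beta, 0.0)
            for k, u in enumerate(sel):
                fits[u] = GLMFit(
                    model_kind=model_kind, beta=beta[:, k],
                    lambda_selected=LAMBDA_GRID[il],
                    alpha_selected=(None if alphas[ia] is None
                                    else float(alphas[ia])),
                    cv_variance_explained=float(scores[ia, il, u]),
                    predicted_trace=pred[:, k])

    if with_predicted_smi:
        _attach_predicted_smi(fits, builder)
    return fits  # type: ignore[return-value]


def fit_model_cv(bundle: SessionBundle, unit: int, model_kind: str,
                 with_predicted_smi: bool = True) -> GLMFit:
    """Cross-validated fit for a single unit (see :func:`fit_models`)."""
    from dataclasses import replace as dc_replace
    sub = dc_replace(bundle, activity=bundle.activity[unit:unit + 1])
    return fit_models(sub, model_kind, with_predicted_smi=with_predicted_smi)[0]


def _attach_predicted_smi(fits, builder: DesignBuilder) -> None:
    """Predicted SMI: the model's trace pushed through the profile/SMI path."""
    odd = builder.trials[builder.trials % 2 == 1]
    even = builder.trials[builder.trials % 2 == 0]
    odd_mask = np.isin(builder.kept_trial_id, odd.astype(float))
    even_mask = ~odd_mask
    dt = builder.bundle.dt
    pred = np.stack([f.predicted_trace for f in fits])
    odd_profiles = profiles_from_samples(
        builder.kept_position[odd_mask], pred[:, odd_mask], dt,
        len(odd), "odd")
    even_profiles = profiles_from_samples(
        builder.kept_position[even_mask], pred[:, even_mask], dt,
        len(even), "even")
    for u, fit in enumerate(fits):
        fit.predicted_smi = smi_from_profiles(odd_profiles[u], even_profiles[u])


def glm_predicted_smi(fit: GLMFit, bundle: SessionBundle) -> SMIResult:
    """Predicted SMI of an already-fitted model on its session."""
    builder = DesignBuilder(bundle, fit.model_kind)
    _attach_predicted_smi([fit], builder)
    return fit.predicted_smi
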
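# Methods

## The measurement and its logic

The virtual corridor is 100 cm long with landmarks at 20, 40, 60 and
80 cm alternating grating–plaid–grating–plaid, so the segments
[10, 50) and [50, 90) cm present identical visual input shifted by
40 cm. A unit whose activity depends only on the visual scene must have
a response profile satisfying R(x) = R(x + 40) on that range. The
spatial modulation index (SMI) measures the departure from this
symmetry with a cross-validated read-out: the preferred position is the
peak of the profile over **odd** trials; the responses Rp and Rn at the
preferred position and at the visually identical position 40 cm away are
read from the profile over **even** trials (or over all qualifying
replay trials, still trained on VR odd trials); SMI = (Rp − Rn)/(Rp + Rn).
Cross-validation makes the null well-behaved: with no consistent segment
preference, Rp and Rn are exchangeable and SMI is symmetric around 0
(it can be negative), rather than biased positive as a within-sample
peak-versus-trough read-out would be.

## Response profiles

1. Deconvolved traces are smoothed in time with a Gaussian kernel,
   σ = 250 ms ("window" is interpreted as the standard deviation;
   σ, FWHM and full width are all defensible readings, and the choice is
   exposed as a constant).
2. Timepoints are kept when the corridor position is valid (not an
   inter-trial gray screen) and the speed criterion holds: speed
   > 1 cm/s in VR and running replay, speed < 5 cm/s in stationary
   replay. Timed-out trials (> 30 s) are always excluded.
3. Spike-count and occupancy maps over 100 × 1 cm bins (half-open
   [i, i+1); the final sample at exactly 100 cm is assigned to bin 99),
   each sample contributing Δt = 1/fs seconds.
4. Both maps are smoothed in space with a Gaussian of σ = 5 cm,
   truncated at ±3σ with the kernel renormalized near the array edges.
   Renormalization preserves constants exactly, so a uniform firing rate
   yields a flat profile with no attenuation at the corridor ends; the
   price is that smoothed maps conserve total mass only in the interior,
   which is why the conservation invariants are asserted on the
   pre-smoothing maps.
5. The profile is the elementwise ratio; bins with smoothed occupancy
   below 1e-9 s are undefined (NaN).

## Reliability and the responsiveness filter

Fivefold cross-validation over **contiguous blocks of trials** (not
timepoints): temporal smoothing spreads signal across neighbouring
samples, and time-blocked folds would leak training activity into the
test fold at every boundary sample, inflating reliability. Per fold,
held-out smoothed activity y is predicted by the training-fold profile
looked up at the animal's position (undefined bins fall back to the
training mean μ), and the fold scores 1 − Σ(y − y′)²/Σ(y − μ)² with μ the
training-fold mean; a degenerate denominator scores 0. Reliability is the
mean over folds; units with reliability ≥ 0.05 pass the filter (the
boundary is taken inclusive, and is a module constant). Reliability is
invariant to positive rescaling of the trace but not to additive offsets.

## SMI details

- Peak bins in [0, 15) ∪ [85, 100) are excluded
  (`peak_outside_matching_segments`): their 40 cm counterpart would leave
  the paired range. Pairing: p ∈ [15, 50) ↔ p + 40; p ∈ [50, 85) ↔ p − 40.
- Ties at the peak break to the lowest bin, for determinism.
- Rp and Rn are single-bin reads of the already-smoothed evaluation
  profile — the 5 cm smoothing has pooled neighbours, so no extra local
  averaging is applied.
- Rp + Rn = 0 (or an undefined bin) excludes the unit (`zero_response`).
- The responsiveness filter runs first; failing units carry
  `not_responsive`.
- The purely visual prediction fits, by least squares, two Gaussians
  sharing their peak position and height but with independent left/right
  widths plus a baseline, to the 40 bins of the peak's segment, then
  copies the fitted curve to the other segment; bins outside [10, 90)
  take the baseline.

## Encoding models

Design matrices are built over the same kept timepoints as the profiles.
Position enters through 2 cm-wide unit-height squares: five onset squares
(0–10 cm), five offset squares (90–100 cm), and twenty matched-segment
predictors whose two squares sit 40 cm apart. Behavioral covariates
(non-spatial and spatial models): running speed min-max normalized to
[0, 1] and entered at five shifts {−1000, −500, 0, +500, +1000} ms
(shifts are rounded to whole samples — ±4 samples at fs = 7.5 Hz — and
edge samples are padded with the series' first/last value); pupil size in
[0, 1]; pupil x/y in [−1, 1]; one binary reward impulse at the sample
containing each reward. Normalization constants come from the full
session: min-max leakage across folds is negligible and matches
single-session preprocessing. The spatial model scales each
matched-segment pair by unit-norm heights (α, 1 − α)/√(α² + (1 − α)²)
(the L2 norm is a choice; the norm is not otherwise pinned down), with
**one α shared by all twenty pairs per unit**.

Coefficients solve (XᵀX + λI)β = Xᵀy by Cholesky factorization — the
constant column is penalized along with everything else, exactly as the
closed form reads; that is nonstandard but faithful, and with λ ≤ 1
against Gram entries of order 10³ the shrinkage is minimal. λ = 0 is
rejected for these designs: the 30 squares tile the corridor and are
exactly collinear with the constant. λ and α are selected jointly on a
single 5-fold grid (the same trial-blocked folds as reliability) by mean
held-out variance explained, using the reliability formula with y′ = Xβ;
a nested search is also defensible but the joint grid is simpler and the
two coincide in expectation. Models are fit to the temporally smoothed
traces, consistent with the reliability target. The refit at the selected
hyperparameters uses all kept data; predictions are clipped at 0 (traces
are nonnegative rates) before being pushed through the same odd/even
profile-and-SMI machinery to give the predicted SMI; the predicted trace
is not re-smoothed in time, being already a smooth function of the
predictors.

Because the design is shared across a session's units, the
cross-validated fit precomputes per-(α, fold) Gram matrices and solves
for all units at once; fitting 50 units over the full (λ, α) grid takes a
fraction of a second.

## Session statistics

Per-session medians are taken over SMI-included units only; dispersion is
the **unnormalized** m.a.d., median(|x − median(x)|). Paired VR-vs-replay
comparisons use the Wilcoxon signed-rank test on per-session medians
(exact null when n ≤ 25 with no zeros or ties, otherwise the normal
approximation with continuity correction); mean-activity comparisons use
the paired t test. Independent groups (areas, training days) use the
rank-sum test, accepting either session summaries or raw unit-level SMI
arrays (the day-over-day comparison pools units). Replay sessions enter
comparisons only if ≥ 10 non-timed-out trials carry the session's mode
flag (running: ≥ 1 timepoint with speed > 1 cm/s; stationary: ≥ 1
timepoint with speed < 5 cm/s).

## Synthetic sessions

The generator emulates the experimental protocol, not any particular
dataset:

- **Corridor and trials.** Speed is a rectified Ornstein–Uhlenbeck
  process (mean 15 cm/s, relaxation 2 s, sd 5 cm/s — placeholders, since
  running statistics beyond the thresholds are unconstrained; all are
  config fields). Position integrates speed at fs = 7.5 Hz (the
  per-plane two-photon rate); a trial ends on crossing 100 cm (the
  crossing sample is kept, clamped to 100) or times out at 30 s.
  Inter-trial gray periods last 3–5 s (uniform) with invalid position.
  Rewards occur at corridor completion.
- **Tuning.** Each unit's visual template is a baseline plus Gaussian
  bumps on the full 40 cm-periodic landmark lattice, with one amplitude
  for gratings and one for plaids. The lattice construction makes
  V(x) = V(x + 40) hold to machine precision, as it must for a visual
  signal in this corridor — truncating the bumps to the four physical
  landmarks would leak asymmetry near segment edges and masquerade as
  spatial modulation.
- **Spatial modulation.** A piecewise-constant gain: 2a on [10, 50),
  2(1 − a) on [50, 90), 1 elsewhere. This makes the true SMI analytic
  (2a − 1) and mirrors the spatial model's α parameterization.
- **Noise.** Activity is Poisson on the expected event count per sample,
  divided by Δt — nonnegative and rate-like, respecting the downstream
  invariant on deconvolved traces. Gray-screen timepoints emit at the
  baseline rate.
- **Replay.** The stimulus position trace is copied from the source VR
  session; treadmill speed is regenerated (fresh OU for running replay,
  sub-1 cm/s jitter for stationary). The gain is attenuated toward the
  visual value, a′ = 0.5 + ρ(a − 0.5), and stationary replay scales
  rates by 0.5 by default.
- Pupil covariates are smoothed noise weakly correlated with speed —
  placeholders sufficient to exercise the design matrix.

What the generator does **not** emulate: calcium-indicator dynamics and
deconvolution artifacts, slow drift and state changes, eye movements with
visual consequences, correlated population noise, realistic pause/lick
structure. Passing tests therefore demonstrate that the pipeline is
correct and well calibrated under protocol-faithful conditions with
independent Poisson noise — not that any particular biological dataset
will show modulation.

## Problem sizes and numerical choices

The packaged analyses use 200 units per gain level (60-trial sessions)
for SMI recovery, cohorts of 20–40 sessions of 30 units for the null and
replay analyses, and 100 units per gain for α recovery; these sizes give
stable medians while keeping any single analysis in the seconds-to-
minutes range on one CPU. Known small biases at these settings: the 5 cm
spatial smoothing pools activity across the segment boundaries at 10, 50
and 90 cm, pulling extreme SMIs slightly toward 0 (median ≈ 0.96 at
a = 1); the effect is a property of the smoothing convention, affects
real and synthetic data alike, and stays within ±0.05 of 2a − 1 at all
gain levels tested.

Degenerate inputs: empty series and all-excluded sessions raise;
constant held-out activity scores 0 in a fold; undefined profile bins
propagate the training mean into predictions; position exactly 100 cm is
bin 99; λ = 0 on a rank-deficient design raises with advice to use
λ > 0.

## Open choices resolved here

- Partial final trials (session ending mid-corridor) are ordinary
  non-timed-out trials.
- Odd/even parity is that of the 1-based trial id.
- Folds are trial-blocked (see Reliability).
- Preferred positions for replay SMIs always come from VR odd trials;
  the same convention is applied uniformly wherever a train split is
  needed.
- Running replay gates timepoints at speed > 1 cm/s, stationary replay
  at < 5 cm/s, symmetric timepoint-level criteria; session inclusion is
  trial-level (≥ 10 flagged trials).
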
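# Methods

## Model

`eegisc` analyses an aligned tensor of N subjects × D electrodes × T samples
per video block.  The working model is that stimulus-evoked activity is a
small set of latent source signals shared by all viewers, mixed into channel
space through fixed scalp topographies, with per-subject response gain and
additive channel noise:

    x_i(t) = g_i · A s(t) + ε_i(t)

Correlated components analysis (CorrCA) estimates spatial filters w that
maximize the ratio of between-subject to within-subject covariance of the
projected signals, w'Rb w / w'Rw w.  The maximizers are the eigenvectors of
Rw⁻¹Rb; the eigenvalue is the attained between/within ratio.  Both
covariances are averaged over video blocks before the eigendecomposition so
one set of filters serves all stimuli, and both groups are pooled when
fitting so the optimization favours neither group.  Intersubject correlation
(ISC) of a subject is the mean Pearson correlation of its component time
courses with each member of the reference cohort (the healthy group
throughout, with self-exclusion), averaged across videos; the reported
scalar is the sum over the three strongest components.

## Numerical choices

- **Eigenproblem.**  Solved via the symmetric equivalent
  M = Rw⁻¹ᐟ² Rb Rw⁻¹ᐟ² (numerically stable, mathematically identical).
  Rw is shrunk toward a scaled identity,
  Rw_reg = (1−γ)Rw + γ·mean(diag Rw)·I with γ = 0.1 by default, because
  zero-filled (artifact-blanked) channels make Rw rank-deficient.  γ = 0 is
  honoured when Rw has full rank and raises a clear error otherwise.
- **Sign convention.**  Each filter/forward-model pair is flipped so the
  largest-magnitude entry of the forward-model column A_k is positive,
  making scalp maps reproducible across runs.
- **Forward models.**  A = Rw W (W'Rw W)⁻¹, the channel-space patterns used
  for topography display and for parameter-recovery checks.
- **Zero-filled samples** stay in the covariance and correlation sums as
  zeros (that is the point of blanking: flagged channels contribute
  nothing); sliding windows in which more than half of a subject's samples
  are blanked are set missing instead.
- **Windowed ISC** uses the whole-recording filters (no per-window refit).
  The grid is n = floor((T_sec − L)/step) + 1 windows of length L
  (default 1.5 s) and step = L − overlap (default 0.3 s).

## Preprocessing chain

Fixed order: segment/align → band-pass → bad-channel zeroing → ocular ICA →
outlier zeroing → z-score.  No stage changes tensor dimensions; with a fixed
seed the chain is deterministic.

- Band-pass: 4th-order Butterworth, 1–50 Hz, applied forward-backward
  (zero phase), because ISC depends on millisecond-level alignment across
  subjects that a causal filter would shift.
- Bad channels: average power (mean squared amplitude) compared across
  channels within subject and video; channels above mean + 4 SD are zeroed
  in full.  Note an arithmetic consequence of using the full channel set for
  the statistics: the largest attainable z-score among D channels is
  √(D−1), so the rule can only fire for D ≥ 17 and flags at most one or two
  extreme channels — the intended behaviour for a montage of 19.
- Ocular ICA: per-subject FastICA (deflation, tol 1e-2; deflation converges
  far more reliably than the parallel update on noise-dominated mixtures).
  Components whose time course correlates |r| > 0.7 with the frontal-pair
  difference proxy (Fp1 − Fp2 by default) are subtracted.  Non-convergence
  degrades to a logged pass-through.
- Outliers: samples with |x| > mean|x| + 3·SD(x) are zeroed together with
  ±40 ms pads (41 samples per isolated spike at 500 Hz); overlapping pads
  merge.  The threshold uses the channel's own SD rather than the SD of
  |x|: on near-Gaussian data the latter sits at 2.6 σ and, with the pads,
  blanks 10–30 % of the recording, which distorts downstream ISC by far
  more than the chain's 0.05 distortion budget; the adopted threshold
  (≈3.8 σ) touches ~0.01 % of clean samples while catching genuine spikes
  by orders of magnitude.
- Z-scoring: population SD (denominator N); differences from the sample SD
  are immaterial at T ≥ 10⁴.  All-zero channels stay zero; a constant
  non-zero channel cannot be scaled and is zeroed (flagged) instead.

## Synthetic cohorts: what they emulate and what they do not

The generator reproduces the *statistical* structure the analysis relies
on: K shared band-limited (1–45 Hz) Gaussian sources, unit-norm random
topographies, group-specific gains (healthy 1.0, patient 0.4 by default —
patients remain partially synchronized, mirroring a reduced but non-zero
shared response), channel noise band-limited to the same range so the
band-pass stage is neutral by construction, and a configurable fraction
(default 0.2) of noise power placed in 8–12 Hz so the alpha covariate is
non-degenerate.  Optional artifacts: blink-like raised-cosine frontal
transients (20× channel SD, loaded asymmetrically on Fp1/Fp2 so the
frontal-difference proxy sees them), channels rescaled ×10, and isolated
50× spikes.  Keypoint tracks place a BODY_25 skeleton in the frame;
scripted limb epochs move the limb's keypoints by per-frame displacements
drawn strictly between the detection thresholds, camera jitter stays below
the lower threshold, and scene cuts are single-frame jumps above the upper
one.

The generator does **not** attempt realistic EEG spectra, volume-conduction
physics, electrode geometry, or actual video content.  Passing tests
demonstrate that the estimator recovers known latent structure and that the
statistical machinery has the advertised operating characteristics — not
that any particular clinical effect size would be reproduced on real
recordings.

## Simulation designs used by the tests and the acceptance script

- **Zero-noise limit**: identical subjects ⇒ every component's
  leave-one-out ISC is 1 to 1e-9 and the top-3 sum is 3.
- **Independent-noise null**: filters are fitted on one pure-noise cohort
  and ISC is scored on a second, independent one.  Scoring in-sample would
  bias the null upward (~+0.004 at N=20, D=19, T=30000): the fit selects
  the direction with the largest chance correlation, exactly the
  degree-of-freedom the out-of-sample design removes.  The grand mean must
  lie within two Monte-Carlo SEs of zero (12 replicates).
- **Single-source recovery** (N=20, T=30000, SNR 1): the forward-model
  column correlates |r| ≥ 0.95 with the true topography, and component-1
  ISC matches the closed form λ²/(λ²+σ²) = 0.5 within 0.02.
- **Group contrast** (N=20+20, T=30000, gains 1.0 vs 0.4, 100 replicates):
  Welch's test on top-3 ISC sums rejects at α=0.05 with the correct
  direction in ≥95 % of runs.  The size check under equal gains uses 600
  replicates at a reduced cohort (N=10+10, T=4000) — under the null the
  test's level does not depend on cohort dimensions, and the larger
  replicate count brings the binomial Monte-Carlo SE (≈0.9 %) safely inside
  the ±2 % acceptance band.
- Tone/noise fixtures for the spectral stage; scripted tracks with known
  labels for the movement stage; brute-force enumeration and explicit
  least-squares oracles for every statistic.

## Statistics conventions

- Cohen's d uses the pooled-SD formula, reported alongside Welch's
  (unequal-variance, Satterthwaite-df) t statistic.
- The ANCOVA fits y ~ group + covariate with Type-II sums of squares; the
  group × covariate interaction is tested in a separate model, matching the
  common two-step reporting.  The eta-squared effect size defaults to
  SS_effect / (SS_effect + SS_error); an `observed_covariate` switch adds
  the covariate's SS to the denominator (the Olejnik–Algina observed-factor
  convention) for studies that treat the covariate as a measured factor.
- Kendall's tau-b is tie-corrected; the p-value is exact for n ≤ 8 without
  ties, asymptotic otherwise.
- The one-sample Wilcoxon signed-rank test is exact for n ≤ 25 (no tied
  magnitudes) and normal-approximated with continuity correction above;
  the effect size is r = |Z|/√n with Z always from the (tie-corrected)
  normal approximation, n the number of non-zero observations.
- The mixed model of windowed ISC uses movement label (baseline «neither»),
  clinical scores, and score × movement interactions as fixed effects, with
  per-subject random intercepts and, when estimable, per-subject movement
  slopes; fitting is statsmodels MixedLM (REML).  A failed random-slope fit
  falls back to intercepts only, logged.

## Movement annotation conventions

Displacement per limb class is the maximum over the limb's configured
keypoints (wrists+elbows / knees+ankles in BODY_25 indexing) and over all
detected people, using only keypoints with confidence ≥ 0.1 in both frames —
the max captures "any visible limb movement" when several people are on
screen.  Movement requires lower < d < upper with *strict* inequalities at
both thresholds (boundary displacements are not movement).  The thresholds
have no universal default: they scale with frame resolution and camera
motion and are explicit configuration.  Window labels take the modal
per-frame joint state; ties resolve deterministically as
both > arm > leg > neither, favouring sensitivity to motor content.

## I/O

EDF is read through MNE.  EDF writing is a minimal 16-bit writer (1 s data
records, microvolt units, subject id and group stored in the patient field);
round trips are exact up to the 16-bit quantization (~1e-4 relative).  The
delimited matrix format (rows = channels, TSV, JSON sidecar for rate/labels/
metadata) round-trips losslessly.  Keypoints follow the OpenPose per-frame
JSON layout (`people` → `pose_keypoints_2d` flat x,y,confidence triples,
BODY_25 ordering).  Readers validate instead of coercing: missing montage
channels and mixed sampling rates are hard errors naming the offending
files.

## Known limitations

- The alpha-power broadband reference is [0, fs/2]; a nominal "0–500 Hz"
  broadband at fs = 500 Hz is not representable and is clipped to Nyquist.
- The within-group ISC of a small group (N < 3) is undefined and rejected.
- ICA component selection uses a single frontal-difference proxy; lateral
  eye movements that cancel in the difference would need a different proxy
  (configurable).
- The EDF writer requires integer sampling rates and whole-second
  recordings.
- Statistical checks on synthetic cohorts characterize the pipeline's
  operating characteristics, not clinical effect sizes.
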
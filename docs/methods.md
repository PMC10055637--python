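# Methods

## Signal model and conditioning

Each channel is treated as a stationary stochastic process over the
whole recording.  Conditioning is deterministic and fixed in order:

1. **Notch** — second-order IIR notch at the 60-Hz line frequency,
   quality factor 35 (≈1.7 Hz wide), applied forward–backward so phase
   is untouched.  Recordings free of mains contamination can skip it
   (`line_freq=None`).
2. **Band-pass** — 4th-order Butterworth, forward–backward
   (zero-phase), with reflect-padding of roughly one impulse-response
   length to suppress startup transients.  The band is a searched
   hyperparameter, not a fixed rhythm.
3. **Unit-power normalisation** — mean removal followed by scaling to
   unit mean-square.  Done *last* so every encoder input has unit power
   regardless of how much energy the band-pass removed; this makes the
   whole pipeline invariant to per-channel gain.

No resampling is performed and no artifact rejection is attempted: the
method is designed to work on raw resting-state EEG.  A 0.1-Hz
acquisition high-pass is assumed to have been applied by the amplifier
and is not re-applied.

## LPC encoding

The conditioned channel is encoded by an order-*p* linear predictor
fitted by the autocorrelation method: biased autocorrelation (divide by
N, not N−k — this keeps the sequence positive semi-definite and the
recursion stable), then Levinson–Durbin.  The entire recording is one
analysis frame; with minutes of data, taper bias is negligible and the
method produces exactly one coefficient vector per channel.  The
feature vector is `(a₁ … a_p)` only: the prediction-error variance σ²
is excluded because unit-power normalisation makes overall gain
uninformative.  The resulting predictor is minimum-phase (all roots of
`1 − Σ a_k z^{−k}` strictly inside the unit circle), so the all-pole
spectrum is well defined everywhere.

Default order is 10, searchable over 2–30; the reduced default grid
uses orders {8, 12}, which bracket the number of pole pairs needed for
two oscillatory peaks plus a 1/f trend inside a restricted band.

## Affine-subspace index

Each cognitive class is modelled as the best-fit *k*-dimensional affine
flat of its training vectors — centroid plus the top-*k* principal
directions of the centred scatter.  The point-to-flat distance is the
norm of the residual after projecting onto the basis.  The
single-electrode index is `L = D₂/(D₁+D₂)` with `D₁` the distance to
the normal-class flat and `D₂` to the impaired-class flat, so **high
index = cognitively normal**; this orientation makes the correlation
with cognitive scores positive.  The degenerate `0/0` case maps to 0.5
by symmetry; exact membership of one flat maps to the corresponding
pole (0 or 1).  Electrode fusion is the geometric mean with an explicit
zero short-circuit (positive values averaged in log space), preserving
exact poles without epsilon flooring.

Per-class subspace dimensions may differ and are searchable 0–8
(default 3).  When a training class has only *m* vectors the requested
dimension is clamped to *m − 1*: a flat cannot use more directions than
its points span.  With very small classes (≲ 5 subjects) the class flat
overfits and held-out members of that class can score poorly — cohorts
should provide at least ~15 subjects per class.

## Training protocol

Groups come from a fixed score cutoff (MoCA < 26 ⇒ impaired; a score of
exactly 26 is normal) or from a median cut for continuous scores (below
the training-fold median ⇒ impaired-side).  Per electrode, every
(band, order, k) grid point is fitted and scored by the age-controlled
Spearman correlation between the training subjects' indices and their
cognitive scores (an AUC criterion is available via configuration).
Exact ties break to the lower order, then the lower band edge; electrode
selection ties break lexicographically.  The best `n_electrodes`
(default 8) electrodes by training correlation are kept.

Hyperparameter search and electrode selection happen **inside each
cross-validation fold**; nothing about a held-out subject — recording or
score — influences the model that scores it.  A fixed-montage mode
(`channels=` in `fit_leapd`) pins the electrode set instead of
re-selecting it per fold, for protocols where the montage is decided in
advance.

Because LPC features depend only on recordings, never on labels, they
are computed once per (channel, band) as autocorrelation sequences up to
the maximal order and shared across grid points, folds and label
shuffles (`FeatureCache`).  This is an exact optimisation, not an
approximation.

## Statistics

* **Partial Spearman** — all three vectors mid-rank transformed, then
  the first-order partial Pearson correlation; p from the t
  approximation with n − 3 df.
* **Dependent correlations** — Meng–Rosenthal–Rubin z for two
  overlapping correlations; Steiger's test could be swapped in but the
  two agree closely in this regime.
* **ROC/AUC** — mid-rank (Mann–Whitney) estimator, identical to
  pairwise counting with half-credit ties.
* **Rank-sum separation** — two-sided Wilcoxon rank-sum, exact for
  small tie-free samples, normal approximation with tie correction
  otherwise.
* **Regression** — OLS of score on index and on (index, index²); the
  nested comparison uses a 1-df chi-square likelihood-ratio test.
* **Randomization null** — the score column is permuted across subjects
  and the entire cross-validated pipeline (including the grid search)
  reruns per shuffle.
* **Spectral baselines** — Welch PSD with 2-s Hann segments at 50%
  overlap (0.5-Hz resolution); relative band powers over delta 1–4,
  theta 4–8, alpha 8–13, beta 13–30, gamma 31–100 Hz, and the
  alpha/theta log-spectral ratio.  p values are reported raw, without
  multiple-testing correction across channels.
* k-fold schemes stratify folds by group, default k ∈ {5, 10} with
  seeded independent shuffles per repeat; results aggregate as
  mean ± sd across repeats.  A balanced mode subsamples the majority
  class to equal group sizes before splitting.

## Synthetic cohort generator

Real cognitive-EEG cohorts are rarely shareable, so the generator
produces seeded surrogate cohorts carrying exactly the spectral
structure the method targets.  Per subject, a latent cognition score
`c ~ U[0, 1]` drives, on the 8 informative electrodes of a 16-channel
montage:

* a theta→alpha resonance whose peak moves linearly from 6.5 Hz (c = 0)
  to 10.5 Hz (c = 1) — an AR(2) resonator with pole radius 0.97, pole
  angle compensated so the spectral *peak* (not the pole) sits at the
  requested frequency; amplitude 1.5 × noise floor;
* a 20-Hz beta resonator whose amplitude grows from 0.4 to 1.2 × noise
  floor with `c`;
* a 1/f aperiodic background (exponent 1.0, realised by spectral
  shaping of white noise, log–log slope checked over 2–40 Hz) and unit
  white noise.

Non-informative channels carry background and noise only.  `c` maps to
a MoCA-like integer `round(10 + 20c)`; ages are uniform on 55–80 y and
independent of cognition by default (an `age_c_correlation` knob mixes
in an age–cognition confound for testing the partial correlation);
PD/control labels are assigned 2:1 independently of cognition, matching
the composition of a typical movement-disorders cohort with community
controls.  Defaults: 500 Hz, 160-s recordings.

The resonator and background amplitudes are calibrated once so that the
full pipeline operates in the high-performance regime (cross-validated
AUC ≥ 0.9) reported for real cohorts of this kind; the published
studies do not quantify their spectral effect size, so this is a
package-level calibration choice.  The generator deliberately omits
volume conduction, inter-channel correlation, artifacts (blinks, EMG),
nonstationarity and event-related activity.  Passing end-to-end tests
therefore demonstrates that the pipeline recovers a cognition-linked
spectral signature without leakage and collapses to chance when none
exists — not that it reaches any particular performance on clinical
recordings.

## Problem sizes and numerical choices

End-to-end checks run on a 120-subject cohort with 60-s recordings and
a reduced search grid (bands {4–14, 2–30, 13–30} Hz × orders {8, 12},
k = 3); null calibration of the effect-free generator uses ten
40-subject, 20-s cohorts.  These sizes put every quantity of interest
well away from its decision boundary while keeping a full run in the
minutes range on one CPU.  Determinism: all randomness flows through
`numpy.random.default_rng` seeds carried by `SyntheticSpec`, CV schemes
and the shuffling routines; refitting with identical inputs is
bit-identical.  Degenerate inputs (constant signals, empty classes,
constant covariates, single-class label sets) raise `ValueError` with
the offending quantity named rather than propagating NaNs.

## Known limitations

* The subspace model is linear; strongly curved class manifolds in LPC
  space would need more dimensions than small cohorts can support.
* The training correlation used for electrode selection is computed
  in-sample (on the training fold); it is an optimistic estimate and is
  never reported as performance.
* Variable-length recordings are accepted, but the biased
  autocorrelation of very short segments (≲ 2 s) is noisy at high
  orders; the truncation sweep quantifies this trade-off.
* Mixed-effects modelling of disease status and scalp-topography
  rendering are out of scope.
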
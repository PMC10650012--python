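# Methods

`sipemg` implements an end-to-end analysis for detecting fluid-swallowing
events and estimating per-sip fluid volume from two-channel surface EMG
(sEMG) of the infrahyoid muscles, together with a statistical simulator of
the underlying two-day drinking study so that every stage is testable
without human recordings.

## The study the simulator emulates

Eleven subjects are recorded on two days, with sensors on the right and
left sternohyoid, sampled at 2.2 kHz. Each subject-day contains 100 cued
events: 60 drinking sips (12 sips at each of 5, 10, 15, 20, 25 mL) and 40
non-drinking events (10 each of talking, coughing, saliva swallows, solid
swallows). The analysis questions are (a) can drinking events be separated
from the other four classes from a single channel, and (b) can sip volume
be estimated from the drinking bursts.

## Synthetic data model

Each event is an amplitude-modulated burst of band-limited Gaussian noise
under a Hann envelope, added to Gaussian baseline noise — the standard
interference-pattern surrogate for sEMG bursts. Class signatures control
duration, amplitude and carrier band:

| class  | duration (s)  | amplitude (a.u.) | band (Hz) | shape |
|--------|---------------|------------------|-----------|-------|
| drink  | 1.00 ± 0.15   | 1.00 × volume factor | 30–300 | single burst |
| saliva | 0.95 ± 0.18   | 1.05             | 30–300    | single burst |
| solid  | 1.20 ± 0.22   | 1.25             | 25–250    | single burst |
| cough  | 0.35 ± 0.08   | 2.20             | 60–450    | single burst |
| talk   | 1.80 ± 0.30   | 0.55             | 40–350    | train of 6 sub-bursts |

These values are free parameters of the simulator (no quantitative
class-conditional model is available to copy); they were chosen once to
make the classification hard but learnable: saliva and solid swallows
deliberately overlap drinking in duration, amplitude and band, while
coughing and talking are easier.

Sip volume `v` (mL) enters drinking bursts through two slopes:
amplitude × (1 + 0.04·v) and duration + 0.010·v s. A per-sip lognormal
amplitude jitter (sd 0.10) keeps single-sip estimation imperfect; with
these defaults the cross-validated single-feature ANN error lands in the
middle of the feasible range — clearly below the no-information floor
(√50 ≈ 7.07 mL for balanced volumes 5..25) and clearly above zero. Setting
both slopes to zero (`null_effect_params()`) produces volume-uninformative
bursts for null calibration.

Nuisance structure: a per-subject lognormal gain (sd 0.15), a per
subject-day lognormal drift gain (sd 0.12) that makes day-to-day transfer
harder than within-day cross-validation, and a fixed right/left gain ratio
of 1.15. Both channels of a session share one event schedule and
per-event burst parameters; carrier noise and baseline noise are
channel-specific. All randomness descends from one root seed via
`numpy.random.SeedSequence` spawn keys `(subject, day, side, role)`, so
identical seeds give bit-identical datasets.

What the simulator does **not** model: motor-unit physiology, electrode
placement and slippage, movement artifacts, mains interference,
non-stationary baselines, or correlated noise between channels. Passing
tests therefore demonstrate that the *pipeline* recovers structure it is
pointed at under controlled conditions — not that these effect sizes hold
in human data.

## Preprocessing

* Band-pass: Butterworth (design order 4), 10–400 Hz, applied zero-phase
  (forward-backward, `sosfiltfilt`). Zero-phase filtering avoids biasing
  envelope peak times.
* Envelope: full-wave rectification followed by a zero-phase Butterworth
  low-pass; tiny negative ringing is clipped to zero.
* Burst windows: for each annotated event the envelope maximum is located
  within ±1.5 s of the nominal event time, and a window of exactly
  `round(window_s · fs)` samples (default 2 s → 4400 samples) is cut from
  the **band-passed** signal, centered on the peak. Windows that straddle
  a recording edge are zero-padded and flagged; annotations outside the
  recording are skipped with a log entry. The window length is a config
  sweep parameter (0.1–2 s) and changes nothing but the segment length.

The envelope cutoff default is 1.5 Hz. This is a deliberate choice: the
peak of a second-long noise burst is only localizable to tens of
milliseconds when the envelope smoother suppresses rectified-noise ripple,
which requires a bandwidth near the reciprocal of the burst duration. At
a 5 Hz cutoff the detected peak wanders with median error ≈ 50 ms; at
1.5 Hz the median error is < 10 ms and ≥ 98% of drinking-event peaks fall
within 50 ms of the true burst center.

## The 26-feature catalog

One scalar per feature per window per channel; definitions are in the
`sipemg.features` module docstring. Numerical choices that the feature
names alone do not fix:

* **Thresholds** (ZC, WAMP, MYOP): multiples of the window RMS
  (0.05 / 0.5 / 0.5), making them invariant to overall amplitude scale
  across subjects and days.
* **PSD**: Welch, 256-sample symmetric-Hann segments, 50% overlap,
  zero-padded to a 2048-point FFT (1.07 Hz grid). The zero-padding gives
  the grid resolution the sinusoid calibration requires while keeping the
  short segments appropriate for 2 s windows.
* **Vector-valued families reduced to scalars**: AC is the first
  coefficient of an order-4 Yule-Walker AR model (Levinson-Durbin on the
  biased autocorrelation). LPCC is the mean of cepstral coefficients
  c1..c4 from the standard LPC→cepstrum recursion — the first cepstral
  coefficient alone is mathematically identical to the first LPC
  coefficient (c1 = a1), which would duplicate AC, so the mean over the
  model order is used instead. MFCC is the mean of coefficients 1..12
  (20 mel filters spanning 0–fs/2, log energies, orthonormal DCT-II) over
  256-sample frames with 50% overlap. ECDF is the mean of the empirical
  CDF at 10 equally spaced amplitudes.
* **Entropy** (amplitude-domain): Shannon entropy of the 64-bin histogram
  over the window's min–max range; distinct from the spectral entropy SE,
  which is normalized by log(#PSD bins) into [0, 1].
* **Degenerate inputs**: constant windows raise a degenerate-input error
  for spectral/model features (time-domain features remain defined);
  NaN/Inf samples are an input error. Batch extraction excludes failed
  windows with a log entry rather than poisoning the matrix.

Every feature is checked against an independently coded
direct-from-definition oracle (Toeplitz solve instead of Levinson, root-
based cepstrum instead of the recursion, explicit cosine-sum DCT, looped
Welch) to 1e-9 relative tolerance on randomized windows.

## Evaluation protocol

* **Classification**: drinking vs. all other events, five classifiers —
  SVC (RBF, C = 1), random forest (100 trees), 1-NN, LDA, QDA
  (reg_param = 1e-3; the catalog contains the exactly collinear pair
  WL/AAC, so an unregularized QDA would fail on that subset). Stratified,
  seeded 5-fold CV; features z-scored with training-fold statistics only;
  the score is the F1 of the drinking class (appropriate for the 60/40
  imbalance), averaged over folds.
* **Regression**: sip volume in mL from the 60 drinking rows, eight
  regressors — SVR, RF, 1-NN, linear regression, decision tree, lasso
  (α = 0.1), ridge (α = 1), and an MLP with hidden layers (36, 16) trained
  full-batch with L-BFGS (cap 2000 iterations, fixed seed, L2 penalty
  α = 0.5). The L2 penalty is sized for a ~700-parameter network fitted to
  ~50 sips: without it the network memorizes uninformative features and
  scores *above* the mean-predictor floor; with it the null-mode error
  sits at the floor while strong effects are still fit to < 2 mL. Targets
  are standardized on training folds for ANN and SVR and predictions
  back-transformed. Score: RMSE in mL.
* **Subset search**: exhaustive over sizes 1–3 (26 + 325 + 2600 = 2951
  sets); size 4 by greedy forward extension of the top-50 size-3 sets per
  cell (exhaustive behind a flag). Subsets are enumerated in lexicographic
  name order and the first optimum wins, making tie-breaks deterministic.
  Subject-specific best = per-cell argmax; global best = argmax of the
  across-subject mean score per (day, side, model, k).
* **Cross-day**: for each direction, the model is trained on all of one
  day's data per subject and side with that day's selected global feature
  set, and scored on the other day; both directions and their mean are
  reported.

## The fast search backend

The exhaustive search is ~650k fold-fits per model at study scale, where
generic estimator overhead (1–100 ms per fit) dominates. The search
therefore uses a vectorized backend with the same model definitions:
closed-form Gaussian discriminants batched over subsets (covariance
sub-matrices sliced from one full-catalog covariance per fold), shared
per-dimension distance tensors for 1-NN and the RBF kernel, an SMO solver
on precomputed kernels, and a JIT-compiled CART forest (Gini splits,
bootstrap, `sqrt` feature sampling; variance splits for regression).
Search-time forests use 25 trees — a screening size whose ranking noise
is small at n = 100 — while the estimator surface (`cv_classify`,
`cv_regress`, cross-day fits) keeps 100. Fold assignment and z-scoring
are byte-identical across backends; the test suite pins QDA and 1-NN to
exact agreement with the sklearn route, LDA/SVC to knife-edge tolerance,
and the forests to distributional agreement (their tree RNG streams
necessarily differ).

## Problem sizes used by the shipped runs

The test suite exercises 2-subject × 2-day studies with full 100-event
sessions (and dedicated larger draws where a property needs more bursts);
`scripts/acceptance.py` runs the full 11 × 2 × 2 design — 4400 events —
with the exhaustive k ≤ 3 classification search over all five
classifiers, the single-feature search over all eight regressors
(screening caps: 25-tree forests, 200 L-BFGS iterations for the ANN,
which its convergence at ~207 iterations makes nearly exact), and both
cross-day analyses, in roughly a quarter hour on one CPU.

## Known limitations

* Class-conditional burst statistics are invented; absolute F-scores and
  RMSEs on synthetic data are properties of the chosen effect sizes, not
  reproductions of human results.
* The greedy size-4 search is not guaranteed optimal (the exhaustive
  flag exists but costs ~5× the size-3 search).
* The JIT forest is an independent implementation of the same algorithm
  family as sklearn's; individual scores differ within forest-to-forest
  variability.
* Left/right channels are always analyzed separately; no fusion features
  are computed.
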
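# Methods

## Problem and model

During post-fracture mobility training a stiff knee joint is flexed
slowly until the patient's pain reaches the clinical training threshold
(level 3 on the 0–10 numerical rating scale).  The joint angle at that
moment — the maximum angle position, maxAP — is the quantity a
rehabilitation robot needs, and it changes from session to session.
The package estimates the maxAP indirectly: pain evokes unconscious
muscle contraction, predominantly of the knee extensors resisting
further flexion, so the pain state is detectable in surface EMG.  The
problem is cast as a binary classification per 250 ms window — windows
from the flexion phase (before the pain mark) are *painless*, windows
from the hold phase (after it) are *pain* — followed by change
detection on the pseudo-online decision stream: the joint angle at the
first window classified as pain is the maxAP estimate.

Pipeline stages:

1. **Preprocessing** — zero-phase Butterworth band-pass 20–450 Hz
   (4th order) plus a 50 Hz notch (2nd-order IIR, Q = 30), both applied
   forward–backward; trials are cut at the start/pain/end event marks.
2. **Features** — per 250 ms window (125 ms step), per channel:
   RMS, MAV, unbiased variance, waveform length; zero crossings and
   slope-sign changes with a noise guard ε = 0.005 mV; mean and median
   frequency of the raw one-sided periodogram (bins f_j = j·fs/N);
   RMS/variance/energy of the 8 terminal sub-bands of a 3-level db4
   wavelet-packet decomposition; sample entropy (m = 2,
   r = 0.2 × per-window SD, Chebyshev distance, self-matches excluded).
   33 values per channel, 132 per window over the four muscles.
3. **Classification** — cost-sensitive linear SVM
   (min ½ωᵀω + RC·Σ_{y=+1}ξ + C·Σ_{y=−1}ξ, pain = +1) or random forest
   (trees N_T, minimum leaf size N_L tuned by expected-improvement
   Bayesian optimisation).  Hyperparameters are chosen per subject by a
   double cross-validation: trials are partitioned into 4 sets of 2;
   each outer fold tests on one set and tunes on the other three via a
   3-fold inner rotation scored by
   T = 0.2·Acc_v + 0.2·Acc_o + 0.3·Pre_v + 0.3·Rec_v.
4. **Online detection** — the trained model scores windows causally;
   labels are smoothed by a causal majority vote (width 5 ≈ 0.75 s);
   the angle at the first smoothed pain window is the maxAP estimate.
   Bias = true maxAP − detected angle (positive ⇒ early, the safe
   direction).

## Parameters that matter

| Parameter | Default | Why |
| --- | --- | --- |
| window / step | 250 / 125 ms | enough samples (500 at 2 kHz) for spectral and entropy estimates while keeping an 8 Hz decision rate |
| ε (count guard) | 0.005 mV | suppresses noise-driven zero crossings at typical surface-EMG noise floors |
| SampEn m, r | 2, 0.2·SD | standard choices; r is per window so entropy is amplitude-invariant |
| wavelet, level | db4, 3 | 8 sub-bands of ~125 Hz width across the 0–1000 Hz band |
| CSVM grid | 2^−20 … 2^20 | full reference grid; `ClassifierSpec.desk_scale()` thins it to 2^−12 … 2^12 stride 4 for interactive runs |
| T weights | 0.2/0.2/0.3/0.3 | favours validation precision and recall over raw accuracies |
| RF search | N_T ∈ [10, 500], N_L ∈ [1, 50], 30 EI evaluations | desk-scale profile caps trees at 200 with 12 evaluations |
| smoothing width | 5 (causal) | removes isolated flips without adding more than ~0.6 s of latency |

## Design choices where the design was open

- **Acc_o in the T value** is the training accuracy of the model on its
  two optimisation sets.  It rewards parameter points that fit the
  training data, balancing the validation terms.
- **Feature scaling**: each feature is z-scored with training-fold
  statistics before the SVM (margin methods are scale-sensitive);
  forests are left unscaled.  Toggleable via `ClassifierSpec`.
- **Tie-breaking** in the grid argmax: smallest C, then smallest R —
  stronger regularisation and weaker asymmetry win ties.
- **Degenerate inner folds** (validation fold with one class, or a
  model that never predicts pain) have undefined precision/recall; such
  rotations are dropped from the T average, with a warning.  A
  candidate whose every rotation is degenerate is excluded.
- **ε guard** on the threshold counts uses absolute differences
  (|x_i − x_{i+1}| > ε); a literal signed reading would make the counts
  depend on sample order.  The signed form is available via
  `literal_eps=True`.
- **Window labels** are decided by the window's end time: a window
  straddling the pain mark is pain only once the mark has passed — the
  causal rule an online system must apply.
- **Smoothing** is a causal majority vote; a centred variant exists for
  retrospective analysis.  Ties vote painless so smoothing can never
  invent a detection.
- **Delayed detections** (first pain window at or after the pain mark)
  carry no bias value: the robot has already stopped at the maxAP, so
  the angle difference is structurally zero.  Bias means are taken over
  early trials; a mean that counts delayed trials as zero bias is
  reported alongside.

## Numerical choices

- The periodised wavelet-packet transform is exactly orthogonal only
  for even input lengths at every level; windows are zero-padded to the
  next multiple of 2^level (500 → 504 samples) so sub-band energies sum
  to the window energy to machine precision.
- Sample entropy follows the definition with all N−m+1 templates at
  dimension m and per-template normalisation 1/(N−m); when either match
  count is zero (including a constant window, where r = 0) the maximum
  resolvable entropy −ln(2/((N−m−1)(N−m))) is returned, flagged.
- Median frequency is the smallest periodogram bin at which cumulative
  power reaches half the total; an all-zero window yields flagged NaNs
  for both spectral moments.
- Marker times snap to the nearest sample; ties round down.

## The synthetic generator

No patient recordings ship with the package, so every stage is
validated on a seeded generator that reproduces the statistical
structure the pipeline assumes.  Per trial the joint angle ramps
linearly (default 10° → 70° over 12 s) and holds 5 s; a latent pain
level rises from 0 to 3 between the pain-onset angle (default 40°) and
the maxAP.  Each channel is band-limited Gaussian noise whose RMS
envelope is baseline + gain · drive, with extensor gains three times
flexor gains, and whose power shifts from a 150–450 Hz band toward a
20–150 Hz band as the drive rises (median frequency falls).  The drive
is the normalised pain level saturated at 85% of the ramp
(`envelope_saturation`): unconscious muscle contraction plateaus before
the joint reaches the angle at which the patient reports threshold
pain, reflecting the reaction delay between muscular response and
self-report.  A small 50 Hz mains component exercises the notch
filter.  Cohorts add per-subject
log-normal gain jitter and Gaussian pain-onset-angle jitter (robot-like:
per subject, not per trial).  A *healthy* profile scales gains to 10%
and disables the spectral shift; a *null* profile removes both effects
entirely for calibration runs.

Because the envelope saturates before the pain mark, late-flexion
windows are statistically indistinguishable from hold windows — so a
classifier trained on hold-vs-flexion labels starts firing slightly
early, which is exactly the early-detection behaviour the maxAP stage
quantifies.

What the generator does **not** emulate: motor-unit recruitment and
firing statistics, electrode artefacts and movement noise,
non-stationarity across trials (fatigue), inter-muscle crosstalk, and
patient-specific pain dynamics.  Passing the end-to-end checks
therefore shows the pipeline recovers the planted amplitude/spectral
structure under realistic SNR, not that the same accuracy would be
reached on clinical recordings.

## Problem sizes used in tests and the acceptance script

The unit suite uses shortened trials (1 kHz, 3–4 s flexion) purely to
keep the feedback loop fast; the acceptance layer runs the full-scale
study conditions: a 7-subject cohort, 8 trials each, 2 kHz, 12 s + 5 s
phases, with the desk-scale search spaces.  The type-I calibration uses
200 zero-effect cohorts of 5 subjects with short single trials: the
t-test's validity depends on the subject count, not the trial length.
The label-permutation control balances the classes by subsampling the
majority class per subject before permuting, so chance level is 0.5
rather than the class prior.

## Known limitations

- The linear-SVM cost grid search is exhaustive; the full 41×41 grid is
  expensive and mainly of reference value — the thinned grid selects
  essentially the same operating points on well-separated data.
- The Bayesian optimiser is a compact EI loop over an integer box; it
  is adequate for the 2-D RF search but is not a general-purpose
  optimisation library.
- Decision streams are recomputed from stored feature tables when
  available; scores are identical to re-extraction because features are
  deterministic in the window samples.
- No artifact rejection beyond the stated filters; recordings with
  electrode drop-outs should be cleaned upstream.
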
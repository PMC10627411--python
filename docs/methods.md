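# Methods

`bruganet` re-implements a screening pipeline for Brugada syndrome
(BrS): reduce a routine multi-lead ECG to one representative heartbeat
per lead, fuse the beats into a single vector, classify it with a small
dense neural network, and validate the classifier with the diagnostic
statistics a clinical study would report. Because the package is
developed and tested against synthetic cohorts, this note is explicit
about what the generator emulates, what the model assumes, and what the
passing test-suite does and does not demonstrate about real ECGs.

## Signal model and preprocessing

**Acquisition dialects.** Two instrument profiles are supported:
`claris` (2000 Hz sampling, 5 µV amplitude quantum) and `mortara`
(1000 Hz, 1 µV), plus a `synthetic` profile (500 Hz, 1 µV). Amplitudes
are held internally in millivolts as floats; quantization happens only
at the text-export boundary. The canonical classifier lead set is the
two recorded limb leads, derived lead III (L3 = L2 − L1, Einthoven),
and the six high-precordial chest leads — nine leads total, excluding
the unipolar limb leads, ordered (L1, L2, L3, V1…V6).

**Quality control.** Screening for unusable recordings is automated:
a record fails if any lead is flat for more than 2 s, saturates for 3
or more consecutive samples at ≥ 2.5 mV, carries broadband (> 40 Hz)
noise with RMS above 0.15 mV, or is shorter than 10 s. The thresholds
live in `QCPolicy` and were chosen to catch the generator's planted
pathologies while passing clean records with wide margin; on real data
they are starting points, not validated clinical criteria.

**R-peak detection.** A Pan–Tompkins-style energy detector: band-pass
5–25 Hz (2nd-order Butterworth, zero-phase), differentiate, square,
moving-window integrate (150 ms), find maxima separated by a 250 ms
refractory period, keep those above a two-pass adaptive threshold, then
refine each to the raw-signal extremum within ±40 ms. Amplitude
quantization can flatten the QRS apex into a plateau of tied maxima;
the refinement takes the plateau center rather than its first sample,
which matters for cross-platform agreement (below). Detection runs on
one fiducial lead — by default the dominant-R lead among (L2, V5, V6).

**Beat reduction.** Each R peak anchors a window from R − 300 ms to
R + 450 ms (the asymmetric split gives the ST segment and T wave more
room than the P wave). Windows overrunning the record are dropped; each
window subtracts the median of its first 80 ms as baseline. Outlier
beats are rejected against a pointwise-median template: Pearson
correlation < 0.90 or peak amplitude off by more than 2× either way;
the template is recomputed on survivors and all beats re-tested once.
At least 3 beats are always kept (the 3 best-correlated, with a warning
flag, if the rule would keep fewer). Accepted beats are averaged with
the arithmetic mean — the mean, not the median, attains the 1/√N noise
law that the tests verify; the median is used only for the screening
template. The average is low-passed (4th-order Butterworth, 90 Hz) and
interpolated onto a 150-sample 200 Hz grid with the R fiducial at
sample 60. The nine per-lead beats concatenated in canonical order give
the 1350-sample fused trace. No per-trace amplitude normalization is
applied by default: ST-elevation criteria are absolute-voltage criteria
(1 mm = 0.1 mV), so the classifier sees millivolts.

**Cross-platform invariance.** The same underlying signal digitized
through both dialects yields fused traces that agree to an RMS
deviation below 0.01 mV. The worst-case pointwise deviation is bounded
by fiducial alignment: the two platforms can place the R anchor up to
half a sample of the coarser rate apart (0.5 ms), and at the maximal
QRS slope of the synthetic beat (~0.06 mV/ms) that is ~0.04 mV. The
stated tolerance is therefore max |Δ| < 0.05 mV, rms < 0.01 mV; the
deviation is schedule-independent because noiseless beats average to
the same template regardless of the RR sequence.

## Synthetic cohorts

Beats are sums of Gaussian wavelets (P, Q, R, S, T) with per-lead
amplitudes following normal precordial R progression and deep right-
precordial S waves. BrS-positive patients add an ST perturbation on
V1–V3 only: a *coved* profile (J-point plateau descending into a
negative T-region lobe) or a *saddleback* profile (elevated J, dip,
positive late hump), both scaling linearly with the elevation
parameter, so zero elevation is exactly the negative morphology.
Records place beats at truncated-normal RR intervals (default
850 ± 40 ms within record, ±60 ms between patients; sinus rhythm only),
and add baseline wander (0.25 and 0.11 Hz sinusoids, 0.05 mV), 50 Hz
powerline interference (0.01 mV), white noise (0.02 mV), and artifact
beats (5% of beats, inverted or replaced by a broad motion lobe so they
decorrelate from the template). Everything is quantized to the target
dialect. All randomness derives from one `SeedSequence`, making cohorts
bit-reproducible.

Default cohort conditions: n = 200, prevalence 0.5, mean ST effect
0.3 mV (per-patient elevation ~ N(0.3, 0.075) truncated at 0, coved and
saddleback equally mixed). Tests and the acceptance script use 20 s
records (≈ 22 beats) rather than a full minute: beat averaging has
converged well before that, and the shorter records keep the suite
fast. One wave-amplitude jitter (lognormal, σ = 0.1) is shared across
leads per patient, which is physiologic (body habitus scales all leads)
and has a consequence for attribution noted below.

**What the generator does not emulate:** atrial fibrillation or any
non-sinus rhythm, conduction-disturbance phenotypes, drug
pharmacodynamics, respiration-modulated morphology, electrode-motion
transients longer than one beat, and — most importantly — the real
baseline BrS signature, which is by definition invisible to the eye and
of unknown shape. The effect knob is an abstraction: passing tests show
the pipeline recovers a V1–V3-localized ST-segment class difference of
0.3 mV under realistic noise, not that it detects clinical BrS.

## Classifier

Architecture (fixed depth): three hidden blocks of
[dense → additive Gaussian noise (training only) → ReLU → batch
normalization], then a dense unit with sigmoid output, read as the
probability ŷ of a positive sodium-channel-blocker response. The
implementation is self-contained numpy — forward, backprop through
batch normalization, Adam, decoupled weight decay — so inference is
exactly reproducible and the input gradient used for saliency is exact
(verified against finite differences).

Training defaults: widths 128/128/128, activation-noise σ 0.05, Adam
at 1e-3, batch 64, at most 200 epochs, early stopping on a stratified
10% slice with patience 20, binary cross-entropy, optional
inverse-frequency class weights, decoupled weight decay 1e-3 on dense
weights. Scaled-down widths (32 or 16) are used throughout the tests;
on the synthetic task they lose nothing measurable and train in
seconds.

**Ensembling and validation.** A 7-member ensemble trains one model
per stratified 7-fold complement; a patient's score is the member mean
(spread reported alongside). Held-out performance inside a training
cohort uses each member's own validation fold (out-of-fold scores).
Full independent validation uses leave-one-out: for each patient, a
fresh 7-fold ensemble trains on the other n − 1 and scores the held-out
patient; a stored certificate asserts the patient appeared in no
member's training split. Fold seeds derive deterministically from
(base seed, patient index).

**Small-cohort leave-one-out configuration.** For n ≲ 60,
`small_cohort_estimator()` disables early stopping (a few-patient
monitor slice is pure noise) and enables balanced class weights.
The weighting matters for a subtle reason: withholding a positive
lowers the training prevalence, and a prior-tracking model then scores
every held-out positive slightly lower than held-out negatives — a
systematic pessimistic bias that can push null-cohort leave-one-out AUC
far below 0.5 without any bug. Balanced weights pin the operating point
at 0.5 regardless of the withheld class, and disabling early stopping
prevents the model from collapsing onto the training prior. Under this
configuration, zero-effect cohorts give leave-one-out AUC ≈ 0.5
(0.47–0.55 over 10 validation seeds at n = 50), which is the package's
leakage detector.

## Diagnostic statistics

Decision threshold: the score cut maximizing Youden's
J = sensitivity + specificity − 1, with `score ≥ threshold` called
positive and the cut placed midway between adjacent distinct scores
(verified against an exhaustive scan); reports also include metrics at
a fixed 0.5. Sensitivity, specificity, PPV, NPV and accuracy come from
the confusion counts, with zero-denominator metrics reported as
undefined (NaN), never 0. AUC is the Mann–Whitney probability with
ties counted one half (midranks), equal by construction to the
trapezoidal area under the swept ROC curve, and equal to
(sens + spec)/2 for a binary rater. Confidence intervals use DeLong's
structural-components variance in the fast midrank formulation with a
normal approximation clipped to [0, 1]; the standard error agrees with
a 10,000-replicate stratified bootstrap within 10% on continuous
scores. Proportions are compared with a two-sided Pearson χ² *without*
continuity correction — the variant consistent with the reference
values the tests reproduce — or with an exact hypergeometric test using
two-tail doubling. A Student/Welch t-test utility covers continuous
cohort descriptors.

## Feature importance

Primary method: gradient saliency, the cohort mean of |∂ŷ/∂x| in
inference mode (noise off, batch norm frozen), averaged over ensemble
members before the absolute value so member-specific initialization
noise partially cancels. Cross-check: model-agnostic permutation
importance (AUC drop after shuffling a lead segment across patients).

Attribution needs a different training regime than classification,
provided by `attribution_estimator()` with inputs put through
`per_lead_standardize()`. The reasons, observed directly on this
architecture: (i) once the classes separate — which happens almost
immediately on a well-posed synthetic task — gradients vanish and the
first layer never rotates toward the informative positions, so the
input gradient of a quickly converged model mostly reflects its random
initialization; (ii) batch normalization makes the network invariant
to the scale of first-layer weight rows, so weight decay alone cannot
prune uninformative inputs. Strong activation noise (σ = 2) keeps
gradients flowing after separation, long training without early
stopping (500 epochs) lets the alignment accumulate, and strong weight
decay (3.0) removes what the noise does not re-grow. Standardization is
per lead segment — one shared scale per 150-sample block — which
equalizes lead voltage ranges without amplifying quiet positions (the
concatenation junctions sit near the quantization floor and would
otherwise be inflated to unit variance). Under this regime ~55–60% of
saliency mass falls inside the generator's perturbed ST windows and the
median junction weight sits at or below the global median. The mass is
not higher for a genuine reason: the generator's shared per-patient
amplitude jitter makes unaffected leads informative as a reference
baseline (an ST elevation is best read as a contrast against the
patient's own T-wave scale), so some cross-lead weight is optimal, not
an artifact — an L2-regularized linear probe on the same features
places 84–93% of its weight in the ST windows, bounding what perfect
attribution could show.

## Numerical and design choices

- Quantization: `round(mV·1000/q)·q/1000`; round-trip through a text
  export is exact for on-grid amplitudes and within half a quantum
  otherwise.
- Resampling uses zero-phase filtering plus linear interpolation so an
  exact 150-sample grid results from any native rate; upsampling from
  below 200 Hz must be requested explicitly.
- Outlier screening with fewer than 3 beats is refused; degenerate
  correlation (zero-variance beats) is treated as 1 when the beats are
  equal, else 0.
- All-identical scores make Youden's J degenerate (J = 0, warned);
  all-tied AUC comparisons make the DeLong variance 0 (warned).
- `ModelConfig` requires exactly three hidden widths; the depth is an
  architectural constant, not a knob.
- Stratified folds are re-drawn (up to 5 times) if a training split
  ever lacks a class; leave-one-out requires n ≥ 10.
- Problem sizes used by the test-suite and acceptance script — 200
  patients at 20 s per record for pipeline checks, 50 patients for the
  null calibration, widths 16–32 — are the package's scaled study
  conditions, chosen once; the full-scale configuration (one-minute
  records, widths of 128) is the default in the public API.

## Known limitations

- The two hidden limitations above (easy-task gradient collapse, BN
  scale invariance) mean gradient saliency from the *default* training
  configuration is close to uniform; use the attribution regime.
- The generator's class signal is injected only into V1–V3 ST
  segments; nothing is claimed about localization behavior under
  multi-region or rhythm-level class differences.
- Training reproducibility is bit-exact on one platform (pure numpy),
  but metrics — not parameters — are the documented contract across
  BLAS builds.
- The exact text-export layout of the clinical instruments is not
  public; the canonical layout here is the package's own, and WFDB or
  vendor formats are out of scope.
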
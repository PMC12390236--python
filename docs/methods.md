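# Methods

## Problem setting

Each examination of a Parkinson's disease (PD) patient yields a set of
30 s tri-axial recordings at 50 Hz — accelerometer and gyroscope, from a
smartphone held in the examined hand and an armband on the forearm —
for up to three exercises: (1) hands at rest, (2) arms extended
(postural), (3) pronation–supination. The targets are the clinician's
0–4 ratings of tremor, bradykinesia, stiffness and dyskinesia, and a
treatment-response scale (TRS) in [−4, 4] rated by both clinician and
patient (negative = parkinsonian symptoms, positive = dyskinesia, 0 =
optimal, on a 0.5 grid). The package regresses these targets from
engineered signal features and evaluates with class-balanced error
metrics, because severity classes are strongly imbalanced.

## Synthetic cohort model

No clinical recordings ship with the package; `pdsense.cohort` generates
a cohort with the statistical structure the analysis needs. All
randomness flows from a single integer seed through per-entity
`SeedSequence`-style keys, so a config reproduces its dataset exactly.

**Patients.** Age at baseline ~ N(62, 11.1²) years, years since
diagnosis ~ N(10.5, 6.1²) (clipped to physical ranges), handedness 90%
right, affected side {left 40%, right 45%, both 15%}, a treatment-group
label, and a latent trait severity per symptom drawn from the class
weights below. Examinations per patient follow 1 + NegBin matched to
mean 3.07 and sd 2.77.

**Severity weights** (classes 0–4): tremor (.30, .28, .22, .17, .03) —
the most balanced symptom; bradykinesia (.18, .35, .27, .15, .05) and
stiffness (.15, .40, .26, .14, .05) — level 1 modal; dyskinesia
(.55, .25, .12, .075, .005) — severe dyskinesia nearly absent. Exam
labels are the patient trait plus N(0, 0.7) jitter, rounded and clipped,
giving within-patient correlation with exam-to-exam fluctuation.

**TRS composition.** The latent state is `dyskinesia − mean(tremor,
bradykinesia, stiffness)`; clinician and patient values add independent
N(0, 0.5) observer noise, clip to [−4, 4] and round to 0.5 steps. The
equal weights and 0.5-grid are modeling choices — clinically the TRS is
a holistic judgment, not an algebraic function of the four ratings — but
they give the two poles the right meaning and keep clinician/patient
discrepancy purely observational.

**Signal model.** Each recording sums directed components in a body
frame, then applies a random device-orientation rotation (≤ 15°), adds
gravity (accelerometer only) and white sensor noise (sd 0.05 m/s²):

* *Tremor*: a sinusoid with per-recording frequency uniform in 4–6 Hz,
  amplitude 0.12 m/s² per severity unit, strongest at rest (factor 1.0),
  damped in the postural task (0.7) and amplitude-modulated during
  pronation–supination (0.4).
* *Voluntary pronation–supination* (exercise 3): an oscillation at
  1.5 − 0.18·bradykinesia Hz with amplitude 1.2·(1 − 0.15·bradykinesia)
  rad/s — bradykinesia slows and shrinks the movement monotonically.
* *Dyskinesia*: a smooth irregular 1–3 Hz process (band-passed noise)
  scaled by 0.05 m/s² per severity unit, multiplied by a lognormal
  expression factor shared across all recordings of an examination
  (σ = 0.8) plus per-recording variation (σ = 0.3) and a slow burst
  envelope. This models the episodic, medication-state-dependent nature
  of dyskinesia: a 30 s snippet underdetermines the rated severity, which
  is why dyskinesia is the hardest target — a structural property of the
  generator, not of any particular model.
* *Stiffness*: all motion components shrink by the factor
  (1 − 0.12·stiffness), reducing movement variability monotonically.
* *Postural sway* in exercises 2–3 gives stiffness something to shrink
  even in otherwise asymptomatic patients; it is absent at rest so a
  fully asymptomatic noise-free rest recording is constant.
* Symptoms express at 60% amplitude on the non-affected side.

Recording blocks (device × sensor × hand × exercise) drop independently
with probability 0.05, mimicking incomplete examinations.

What the generator does **not** emulate: medication cycles and diurnal
fluctuation, sensor drift/artifacts, inter-rater disagreement beyond
i.i.d. noise, harmonics and waveform asymmetry of real tremor, and any
correlation between symptoms beyond what the trait draws induce. Passing
end-to-end tests therefore shows the pipeline recovers *this* encoding
under realistic imbalance and noise — not clinical-grade accuracy.

## Preprocessing

4th-order Butterworth filters applied forward–backward (zero phase):
0.1 Hz high-pass for gravity removal on accelerometer channels only
(gyroscopes carry no gravity component), 20 Hz low-pass on everything
(PD motor content lies below 20 Hz; sampling is 50 Hz). The reflect
padding for the high-pass is extended to the full record length because
the 0.1 Hz corner has a multi-second impulse response. The magnitude
signal is computed from the filtered axes and is exactly invariant under
axis rotation, which motivates it: devices are not always worn in the
same orientation. Band decomposition uses a 3 Hz low-pass for 0–3 Hz and
band-passes for 3–9 and 9–14 Hz. The PSD estimator is Welch with 4 s
Hann segments at 50% overlap — consistent with the 4 s STFT windowing —
and satisfies Parseval within estimator error.

## Feature bank

Per recording, on each of X, Y, Z and M: 12 time-domain features, 8
frequency-domain features on each of the three bands plus the full
0–25 Hz spectrum (4 × 8 × 4 = 128), 5 statistics of the per-window mean
PSD from a 4 s / 2 s-hop STFT per band (80), 5 statistics each of
per-window value range and 16-bin amplitude-histogram entropy (40), and
mean/sd of the D1–D3 detail coefficients of a 3-level db10 DWT with
symmetric padding (24); plus 3 axis-pair Pearson correlations. Total:
323 named features, e.g. `Phone-ACC-#1/Left/Z/Spectral centroid (0-25 Hz)`.

Numerical conventions, chosen so tables are always finite:

* Skewness is the adjusted Fisher–Pearson coefficient; kurtosis is the
  population (biased) excess form — the two standard estimators are
  deliberately not harmonized, matching the formulas the bank
  implements.
* Approximate/sample entropy use m = 2, r = 0.2·sd, Chebyshev distance
  (the conventional defaults); both are 0 on constant or too-short
  input. The O(n²) pair scan is numba-compiled and computes both
  statistics in one pass.
* Band-limited frequency and STFT features restrict the Welch PSD /
  spectrogram to the band's bins rather than re-filtering the time
  signal: one FFT per channel, no filter edge effects, same energy view.
* Spectral centroid and weighted mean power weight by the PSD values;
  the weighted-mean-power denominator is Σfᵢ (not Σ power), implemented
  exactly as specified even though it is nonstandard.
* Zero-variance or zero-power inputs map skewness, kurtosis, centroid,
  WMP and correlations to 0; STFT skewness is 0 with fewer than 3
  windows; partial trailing windows are dropped.
* The windowed "entropy" is the Shannon entropy of a 16-bin amplitude
  histogram per 4 s window (an operational choice; the statistic is
  often cited without a concrete definition).
* A config switch drops the axis entropies, reducing the time-domain
  block from 48 to 42 — published counts for such banks vary (44 is
  sometimes quoted) and cannot be reconciled exactly; the block counts
  128/80/40/24/3 are treated as normative and asserted in tests.

Metadata features: one-hot affected side / handedness / group over fixed
vocabularies (unknown category → all-zero block), years since diagnosis
and age evaluated at examination time. Feature tables use a complete-case
policy per requested block set; dropped examinations are logged with the
reason. z-normalization is deliberately *not* part of table assembly: the
scaler lives inside each model pipeline and is fitted on the training
rows of the current fold only, avoiding leakage (where the statistics
were historically computed is ambiguous; fold-aware is the safe choice).

## Feature selection

Step 1 prunes correlated pairs: columns are scanned in canonical order
and a column is dropped when its |Pearson r| with any already-kept column
exceeds 0.97 (absolute correlation; the later column of a pair is the
one dropped; constant columns are kept since their correlation is
undefined). Step 2 ranks survivors by random-forest impurity importance —
the ranking forest uses sqrt-feature splits, which is orders of magnitude
faster on thousands of columns and changes only the ranking, not the
final retained set's validation — cuts to the top 60% (ceiling), and
walks the ranking greedily: a candidate is retained only if it *strictly*
improves 5-fold cross-validated R² (an epsilon is exposed). Selection can
run globally once, or nested inside each outer training fold; nesting is
the leak-free default in `cross_validate`, and the study pipeline uses
the global mode (with the greedy pass capped at the top 40 candidates)
for tractability.

## Models, validation, metrics

Random forest, XGBoost and RBF-kernel SVR at their library defaults, each
behind a fold-fitted standard scaler. Validation: shuffled 10-fold, and
leave-one-patient-out via grouped folds so no patient appears in both
train and test; every row is predicted exactly once. Metrics follow the
usual definitions; per-class errors discretize the *true* labels back to
their grid (integers for symptoms, 0.5 for TRS) while predictions stay
continuous, and bMAE/bMSE average the per-class errors over the classes
present. When the truth (or prediction) vector has zero variance, R² and
r are reported as NaN with a `degenerate` flag rather than a silent 0.
Out-of-range predictions are handled by clipping to the valid target
range as a post-processing step; metrics default to the unclipped values
(published figures show negative severity predictions, so clipping is
reported separately). Permutation importance uses R² scoring with 10
repeats by default.

## Study pipeline sizes

`pdsense.pipeline.run_study` uses 200 patients at generator defaults,
with recordings from both devices and both sensors on the examined
(right) hand for exercises 1 and 3 — the rest task carries tremor and
dyskinesia information, pronation–supination carries bradykinesia and
stiffness — and the greedy pass capped at 40 candidates. These sizes
keep a complete run (cohort → 2 594 features → selection → seven
cross-validated model evaluations) in the minutes range on one CPU while
exercising every stage. The qualitative findings it checks — tremor
learnable and more predictable than dyskinesia, combined devices at
least as good as either alone, grouped and random splits agreeing — are
properties of the study design the generator encodes, not of a
particular seed.

## Known limitations

* The synthetic severity encodings are cleaner than clinical reality;
  absolute R² values on synthetic data say nothing about clinical
  performance.
* The TRS composition rule is an assumption; only its poles and sign
  convention are anchored.
* SVR predictions are not deterministic across library versions (tree
  models are seeded explicitly).
* The correlation-pruning drop order is canonical-order greedy; other
  orders satisfy the same post-condition with different survivors.
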
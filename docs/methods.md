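# Methods

## Scope and model

The package implements a three-class (TE/SE/SY) constitutional
classifier from sentence-level vocal features, per sex. The
probability model is a two-stage composition: sparse per-class affine
scores η̂ₖ over 21 standardized acoustic features (L1-penalized
least squares on class indicators, one shared penalty), followed by a
multinomial logistic regression of the class on [age, η₁, η₂, η₃]
with SY as the reference category. The stages are deliberately kept
separate: the L1 stage handles the strong inter-feature correlation
of acoustic measurements (band powers, MFCCs and pitch statistics
overlap heavily in information), while the multinomial stage
calibrates the three scores and age into probabilities.

The assumptions worth stating explicitly: (i) the 21 features carry
whatever constitutional signal the voice has — the model is linear in
them; (ii) age affects features smoothly enough that a ±5-year moving
window captures it; (iii) within a sex, one model applies to all
subjects; (iv) the class indicator regression with squared loss is an
adequate scoring device even though the indicator is binary — the
multinomial stage re-calibrates any miscalibration of the scores.

## Feature extraction

Frames are 2048 samples with 50 % overlap (46.4 ms and 23.2 ms hop at
44.1 kHz); the power-of-two length avoids FFT zero padding. Frames
with RMS below −60 dBFS count as silent and are ignored by the pitch,
intensity and MFCC summaries; the speech span for reading speed runs
from the first to the last non-silent frame.

* **Pitch** — per-frame normalized autocorrelation, searched over
  60–400 Hz, with parabolic interpolation of the peak lag (without
  it the lag grid quantizes F0 by ~2 Hz at 300 Hz). A frame is voiced
  when the peak exceeds 0.45; a recording with no voiced frame is
  rejected rather than imputed.
* **Intensity** — frame RMS in dBFS (full scale = 1.0). No absolute
  calibration is attempted; only amplitude-relative statements are
  meaningful, and scaling a waveform by *a* shifts sI0 by exactly
  20·log₁₀(a) while leaving every other feature unchanged.
* **MFCC** — pre-emphasis 0.97, Hamming window, periodogram, 26
  triangular mel filters spanning 0 to Nyquist on the 2595·log₁₀(1 +
  f/700) scale, log energies floored at 1e−30, orthonormal DCT-II,
  coefficients 0–12 retained (c₀ kept as a loudness/spectral-mass
  summary). Averages run over non-silent frames so head/tail silence
  does not dilute the envelope summary.
* **Log power ratios** — per-frame periodogram power summed over the
  bins in [60, 240), [240, 960) and [960, 3840) Hz, averaged across
  frames *before* the ratios, so sLPR3 = sLPR1 + sLPR2 holds to
  floating precision. Band edges quantize to the 21.5 Hz bin grid:
  for ideal white noise the expected sLPR1 is log₁₀(9/33) ≈ −0.56
  rather than the continuous-band log₁₀(180/720) ≈ −0.60.
* **Reading speed** — syllable count (a configurable constant for the
  fixed sentence; default 18) divided by the detected speech span.
  The span is quantized to the frame grid, so silence padding can
  move the estimate by up to one window per side.
* The two repetitions of the sentence are averaged feature-wise
  (unweighted); per-utterance failures carry the utterance index in
  the error.

Deterministic by construction: identical samples give identical
features.

## Preprocessing

Exclusions are applied in a fixed order and each subject receives at
most one reason: underage (< 15 years) → TY label → multivariate
outlier → influential. The report partitions the removed ids.

**Outliers.** Adjusted outlyingness: for each of 250·p random
directions (differences of random data-point pairs, unit length,
seeded), every subject's projection is scored by its distance from
the median scaled by the medcouple-adjusted boxplot whisker on its
side; a subject's AO is the maximum over directions, and subjects
beyond the adjusted upper fence of the AO distribution are flagged.
The medcouple itself is the median of the kernel
h(xᵢ,xⱼ) = ((xⱼ−m)−(m−xᵢ))/(xⱼ−xᵢ) over pairs straddling the median,
with the sign-rule kernel for ties at the median (delegated to
statsmodels, which implements exactly this definition; the test suite
checks it against a brute-force enumeration). Fences use exponents
(−4, 3)·MC for right skew and (−3, 4)·MC for left skew, reducing to
Tukey's fences at MC = 0. Quartiles are linear-interpolation (type 7)
quantiles. Outlier detection runs within sex, matching the
sex-specific models downstream.

**Age standardization.** For a subject of age *a*, each feature is
centred/scaled by the mean/SD of training subjects within [a−5, a+5];
windows at the edges of the observed age range truncate to the data
available. Columns are then rescaled to overall mean 0, SD 1. The
tables (per integer age on the training grid, plus the final rescale
constants) are stored and applied unchanged to test subjects —
nearest grid age, with a warning outside the training range — so no
test information enters the transform. A known limitation: truncated
edge windows only attenuate, not remove, an age trend within the
outermost half-window ages; for trends of realistic size the residual
age correlation is negligible, but it is measurable when the trend
dwarfs the within-age variation.

**Influence screening.** For each one-vs-rest binary logistic fit,
hat values come from the IRLS-weighted design, standardized Pearson
residuals as rP/√(1−h), Cook's distance from the weighted leverage
form, and DFFITS as the standardized residual times √(h/(1−h)). A
subject exceeding |DFFITS| > 2√(p/n), h > 2p/n, |r| > 2 or Cook >
4/n in any of the three fits is excluded; the cutoffs are the
conventional ones and configurable. A fit with perfect separation is
skipped with a warning rather than contributing unstable flags.

## Fitting

λ is selected on a 100-point log grid from the pooled λ_max (the
smallest penalty that zeroes all three fits) down four decades.
Cross-validation is 10-fold, stratified by class and seeded; the loss
is the absolute error pooled over the three class indicators, and the
one-SE rule takes the largest λ whose mean CV loss is within one
standard error (across folds) of the minimum. The quadratic-loss L1
solver is scikit-learn's coordinate descent (objective rescaled so
that the penalty is λΣ|βⱼ| exactly); λ = 0 falls back to least
squares. On orthonormal designs the solution soft-thresholds the OLS
coefficients at λ/2, which the tests verify.

The multinomial stage is the Newton MLE (statsmodels) with the
reference category ordered first. Two degeneracies are handled
explicitly: constant input columns (scores fully shrunk to their
intercepts) are dropped and given zero coefficients; and when the
MLE diverges — quasi-complete separation, where the likelihood has
no finite maximizer — the model is refitted with a very light L2
stabilizer (ridge-penalized multinomial fit, C = 10³) and a warning.
Age enters in raw years; the bundled age coefficients (~0.004–0.017)
are on that per-year scale.

Classification is the softmax argmax over the two logits and the
zero reference logit (computed shift-invariantly, so large logits do
not overflow); exact ties resolve toward the earlier class in the
order TE, SE, SY. Reported percentages round half-up to one decimal,
matching the convention of the reference report (e.g. 20/64 →
31.3 %).

## Synthetic data

The cohort generator draws, per subject, a class label, an age
(normal, mean 47, SD 16, clipped to 15–85), and a feature vector
built in SD units as class shift + smooth age drift (linear +
quadratic in (age−45)/20) + correlated Gaussian noise (AR(1)-style
correlation ρ = 0.5 with an extra 0.65 block over the three band
ratios), then mapped to plausible raw scales (e.g. male sF0
120 ± 18 Hz). Defaults mirror the population the classifier targets:
class mix 43/24/33 (TE/SE/SY) for men, 35/28/37 for women, and weak
class shifts (≤ 0.3 SD on a few features, echoing the traditional
descriptions — TE loud and grave, SE calm and slow, SY fast and
high-pitched), because voice alone is a weak constitutional signal.
Planted outliers displace a chosen fraction of rows by a fixed number
of SDs along a random direction and are recorded in a ground-truth
sidecar. What the generator does **not** emulate: non-Gaussian
feature distributions, label noise in the clinical diagnoses,
recording-site effects, and the audio-to-feature measurement error
chain — so passing pipeline tests demonstrate the statistics of the
method, not clinical performance.

The audio generator synthesizes a jittered harmonic source (harmonics
to ~4 kHz, amplitudes rolled off at a configurable dB/octave tilt),
an amplitude envelope with raised-cosine edges and optional
syllable-rate modulation, a white-noise floor, and silent head/tail;
the two "repetitions" share all parameters and differ only in the
noise realization, exercising the two-utterance averaging contract.

## Problem sizes and tolerances

Stochastic tests run at sizes chosen to make their expectations
sharp while keeping the suite fast: the null multinomial fit at
n = 5000 (intercepts within 0.1 of log frequency ratios), parameter
recovery at n = 2000 (within 3 SE), outlyingness recall/false-flag
rates over 10 replicates of n = 500, p = 5 (recall ≥ 95 % at 8 SD,
false flags < 5 %), and pipeline accuracy checks on cohorts of
500–1500 subjects (null accuracy within 5 points of the
majority-class rate; > 80 % under 2-SD shifts on five features per
class). The full suite runs in well under a minute.

## Known limitations

* The exact estimators of the original feature-extraction chain
  (pitch tracker, MFCC filterbank variant) are not recoverable, so
  numerical equality with historical feature values is not claimed;
  the bundled coefficient tables make the *classifier* arithmetic
  exact.
* The adjusted-outlyingness direction search is stochastic; flags are
  reproducible only under a fixed seed.
* Standardization edge bias at the extremes of the training age range
  (see above).
* The reference model's selected-feature counts per class, as
  transcribed, differ from the counts quoted alongside the table in
  derived renderings of the source; the intercepts and all
  coefficients used in the worked examples are unambiguous.
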
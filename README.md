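# scvoice

Voice-based diagnosis of the Sasang constitution — the traditional
Korean medical typology that assigns people to the Tae-Eum (TE),
So-Eum (SE) or So-Yang (SY) type (the rare Tae-Yang type is excluded)
— from a short sentence recording. The package is aimed at
biostatisticians and clinical-informatics developers who need the
full measurement-to-classification chain: acoustic feature
extraction, cohort-level cleaning, model fitting, and the deployed
reference model's arithmetic, exactly reproducible.

## The method

**Features.** Each subject reads a fixed sentence twice (mono 16-bit
PCM WAV, 44.1 kHz). Every recording is framed into 2048-sample
windows (46.4 ms) with 50 % overlap, and 21 sentence-level features
are computed: mean and SD of the fundamental frequency (sF0, sFSTD),
mean and SD of frame intensity (sI0, sISTD), 13 frame-averaged MFCCs
(sMFCC0–12), reading speed in syllables/s (sSPD), and three base-10
log power ratios between the bands 60–240, 240–960 and 960–3840 Hz
(sLPR1–3, with sLPR3 = sLPR1 + sLPR2 by construction). The two
utterances' features are averaged.

**Preprocessing.** Subjects under 15 and TY-type subjects are
excluded; multivariate outliers are removed by projection-pursuit
adjusted outlyingness with medcouple-adjusted (skewness-aware)
boxplot fences; each feature is standardized by its moving mean/SD
over subjects within ±5 years of age and rescaled to overall mean 0,
SD 1; finally, influential observations (hat values, standardized
residuals, Cook's distance, DFFITS from one-vs-rest binary logistic
fits) are dropped.

**Classifier.** Stage 1 fits, per class *k*, an L1-penalized
least-squares regression of the class indicator on the standardized
features,

> η̂ₖ = β̂ₖ₀ + **x**ᵀ β̂ₖ ,

with one penalty λ shared across classes, chosen by 10-fold
cross-validated mean absolute error under the one-standard-error
rule. Stage 2 is a multinomial logistic regression on
**c** = [age, η₁, η₂, η₃] with SY as the reference class,

> log(π_l / π_SY) = γ_l0 + **c**ᵀ γ_l ,  l ∈ {TE, SE},

and the predicted type is the softmax argmax. Models are fitted per
sex. The coefficient tables of the deployed reference model (both
sexes, both stages) ship with the package.

## Worked example

Score a 50-year-old male subject whose 21 standardized features are
all zero (i.e. exactly average for his age) with the bundled
reference model:

```python
import numpy as np
from scvoice import load_published_model, compute_scores, class_probabilities, classify

score_model, mlr_model = load_published_model("male")
eta = compute_scores(score_model, np.zeros(21))
pi = class_probabilities(mlr_model, np.array([50.0, *eta]))
print("eta =", eta)            # eta = [ 0.31  -0.309  0.   ]
print("pi  =", np.round(pi, 4))  # pi  = [0.4435 0.2295 0.3271]
print("g   =", classify(pi))   # g   = TE
```

The scores at a zero feature vector are the stage-1 intercepts; the
probabilities combine them with the age term of the stage-2 logits
(TE logit −0.284 + 0.004·age + …), and the subject is called TE —
the most probable type for an acoustically average 50-year-old man.

An end-to-end run on synthetic data:

```bash
scvoice simulate cohort --n 600 --sex male --seed 1 --out cohort.csv --truth truth.json
scvoice run --config config.json            # train phase: preprocess + fit + evaluate
scvoice run --config config.json --phase test --test-csv test.csv
```

where `config.json` holds `{"cohort_csv": "cohort.csv", "out_dir":
"out", "sex": "male", "seed": 1}`. The train phase writes
`model.json`, the age-standardization tables (`norm.json`), an
exclusion report and training metrics; the test phase applies the
stored tables and model to held-out subjects and writes a confusion
matrix with accuracy and per-class sensitivity.

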
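# braingrid

Sublobar **brain-grid** analysis of tumour topography and seizure risk in
diffuse glioma (astrocytoma and oligodendroglioma, WHO grades 2–3).

Tumour-related epilepsy affects roughly three in four patients with diffuse
low-grade glioma, and *where* the tumour sits matters. This package
implements the sublobar lesion–symptom mapping workflow used to study that
question: binary tumour masks in template (MNI) space are discretized into a
coarse grid of **48 labelled sublobar cells**, each patient becomes a
48-dimensional binary *involvement* vector, and the per-cell association
between tumour involvement and seizures is scanned with logistic regression.
Group-normalised tumour *occurrence maps* and white-matter *tract-overlap*
summaries complete the picture. A synthetic-cohort generator with known
ground-truth effects makes the whole pipeline testable without patient data.

## The model

The grid divides a template bounding box by 3 mediolateral, 2
anteroposterior and 3 dorsoventral planes into cells labelled `AxCySz`
(axial A1–A4 right→left, coronal C1–C3 anterior→posterior, sagittal S1–S4
superior→inferior); A1/A2 lie in the right hemisphere, A3/A4 in the left.
For patient *i* and cell *c*, involvement is
`I_ic = 1{overlap(mask_i, c) > threshold}` (default threshold 0 mL).

Per cell, seizure association is the univariate logistic model

```
logit P(seizure_i) = β0 + β_c · I_ic
```

reported as an odds ratio `exp(β_c)` with a log-scale Wald 95% CI and a
nominal p-value (no multiplicity adjustment by default; Benjamini–Hochberg
behind a flag). Cells involved in fewer than `min_involved` patients are
excluded as degenerate; separated fits are flagged and withheld. Candidate
cells can then enter a multivariate model with confounders (sex, tumour
volume, border sharpness) by forward stepwise selection — entry by Rao
score test (`p_enter = 0.05`), conditional removal by likelihood-ratio test
(`p_remove = 0.10`). 2×2 effect measures (odds ratio, relative risk) use
the standard closed forms with log-scale Wald intervals.

An occurrence map for a patient group is the voxelwise fraction of the
group's masks covering each template voxel (values in [0, 1], normalised by
group size); tract profiles report mean/max occurrence and occupied
fraction within each of the 8 default bundles (IFOF, CST, UF, aSLF, pSLF,
AF, FAT, Ci).

## Worked example

```python
import numpy as np
from braingrid import TwoByTwo, odds_ratio, relative_risk, fit_logistic

# sex x seizure contingency from a 93-patient cohort:
# 49/9 men with/without seizures, 21/14 women
t = TwoByTwo(49, 9, 21, 14)
est = odds_ratio(t)
print(f"male sex OR {est.point:.2f} (95% CI {est.ci_low:.2f}-{est.ci_high:.2f}), p={est.p:.3f}")

# the same association through the logistic-regression route
x = np.r_[np.ones(58), np.zeros(35)]
y = np.r_[np.ones(49), np.zeros(9), np.ones(21), np.zeros(14)]
fit = fit_logistic(np.column_stack([np.ones(93), x]), y, names=["const", "male"])
print(f"logistic OR {np.exp(fit.params[1]):.4f}")

# diffuse (11/28) vs sharp (12/54) border seizure risk
print(f"diffuse-border RR {relative_risk(TwoByTwo(11, 17, 12, 42)).point:.2f}")
```

prints

```
male sex OR 3.63 (95% CI 1.36-9.68), p=0.010
logistic OR 3.6296
diffuse-border RR 1.77
```

Men carry ~3.6-fold seizure odds in this cohort; the closed-form 2×2 and
maximum-likelihood logistic routes agree to numerical precision, and a
diffuse tumour border carries ~1.8-fold seizure risk relative to a sharp
one (0.39/0.22 ≈ 1.78 when computed from the rounded percentages).

A full synthetic run, from simulation to scan:

```sh
braingrid simulate --n 93 --seed 0 --out sim/
braingrid run config.yaml        # grid → involvement → maps → scan → tracts
```

See `braingrid --help` for the individual stage subcommands
(`grid-export`, `involve`, `maps`, `scan`, `stepwise`, `tracts`,
`simulate`, `fixtures`, `validate`).

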
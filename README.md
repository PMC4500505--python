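# breathdx

Classification of exhaled-breath "smell-prints" for non-invasive screening of
neurodegenerative disease — Alzheimer's disease (AD), Parkinson's disease (PD)
and healthy controls (HC) — from two complementary readouts:

* **eNose sensor panels** — a 32-channel cross-reactive chemical sensor array
  measured in triplicate per subject. Replicates are aggregated by the
  per-sensor median, normalized per sensor to [0, 1], factorised by PCA, and
  classified by linear discriminant analysis (LDA) over the combined pool of
  raw sensor values and PC scores. Predictors are chosen by stepwise selection
  on the Akaike information criterion, and models are validated by
  leave-one-out cross-validation (LOOCV) and by cross-site transfer (fit on
  one study site, predict the other).
* **MCC-IMS peak tables** — ion-mobility-spectrometry analytes characterised
  by drift time (inverse reduced mobility, 1/K₀), retention time and peak
  intensity. Classification uses per-analyte optimal intensity thresholds
  (maximizing accuracy = (TP+TN)/(TP+FP+TN+FN)) and a greedy threshold-cascade
  decision tree. The package bundles the fixed four-analyte reference cascade
  (1-butanol P17 < 0.016 → PD; zP2 < 0.001 → AD; 2-methylfuran P47 < 0.036 →
  AD; P26 ≤ 0.001 → AD; else HC).

Group separation is quantified by the Mahalanobis distance between group
centroids,

```
MD(x, y) = √((x − y)ᵀ C⁻¹ (x − y))
```

with C⁻¹ the inverse covariance of the analysed data, mapped to a two-sided
normal p-value (MD > 1.96 ⇔ p < 0.05, MD > 2.58 ⇔ p < 0.01), plus a k-fold
cross-validation where k is the product of the group sizes and each fold
holds out one sample per group (the cross-validation value, CVV).

Validation statistics follow the conventions of diagnostic studies:
sensitivity/specificity with exact (Clopper–Pearson) binomial confidence
intervals and the continuity-corrected (Yates) χ² test of association.

Because no raw instrument data are distributable, `breathdx.synthetic`
generates eNose and IMS cohorts with planted, seed-reproducible class
structure so the entire pipeline is testable end to end (see
`docs/methods.md` for the generative model and its limitations).

## Worked example

Generate a 53-subject IMS cohort (21 AD / 16 PD / 16 HC) with an expected
tree misclassification fraction of 3/53, then evaluate the bundled reference
cascade:

```bash
breathdx simulate --kind ims --seed 3 --overlap 0.0566 --out peaks.csv
breathdx ims-eval --peaks peaks.csv --tree reference
```

```json
{
  "labels": ["AD", "HC", "PD"],
  "confusion": [[21, 0, 0], [0, 14, 1], [0, 2, 15]],
  "n": 53,
  "accuracy": 0.9433962264150944,
  "misclassified": 3
}
```

Three of 53 subjects are misclassified, an accuracy of 94% — rows of the
confusion table are the estimated class, columns the true class, so here one
PD subject was routed to HC and two HC subjects to PD.

The same statistics are available from Python. For a binary estimated-vs-true
cross-table (here 30/60 true AD recognised, 44/57 true HC recognised):

```python
>>> import numpy as np, breathdx as bx
>>> cm = bx.ConfusionMatrix(np.array([[30, 13], [30, 44]]), ["AD", "HC"])
>>> rep = bx.crosstab_report(cm, "AD")
>>> round(100 * rep["sensitivity"], 1), round(100 * rep["specificity"], 1)
(50.0, 77.2)
>>> round(rep["chi_square"], 2), rep["df"]
(8.17, 1)
>>> [round(100 * v, 1) for v in rep["sensitivity_ci"]]
[36.8, 63.2]
```

i.e. sensitivity 50.0% (95% CI 36.8–63.2), specificity 77.2%, and a Yates χ²
of 8.17 on 1 df: the eNose discriminates the groups well above chance even
though per-subject accuracy is modest.

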
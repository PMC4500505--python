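# Methods

This note documents the statistical procedures implemented in `breathdx`,
the choices made where the procedures are underdetermined, and what the
synthetic cohorts do and do not establish about real breath data.

## eNose pipeline

**Preprocessing.** Each subject contributes replicate (typically triplicate)
readings of a 32-channel sensor array. Replicates are aggregated by the
per-sensor **median** — robust to the heterogeneity of repeated
smell-prints — and each sensor column is normalized to [0, 1] by
`(x − min)/(max − min)`. Normalization is **per sensor across the analysed
cohort**: channels have heterogeneous response scales, and a single global
map would let one channel dominate. Constant columns map to 0 (not NaN) so
PCA/LDA never see non-finite values. Aggregation precedes normalization; the
reverse order would let a single outlying replicate set a sensor's range.
Whenever a training/test split exists (every LOOCV fold, every cross-site
transfer) the min/max are fit on training data only and test values are
clamped into [0, 1].

**Replicate handling in cross-validation.** Cross-validation can treat each
replicate as its own observation (`per="replicate"`, the default for the
eNose CLI — prediction totals are then subjects × replicates, e.g. 117 for a
37-subject triplicate cohort) or operate on per-subject medians
(`per="subject"`). The replicate-level interpretation matches the bundled
cross-table totals; it does treat replicates of one subject as independent,
which overstates the effective sample size — a caveat inherited from the
study design this package models.

**Predictor pool and LDA.** The normalized matrix is factorised by PCA
(numpy SVD of the centered data; components with eigenvalue below 10⁻¹⁰ of
the largest are dropped, so the score count never exceeds min(n − 1, p)).
The classifier draws from the combined pool of raw sensor columns
(`raw-1` … `raw-32`) and PC scores (`PC-1` …). The LDA uses a pooled
within-class covariance; prediction minimizes the Mahalanobis distance to
the class mean adjusted by the log prior, priors estimated from training
class frequencies. A singular pooled covariance (p can approach n inside
folds) is ridge-regularized with λ = 10⁻⁶ × mean diagonal, with a warning.

**Stepwise AIC selection.** Greedy forward (optionally forward–backward)
selection minimizing AIC = −2·ℓ + 2·k, where ℓ is the multinomial
log-likelihood of the LDA posterior class probabilities on the training data
and k counts g·d class-mean parameters, d(d+1)/2 covariance parameters and
g − 1 free priors (g classes, d predictors). The quadratic covariance term
makes the penalty grow fast, which keeps null (pure-noise) selections small:
empirically ≤ 2 of the >60 candidates in ≈98% of null cohorts. Ties break
toward the earlier pool position (lowest predictor index), so selection is
deterministic given the pool order. The selection cap is n − g − 1
predictors, keeping the pooled covariance estimable.

**Cross-validation.** LOOCV refits everything — normalization, PCA basis,
stepwise selection, LDA — inside every fold; the held-out observation is
normalized with the training min/max (clamped) and projected into the
training PCA basis. This is verified by corrupting a held-out sample and
checking its fold's fit is unchanged. Cross-site transfer fits once on the
training site and projects the test site the same way. An empty selection
falls back to predicting the training majority class.

## Mahalanobis group separation

The distance between two group centroids uses, by default, the covariance of
the **total analysed data** (a pooled within-group option is provided). The
total-covariance convention has a structural consequence worth knowing: for
two equal groups the between-group spread inflates C, so the centroid MD
saturates near 2 regardless of separation; with three groups, values
slightly above 2 indicate strong separation. The MD → p mapping is the
two-sided standard-normal tail p = 2(1 − Φ(MD)), which reproduces the
conventional cutoffs (1.96 ⇔ 0.05, 2.58 ⇔ 0.01). The computation solves the
linear system via Cholesky factorization rather than inverting C; singular
covariances are ridge-regularized (λ = 10⁻⁶ × mean diagonal) with a warning.

The CVV scheme enumerates all k = ∏ group-size tuples holding out one sample
per group and scores per-sample predictions (k × g predictions in total; the
default classifier is nearest-centroid, any fit/predict estimator is
accepted). Note that under a label-permutation null, cross-validated
accuracy sits slightly **below** chance (the usual finite-sample pessimism
of CV); tests compare against chance at the per-fold-set binomial scale.

## IMS thresholds and decision trees

**Single-analyte thresholds.** Candidate cuts are midpoints between
consecutive distinct sorted intensities plus sentinels beyond the data range
(the maximum-margin convention); both directions are scanned and the rule
maximizing accuracy is returned together with sensitivity, specificity, PPV,
NPV and accuracy. Ratios with zero denominators are reported as NaN, never 0.

**Tree induction.** Greedy cascade construction: at each node, the
(analyte, threshold, direction) maximizing the number of correctly
classified samples — the fired side becomes a leaf labelled by its majority
class, the remainder by its majority — with ties broken toward the lower
analyte index, then the lower threshold, then the `<` direction. Analytes
are not reused along the cascade. Stopping: purity, `max_depth`, or
`min_leaf`. Gini impurity is available as an alternative criterion. The
accuracy criterion is deliberate: it mirrors choosing "the threshold at
which the maximum number of samples is classified correctly", at the cost of
the known greediness of accuracy splits.

**Fixed reference cascade.** `breathdx.reference.REFERENCE_TREE` encodes the
four-analyte cascade with strict `<` comparisons at P17, zP2 and P47 and an
inclusive `≤` at P26 — the asymmetry is intentional and preserved.

## Validation statistics

Sensitivity and specificity are column-conditional rates of the
estimated-vs-true cross-table. Confidence intervals are **Clopper–Pearson
exact** intervals from the beta-quantile construction (with lower = 0 at 0
successes, upper = 1 at n successes); the exact interval — not Wilson or
normal-approximation — is the one that reproduces the bundled reference
bounds. The χ² test is the 2×2 **Yates continuity-corrected** statistic
(df = 1), floored at zero; again the corrected statistic, not the plain one,
matches the bundled reference values. Percentages are conventionally printed
to one decimal and statistics to two; JSON reports always carry full
precision.

## Synthetic cohorts

**eNose generator.** Per subject, replicate vectors are
baseline + group shift + site offset + independent Gaussian noise per
channel (defaults: baseline 10, noise sd 1, planted shifts 4 sd on a single
sensor). Site batch effects are additive per-sensor offsets, motivated by
the qualitative failure of cross-site model transfer that such offsets
produce. A single integer seed fully determines the cohort; noise is drawn
sequentially so outputs are byte-reproducible.

**IMS generator.** Intensities are planted from a threshold cascade. Each
clean sample routes to a leaf of its true class (multi-leaf classes choose a
leaf uniformly); the value at each node on the path sits strictly on the
required side of the cut. Band geometry, as fractions of each node threshold
t: expressed (below-cut) compounds at 0.5 t; unexpressed compounds of
**affected** classes at a partially depressed 1.4 t; the healthy/else class
at the full background 2.0 t; all bands have sd t/12, i.e. > 4 sd clear of
the cut and of each other. Intensities are truncated at 0 and clipped to the
correct side of the cut. Four uninformative analytes (uniform on [0, 0.05])
are added so induction has to find the signal.

The three-band geometry is what makes greedy tree induction exactly
recoverable at zero overlap: a perfect split exists at every stage, so the
first split lands on the cascade's first analyte inside the true gap and
resubstitution accuracy is 1.0. With a single shared above-cut band this
fails ~20–60% of the time — integer-accuracy greedy splits profitably cut
*inside* an exchangeable shared band — which is a property of greedy
induction, not a bug. The price of the three-band design is that the clean
synthetic cohort is *easier* than real breath data: in the zero-overlap
limit each signature analyte alone separates affected from healthy, whereas
real cohorts need the full cascade. Passing recovery tests therefore
establishes correctness of the machinery, not expected performance on real
IMS tables.

**Overlap.** `overlap` is the expected misclassification fraction of the
generating tree. A sample is a *decoy* with probability
q = min(1, overlap · g/(g − 1)); decoys draw their intensities from a
uniformly random class (possibly their own), so the expected
misclassification fraction equals `overlap` whenever overlap ≤ (g − 1)/g and
saturates at chance beyond (at overlap 1 the intensities are
label-independent, giving accuracy ≈ 1/g·Σ-weighted chance, e.g. 0.5 for two
equiprobable classes).

**Problem sizes.** Synthetic validation uses the cohort compositions the
pipeline is designed around: 53-subject IMS cohorts (21 AD / 16 PD / 16 HC),
30-subject two-group eNose cohorts for selection experiments, and 12-subject
three-group cohorts (k = 64 folds) for the CVV permutation null; recovery
rates are estimated over 100 seeded repetitions.

## Known limitations

* The synthetic generators emulate additive effects and Gaussian/uniform
  noise only: no sensor drift, no replicate autocorrelation, no heavy tails,
  no correlated analytes. Results on them bound machinery correctness, not
  field performance.
* Replicate-level cross-validation treats triplicates as independent.
* The MD → p normal mapping is a calibration convention, not a derived
  sampling distribution for centroid distances.
* Greedy accuracy-split trees are myopic; the induced cascade is not
  guaranteed optimal beyond the planted, separable setting.
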
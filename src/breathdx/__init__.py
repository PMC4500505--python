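"""breathdx: exhaled-breath classification for neurodegenerative disease.

Analysis pipeline for two complementary breath-volatolomics readouts:

* **eNose smell-prints** — 32-channel chemical-sensor panels classified by
  linear discriminant analysis over raw sensor values and PCA scores, with
  stepwise AIC predictor selection, leave-one-out cross-validation and
  cross-site model transfer (:mod:`breathdx.preprocess`,
  :mod:`breathdx.enose`);
* **MCC-IMS peak tables** — per-analyte optimal intensity thresholds and
  greedy threshold-cascade decision trees (:mod:`breathdx.ims`).

Group separation is quantified by the Mahalanobis distance between group
centroids with a two-sided normal significance mapping and a
product-of-group-sizes cross-validation (:mod:`breathdx.distance`);
validation statistics (sensitivity/specificity, exact binomial CIs, Yates
chi-square) live in :mod:`breathdx.metrics`.  Synthetic cohorts with planted
class structure (:mod:`breathdx.synthetic`) make every stage testable
without instrument data.
"""

from .distance import (
    CvvReport,
    MdResult,
    group_md,
    mahalanobis_distance,
    md_p_value,
    product_kfold_cvv,
)
from .enose import (
    CvReport,
    LdaClassifier,
    LdaModel,
    PredictorPool,
    cross_site_transfer,
    fit_lda,
    loocv,
    pca_scores,
    stepwise_select,
)
from .ims import (
    Analyte,
    DecisionTree,
    PeakTable,
    SeparationPower,
    ThresholdRule,
    TreeNode,
    best_threshold,
    evaluate_fixed_tree,
    induce_tree,
    separation_power,
)
from .metrics import (
    ConfusionMatrix,
    ProportionCI,
    ValidationError,
    crosstab_report,
    exact_binomial_ci,
    sens_spec,
    yates_chi_square,
)
from .preprocess import (
    SampleRecord,
    SensorMatrix,
    aggregate_replicates,
    normalize_unit_range,
    observation_table,
    read_enose_csv,
    write_enose_csv,
)
from .synthetic import CohortSpec, EffectModel, generate_enose_cohort, generate_ims_cohort
from . import reference

__version__ = "0.1.0"

__all__ = [
    "Analyte", "CohortSpec", "ConfusionMatrix", "CvReport", "CvvReport",
    "DecisionTree", "EffectModel", "LdaClassifier", "LdaModel", "MdResult",
    "PeakTable", "PredictorPool", "ProportionCI", "SampleRecord",
    "SensorMatrix", "SeparationPower", "ThresholdRule", "TreeNode",
    "ValidationError", "aggregate_replicates", "best_threshold",
    "cross_site_transfer", "crosstab_report", "evaluate_fixed_tree",
    "exact_binomial_ci", "fit_lda", "generate_enose_cohort",
    "generate_ims_cohort", "group_md", "induce_tree", "loocv",
    "mahalanobis_distance", "md_p_value", "normalize_unit_range",
    "observation_table", "pca_scores", "product_kfold_cvv",
    "read_enose_csv", "reference", "sens_spec", "separation_power",
    "stepwise_select", "write_enose_csv", "yates_chi_square",
]
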
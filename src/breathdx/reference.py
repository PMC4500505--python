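"""Bundled reference objects: published cross-tables and the fixed IMS tree.

These small constants let validation statistics be recomputed without any
raw instrument data:

* the four AD-vs-HC cross-tables (estimated rows x true columns) from the
  two study sites — per-site leave-one-out cross-validations and the two
  cross-site transfers;
* the fixed four-analyte IMS threshold cascade (1-butanol P17, zP2,
  2-methylfuran P47 and the unidentified peak P26) that separates PD, AD
  and HC;
* the IMS cohort composition (21 AD, 16 PD, 16 HC = 53 subjects).
"""

from __future__ import annotations

import numpy as np

from .ims import DecisionTree, TreeNode
from .metrics import ConfusionMatrix


def _cm(counts, labels=("AD", "HC")) -> ConfusionMatrix:
    return ConfusionMatrix(np.array(counts), list(labels))


#: LOOCV cross-table, Marburg site (rows estimated, cols true; AD, HC).
MARBURG_LOOCV = _cm([[30, 13], [30, 44]])

#: LOOCV cross-table, Bonn site.
BONN_LOOCV = _cm([[44, 15], [19, 33]])

#: Model fit on Bonn, applied to Marburg subjects.
BONN_TO_MARBURG = _cm([[34, 29], [26, 28]])

#: Model fit on Marburg, applied to Bonn subjects.
MARBURG_TO_BONN = _cm([[48, 26], [15, 22]])

CROSS_TABLES = {
    "marburg_loocv": MARBURG_LOOCV,
    "bonn_loocv": BONN_LOOCV,
    "bonn_to_marburg": BONN_TO_MARBURG,
    "marburg_to_bonn": MARBURG_TO_BONN,
}

#: The fixed four-analyte threshold cascade: intensities below 0.016 on
#: P17 (1-butanol) identify PD; among the rest, zP2 below 0.001 flags AD;
#: then P47 (2-methylfuran) below 0.036 flags AD; then P26 at or below
#: 0.001 flags AD; everything else is HC.  Note the inclusive comparison
#: at P26, unlike the strict cuts at the other three nodes.
REFERENCE_TREE = DecisionTree(
    nodes=[
        TreeNode(analyte="P17", threshold=0.016, op="<", class_if_true="PD"),
        TreeNode(analyte="zP2", threshold=0.001, op="<", class_if_true="AD"),
        TreeNode(analyte="P47", threshold=0.036, op="<", class_if_true="AD"),
        TreeNode(analyte="P26", threshold=0.001, op="<=", class_if_true="AD"),
    ],
    else_class="HC",
)

#: IMS study cohort composition (53 subjects).
IMS_COHORT_SIZES = {"AD": 21, "PD": 16, "HC": 16}

#: eNose cohort sizes per site (AD/HC classification arms).
ENOSE_COHORT_SIZES = {
    "Marburg": {"AD": 18, "HC": 19},
    "Bonn": {"AD": 21, "HC": 16},
}
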
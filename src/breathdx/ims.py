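"""MCC-IMS peak-table classification: thresholds and decision trees.

Ion-mobility spectrometry coupled to a multi-capillary column characterises
each analyte by its drift time (the inverse reduced mobility 1/K0), its
chromatographic retention time and a peak intensity proportional to
concentration.  At the peak-table level, classification works by simple
intensity thresholds:

* per-analyte *separation power* — the best single cut-point maximizing
  accuracy = (TP + TN) / (TP + FP + TN + FN), reported with sensitivity,
  specificity, PPV and NPV;
* a greedy *decision tree* that at each node peels off the class best
  separated by a single (analyte, threshold) rule, so multi-class structure
  is captured by the sequence of thresholds rather than any one analyte.

Candidate thresholds are midpoints between consecutive distinct sorted
intensities (maximum-margin convention) plus sentinels beyond the data
range.  The split criterion is the raw count of correctly classified
samples; Gini impurity is available as an option.  Ties break toward the
lower analyte index, then the lower threshold, so induction is
deterministic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import ConfusionMatrix, ValidationError

_OPS = {
    "<": np.less,
    "<=": np.less_equal,
    ">": np.greater,
    ">=": np.greater_equal,
}


@dataclass
class Analyte:
    """A named IMS peak with its drift-time and retention-time coordinates."""

    peak_id: str
    name: str | None = None
    drift_time: float | None = None      # inverse reduced mobility, Vs/cm^2
    retention_time: float | None = None  # seconds

    def __post_init__(self) -> None:
        if self.drift_time is not None and self.drift_time <= 0:
            raise ValidationError(f"{self.peak_id}: drift time must be positive")
        if self.retention_time is not None and self.retention_time < 0:
            raise ValidationError(f"{self.peak_id}: retention time must be >= 0")


@dataclass
class PeakTable:
    """Samples x analytes intensity matrix with group labels."""

    analytes: list[Analyte]
    intensities: np.ndarray
    labels: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        n, m = self.intensities.shape
        if n != len(self.labels) or n != len(self.sample_ids):
            raise ValidationError("intensity rows do not match sample labels/ids")
        if m != len(self.analytes):
            raise ValidationError("intensity columns do not match analyte list")
        ids = [a.peak_id for a in self.analytes]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate peak ids")
        if np.any(self.intensities < 0):
            raise ValidationError("peak intensities must be non-negative")

    @property
    def peak_ids(self) -> list[str]:
        return [a.peak_id for a in self.analytes]

    def column(self, peak_id: str) -> np.ndarray:
        try:
            j = self.peak_ids.index(peak_id)
        except ValueError as exc:
            raise ValidationError(f"analyte {peak_id!r} not in table") from exc
        return self.intensities[:, j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.intensities, columns=self.peak_ids)
        df.insert(0, "group", self.labels)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   analytes: list[Analyte] | None = None) -> "PeakTable":
        peak_cols = [c for c in df.columns if c not in ("sample_id", "group")]
        if analytes is None:
            analytes = [Analyte(peak_id=c) for c in peak_cols]
        return cls(
            analytes=analytes,
            intensities=df[peak_cols].to_numpy(dtype=float),
            labels=[str(g) for g in df["group"]],
            sample_ids=[str(s) for s in df["sample_id"]],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, analyte_csv=None) -> "PeakTable":
        analytes = None
        if analyte_csv is not None:
            meta = pd.read_csv(analyte_csv)
            analytes = [
                Analyte(
                    peak_id=str(r.peak_id),
                    name=None if pd.isna(r.name) else str(r.name),
                    drift_time=None if pd.isna(r.drift_1K0) else float(r.drift_1K0),
                    retention_time=None if pd.isna(r.retention_s) else float(r.retention_s),
                )
                for r in meta.itertuples()
            ]
        return cls.from_frame(pd.read_csv(path), analytes=analytes)


# ---------------------------------------------------------------------------
# Single-analyte threshold rules
# ---------------------------------------------------------------------------

@dataclass
class ThresholdRule:
    """Binary rule: positive class on one side of a cut on one analyte."""

    analyte: str
    threshold: float
    direction: str                 # 'below' or 'above': side of the positive class
    classes: tuple[str, str]       # (positive, negative)

    def apply(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        pos, neg = self.classes
        if self.direction == "below":
            mask = values < self.threshold
        elif self.direction == "above":
            mask = values >= self.threshold
        else:
            raise ValidationError("direction must be 'below' or 'above'")
        return np.where(mask, pos, neg).astype(object)


@dataclass
class SeparationPower:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float


def separation_power(confusion: ConfusionMatrix,
                     positive_class: str | None = None) -> SeparationPower:
    """Sensitivity, specificity, PPV, NPV and accuracy of a 2x2 cross-table.

    Accuracy = (TP + TN) / (TP + FP + TN + FN).  Any ratio with a zero
    denominator is reported as ``nan``.
    """
    if positive_class is None:
        positive_class = confusion.labels[0]
    tp, fp, fn, tn = confusion._binary(positive_class)

    def ratio(a: int, b: int) -> float:
        return a / b if b > 0 else math.nan

    return SeparationPower(
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
        accuracy=ratio(tp + tn, tp + fp + tn + fn),
    )


def _candidate_thresholds(values: np.ndarray) -> np.ndarray:
    """Midpoints of consecutive distinct sorted values plus outer sentinels."""
    v = np.unique(values)
    mids = (v[:-1] + v[1:]) / 2.0
    span = (v[-1] - v[0]) or 1.0
    return np.concatenate([[v[0] - 0.5 * span], mids, [v[-1] + 0.5 * span]])


def best_threshold(
    table: PeakTable, analyte: str, positive_class: str
) -> tuple[ThresholdRule, SeparationPower]:
    """Exhaustive best single cut for one analyte (one class vs the rest).

    Scans every candidate threshold in both directions and returns the rule
    maximizing accuracy; ties resolve to direction 'below' then the lower
    threshold, deterministically.
    """
    values = table.column(analyte)
    y = np.asarray(table.labels)
    pos_mask = y == positive_class
    if pos_mask.all() or not pos_mask.any():
        raise ValidationError("both classes must be represented")
    others = sorted(set(y[~pos_mask].tolist()))
    neg_label = others[0] if len(others) == 1 else "rest"
    n_pos = int(pos_mask.sum())
    n = len(y)

    best_rule, best_acc = None, -1.0
    for direction in ("below", "above"):
        for thr in _candidate_thresholds(values):
            if direction == "below":
                pred_pos = values < thr
            else:
                pred_pos = values >= thr
            correct = int(np.sum(pred_pos & pos_mask)) + int(
                np.sum(~pred_pos & ~pos_mask)
            )
            acc = correct / n
            if acc > best_acc + 1e-12:
                best_acc = acc
                best_rule = ThresholdRule(analyte, float(thr), direction,
                                          (positive_class, neg_label))
    tp = int(np.sum((best_rule.apply(values) == positive_class) & pos_mask))
    pred_pos = best_rule.apply(values) == positive_class
    fp = int(np.sum(pred_pos & ~pos_mask))
    fn = n_pos - tp
    tn = n - n_pos - fp
    cm = ConfusionMatrix(np.array([[tp, fp], [fn, tn]]),
                         [positive_class, neg_label])
    return best_rule, separation_power(cm, positive_class)


# ---------------------------------------------------------------------------
# Decision trees (ordered threshold cascade)
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    analyte: str
    threshold: float
    op: str                 # one of '<', '<=', '>', '>='
    class_if_true: str

    def fires(self, value: float | np.ndarray):
        return _OPS[self.op](value, self.threshold)


@dataclass
class DecisionTree:
    """Ordered cascade of threshold nodes with a final else class.

    Each sample is routed through the nodes in order; the first node whose
    comparison holds assigns its class, and samples failing every node get
    ``else_class``.  Analytes along the cascade are distinct.
    """

    nodes: list[TreeNode]
    else_class: str

    def __post_init__(self) -> None:
        ids = [n.analyte for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValidationError("analytes on a tree path must be distinct")
        for n in self.nodes:
            if n.op not in _OPS:
                raise ValidationError(f"unknown comparison {n.op!r}")

    @property
    def analytes(self) -> list[str]:
        return [n.analyte for n in self.nodes]

    @property
    def classes(self) -> list[str]:
        return sorted({n.class_if_true for n in self.nodes} | {self.else_class})

    def classify_table(self, table: PeakTable) -> np.ndarray:
        missing = [a for a in self.analytes if a not in table.peak_ids]
        if missing:
            raise ValidationError(f"table lacks tree analytes: {missing}")
        n = len(table.labels)
        out = np.array([self.else_class] * n, dtype=object)
        unassigned = np.ones(n, dtype=bool)
        for node in self.nodes:
            fired = node.fires(table.column(node.analyte)) & unassigned
            out[fired] = node.class_if_true
            unassigned &= ~fired
        return out

    def classify_sample(self, values: dict[str, float]) -> str:
        for node in self.nodes:
            if node.fires(values[node.analyte]):
                return node.class_if_true
        return self.else_class

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "nodes": [
                {"analyte": n.analyte, "threshold": n.threshold,
                 "comparison": n.op, "class_if_true": n.class_if_true}
                for n in self.nodes
            ],
            "else_class": self.else_class,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionTree":
        nodes = [TreeNode(x["analyte"], float(x["threshold"]),
                          x["comparison"], x["class_if_true"])
                 for x in d["nodes"]]
        return cls(nodes=nodes, else_class=d["else_class"])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "DecisionTree":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def evaluate_fixed_tree(table: PeakTable, tree: DecisionTree) -> ConfusionMatrix:
    """Route every sample through a fixed tree; estimated-vs-true counts."""
    predicted = tree.classify_table(table)
    classes = sorted(set(tree.classes) | set(table.labels))
    return ConfusionMatrix.from_predictions(list(predicted), list(table.labels),
                                            classes)


def _split_score(mask_true: np.ndarray, y: np.ndarray,
                 criterion: str) -> tuple[float, str, str]:
    """Score of a candidate node: leaf on the fired side, majority else side.

    Returns (score, leaf_class, else_majority).  For 'accuracy' the score is
    the number of correctly classified samples when the fired side becomes a
    majority-labelled leaf and the remaining side is labelled by its
    majority; for 'gini' the (negated) weighted impurity.
    """
    y_true = y[mask_true]
    y_false = y[~mask_true]
    if len(y_true) == 0 or len(y_false) == 0:
        return (-np.inf, "", "")

    def majority(arr):
        vals, counts = np.unique(arr, return_counts=True)
        # deterministic: ties to lexicographically first label
        order = np.lexsort((vals, -counts))
        return vals[order[0]], int(counts[order[0]])

    leaf_class, leaf_correct = majority(y_true)
    else_class, else_correct = majority(y_false)
    if criterion == "accuracy":
        return (float(leaf_correct + else_correct), leaf_class, else_class)
    if criterion == "gini":
        def gini(arr):
            _, c = np.unique(arr, return_counts=True)
            p = c / len(arr)
            return 1.0 - float(np.sum(p**2))
        w = (len(y_true) * gini(y_true) + len(y_false) * gini(y_false)) / len(y)
        return (-w, leaf_class, else_class)
    raise ValidationError("criterion must be 'accuracy' or 'gini'")


def induce_tree(
    table: PeakTable,
    max_depth: int | None = None,
    min_leaf: int = 1,
    criterion: str = "accuracy",
) -> DecisionTree:
    """Greedy threshold-cascade induction.

    At each node the (analyte, threshold, direction) maximizing the number of
    correctly classified samples (one-vs-rest: the fired side becomes a leaf
    labelled by its majority class) is chosen; ties break toward the lower
    analyte index then the lower threshold.  The remaining samples are
    recursively partitioned until purity, ``max_depth`` or ``min_leaf``.
    """
    y_all = np.asarray(table.labels)
    if len(set(y_all.tolist())) < 1:
        raise ValidationError("empty table")
    nodes: list[TreeNode] = []
    active = np.ones(len(y_all), dtype=bool)
    used: set[str] = set()
    while True:
        y = y_all[active]
        classes = set(y.tolist())
        if len(classes) == 1:
            return DecisionTree(nodes=nodes, else_class=y[0])
        if max_depth is not None and len(nodes) >= max_depth:
            break
        best = None  # (score, j, thr, op, leaf_class)
        for j, pid in enumerate(table.peak_ids):
            if pid in used:
                continue
            values = table.intensities[active, j]
            for thr in _candidate_thresholds(values):
                for op in ("<", ">="):
                    fired = _OPS[op](values, thr)
                    if fired.sum() < min_leaf or (~fired).sum() < min_leaf:
                        continue
                    score, leaf_class, _ = _split_score(fired, y, criterion)
                    cand = (score, -j, -thr, op == "<")
                    if best is None or cand > (best[0], -best[1], -best[2],
                                               best[3] == "<"):
                        best = (score, j, float(thr), op, leaf_class)
        if best is None or not np.isfinite(best[0]):
            break
        score, j, thr, op, leaf_class = best
        pid = table.peak_ids[j]
        values = table.intensities[:, j]
        fired_global = _OPS[op](values, thr) & active
        nodes.append(TreeNode(pid, thr, op, leaf_class))
        used.add(pid)
        active &= ~fired_global
        if not active.any():
            break
    # label remaining samples by their majority class
    y = y_all[active] if active.any() else y_all
    vals, counts = np.unique(y, return_counts=True)
    order = np.lexsort((vals, -counts))
    return DecisionTree(nodes=nodes, else_class=str(vals[order[0]]))
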
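"""IMS peak-table thresholds, separation power, and decision trees."""

import math

import numpy as np
import pytest

from breathdx import (
    Analyte,
    ConfusionMatrix,
    DecisionTree,
    PeakTable,
    TreeNode,
    ValidationError,
    best_threshold,
    evaluate_fixed_tree,
    induce_tree,
    separation_power,
)
from breathdx.reference import REFERENCE_TREE


def _table(intensities, labels, peak_ids=None):
    intensities = np.atleast_2d(np.asarray(intensities, float))
    if intensities.shape[0] == 1:
        intensities = intensities.T
    if peak_ids is None:
        peak_ids = [f"P{j}" for j in range(intensities.shape[1])]
    return PeakTable(
        analytes=[Analyte(peak_id=p) for p in peak_ids],
        intensities=intensities,
        labels=list(labels),
        sample_ids=[f"x{i}" for i in range(len(labels))],
    )


# ---------------------------------------------------------------------------
# best_threshold
# ---------------------------------------------------------------------------

def test_best_threshold_perfectly_separable():
    t = _table([0.1, 0.2, 0.8, 0.9], ["A", "A", "B", "B"], ["P0"])
    rule, power = best_threshold(t, "P0", "A")
    assert rule.threshold == pytest.approx(0.5)
    assert rule.direction == "below"
    assert power.accuracy == 1.0


def test_best_threshold_inseparable_interleaved():
    t = _table([0.1, 0.1, 0.2, 0.2], ["A", "B", "A", "B"], ["P0"])
    _, power = best_threshold(t, "P0", "A")
    assert power.accuracy == pytest.approx(0.5)


def test_best_threshold_single_class_rejected():
    t = _table([0.1, 0.2], ["A", "A"], ["P0"])
    with pytest.raises(ValidationError):
        best_threshold(t, "P0", "A")


def _brute_force_best_accuracy(values, labels, positive):
    """Oracle: scan every sample value as cut, both directions, both <= / >."""
    y = np.asarray(labels) == positive
    best = 0.0
    cuts = np.concatenate([values, [values.min() - 1, values.max() + 1]])
    for c in cuts:
        for pred in (values < c, values <= c, values > c, values >= c):
            best = max(best, float(np.mean(pred == y)))
    return best


def test_best_threshold_matches_brute_force_oracle():
    rng = np.random.default_rng(12)
    for _ in range(120):
        values = np.round(rng.uniform(0, 1, size=12), 3)
        labels = rng.choice(["A", "B"], size=12)
        if len(set(labels)) < 2:
            continue
        t = _table(values, labels, ["P0"])
        _, power = best_threshold(t, "P0", "A")
        oracle = _brute_force_best_accuracy(values, labels, "A")
        assert power.accuracy == pytest.approx(oracle)


def test_best_threshold_invariant_under_monotone_transform():
    rng = np.random.default_rng(13)
    values = rng.uniform(0.1, 1, size=15)
    labels = rng.choice(["A", "B"], size=15)
    base = best_threshold(_table(values, labels, ["P0"]), "P0", "A")[1].accuracy
    for f in (np.sqrt, np.log1p, lambda v: v**3):
        moved = best_threshold(_table(f(values), labels, ["P0"]), "P0", "A")[1]
        assert moved.accuracy == pytest.approx(base)


# ---------------------------------------------------------------------------
# separation power
# ---------------------------------------------------------------------------

def test_separation_power_study_accuracy():
    # 50 of 53 correct -> accuracy 94% after rounding
    # rows are estimated class: TP=35, FP=1 / FN=2, TN=15
    cm = ConfusionMatrix(np.array([[35, 1], [2, 15]]), ["pos", "neg"])
    p = separation_power(cm, "pos")
    assert p.accuracy == pytest.approx(50 / 53)
    assert p.sensitivity == pytest.approx(35 / 37)
    assert p.specificity == pytest.approx(15 / 16)


def test_separation_power_perfect_and_undefined():
    perfect = separation_power(ConfusionMatrix(np.diag([5, 5]), ["p", "n"]), "p")
    assert (perfect.sensitivity, perfect.specificity, perfect.ppv,
            perfect.npv, perfect.accuracy) == (1, 1, 1, 1, 1)
    degenerate = separation_power(
        ConfusionMatrix(np.array([[0, 0], [3, 5]]), ["p", "n"]), "p")
    assert math.isnan(degenerate.ppv)  # no predicted positives
    assert degenerate.npv == pytest.approx(5 / 8)


# ---------------------------------------------------------------------------
# fixed tree evaluation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "sample, expected",
    [
        ({"P17": 0.010, "zP2": 0.5, "P47": 0.5, "P26": 0.5}, "PD"),
        ({"P17": 0.020, "zP2": 0.0005, "P47": 0.5, "P26": 0.5}, "AD"),
        ({"P17": 0.020, "zP2": 0.002, "P47": 0.030, "P26": 0.5}, "AD"),
        ({"P17": 0.020, "zP2": 0.002, "P47": 0.040, "P26": 0.001}, "AD"),  # <= cut
        ({"P17": 0.020, "zP2": 0.002, "P47": 0.040, "P26": 0.005}, "HC"),
        ({"P17": 0.016, "zP2": 0.001, "P47": 0.036, "P26": 0.0011}, "HC"),  # strict cuts
    ],
)
def test_reference_tree_routing(sample, expected):
    assert REFERENCE_TREE.classify_sample(sample) == expected


def test_fixed_tree_partition_property():
    """Every sample lands in exactly one class, whatever the intensities."""
    rng = np.random.default_rng(14)
    for _ in range(25):
        n = rng.integers(2, 30)
        t = _table(rng.uniform(0, 0.1, size=(n, 4)),
                   rng.choice(["AD", "PD", "HC"], size=n),
                   ["P17", "zP2", "P47", "P26"])
        pred = REFERENCE_TREE.classify_table(t)
        assert len(pred) == n
        assert set(pred) <= set(REFERENCE_TREE.classes)


def test_evaluate_fixed_tree_missing_analyte():
    t = _table([0.1, 0.2], ["AD", "HC"], ["P17"])
    with pytest.raises(ValidationError):
        evaluate_fixed_tree(t, REFERENCE_TREE)


def test_tree_json_round_trip(tmp_path):
    path = tmp_path / "tree.json"
    REFERENCE_TREE.to_json(path)
    back = DecisionTree.from_json(path)
    assert back.to_dict() == REFERENCE_TREE.to_dict()


def test_tree_rejects_repeated_analyte():
    with pytest.raises(ValidationError):
        DecisionTree(nodes=[TreeNode("P1", 0.5, "<", "A"),
                            TreeNode("P1", 0.7, "<", "B")], else_class="C")


# ---------------------------------------------------------------------------
# tree induction
# ---------------------------------------------------------------------------

def test_induce_single_class_is_pure_root():
    t = _table([0.1, 0.2, 0.3], ["A", "A", "A"], ["P0"])
    tree = induce_tree(t)
    assert tree.nodes == [] and tree.else_class == "A"


def test_induced_tree_recovers_planted_structure(clean_ims_table):
    tree = induce_tree(clean_ims_table)
    first = tree.nodes[0]
    assert first.analyte == "P17" and first.class_if_true == "PD"
    p17 = clean_ims_table.column("P17")
    labels = np.asarray(clean_ims_table.labels)
    assert p17[labels == "PD"].max() < first.threshold < p17[labels != "PD"].min()
    assert evaluate_fixed_tree(clean_ims_table, tree).accuracy() == 1.0


def test_induced_tree_at_least_best_single_rule():
    rng = np.random.default_rng(15)
    values = rng.uniform(0, 1, size=(20, 3))
    labels = rng.choice(["A", "B"], size=20)
    if len(set(labels)) < 2:
        labels[0] = "A"
        labels[1] = "B"
    t = _table(values, labels)
    tree = induce_tree(t)
    tree_acc = evaluate_fixed_tree(t, tree).accuracy()
    best_single = max(best_threshold(t, p, "A")[1].accuracy for p in t.peak_ids)
    assert tree_acc >= best_single - 1e-12


def test_induce_max_depth_limits_cascade(clean_ims_table):
    tree = induce_tree(clean_ims_table, max_depth=1)
    assert len(tree.nodes) == 1


def test_peak_table_csv_round_trip(tmp_path, clean_ims_table):
    path = tmp_path / "peaks.csv"
    clean_ims_table.to_csv(path)
    back = PeakTable.from_csv(path)
    assert back.peak_ids == clean_ims_table.peak_ids
    assert back.labels == clean_ims_table.labels
    assert np.allclose(back.intensities, clean_ims_table.intensities)
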
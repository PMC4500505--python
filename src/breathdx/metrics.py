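"""Confusion-matrix validation statistics.

Cross-tables of estimated vs. true class are the common currency of every
classifier in this package (eNose LDA cross-validations, IMS threshold rules
and decision trees).  This module holds the shared :class:`ConfusionMatrix`
container and the statistics reported for a binary cross-table: sensitivity
and specificity, exact (Clopper–Pearson) binomial confidence intervals, and
the continuity-corrected (Yates) chi-square test of association.

Conventions
-----------
Rows of a confusion matrix are the *estimated* class, columns the *true*
class.  Undefined ratios (zero denominators) are reported as ``nan``, never
silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """k x k table of counts; rows = estimated class, columns = true class."""

    counts: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValidationError("confusion matrix must be square")
        if self.counts.shape[0] != len(self.labels):
            raise ValidationError("label count does not match matrix size")
        if np.any(self.counts < 0):
            raise ValidationError("confusion counts must be non-negative")
        if self.counts.sum() < 1:
            raise ValidationError("confusion matrix must contain at least one count")
        self.counts = self.counts.astype(int)

    @classmethod
    def from_predictions(
        cls,
        estimated: Sequence[str],
        true: Sequence[str],
        labels: Sequence[str] | None = None,
    ) -> "ConfusionMatrix":
        estimated = list(estimated)
        true = list(true)
        if len(estimated) != len(true):
            raise ValidationError("estimated and true label lists differ in length")
        if labels is None:
            labels = sorted(set(estimated) | set(true))
        labels = list(labels)
        index = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for e, t in zip(estimated, true):
            counts[index[e], index[t]] += 1
        return cls(counts, labels)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)

    def _binary(self, positive_class: str) -> tuple[int, int, int, int]:
        """Return (TP, FP, FN, TN) for a 2x2 table."""
        if self.counts.shape != (2, 2):
            raise ValidationError("operation requires a 2x2 confusion matrix")
        if positive_class not in self.labels:
            raise ValidationError(f"unknown positive class {positive_class!r}")
        p = self.labels.index(positive_class)
        n = 1 - p
        tp = int(self.counts[p, p])
        fp = int(self.counts[p, n])
        fn = int(self.counts[n, p])
        tn = int(self.counts[n, n])
        return tp, fp, fn, tn


@dataclass
class ProportionCI:
    """Exact binomial confidence interval for a proportion."""

    successes: int
    trials: int
    level: float
    lower: float
    upper: float

    @property
    def estimate(self) -> float:
        return self.successes / self.trials


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def sens_spec(confusion: ConfusionMatrix, positive_class: str) -> tuple[float, float]:
    """Sensitivity and specificity of a 2x2 estimated-vs-true cross-table.

    Sensitivity is the fraction of the true-positive column estimated
    positive; specificity the fraction of the true-negative column estimated
    negative.  A zero column total yields ``nan``.
    """
    tp, fp, fn, tn = confusion._binary(positive_class)
    sens = tp / (tp + fn) if (tp + fn) > 0 else math.nan
    spec = tn / (tn + fp) if (tn + fp) > 0 else math.nan
    return sens, spec


def exact_binomial_ci(
    successes: int, trials: int, level: float = 0.95
) -> ProportionCI:
    """Clopper–Pearson exact interval via the beta-quantile construction.

    ``lower = 0`` when ``successes = 0`` and ``upper = 1`` when
    ``successes = trials`` (the exact interval's boundary convention).
    """
    if not (0 <= successes <= trials) or trials < 1:
        raise ValidationError("need 0 <= successes <= trials, trials >= 1")
    if not (0.0 < level < 1.0):
        raise ValidationError("confidence level must lie in (0, 1)")
    alpha = (1.0 - level) / 2.0
    lower = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha, successes, trials - successes + 1)
    )
    upper = 1.0 if successes == trials else float(
        stats.beta.ppf(1.0 - alpha, successes + 1, trials - successes)
    )
    return ProportionCI(successes, trials, level, lower, upper)


def yates_chi_square(confusion: ConfusionMatrix) -> tuple[float, int, float]:
    """Continuity-corrected chi-square test of association for a 2x2 table.

    Returns ``(statistic, df, p_value)`` with df = 1.  The correction is
    floored so the statistic is never negative.  Raises on zero marginals
    (expected counts undefined).
    """
    if confusion.counts.shape != (2, 2):
        raise ValidationError("Yates chi-square requires a 2x2 table")
    t = confusion.counts
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValidationError("zero marginal total: chi-square undefined")
    stat, p, df, _ = stats.chi2_contingency(t, correction=True)
    return float(stat), int(df), float(p)


def crosstab_report(
    confusion: ConfusionMatrix,
    positive_class: str,
    level: float = 0.95,
) -> dict:
    """The full statistic set reported for one binary cross-table.

    Sensitivity/specificity with exact CIs plus the Yates chi-square, as a
    plain dict (fractions, not percentages) ready for JSON output.
    """
    tp, fp, fn, tn = confusion._binary(positive_class)
    sens, spec = sens_spec(confusion, positive_class)
    sens_ci = exact_binomial_ci(tp, tp + fn, level) if (tp + fn) else None
    spec_ci = exact_binomial_ci(tn, tn + fp, level) if (tn + fp) else None
    chi2, df, p = yates_chi_square(confusion)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "sensitivity_ci": [sens_ci.lower, sens_ci.upper] if sens_ci else None,
        "specificity_ci": [spec_ci.lower, spec_ci.upper] if spec_ci else None,
        "ci_level": level,
        "chi_square": chi2,
        "df": df,
        "p_value": p,
        "n": confusion.total,
    }
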
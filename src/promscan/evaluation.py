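"""Scoring detectors against the gold standard.

Confusion matrix, the five headline metrics (accuracy, sensitivity,
specificity, PPV, NPV) with 95% confidence intervals, and the
between-algorithm chi-square comparison on correctness counts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise EvaluationError("confusion cells must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def correct(self) -> int:
        return self.tp + self.tn


#: published benchmark confusion cells for the held-out test subset
#: (n = 1065 outcomes), used as built-in fixtures for metric checks
EXPERT_BENCHMARK_CELLS = ConfusionMatrix(tp=448, fp=110, fn=58, tn=449)
CLASSIFIER_BENCHMARK_CELLS = ConfusionMatrix(tp=460, fp=60, fn=46, tn=499)

_METRIC_DEFS = {
    "accuracy": lambda c: (c.tp + c.tn, c.n),
    "sensitivity": lambda c: (c.tp, c.tp + c.fn),
    "specificity": lambda c: (c.tn, c.tn + c.fp),
    "ppv": lambda c: (c.tp, c.tp + c.fp),
    "npv": lambda c: (c.tn, c.tn + c.fn),
}


@dataclass(frozen=True)
class MetricEstimate:
    value: float | None  # None when the denominator is zero (undefined)
    ci_low: float | None
    ci_high: float | None
    numerator: int
    denominator: int

    @property
    def defined(self) -> bool:
        return self.value is not None


@dataclass
class MetricsReport:
    cm: ConfusionMatrix
    ci_method: str
    estimates: dict[str, MetricEstimate]

    def percent(self, metric: str) -> int | None:
        """Point estimate to the nearest whole percent (half away from zero)."""
        est = self.estimates[metric]
        return None if est.value is None else round_percent(est.value)

    def percent_ci(self, metric: str) -> tuple[int, int] | None:
        est = self.estimates[metric]
        if est.ci_low is None:
            return None
        return (round_percent(est.ci_low), round_percent(est.ci_high))


def round_percent(proportion: float) -> int:
    """Round a proportion to whole percent, halves away from zero."""
    x = proportion * 100.0
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def confusion(predicted: Sequence[int], gold: Sequence[int]) -> ConfusionMatrix:
    """Tabulate predictions against gold labels."""
    if len(predicted) != len(gold):
        raise EvaluationError(
            f"length mismatch: {len(predicted)} predictions vs {len(gold)} gold labels"
        )
    if len(gold) == 0:
        raise EvaluationError("need at least one labeled item")
    p = np.asarray(predicted, dtype=bool)
    g = np.asarray(gold, dtype=bool)
    return ConfusionMatrix(
        tp=int(np.sum(p & g)),
        fp=int(np.sum(p & ~g)),
        fn=int(np.sum(~p & g)),
        tn=int(np.sum(~p & ~g)),
    )


def _proportion_ci(k: int, n: int, method: str) -> tuple[float, float]:
    p = k / n
    z = stats.norm.ppf(0.975)
    if method == "wald":
        half = z * math.sqrt(p * (1 - p) / n)
        return (max(0.0, p - half), min(1.0, p + half))
    if method == "wilson":
        denom = 1 + z * z / n
        centre = (p + z * z / (2 * n)) / denom
        half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
        return (centre - half, centre + half)
    raise EvaluationError(f"unknown ci method: {method!r}")


def metrics(cm: ConfusionMatrix, ci_method: str = "wald") -> MetricsReport:
    """Compute accuracy/sensitivity/specificity/PPV/NPV with 95% CIs.

    A metric whose denominator is zero is reported as undefined (``None``),
    never as 0.
    """
    if cm.n == 0:
        raise EvaluationError("empty confusion matrix")
    estimates: dict[str, MetricEstimate] = {}
    for name, cells in _METRIC_DEFS.items():
        k, denom = cells(cm)
        if denom == 0:
            estimates[name] = MetricEstimate(None, None, None, k, denom)
            continue
        lo, hi = _proportion_ci(k, denom, ci_method)
        estimates[name] = MetricEstimate(k / denom, lo, hi, k, denom)
    return MetricsReport(cm=cm, ci_method=ci_method, estimates=estimates)


def compare_algorithms(cm_a: ConfusionMatrix, cm_b: ConfusionMatrix) -> dict[str, float]:
    """Pearson chi-square (no continuity correction) on algorithm x correctness.

    Approximation: the two algorithms are treated as independent samples
    because joint per-item predictions are not available from marginal
    confusion matrices; pairing is ignored.
    """
    if cm_a.n != cm_b.n:
        raise EvaluationError("confusion matrices must share the same gold-standard size")
    table = np.array(
        [
            [cm_a.correct, cm_a.n - cm_a.correct],
            [cm_b.correct, cm_b.n - cm_b.correct],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise EvaluationError("zero expected cell count; use an exact test instead")
    if np.array_equal(table[0], table[1]):
        return {"statistic": 0.0, "p_value": 1.0}
    stat, p, _, expected = stats.chi2_contingency(table, correction=False)
    if (expected == 0).any():
        raise EvaluationError("zero expected cell count; use an exact test instead")
    return {"statistic": float(stat), "p_value": float(p)}


# ---------------------------------------------------------------------------
# report writers

def report_to_json(report: MetricsReport) -> str:
    payload = {
        "n": report.cm.n,
        "cells": {
            "tp": report.cm.tp,
            "fp": report.cm.fp,
            "fn": report.cm.fn,
            "tn": report.cm.tn,
        },
        "ci_method": report.ci_method,
        "metrics": {
            name: {
                "value": est.value,
                "ci95": [est.ci_low, est.ci_high],
                "percent": report.percent(name),
                "numerator": est.numerator,
                "denominator": est.denominator,
            }
            for name, est in report.estimates.items()
        },
    }
    return json.dumps(payload, indent=2)


def format_report(report: MetricsReport, label: str = "detector") -> str:
    """Human-readable confusion table with margins and footnote metrics."""
    cm = report.cm
    lines = [
        f"{label} vs gold standard (n={cm.n})",
        f"{'':>16}  gold yes  gold no",
        f"{'pred yes':>16}  {cm.tp:>8}  {cm.fp:>7}   (n={cm.tp + cm.fp})",
        f"{'pred no':>16}  {cm.fn:>8}  {cm.tn:>7}   (n={cm.fn + cm.tn})",
        f"{'margin':>16}  {cm.tp + cm.fn:>8}  {cm.fp + cm.tn:>7}",
        "",
    ]
    for name in _METRIC_DEFS:
        pct = report.percent(name)
        if pct is None:
            lines.append(f"  {name:>12}: undefined (0 denominator)")
        else:
            lo, hi = report.percent_ci(name)
            lines.append(f"  {name:>12}: {pct}% (95% CI {lo}-{hi})")
    return "\n".join(lines)
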
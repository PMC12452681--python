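"""Cohort-level metrics: confusion counts, prevalence, two-proportion Z.

Used both to score the simulator benchmark (sensitivity/specificity and
fold-localization accuracy) and to compare fold-over prevalence between
electrode array families with the pooled two-proportion Z-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from scipy.stats import norm

from .tfo_detector import TFOResult

__all__ = [
    "ConfusionCounts",
    "PrevalenceTable",
    "BenchmarkEvaluation",
    "sens_spec",
    "prevalence",
    "two_proportion_z",
    "evaluate_benchmark",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise ValueError("at least one case required")


@dataclass(frozen=True)
class PrevalenceTable:
    """Detected counts and totals per group, with derived percentages."""

    groups: Mapping[str, tuple[int, int]]  # group -> (detected, total)

    def percentage(self, group: str) -> float:
        detected, total = self.groups[group]
        return prevalence(detected, total)

    def as_dict(self) -> dict[str, dict[str, float | int]]:
        return {
            g: {"detected": d, "total": n, "percent": prevalence(d, n)}
            for g, (d, n) in self.groups.items()
        }


def sens_spec(c: ConfusionCounts) -> tuple[float, float]:
    """Sensitivity tp/(tp+fn) and specificity tn/(tn+fp), as fractions."""
    if c.tp + c.fn < 1:
        raise ValueError("sensitivity undefined: no positive cases")
    if c.tn + c.fp < 1:
        raise ValueError("specificity undefined: no negative cases")
    return c.tp / (c.tp + c.fn), c.tn / (c.tn + c.fp)


def prevalence(detected: int, total: int) -> float:
    """Percentage 100*detected/total, rounded half-away-from-zero to 2 dp."""
    if total < 1:
        raise ValueError("total must be >= 1")
    if not 0 <= detected <= total:
        raise ValueError("require 0 <= detected <= total")
    pct = Decimal(100 * detected) / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion Z-test, two-sided.

    With p̂ = (x1+x2)/(n1+n2),

        z = (x1/n1 - x2/n2) / sqrt(p̂ (1-p̂) (1/n1 + 1/n2))

    and p the two-sided tail probability of the standard normal.  No
    continuity correction is applied.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise ValueError("degenerate pooled proportion (all successes or all failures)")
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (x1 / n1 - x2 / n2) / se
    p = 2.0 * float(norm.sf(abs(z)))
    return z, p


@dataclass(frozen=True)
class BenchmarkEvaluation:
    """Detector performance against a benchmark truth manifest."""

    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    localization_accuracy: float | None  # fraction of TPs within +/-1 contact


def evaluate_benchmark(
    results: Mapping[str, TFOResult] | Sequence[tuple[str, TFOResult]],
    truth: Mapping[str, int | None] | Sequence[tuple[str, int | None]],
    localization_tolerance: int = 1,
) -> BenchmarkEvaluation:
    """Score detector results against ground truth, aligned by case id.

    ``truth`` maps each case id to the true fold contact, or None for a
    normal insertion.  Raises on any id mismatch — silent misalignment
    would corrupt every metric downstream.
    """
    res = dict(results)
    tru = dict(truth)
    if set(res) != set(tru):
        missing = set(tru) ^ set(res)
        raise ValueError(f"result/truth id mismatch: {sorted(missing)[:5]}")

    tp = fp = tn = fn = 0
    localized = 0
    for cid in sorted(res):
        r, fold_true = res[cid], tru[cid]
        if fold_true is not None:
            if r.tfo_detected:
                tp += 1
                if (
                    r.fold_electrode is not None
                    and abs(r.fold_electrode - fold_true) <= localization_tolerance
                ):
                    localized += 1
            else:
                fn += 1
        else:
            if r.tfo_detected:
                fp += 1
            else:
                tn += 1

    counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    sens, spec = sens_spec(counts)
    loc = localized / tp if tp else None
    return BenchmarkEvaluation(
        counts=counts,
        sensitivity=sens,
        specificity=spec,
        localization_accuracy=loc,
    )
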
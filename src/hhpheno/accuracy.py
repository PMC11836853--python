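"""Diagnostic accuracy of a phenotyping rule against the chart-review gold standard.

Builds the 2×2 contingency table (positive class: C282Y homozygosity) and
reports sensitivity tp/(tp+fn), specificity tn/(fp+tn), positive predictive
value tp/(tp+fp) and negative predictive value tn/(fn+tn), each with an
exact (Clopper–Pearson) 95% confidence interval obtained from beta
quantiles. Percentages are rendered half-up to one decimal place; internal
values keep full precision. A metric with a zero denominator is reported as
missing rather than 0 or 100.

Also provides the Pearson χ² test (uncorrected, df=1) used for the age-band
association with C282Y homozygosity, and the diagnosis × venesection
cross-tabulation of the baseline cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .algorithms import Prediction
from .cohort import CATEGORY_DISPLAY, GoldCategory, GoldLabel, PatientRecord

__all__ = [
    "ContingencyTable",
    "MetricEstimate",
    "AccuracyReport",
    "UndefinedMetricError",
    "UnlabeledPatientError",
    "contingency",
    "binomial_ci_exact",
    "accuracy_report",
    "chi2_association",
    "age_association",
    "crosstab_by_category",
    "round_half_up",
]


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero."""


class UnlabeledPatientError(KeyError):
    """A predicted patient has no gold-standard label."""


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 counts of rule output against the gold standard."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for cell in (self.tp, self.fp, self.fn, self.tn):
            if cell < 0:
                raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def gold_positives(self) -> int:
        return self.tp + self.fn

    @property
    def gold_negatives(self) -> int:
        return self.fp + self.tn

    @property
    def predicted_positives(self) -> int:
        return self.tp + self.fp

    @property
    def predicted_negatives(self) -> int:
        return self.fn + self.tn


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion with its exact confidence interval.

    ``point``, ``ci_low`` and ``ci_high`` are ``None`` when the denominator
    is zero (the metric is undefined, not 0 or 1).
    """

    name: str
    numerator: int
    denominator: int
    point: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    level: float = 0.95

    def render(self) -> str:
        """Table-style "point (low to high)" percentages at 1 dp."""
        if self.point is None:
            return "—"
        return (
            f"{round_half_up(100 * self.point):.1f} "
            f"({round_half_up(100 * self.ci_low):.1f} to "
            f"{round_half_up(100 * self.ci_high):.1f})"
        )


@dataclass(frozen=True)
class AccuracyReport:
    """Contingency table plus the four metrics for one algorithm."""

    algorithm: str
    table: ContingencyTable
    metrics: Mapping[str, MetricEstimate]

    def summary(self) -> str:
        t = self.table
        lines = [
            f"Algorithm {self.algorithm}  (n={t.n})",
            f"  tp={t.tp}  fp={t.fp}  fn={t.fn}  tn={t.tn}",
        ]
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            m = self.metrics[name]
            lines.append(
                f"  {name:<12} {m.render():<22} [{m.numerator}/{m.denominator}]"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "table": {"tp": self.table.tp, "fp": self.table.fp,
                      "fn": self.table.fn, "tn": self.table.tn},
            "metrics": {
                name: {
                    "numerator": m.numerator,
                    "denominator": m.denominator,
                    "point": m.point,
                    "ci_low": m.ci_low,
                    "ci_high": m.ci_high,
                    "rendered": m.render(),
                }
                for name, m in self.metrics.items()
            },
        }


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (0.05 at 1 dp rounds to 0.1, not 0.0)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def contingency(
    predictions: Iterable[Prediction],
    labels: Iterable[GoldLabel],
    positive_category: GoldCategory = GoldCategory.C282Y_HOM,
) -> ContingencyTable:
    """Cross-tabulate rule output against the gold standard.

    Every predicted patient must carry a label; unlabeled patients raise
    :class:`UnlabeledPatientError` naming them. Labels without predictions
    are ignored (they are outside the evaluated cohort).
    """
    predictions = list(predictions)
    if not predictions:
        raise ValueError("empty prediction set")
    label_map = {l.patient_id: l.category for l in labels}
    missing = sorted(p.patient_id for p in predictions if p.patient_id not in label_map)
    if missing:
        shown = ", ".join(missing[:10])
        raise UnlabeledPatientError(
            f"{len(missing)} predicted patient(s) without gold labels: {shown}"
        )
    tp = fp = fn = tn = 0
    for p in predictions:
        gold_positive = label_map[p.patient_id] is positive_category
        if p.label and gold_positive:
            tp += 1
        elif p.label:
            fp += 1
        elif gold_positive:
            fn += 1
        else:
            tn += 1
    return ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)


def binomial_ci_exact(
    successes: int, trials: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact (Clopper–Pearson) binomial confidence interval.

    Computed from beta-distribution quantiles, the closed form of inverting
    the binomial tail probabilities. The lower bound is 0 when
    ``successes == 0`` and the upper bound is 1 when ``successes == trials``.
    """
    if trials <= 0:
        raise UndefinedMetricError("confidence interval undefined for zero trials")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    alpha = 1.0 - level
    k, n = successes, trials
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def _metric(name: str, numerator: int, denominator: int, level: float) -> MetricEstimate:
    if denominator == 0:
        return MetricEstimate(name, numerator, denominator, None, None, None, level)
    low, high = binomial_ci_exact(numerator, denominator, level)
    return MetricEstimate(
        name, numerator, denominator, numerator / denominator, low, high, level
    )


def accuracy_report(
    table: ContingencyTable, algorithm: str = "?", level: float = 0.95
) -> AccuracyReport:
    """Sensitivity, specificity, PPV and NPV with exact CIs for one table."""
    metrics = {
        "sensitivity": _metric("sensitivity", table.tp, table.gold_positives, level),
        "specificity": _metric("specificity", table.tn, table.gold_negatives, level),
        "ppv": _metric("ppv", table.tp, table.predicted_positives, level),
        "npv": _metric("npv", table.tn, table.predicted_negatives, level),
    }
    return AccuracyReport(algorithm=algorithm, table=table, metrics=metrics)


def chi2_association(table2x2) -> tuple[float, float]:
    """Pearson χ² (no continuity correction, df=1) on a 2×2 count table."""
    observed = np.asarray(table2x2, dtype=float)
    if observed.shape != (2, 2):
        raise ValueError("expected a 2×2 table")
    if (observed.sum(axis=0) == 0).any() or (observed.sum(axis=1) == 0).any():
        raise ValueError("χ² undefined: a marginal total is zero")
    result = stats.chi2_contingency(observed, correction=False)
    return float(result.statistic), float(result.pvalue)


def age_association(
    records: Iterable[PatientRecord],
    labels: Iterable[GoldLabel],
    age_cut: int = 60,
) -> tuple[float, float, np.ndarray]:
    """χ² test of age band (<cut / ≥cut) against C282Y homozygosity.

    Returns (statistic, p_value, observed 2×2 table with rows young/old and
    columns homozygote/other). Age is age at first in-window episode.
    """
    label_map = {l.patient_id: l.is_positive for l in labels}
    table = np.zeros((2, 2), dtype=int)
    for r in records:
        if r.patient_id not in label_map:
            raise UnlabeledPatientError(f"patient {r.patient_id} has no gold label")
        row = 0 if r.age_at_first_episode < age_cut else 1
        col = 0 if label_map[r.patient_id] else 1
        table[row, col] += 1
    statistic, p_value = chi2_association(table)
    return statistic, p_value, table


def crosstab_by_category(
    records: Iterable[PatientRecord], labels: Iterable[GoldLabel]
) -> pd.DataFrame:
    """Diagnosis/genotype × venesection-exposure cross-tab of the cohort.

    One row per gold category (display name), columns: total patients,
    patients with ≥1 venesection episode, patients with none.
    """
    label_map = {l.patient_id: l.category for l in labels}
    rows = {c: [0, 0, 0] for c in GoldCategory}
    for r in records:
        if r.patient_id not in label_map:
            raise UnlabeledPatientError(f"patient {r.patient_id} has no gold label")
        counts = rows[label_map[r.patient_id]]
        counts[0] += 1
        counts[1 if r.venesection_episodes >= 1 else 2] += 1
    frame = pd.DataFrame(
        [(CATEGORY_DISPLAY[c], *v) for c, v in rows.items()],
        columns=["category", "total", "venesected", "not_venesected"],
    )
    return frame.set_index("category")
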
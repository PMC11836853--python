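"""Contingency tables, exact binomial CIs, χ² association, rendering."""

import numpy as np
import pytest
from scipy import stats

from hhpheno.accuracy import (
    ContingencyTable,
    UndefinedMetricError,
    UnlabeledPatientError,
    accuracy_report,
    age_association,
    binomial_ci_exact,
    chi2_association,
    contingency,
    crosstab_by_category,
    round_half_up,
)
from hhpheno.algorithms import Prediction
from hhpheno.cohort import GoldCategory, GoldLabel


def _cp_bisect(k, n, level=0.95):
    """Independent oracle: invert binomial tail probabilities by bisection."""
    alpha = (1.0 - level) / 2.0

    def solve(tail, increasing):
        lo, hi = 0.0, 1.0
        for _ in range(200):
            mid = (lo + hi) / 2.0
            if (tail(mid) > alpha) == increasing:
                hi = mid
            else:
                lo = mid
        return (lo + hi) / 2.0

    # lower bound: P(X >= k | p) = alpha, upper tail increasing in p
    low = 0.0 if k == 0 else solve(lambda p: 1.0 - stats.binom.cdf(k - 1, n, p), True)
    # upper bound: P(X <= k | p) = alpha, lower tail decreasing in p
    high = 1.0 if k == n else solve(lambda p: stats.binom.cdf(k, n, p), False)
    return low, high


class TestContingency:
    def _labels(self):
        return [
            GoldLabel("A", GoldCategory.C282Y_HOM),
            GoldLabel("B", GoldCategory.C282Y_H63D),
            GoldLabel("C", GoldCategory.C282Y_HOM),
            GoldLabel("D", GoldCategory.INCORRECT_CODING),
        ]

    def test_cells_partition_cohort(self):
        preds = [Prediction(p, "t", lab) for p, lab in
                 [("A", True), ("B", True), ("C", False), ("D", False)]]
        t = contingency(preds, self._labels())
        assert (t.tp, t.fp, t.fn, t.tn) == (1, 1, 1, 1)
        assert t.n == 4

    def test_unlabeled_patient_named(self):
        preds = [Prediction("Z", "t", True)]
        with pytest.raises(UnlabeledPatientError, match="Z"):
            contingency(preds, self._labels())

    def test_empty_predictions_rejected(self):
        with pytest.raises(ValueError):
            contingency([], self._labels())

    def test_all_positive_predictor_recovers_class_split(self, records, labels):
        preds = [Prediction(r.patient_id, "0", True) for r in records]
        t = contingency(preds, labels)
        assert (t.tp, t.fp, t.fn, t.tn) == (479, 308, 0, 0)


class TestExactCI:
    @pytest.mark.parametrize(
        "k, n, expected",
        [
            (416, 479, (0.835, 0.897)),
            (411, 553, (0.705, 0.779)),
        ],
    )
    def test_published_bounds_at_3dp(self, k, n, expected):
        low, high = binomial_ci_exact(k, n)
        assert (round(low, 3), round(high, 3)) == expected

    @pytest.mark.parametrize("k, n", [(5, 10), (1, 10), (0, 10), (10, 10), (416, 479)])
    def test_against_bisection_oracle(self, k, n):
        got = binomial_ci_exact(k, n)
        want = _cp_bisect(k, n)
        assert got == pytest.approx(want, abs=1e-6)

    def test_degenerate_bounds(self):
        assert binomial_ci_exact(0, 10)[0] == 0.0
        assert binomial_ci_exact(10, 10)[1] == 1.0

    def test_zero_trials_undefined(self):
        with pytest.raises(UndefinedMetricError):
            binomial_ci_exact(0, 0)

    def test_coverage_is_conservative(self):
        """Exact intervals cover the true p at ≥ the nominal 95% rate."""
        rng = np.random.default_rng(123)
        n, p = 60, 0.37
        draws = rng.binomial(n, p, size=2000)
        covered = sum(
            low <= p <= high
            for low, high in (binomial_ci_exact(int(k), n) for k in draws)
        )
        assert covered / 2000 >= 0.95


class TestAccuracyReport:
    def test_published_contingency_metrics(self):
        report = accuracy_report(ContingencyTable(tp=411, fp=142, fn=68, tn=166), "4")
        rendered = {k: m.render() for k, m in report.metrics.items()}
        assert rendered == {
            "sensitivity": "85.8 (82.4 to 88.8)",
            "specificity": "53.9 (48.2 to 59.6)",
            "ppv": "74.3 (70.5 to 77.9)",
            "npv": "70.9 (64.7 to 76.7)",
        }

    def test_perfect_classifier(self):
        report = accuracy_report(ContingencyTable(1, 0, 0, 1))
        assert all(m.point == 1.0 for m in report.metrics.values())

    def test_zero_denominator_reported_missing(self):
        report = accuracy_report(ContingencyTable(tp=3, fp=1, fn=0, tn=0))
        assert report.metrics["npv"].point is None
        assert report.metrics["npv"].render() == "—"
        assert report.metrics["sensitivity"].point == 1.0  # others still defined

    def test_prevalence_weighted_identity(self):
        t = ContingencyTable(tp=37, fp=11, fn=9, tn=43)
        r = accuracy_report(t).metrics
        lhs = r["ppv"].point * t.predicted_positives
        rhs = r["sensitivity"].point * t.gold_positives
        assert lhs == pytest.approx(rhs) == t.tp


class TestChi2:
    def test_independence_gives_zero(self):
        statistic, p = chi2_association([[50, 50], [50, 50]])
        assert statistic == 0.0 and p == 1.0

    def test_matches_direct_formula(self):
        """Σ(O−E)²/E computed by hand for a 2×2 table."""
        observed = np.array([[30, 10], [10, 30]], dtype=float)
        expected = np.outer(observed.sum(1), observed.sum(0)) / observed.sum()
        by_hand = ((observed - expected) ** 2 / expected).sum()
        statistic, _ = chi2_association(observed)
        assert statistic == pytest.approx(by_hand)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi2_association([[0, 0], [5, 5]])

    def test_age_association_on_synthetic_cohort(self, records, labels):
        statistic, p, table = age_association(records, labels)
        assert table.sum() == 787
        assert p < 0.01
        # younger patients enriched for homozygosity
        young, old = table[0], table[1]
        assert young[0] / young.sum() > old[0] / old.sum()


class TestRendering:
    @pytest.mark.parametrize(
        "value, expected",
        [(86.8476, 86.8), (86.85, 86.9), (85.0, 85.0), (74.35, 74.4), (0.05, 0.1)],
    )
    def test_round_half_up(self, value, expected):
        assert round_half_up(value) == expected


def test_crosstab_matches_gold_structure(records, labels):
    frame = crosstab_by_category(records, labels)
    assert frame.loc["C282Y/C282Y"].tolist() == [479, 416, 63]
    assert frame.loc["Hyperferritinaemia"].tolist() == [73, 24, 49]
    assert frame["total"].sum() == 787
    assert frame["venesected"].sum() == 581
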
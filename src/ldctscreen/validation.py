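"""Diagnostic-accuracy validation of classifier calls against chart-review
gold labels.

Metrics follow the standard definitions: sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(TN+FN), where
"positive" means a screening call and the gold label is the chart-review
indication. Confidence intervals are exact Clopper-Pearson (the inversion of
the two-sided binomial test, computed from beta quantiles). Scans the
classifier cannot call are handled under an explicit policy: excluded from
the table, or counted as algorithm-non-screening. Survey-weighted variants
replace counts with weight sums and adjust the interval via the Kish
effective sample size.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .classifier import Call, ClassificationResult

__all__ = [
    "UnablePolicy",
    "ContingencyTable",
    "MetricEstimate",
    "AccuracyReport",
    "ProportionComparison",
    "build_contingency",
    "accuracy_metrics",
    "clopper_pearson",
    "weighted_metrics",
    "cpt_baseline",
    "compare_proportions",
    "percent",
]


class UnablePolicy(str, Enum):
    EXCLUDE = "exclude_unable"
    AS_NONSCREENING = "unable_as_nonscreening"


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts of algorithm call (rows) vs gold label (columns) under a
    stated unable-scan policy. ``tp`` = called screening, gold screening;
    ``fp`` = called screening, gold non-screening; etc."""

    tp: int
    fp: int
    fn: int
    tn: int
    policy: UnablePolicy = UnablePolicy.EXCLUDE
    n_unable_included: int = 0
    n_unable_dropped: int = 0
    n_excluded: int = 0
    n_unknown_gold: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.policy is UnablePolicy.EXCLUDE and self.n_unable_included:
            raise ValueError("exclude_unable policy cannot include unable scans")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion with its exact two-sided CI; ``defined`` is False when
    the denominator is zero (the point and bounds are then NaN, never 0/1)."""

    point: float
    lower: float
    upper: float
    numerator: float
    denominator: float
    defined: bool = True

    @staticmethod
    def undefined() -> "MetricEstimate":
        nan = float("nan")
        return MetricEstimate(nan, nan, nan, 0.0, 0.0, defined=False)


@dataclass(frozen=True)
class AccuracyReport:
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    confidence: float = 0.95
    weighted: bool = False
    notes: tuple[str, ...] = ()


@dataclass(frozen=True)
class ProportionComparison:
    """Two-sample proportion chi-squared test (Yates-corrected by default)."""

    statistic: float
    pvalue: float
    p1: float
    p2: float
    correction: bool = True


def percent(x: float) -> int:
    """Whole-percent display rounding, half-up (0.945 -> 95 if exactly
    94.5+). Underlying values are never rounded."""
    return int(Decimal(str(x * 100)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


class MissingGoldError(ValueError):
    """Non-excluded calls without a usable gold label; lists the scan ids."""

    def __init__(self, scan_ids: Sequence[str]):
        self.scan_ids = list(scan_ids)
        super().__init__(f"calls without gold label: {self.scan_ids}")


def build_contingency(
    calls: Sequence[ClassificationResult],
    gold: Mapping[str, str],
    policy: UnablePolicy | str = UnablePolicy.EXCLUDE,
) -> ContingencyTable:
    """Cross algorithm calls with gold labels.

    Excluded calls and gold "unknown" scans are dropped (counted in the
    table's bookkeeping fields). Unable calls are dropped or counted as
    algorithm-non-screening per ``policy``. A non-excluded call whose scan
    has no gold label raises :class:`MissingGoldError`.
    """
    policy = UnablePolicy(policy)
    tp = fp = fn = tn = 0
    n_excluded = n_unknown = n_unable_inc = n_unable_drop = 0
    missing: list[str] = []
    for call in calls:
        if call.call is Call.EXCLUDED:
            n_excluded += 1
            continue
        g = gold.get(call.scan_id)
        if g is None:
            missing.append(call.scan_id)
            continue
        if g == "unknown":
            n_unknown += 1
            continue
        if g not in ("screening", "non_screening"):
            raise ValueError(f"invalid gold label {g!r} for scan {call.scan_id}")
        if call.call is Call.UNABLE:
            if policy is UnablePolicy.EXCLUDE:
                n_unable_drop += 1
                continue
            algo_screening = False
            n_unable_inc += 1
        else:
            algo_screening = call.call is Call.SCREENING
        if algo_screening and g == "screening":
            tp += 1
        elif algo_screening:
            fp += 1
        elif g == "screening":
            fn += 1
        else:
            tn += 1
    if missing:
        raise MissingGoldError(missing)
    return ContingencyTable(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        policy=policy,
        n_unable_included=n_unable_inc,
        n_unable_dropped=n_unable_drop,
        n_excluded=n_excluded,
        n_unknown_gold=n_unknown,
    )


def clopper_pearson(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial CI by inverting the binomial test.

    Beta-quantile form: lower = B(alpha/2; k, n-k+1), upper =
    B(1-alpha/2; k+1, n-k), with lower = 0 at k = 0 and upper = 1 at k = n.
    """
    if n < 1 or k < 0 or k > n:
        raise ValueError(f"require 0 <= k <= n and n >= 1, got k={k}, n={n}")
    if not 0 < confidence < 1:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    return _beta_interval(float(k), float(n), confidence)


def _beta_interval(k: float, n: float, confidence: float) -> tuple[float, float]:
    # accepts non-integer k/n for effective-sample-size-adjusted intervals
    alpha = 1.0 - confidence
    lower = 0.0 if k <= 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k >= n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


def _estimate(k: float, n: float, confidence: float) -> MetricEstimate:
    if n <= 0:
        return MetricEstimate.undefined()
    lower, upper = _beta_interval(k, n, confidence)
    return MetricEstimate(point=k / n, lower=lower, upper=upper, numerator=k, denominator=n)


def accuracy_metrics(table: ContingencyTable, confidence: float = 0.95) -> AccuracyReport:
    """Point estimates and exact CIs for the four accuracy metrics.
    Zero-denominator metrics are flagged undefined, not raised."""
    return AccuracyReport(
        sensitivity=_estimate(table.tp, table.tp + table.fn, confidence),
        specificity=_estimate(table.tn, table.tn + table.fp, confidence),
        ppv=_estimate(table.tp, table.tp + table.fp, confidence),
        npv=_estimate(table.tn, table.tn + table.fn, confidence),
        confidence=confidence,
    )


def _kish_estimate(
    num_weights: Sequence[float], denom_weights: Sequence[float], confidence: float
) -> MetricEstimate:
    """Weighted proportion with a CI from the Kish effective sample size
    n_eff = (sum w)^2 / sum w^2 over the denominator group."""
    wsum = float(sum(denom_weights))
    if wsum <= 0:
        return MetricEstimate.undefined()
    p = float(sum(num_weights)) / wsum
    n_eff = wsum * wsum / float(sum(w * w for w in denom_weights))
    k_eff = p * n_eff
    lower, upper = _beta_interval(k_eff, n_eff, confidence)
    return MetricEstimate(point=p, lower=lower, upper=upper, numerator=k_eff, denominator=n_eff)


def weighted_metrics(
    calls: Sequence[ClassificationResult],
    gold: Mapping[str, str],
    weights: Mapping[str, float],
    policy: UnablePolicy | str = UnablePolicy.EXCLUDE,
    confidence: float = 0.95,
) -> AccuracyReport:
    """Survey-weighted accuracy metrics: each metric is a ratio of sampling
    weight sums; with all weights equal the point estimates equal the
    unweighted ones exactly."""
    policy = UnablePolicy(policy)
    cells: dict[str, list[float]] = {"tp": [], "fp": [], "fn": [], "tn": []}
    missing_weight: list[str] = []
    for call in calls:
        if call.call is Call.EXCLUDED:
            continue
        g = gold.get(call.scan_id)
        if g in (None, "unknown"):
            continue
        if call.call is Call.UNABLE:
            if policy is UnablePolicy.EXCLUDE:
                continue
            algo_screening = False
        else:
            algo_screening = call.call is Call.SCREENING
        w = weights.get(call.scan_id)
        if w is None or not w > 0:
            missing_weight.append(call.scan_id)
            continue
        cell = ("tp" if g == "screening" else "fp") if algo_screening else ("fn" if g == "screening" else "tn")
        cells[cell].append(float(w))
    if missing_weight:
        raise ValueError(f"missing or non-positive weight for scans: {missing_weight}")
    return AccuracyReport(
        sensitivity=_kish_estimate(cells["tp"], cells["tp"] + cells["fn"], confidence),
        specificity=_kish_estimate(cells["tn"], cells["tn"] + cells["fp"], confidence),
        ppv=_kish_estimate(cells["tp"], cells["tp"] + cells["fp"], confidence),
        npv=_kish_estimate(cells["tn"], cells["tn"] + cells["fn"], confidence),
        confidence=confidence,
        weighted=True,
    )


def cpt_baseline(gold_labels: Iterable[str], confidence: float = 0.95) -> AccuracyReport:
    """Accuracy of administrative codes alone: every in-scope scan is
    "screening per codes", so the baseline PPV is the gold-screening
    fraction. Sensitivity, specificity and NPV are flagged undefined —
    codes yield no negative calls to evaluate."""
    labels = list(gold_labels)
    usable = [g for g in labels if g in ("screening", "non_screening")]
    k = sum(1 for g in usable if g == "screening")
    n = len(usable)
    return AccuracyReport(
        sensitivity=MetricEstimate.undefined(),
        specificity=MetricEstimate.undefined(),
        ppv=_estimate(k, n, confidence) if n else MetricEstimate.undefined(),
        npv=MetricEstimate.undefined(),
        confidence=confidence,
        notes=("sensitivity/specificity/npv not meaningful: codes flag every in-scope scan",),
    )


def compare_proportions(
    k1: int, n1: int, k2: int, n2: int, correction: bool = True
) -> ProportionComparison:
    """Two-sample proportion test: chi-squared on the 2x2 table with Yates
    continuity correction by default (two-sided)."""
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1 or k < 0 or k > n:
            raise ValueError(f"require 0 <= k <= n and n >= 1, got k={k}, n={n}")
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    res = stats.chi2_contingency(table, correction=correction)
    return ProportionComparison(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        p1=k1 / n1,
        p2=k2 / n2,
        correction=correction,
    )
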
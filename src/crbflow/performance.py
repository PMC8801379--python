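"""Diagnostic accuracy, cohort-weighted combination, and comparison statistics.

Definitions follow the study design of a validation screen with three
subject groups:

* sensitivity  = test-positive P/LP carriers (group 1) / all carriers,
* specificity  = test-negative relatives without the familial variant
  (group 3) / all such relatives,
* accuracy     = (TP + TN) / (group-1 + group-3 count).

Group-2 subjects (VUS or no reported variant) have no genotype truth and
are excluded from all three metrics.

The all-cohort combination is a weighted mean of per-cohort metric values
with weights equal to the *total cohort size N* (not the metric-specific
denominators), restricted to cohorts where the metric is available.  This
differs from pooling the 2x2 tables: the combined numerator is the implied
fraction value x sum(N) and is generally non-integer.  A caveat is attached
to reports because the sensitivity denominator is then sum(N) rather than
the carrier count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InputError, UndefinedStatisticError

ASSAY_KEYS = ("brca1", "brca2", "p53", "rcs")
METRIC_KEYS = ("sensitivity", "specificity", "accuracy")

WEIGHTING_CAVEAT = (
    "Combined metrics are cohort-N-weighted means of per-cohort values "
    "(cohorts lacking a metric are dropped from its mean); numerators are "
    "implied fractions, not pooled 2x2 counts."
)


@dataclass
class MetricValue:
    """One metric with its numerator/denominator; ``available=False`` => NA."""

    value: float | None = None
    numerator: float | None = None
    denominator: float | None = None
    available: bool = True

    @classmethod
    def na(cls) -> "MetricValue":
        return cls(None, None, None, available=False)

    @classmethod
    def from_counts(cls, numerator: float, denominator: float) -> "MetricValue":
        if denominator <= 0:
            return cls.na()
        if numerator < 0 or numerator > denominator:
            raise InputError(
                f"metric numerator {numerator} outside [0, {denominator}]"
            )
        return cls(numerator / denominator, numerator, denominator)

    def render(self) -> str:
        if not self.available:
            return "NA"
        num = self.numerator
        num_s = f"{num:.0f}" if float(num).is_integer() else f"{num:.1f}"
        return f"{self.value:.2f} ({num_s}/{self.denominator:.0f})"


@dataclass
class CohortMetrics:
    """Per-assay sensitivity/specificity/accuracy for one cohort."""

    cohort: str
    n_total: int
    metrics: dict[str, dict[str, MetricValue]] = field(default_factory=dict)

    @classmethod
    def from_counts(
        cls, cohort: str, n_total: int, counts: dict[str, dict[str, tuple | None]]
    ) -> "CohortMetrics":
        """Build from (numerator, denominator) pairs per assay and metric.

        Accuracy, when not given, is derived as (TP + TN) / (P + N) from the
        sensitivity and specificity counts; it is NA unless both are present.
        """
        out = cls(cohort=cohort, n_total=n_total)
        for assay, per_metric in counts.items():
            block: dict[str, MetricValue] = {}
            sens = per_metric.get("sensitivity")
            spec = per_metric.get("specificity")
            block["sensitivity"] = (
                MetricValue.from_counts(*sens) if sens else MetricValue.na()
            )
            block["specificity"] = (
                MetricValue.from_counts(*spec) if spec else MetricValue.na()
            )
            if "accuracy" in per_metric and per_metric["accuracy"]:
                block["accuracy"] = MetricValue.from_counts(*per_metric["accuracy"])
            elif sens and spec:
                block["accuracy"] = MetricValue.from_counts(
                    sens[0] + spec[0], sens[1] + spec[1]
                )
            else:
                block["accuracy"] = MetricValue.na()
            out.metrics[assay] = block
        return out


@dataclass
class CombinedMetrics:
    """All-cohort weighted metrics plus the weighting record."""

    metrics: dict[str, dict[str, MetricValue]]
    weights: dict[str, int]  # cohort -> total N
    caveat: str = WEIGHTING_CAVEAT


def cohort_confusion_metrics(
    calls, subjects, cohort: str
) -> CohortMetrics:
    """Confusion metrics for one cohort from per-subject binary calls.

    ``calls``: table with ``subject_id`` plus one boolean column per assay
    (True = test positive, i.e. repair-defective call).  ``subjects``: table
    with ``subject_id``, ``cohort``, ``group``.  Metrics with empty
    denominators are flagged NA, never reported as 0/0; a cohort with no
    group-1 and no group-3 subjects yields all-NA metrics with a warning.
    """
    import pandas as pd

    sub = subjects.loc[subjects["cohort"] == cohort]
    if sub.empty:
        raise InputError(f"no subjects in cohort '{cohort}'")
    assay_cols = [c for c in calls.columns if c != "subject_id"]
    if not assay_cols:
        raise InputError("calls table has no assay columns")
    merged = sub.merge(calls, on="subject_id", how="left")
    g1 = merged.loc[merged["group"] == 1]
    g3 = merged.loc[merged["group"] == 3]
    labeled = pd.concat([g1, g3])
    if labeled.empty:
        warnings.warn(
            f"cohort '{cohort}' has no group-1 or group-3 subjects; all metrics NA",
            stacklevel=2,
        )
    elif labeled[assay_cols].isna().any().any():
        missing = labeled.loc[labeled[assay_cols].isna().any(axis=1), "subject_id"]
        raise InputError(
            f"group-1/group-3 subjects lack calls: {missing.tolist()}"
        )
    out = CohortMetrics(cohort=cohort, n_total=len(labeled))
    for assay in assay_cols:
        block = {}
        if len(g1):
            tp = int(g1[assay].astype(bool).sum())
            block["sensitivity"] = MetricValue.from_counts(tp, len(g1))
        else:
            block["sensitivity"] = MetricValue.na()
        if len(g3):
            tn = int((~g3[assay].astype(bool)).sum())
            block["specificity"] = MetricValue.from_counts(tn, len(g3))
        else:
            block["specificity"] = MetricValue.na()
        if len(g1) and len(g3):
            block["accuracy"] = MetricValue.from_counts(tp + tn, len(g1) + len(g3))
        else:
            block["accuracy"] = MetricValue.na()
        out.metrics[assay] = block
    return out


def combine_weighted_metrics(per_cohort: list[CohortMetrics]) -> CombinedMetrics:
    """Cohort-N-weighted mean of each metric over cohorts where available."""
    if not per_cohort:
        raise InputError("need at least one cohort")
    assays: list[str] = []
    for cm in per_cohort:
        for a in cm.metrics:
            if a not in assays:
                assays.append(a)
    combined: dict[str, dict[str, MetricValue]] = {}
    for assay in assays:
        combined[assay] = {}
        for metric in METRIC_KEYS:
            avail = [
                cm
                for cm in per_cohort
                if assay in cm.metrics and cm.metrics[assay][metric].available
            ]
            if not avail:
                combined[assay][metric] = MetricValue.na()
                continue
            total_n = sum(cm.n_total for cm in avail)
            value = (
                sum(cm.metrics[assay][metric].value * cm.n_total for cm in avail)
                / total_n
            )
            combined[assay][metric] = MetricValue(value, value * total_n, total_n)
    return CombinedMetrics(
        metrics=combined, weights={cm.cohort: cm.n_total for cm in per_cohort}
    )


def pearson_r2(x, y) -> dict:
    """Pearson r and r^2 (both returned so the sign is never lost)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) != len(y):
        raise InputError("x and y must have equal length")
    if len(x) < 3:
        raise InputError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("correlation undefined for zero-variance input")
    r = float(stats.pearsonr(x, y).statistic)
    return {"r": r, "r2": r * r}


EXACT_MW_MAX_N = 12


def mann_whitney_test(a, b) -> dict:
    """Two-sided Mann-Whitney U test.

    Exact p (equivalent to full enumeration of rank assignments) when the
    combined sample has <= 12 observations and no ties; otherwise a normal
    approximation with tie correction and a continuity correction applied as
    max(|U - mu| - 1/2, 0), so identical samples give p = 1.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InputError("each group needs >= 2 observations")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if n1 + n2 <= EXACT_MW_MAX_N and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return {"U": float(res.statistic), "p_two_sided": float(res.pvalue)}
    ranks = stats.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return {"U": u1, "p_two_sided": 1.0}
    z = max(abs(u1 - mu) - 0.5, 0.0) / np.sqrt(var)
    p = min(1.0, 2.0 * float(stats.norm.sf(z)))
    return {"U": u1, "p_two_sided": p}


def two_sample_t_test(a, b) -> dict:
    """Student's two-sample t test with pooled variance, two-sided.

    Zero pooled variance with equal means returns t = 0, p = 1 (no-effect
    convention); with unequal means it raises, since t is infinite.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InputError("each group needs >= 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InputError("inputs contain non-finite values")
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        if diff == 0:
            return {"t": 0.0, "p_two_sided": 1.0, "df": df}
        raise UndefinedStatisticError(
            "zero pooled variance with unequal means: t is infinite"
        )
    t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return {"t": float(t), "p_two_sided": p, "df": df}
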
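"""Validation statistics: contingency tables, classification metrics, exact tests.

These are the statistics used to judge a copy-number imputation panel
against real-time PCR truth data (sensitivity, specificity, PPV, NPV,
overall accuracy on the imputed-vs-genotyped cross-tabulation) and to
compare phenotype prevalences between groups (Fisher's exact test with
odds ratio and confidence interval, allele-frequency fold-enrichment).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from starimpute.panel import CopyNumberCall


@dataclass
class ContingencyTable:
    """Cross-tabulation of genotyped (rows) vs imputed (columns) CN classes."""

    row_labels: list
    col_labels: list
    counts: np.ndarray
    n_unmatched: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("count matrix shape does not match labels")
        if len(set(self.row_labels)) != len(self.row_labels):
            raise ValueError("row labels must be unique")
        if len(set(self.col_labels)) != len(self.col_labels):
            raise ValueError("column labels must be unique")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)

    def accuracy(self) -> float:
        """Fraction of samples whose imputed class equals the genotyped class."""
        diag = sum(
            self.counts[i, self.col_labels.index(r)]
            for i, r in enumerate(self.row_labels)
            if r in self.col_labels
        )
        return diag / self.total


def contingency(
    imputed: list[CopyNumberCall], genotyped: list[CopyNumberCall]
) -> ContingencyTable:
    """Cross-tabulate imputed vs genotyped calls matched on sample id.

    Samples present in only one list are counted in ``n_unmatched`` and
    excluded (with a warning).
    """
    if not imputed or not genotyped:
        raise ValueError("both call lists must be non-empty")
    imp = {c.sample_id: c.cn for c in imputed}
    gen = {c.sample_id: c.cn for c in genotyped}
    shared = sorted(set(imp) & set(gen))
    n_unmatched = len(set(imp) ^ set(gen))
    if not shared:
        raise ValueError("no overlapping sample ids between call lists")
    if n_unmatched:
        warnings.warn(f"{n_unmatched} samples present in only one call list; excluded")
    rows = sorted({gen[s] for s in shared})
    cols = sorted({imp[s] for s in shared})
    counts = np.zeros((len(rows), len(cols)), dtype=np.int64)
    for s in shared:
        counts[rows.index(gen[s]), cols.index(imp[s])] += 1
    return ContingencyTable(rows, cols, counts, n_unmatched=n_unmatched)


@dataclass
class ClassMetrics:
    """Binary classification metrics for one positive-class definition."""

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float | None = field(init=False)
    specificity: float | None = field(init=False)
    ppv: float | None = field(init=False)
    npv: float | None = field(init=False)
    accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        def ratio(num, den):
            return num / den if den > 0 else None  # undefined, not zero

        self.sensitivity = ratio(self.tp, self.tp + self.fn)
        self.specificity = ratio(self.tn, self.tn + self.fp)
        self.ppv = ratio(self.tp, self.tp + self.fp)
        self.npv = ratio(self.tn, self.tn + self.fn)
        self.accuracy = (self.tp + self.tn) / (self.tp + self.fp + self.fn + self.tn)


def class_metrics(
    table: ContingencyTable, positive, predicted_positive
) -> ClassMetrics:
    """Collapse a CN contingency table to binary metrics.

    ``positive`` is a predicate on genotyped (row) labels defining the true
    positive class; ``predicted_positive`` the predicate on imputed (column)
    labels.  Sensitivity/specificity/PPV/NPV follow the standard formulas;
    a metric with an empty denominator is reported as None.
    """
    tp = fp = fn = tn = 0
    for i, r in enumerate(table.row_labels):
        for j, c in enumerate(table.col_labels):
            n = int(table.counts[i, j])
            if positive(r):
                if predicted_positive(c):
                    tp += n
                else:
                    fn += n
            else:
                if predicted_positive(c):
                    fp += n
                else:
                    tn += n
    return ClassMetrics(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass
class TwoByTwo:
    """2×2 table in exposed-case layout: [[a, b], [c, d]]."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or v != int(v):
                raise ValueError("2x2 cells must be non-negative integers")

    @property
    def array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def fisher_exact(t: TwoByTwo) -> tuple[float, float, float]:
    """Fisher's exact test on a 2×2 table.

    Returns ``(p_two_sided, OR_sample, OR_conditional_mle)``.  The two-sided
    p sums hypergeometric probabilities no greater than that of the observed
    table with margins fixed (probability-mass ordering — the convention of
    the standard exact test in mainstream statistics environments).
    ``OR_sample`` is ad/bc; the conditional MLE maximizes the noncentral
    hypergeometric likelihood.  A zero margin is degenerate: p = 1 with a
    warning.
    """
    arr = t.array
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn("degenerate 2x2 table (zero margin): p = 1")
        return 1.0, math.nan, math.nan
    _, p = scipy.stats.fisher_exact(arr, alternative="two-sided")
    or_sample = (
        (t.a * t.d) / (t.b * t.c) if t.b * t.c > 0 else math.inf
    )
    or_cmle = float(scipy.stats.contingency.odds_ratio(arr, kind="conditional").statistic)
    return float(p), float(or_sample), or_cmle


def odds_ratio_ci(
    t: TwoByTwo, level: float = 0.95, continuity: bool = False
) -> tuple[float, float]:
    """Woolf (log-OR normal) confidence interval for the sample odds ratio.

    exp(ln OR ± z·sqrt(1/a + 1/b + 1/c + 1/d)).  Zero cells raise unless
    ``continuity`` adds 0.5 to every cell (Haldane–Anscombe).
    """
    a, b, c, d = (float(x) for x in (t.a, t.b, t.c, t.d))
    if continuity:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) <= 0:
        raise ValueError(
            "zero cell in 2x2 table; pass continuity=True for the +0.5 correction"
        )
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = scipy.stats.norm.ppf(0.5 + level / 2.0)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def odds_ratio_ci_exact(t: TwoByTwo, level: float = 0.95) -> tuple[float, float]:
    """Exact conditional confidence interval for the odds ratio."""
    res = scipy.stats.contingency.odds_ratio(t.array, kind="conditional")
    ci = res.confidence_interval(confidence_level=level)
    return float(ci.low), float(ci.high)


@dataclass
class EnrichmentResult:
    freq_group1: float
    freq_group2: float
    fold: float


def fold_enrichment(f1: float, f2: float) -> EnrichmentResult:
    """Allele-frequency ratio between two populations (group1 / group2)."""
    if not (0.0 <= f1 <= 1.0) or not (0.0 <= f2 <= 1.0):
        raise ValueError("frequencies must lie in [0, 1]")
    if f2 == 0:
        raise ValueError(
            "reference frequency is zero: enrichment is unbounded, not a number"
        )
    return EnrichmentResult(freq_group1=f1, freq_group2=f2, fold=f1 / f2)


def concordance(predicted: list, truth: list) -> float:
    """Fraction of pairwise-equal entries between two aligned call lists."""
    if len(predicted) != len(truth):
        raise ValueError("lists must be aligned")
    if not predicted:
        raise ValueError("empty input")
    return sum(p == t for p, t in zip(predicted, truth)) / len(predicted)


def compare_regions(
    calls: pd.DataFrame,
    category: str,
    region_col: str = "region",
    category_col: str = "category",
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Pairwise regional prevalence comparison of one phenotype category.

    For every pair of regions builds the carriers/non-carriers 2×2, runs
    Fisher's exact test and the Woolf interval.  Nominal p-values by
    default; optional Bonferroni across region pairs.
    """
    regions = sorted(calls[region_col].unique())
    rows = []
    pairs = [(r1, r2) for i, r1 in enumerate(regions) for r2 in regions[i + 1 :]]
    for r1, r2 in pairs:
        g1 = calls[calls[region_col] == r1]
        g2 = calls[calls[region_col] == r2]
        a = int((g1[category_col] == category).sum())
        c = int((g2[category_col] == category).sum())
        t = TwoByTwo(a, len(g1) - a, c, len(g2) - c)
        p, or_sample, or_cmle = fisher_exact(t)
        try:
            lo, hi = odds_ratio_ci(t)
        except ValueError:
            lo = hi = math.nan
        rows.append(
            {
                "region1": r1,
                "region2": r2,
                "prev1": a / len(g1),
                "prev2": c / len(g2),
                "odds_ratio": or_sample,
                "or_cmle": or_cmle,
                "ci_low": lo,
                "ci_high": hi,
                "p_value": min(1.0, p * len(pairs)) if bonferroni else p,
            }
        )
    return pd.DataFrame(rows)
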
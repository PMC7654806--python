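"""Accuracy/precision statistics over collections of dispensing runs.

Accuracy is the mean percent difference between the number dispensed and
the target; precision is the dispersion of the dispensed counts (95% CI of
the mean, integer mode, the proportions falling in target+/-2 and
target+/-5, normality and skew).  One-way ANOVA across detector-threshold
groups can be computed either from raw counts or from published-style
summaries (n, mean, 95% CI per group), with Tukey HSD pairwise comparisons
evaluated at a Bonferroni-adjusted alpha and reported as shared-letter
group labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .dispenser import DispenseRun

__all__ = [
    "EvalSummary",
    "GroupSummary",
    "AnovaResult",
    "accuracy_pct",
    "display_pct",
    "summarize_runs",
    "zscore_anova",
    "lps_accuracy_correlation",
    "two_sample_ttest",
    "z_error_probability",
    "disagreement_rate",
]


@dataclass
class EvalSummary:
    """Headline accuracy/precision numbers for a set of runs.

    ``mean_pct_error`` and ``ci95_halfwidth`` are percentages of the
    target; ``mode`` is the set of tied most-frequent integer counts;
    ``prop_98_102`` / ``prop_95_105`` are the proportions of runs within
    target+/-2 and target+/-5; ``shapiro_p`` tests normality of the
    counts; ``skew_direction`` is "left", "right" or "none".
    ``ci95_halfwidth`` and ``shapiro_p`` are None when the sample is too
    small to estimate them.
    """

    n_runs: int
    mean_pct_error: float
    ci95_halfwidth: Optional[float]
    mode: Tuple[int, ...]
    mode_count: int
    prop_98_102: float
    prop_95_105: float
    shapiro_p: Optional[float]
    skew_direction: str


@dataclass(frozen=True)
class GroupSummary:
    """Published-style per-group summary: label, n, mean, 95% CI half-width."""

    label: str
    n: int
    mean: float
    ci95_halfwidth: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @property
    def sd(self) -> Optional[float]:
        """Sample sd recovered from the CI half-width via the t quantile."""
        if self.ci95_halfwidth is None or self.n < 2:
            return None
        t = stats.t.ppf(0.975, self.n - 1)
        return self.ci95_halfwidth * math.sqrt(self.n) / t


@dataclass
class AnovaResult:
    ss_between: float
    ss_within: Optional[float]
    df_between: int
    df_within: int
    ms_between: float
    ms_within: Optional[float]
    f: Optional[float]
    p: Optional[float]
    letters: Optional[dict] = None  # label -> shared-letter string


def accuracy_pct(dispensed_mean: float, target: int) -> float:
    """Percent deviation of the dispensed mean from the target (raw value;
    headline figures round to the nearest integer percent)."""
    if target < 1:
        raise ValueError("target must be >= 1")
    return 100.0 * (dispensed_mean - target) / target


def display_pct(value: float, decimals: int = 0) -> float:
    """Display rounding (half away from zero), separate from stored precision."""
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(value) * factor + 0.5) / factor, value)


def _dispensed(runs: Union[Sequence[DispenseRun], Sequence[int]]) -> np.ndarray:
    vals = [r.dispensed if isinstance(r, DispenseRun) else r for r in runs]
    return np.asarray(vals, dtype=float)


def summarize_runs(runs: Union[Sequence[DispenseRun], Sequence[int]],
                   target: int) -> EvalSummary:
    """Accuracy/precision summary of dispensed counts against a target."""
    x = _dispensed(runs)
    n = len(x)
    if n < 1:
        raise ValueError("need at least one run")
    errors = 100.0 * (x - target) / target
    mean_err = float(np.mean(errors))

    if n >= 2 and np.std(errors, ddof=1) > 0:
        half = float(stats.t.ppf(0.975, n - 1) * np.std(errors, ddof=1) / math.sqrt(n))
    elif n >= 2:
        half = 0.0
    else:
        half = None

    ints = np.round(x).astype(int)
    values, counts = np.unique(ints, return_counts=True)
    top = counts.max()
    mode = tuple(int(v) for v in values[counts == top])

    prop_tight = float(np.mean((ints >= target - 2) & (ints <= target + 2)))
    prop_wide = float(np.mean((ints >= target - 5) & (ints <= target + 5)))

    if n >= 3 and np.ptp(x) > 0:
        shapiro_p = float(stats.shapiro(x).pvalue)
    else:
        shapiro_p = None

    if n >= 3 and np.std(x) > 0:
        g1 = float(stats.skew(x))
        skew_direction = "left" if g1 < 0 else ("right" if g1 > 0 else "none")
    else:
        skew_direction = "none"

    return EvalSummary(
        n_runs=n, mean_pct_error=mean_err, ci95_halfwidth=half,
        mode=mode, mode_count=int(top),
        prop_98_102=prop_tight, prop_95_105=prop_wide,
        shapiro_p=shapiro_p, skew_direction=skew_direction,
    )


def zscore_anova(groups: Union[Sequence[GroupSummary], Sequence[Sequence[float]]],
                 labels: Optional[Sequence[str]] = None,
                 alpha: float = 0.05,
                 bonferroni: bool = True) -> AnovaResult:
    """One-way ANOVA across threshold groups, from raw values or summaries.

    With :class:`GroupSummary` inputs the between-group sum of squares is
    computed from (n, mean) and the within-group variance recovered from
    the CI half-widths (sd = ci * sqrt(n) / t_{0.975,n-1}); groups of n=1
    or without a CI are excluded from the within-SS recovery (their df
    still counts toward df_within only if they contribute variance, so
    they are dropped from df_within too, with the exclusion recorded by a
    warning).  Pairwise comparisons use Tukey's honestly-significant-
    difference statistic evaluated, by default, at a Bonferroni-adjusted
    alpha; groups that do not differ share a letter.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if isinstance(groups[0], GroupSummary):
        summaries: List[GroupSummary] = list(groups)  # type: ignore[arg-type]
    else:
        if labels is None:
            labels = [str(i) for i in range(len(groups))]
        summaries = []
        for lab, vals in zip(labels, groups):
            v = np.asarray(vals, dtype=float)
            if len(v) >= 2:
                half = float(stats.t.ppf(0.975, len(v) - 1)
                             * np.std(v, ddof=1) / math.sqrt(len(v)))
            else:
                half = None
            summaries.append(GroupSummary(lab, len(v), float(np.mean(v)), half))

    ns = np.array([g.n for g in summaries], dtype=float)
    means = np.array([g.mean for g in summaries], dtype=float)
    total_n = ns.sum()
    grand = float((ns * means).sum() / total_n)
    ss_between = float((ns * (means - grand) ** 2).sum())
    df_between = len(summaries) - 1
    df_within = int(total_n) - len(summaries)
    ms_between = ss_between / df_between

    usable = [g for g in summaries if g.sd is not None]
    if len(usable) < len(summaries):
        import warnings
        excluded = [g.label for g in summaries if g.sd is None]
        warnings.warn(
            f"groups excluded from within-group variance recovery: {excluded}")
    if usable:
        ss_within = float(sum((g.n - 1) * g.sd ** 2 for g in usable))
        df_w_recovered = sum(g.n - 1 for g in usable)
        ms_within = ss_within / df_w_recovered if df_w_recovered > 0 else None
    else:
        ss_within = None
        ms_within = None

    if ms_within and ms_within > 0:
        f = ms_between / ms_within
        p = float(stats.f.sf(f, df_between, df_within))
    elif ss_between == 0:
        f, p = 0.0, 1.0
    else:
        f, p = None, None

    letters = None
    if ms_within and ms_within > 0:
        letters = _tukey_letters(summaries, ms_within, df_within, alpha,
                                 bonferroni)

    return AnovaResult(ss_between=ss_between, ss_within=ss_within,
                       df_between=df_between, df_within=df_within,
                       ms_between=ms_between, ms_within=ms_within,
                       f=f, p=p, letters=letters)


def _tukey_letters(summaries: Sequence[GroupSummary], ms_within: float,
                   df_within: int, alpha: float, bonferroni: bool) -> dict:
    k = len(summaries)
    n_pairs = k * (k - 1) // 2
    a = alpha / n_pairs if bonferroni else alpha
    q_crit = stats.studentized_range.ppf(1.0 - a, k, df_within)
    differ = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            se = math.sqrt(ms_within / 2.0
                           * (1.0 / summaries[i].n + 1.0 / summaries[j].n))
            if abs(summaries[i].mean - summaries[j].mean) > q_crit * se:
                differ[i, j] = differ[j, i] = True
    return _compact_letter_display([g.label for g in summaries], differ)


def _compact_letter_display(labels: Sequence[str], differ: np.ndarray) -> dict:
    """Greedy insert-and-absorb compact letter display: groups sharing a
    letter are not significantly different."""
    k = len(labels)
    letter_sets: List[set] = []
    for i in range(k):
        placed = False
        for s in letter_sets:
            if all(not differ[i, j] for j in s):
                s.add(i)
                placed = True
        if not placed:
            new = {i}
            # absorb every group compatible with all current members
            for j in range(k):
                if j != i and all(not differ[j, m] for m in new):
                    new.add(j)
            letter_sets.append(new)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lab: "" for lab in labels}
    for idx, s in enumerate(letter_sets):
        for i in sorted(s):
            out[labels[i]] += alphabet[idx % len(alphabet)]
    return out


def lps_accuracy_correlation(runs: Sequence[DispenseRun]
                             ) -> Tuple[Optional[float], Optional[float]]:
    """Pearson correlation between per-run mean LPS and percent error."""
    if len(runs) < 3:
        raise ValueError("need at least three runs")
    lps = np.array([r.mean_lps for r in runs])
    err = np.array([r.pct_error for r in runs])
    if np.std(lps) == 0 or np.std(err) == 0:
        return None, None
    r, p = stats.pearsonr(lps, err)
    return float(r), float(p)


def two_sample_ttest(mean1: float, sd1: float, n1: int,
                     mean2: float, sd2: float, n2: int,
                     welch: bool = False) -> Tuple[float, float, float]:
    """Two-sided two-sample t-test from summary statistics.

    Pooled-variance by default; ``welch=True`` for unequal variances.
    Returns (t, df, p).  With both sds zero and equal means, p = 1 by
    convention.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("sds must be non-negative")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return 0.0, float(n1 + n2 - 2), 1.0
        return math.inf, float(n1 + n2 - 2), 0.0
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                     equal_var=not welch)
    if welch:
        v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
        df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    else:
        df = float(n1 + n2 - 2)
    return float(res.statistic), float(df), float(res.pvalue)


def z_error_probability(z: float) -> float:
    """Two-sided standard-normal exceedance probability 2(1 - Phi(z)).

    The manufacturer's default trigger threshold of 3.5 baseline standard
    deviations corresponds to a random-error probability of ~0.00047, one
    spurious flag per ~2100 samples of pure noise.
    """
    if z < 0:
        raise ValueError("z must be non-negative")
    return float(2.0 * stats.norm.sf(z))


def disagreement_rate(n_disagree: int, n_total: int) -> float:
    """Percent of paired counts that disagreed (raw value; display to one
    decimal)."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_disagree <= n_total:
        raise ValueError("n_disagree must lie in [0, n_total]")
    return 100.0 * n_disagree / n_total
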
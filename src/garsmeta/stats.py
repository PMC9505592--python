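"""Per-study association statistics.

Odds ratios with Wald confidence intervals (Haldane-Anscombe corrected when
a cell is empty), Pearson chi-square, Fisher's exact test (point-probability
rule), the Wilcoxon rank-sum test, and Hardy-Weinberg equilibrium testing
with an exact fallback for sparse genotype classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .data import ContingencyTable, GenotypeCounts

__all__ = [
    "EffectEstimate",
    "TestResult",
    "study_odds_ratio",
    "pearson_chi2",
    "fisher_exact",
    "wilcoxon_rank_sum",
    "hwe_test",
]


@dataclass(frozen=True)
class EffectEstimate:
    """A single study's log odds ratio and its sampling uncertainty."""

    log_or: float
    se: float
    or_value: float
    ci_low: float
    ci_high: float
    corrected: bool = False
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"se must be positive, got {self.se}")
        if not (self.ci_low <= self.or_value <= self.ci_high):
            raise ValueError("confidence interval must contain the point estimate")
        if self.ci_low <= 0:
            raise ValueError("odds-ratio CI bounds must be strictly positive")


@dataclass(frozen=True)
class TestResult:
    """A test statistic, optional degrees of freedom, and two-sided p-value.

    ``note`` carries non-fatal flags such as "monomorphic" (HWE undefined)
    or "exact" (exact fallback used).
    """

    statistic: float
    df: int | None
    p_value: float
    note: str | None = None

    def __post_init__(self) -> None:
        if self.note != "monomorphic" and not 0 <= self.p_value <= 1:
            raise ValueError(f"p_value must lie in [0, 1], got {self.p_value}")
        if self.df is not None and self.df < 1:
            raise ValueError(f"df must be a positive integer, got {self.df}")


def study_odds_ratio(table: ContingencyTable, alpha: float = 0.05,
                     label: str | None = None) -> EffectEstimate:
    """Odds ratio and Wald CI for one study's 2x2 allele-count table.

    OR = (a*d)/(b*c) with a..d the case-risk, case-other, control-risk and
    control-other counts.  If any cell is zero, 0.5 is added to all four
    cells (Haldane-Anscombe) and the estimate is flagged ``corrected``.
    A zero column even before correction (no risk alleles anywhere, or no
    reference alleles anywhere) leaves the OR undefined and raises.
    """
    a, b, c, d = table.cells
    if (a == 0 and c == 0) or (b == 0 and d == 0):
        raise ValueError("odds ratio undefined: a full column of the 2x2 table is zero")
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(1 - alpha / 2)
    return EffectEstimate(
        log_or=log_or,
        se=se,
        or_value=math.exp(log_or),
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        corrected=corrected,
        label=label,
    )


def pearson_chi2(table: np.ndarray | list) -> TestResult:
    """Pearson chi-square test of independence on a rectangular count table."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("chi-square test undefined with a zero margin")
    stat, p, df, _ = sps.chi2_contingency(arr, correction=False)
    return TestResult(statistic=float(stat), df=int(df), p_value=float(p))


def fisher_exact(table: ContingencyTable | np.ndarray | list) -> TestResult:
    """Fisher's exact test on a 2x2 table.

    Two-sided by the point-probability rule: the p-value sums the
    hypergeometric probabilities of every margin-preserving table whose
    probability does not exceed that of the observed table.
    """
    arr = table.as_array() if isinstance(table, ContingencyTable) else np.asarray(table)
    _, p = sps.fisher_exact(arr, alternative="two-sided")
    return TestResult(statistic=float(_), df=None, p_value=float(min(p, 1.0)))


def wilcoxon_rank_sum(group_a, group_b) -> TestResult:
    """Two-sided Wilcoxon rank-sum test with mid-ranks for ties.

    Uses exact enumeration of the rank-sum distribution when the combined
    sample size is at most 10 and the data are tie-free; otherwise the
    normal approximation with tie-corrected variance and no continuity
    correction.  The reported statistic is group_a's rank sum.
    """
    x = np.asarray(group_a, dtype=float)
    y = np.asarray(group_b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n = x.size + y.size
    ranks = sps.rankdata(np.concatenate([x, y]))
    w = float(ranks[: x.size].sum())
    has_ties = len(np.unique(np.concatenate([x, y]))) < n
    method = "exact" if (n <= 10 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=False)
    return TestResult(statistic=w, df=None, p_value=float(min(res.pvalue, 1.0)),
                      note=None if method == "asymptotic" else "exact")


def _hwe_exact_p(counts: GenotypeCounts) -> float:
    """Exact Hardy-Weinberg test: sum of probabilities, over heterozygote
    counts compatible with the observed allele counts, that do not exceed
    the observed configuration's probability (point-probability rule)."""
    n = counts.total
    n_rare = min(2 * counts.n_hom_risk + counts.n_het,
                 2 * counts.n_hom_other + counts.n_het)
    obs_het = counts.n_het
    # P(het = h | allele counts) up to a shared constant, via the recurrence
    # P(h+2)/P(h) = 4*hom_rare(h)*hom_common(h) / ((h+2)*(h+1)).
    h0 = n_rare % 2
    hs = list(range(h0, n_rare + 1, 2))
    logp = {h0: 0.0}
    for h in hs[:-1]:
        hom_rare = (n_rare - h) // 2
        hom_common = n - hom_rare - h
        logp[h + 2] = logp[h] + math.log(4 * hom_rare * hom_common) - math.log((h + 2) * (h + 1))
    mx = max(logp.values())
    probs = {h: math.exp(lp - mx) for h, lp in logp.items()}
    total = sum(probs.values())
    p_obs = probs[obs_het] / total
    return min(1.0, sum(p for p in probs.values() if p / total <= p_obs * (1 + 1e-12)) / total)


def hwe_test(counts: GenotypeCounts) -> TestResult:
    """Hardy-Weinberg equilibrium test for one sample's genotype counts.

    Pearson's 1-df chi-square against the expected proportions
    (n p^2, 2 n p q, n q^2) at the observed allele frequency p.  When any
    expected genotype count is below 5 the chi-square approximation is
    unreliable and an exact test conditional on the allele counts is used
    instead (flagged ``note="exact"``).  A monomorphic sample leaves the
    test undefined and is flagged rather than raising.
    """
    n = counts.total
    p = counts.allele_freq
    if p in (0.0, 1.0):
        return TestResult(statistic=float("nan"), df=None, p_value=float("nan"),
                          note="monomorphic")
    q = 1 - p
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([counts.n_hom_risk, counts.n_het, counts.n_hom_other], dtype=float)
    if expected.min() < 5:
        return TestResult(statistic=float("nan"), df=None,
                          p_value=_hwe_exact_p(counts), note="exact")
    stat = float(((observed - expected) ** 2 / expected).sum())
    return TestResult(statistic=stat, df=1, p_value=float(sps.chi2.sf(stat, 1)))
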
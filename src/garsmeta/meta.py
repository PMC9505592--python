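"""Meta-analytic pooling of per-study odds ratios.

Two fixed-effects estimators (inverse-variance on the log-OR scale and
Mantel-Haenszel on the counts, with the Robins-Breslow-Greenland variance),
the DerSimonian-Laird random-effects model, the Z-test on the pooled log-OR,
Bonferroni adjustment, and leave-one-out sensitivity analysis.

The module-level functions are the primitive estimators; :class:`MetaAnalysis`
wraps a study collection into a model object whose :meth:`MetaAnalysis.fit`
returns a :class:`MetaAnalysisResults` carrying the pooled estimate together
with heterogeneity, bias diagnostics, power, and sensitivity methods.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import ContingencyTable, StudyRecord
from .stats import EffectEstimate, TestResult, study_odds_ratio

logger = logging.getLogger(__name__)

__all__ = [
    "PooledResult",
    "pool_fixed_iv",
    "pool_mantel_haenszel",
    "pool_random_dl",
    "z_test",
    "bonferroni",
    "leave_one_out",
    "MetaAnalysis",
    "MetaAnalysisResults",
]


@dataclass(frozen=True)
class PooledResult:
    """A pooled odds ratio and its inferential summary.

    ``model`` tags the estimator: ``fixed_iv``, ``fixed_mh`` or
    ``random_dl``.  ``tau2`` is the between-study variance (always 0 for
    the fixed models).  ``per_study_weights`` are normalized to sum to 1.
    ``omitted`` labels the study left out in a sensitivity re-fit.
    """

    model: str
    k: int
    pooled_log_or: float
    pooled_se: float
    or_value: float
    ci_low: float
    ci_high: float
    z: float
    p_value: float
    tau2: float = 0.0
    per_study_weights: tuple[float, ...] = ()
    omitted: str | None = None
    note: str | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be at least 1")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        if not (self.ci_low <= self.or_value <= self.ci_high):
            raise ValueError("CI must contain the pooled estimate")
        if self.per_study_weights:
            w = np.asarray(self.per_study_weights)
            if (w <= 0).any() or not math.isclose(w.sum(), 1.0, rel_tol=1e-9):
                raise ValueError("weights must be positive and sum to 1")


def _summarize(model: str, k: int, pooled: float, se: float, alpha: float,
               tau2: float, weights: np.ndarray, note: str | None = None) -> PooledResult:
    zq = sps.norm.ppf(1 - alpha / 2)
    ztest = z_test(pooled, se)
    return PooledResult(
        model=model, k=k, pooled_log_or=pooled, pooled_se=se,
        or_value=math.exp(pooled),
        ci_low=math.exp(pooled - zq * se), ci_high=math.exp(pooled + zq * se),
        z=ztest.statistic, p_value=ztest.p_value, tau2=tau2,
        per_study_weights=tuple(weights / weights.sum()), note=note,
    )


def pool_fixed_iv(estimates: Sequence[EffectEstimate], alpha: float = 0.05) -> PooledResult:
    """Fixed-effects pooling by inverse-variance weighting on the log-OR scale."""
    if not estimates:
        raise ValueError("cannot pool an empty collection")
    theta = np.array([e.log_or for e in estimates])
    w = np.array([1.0 / e.se**2 for e in estimates])
    pooled = float((w * theta).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    return _summarize("fixed_iv", len(estimates), pooled, se, alpha, 0.0, w)


def pool_mantel_haenszel(tables: Sequence[ContingencyTable],
                         alpha: float = 0.05) -> PooledResult:
    """Mantel-Haenszel pooled odds ratio over stratified 2x2 tables.

    OR_MH = sum(a_i d_i / n_i) / sum(b_i c_i / n_i); the variance of its
    logarithm is the Robins-Breslow-Greenland estimator, valid in both the
    sparse-data and the large-stratum limit.  No continuity correction is
    applied: zero cells are handled natively by the summation.
    """
    if not tables:
        raise ValueError("cannot pool an empty collection")
    a, b, c, d = (np.array(x, dtype=float)
                  for x in zip(*(t.cells for t in tables)))
    n = a + b + c + d
    R = a * d / n
    S = b * c / n
    if S.sum() == 0:
        raise ValueError("Mantel-Haenszel OR undefined: no discordant information")
    if R.sum() == 0:
        raise ValueError("Mantel-Haenszel OR is zero: log-OR undefined")
    or_mh = R.sum() / S.sum()
    P = (a + d) / n
    Q = (b + c) / n
    var = ((P * R).sum() / (2 * R.sum() ** 2)
           + (P * S + Q * R).sum() / (2 * R.sum() * S.sum())
           + (Q * S).sum() / (2 * S.sum() ** 2))
    weights = np.where(S > 0, S, np.finfo(float).tiny)
    return _summarize("fixed_mh", len(tables), math.log(or_mh), math.sqrt(var),
                      alpha, 0.0, weights)


def pool_random_dl(estimates: Sequence[EffectEstimate], alpha: float = 0.05) -> PooledResult:
    """DerSimonian-Laird random-effects pooling.

    The between-study variance tau^2 is the moment estimator
    max(0, (Q - (k-1)) / (sum(w) - sum(w^2)/sum(w))) with fixed-effects
    weights w = 1/se^2 and Cochran's Q; the pooled estimate then uses
    weights 1/(se^2 + tau^2).  With a single study the fixed-effects
    estimate is returned with a logged note.
    """
    if not estimates:
        raise ValueError("cannot pool an empty collection")
    if len(estimates) == 1:
        logger.info("random-effects pooling with k=1 falls back to fixed effects")
        res = pool_fixed_iv(estimates, alpha)
        return replace(res, model="random_dl", note="k=1: fixed-effects fallback")
    theta = np.array([e.log_or for e in estimates])
    w = np.array([1.0 / e.se**2 for e in estimates])
    fixed = float((w * theta).sum() / w.sum())
    q = float((w * (theta - fixed) ** 2).sum())
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - (len(estimates) - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (np.array([e.se**2 for e in estimates]) + tau2)
    pooled = float((w_star * theta).sum() / w_star.sum())
    se = float(w_star.sum() ** -0.5)
    return _summarize("random_dl", len(estimates), pooled, se, alpha, tau2, w_star)


def z_test(pooled_log_or: float, pooled_se: float) -> TestResult:
    """Standard two-sided Z-test of the pooled log-OR against zero."""
    if not pooled_se > 0:
        raise ValueError("pooled_se must be positive")
    z = pooled_log_or / pooled_se
    return TestResult(statistic=float(z), df=None,
                      p_value=float(2 * sps.norm.sf(abs(z))))


def bonferroni(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment min(1, p*m); m defaults to the number of tests."""
    p = list(p_values)
    if m is None:
        m = len(p)
    if m < 1:
        raise ValueError("m must be a positive integer")
    if m < len(p):
        raise ValueError(f"m={m} is smaller than the number of p-values ({len(p)})")
    return [min(1.0, v * m) for v in p]


def leave_one_out(estimates: Sequence[EffectEstimate], model: str = "fixed_iv",
                  alpha: float = 0.05) -> list[PooledResult]:
    """Sensitivity analysis: re-pool k times, omitting one study each time."""
    if len(estimates) < 2:
        raise ValueError("leave-one-out requires at least 2 studies")
    pool = {"fixed_iv": pool_fixed_iv, "random_dl": pool_random_dl}[model]
    out = []
    for i, e in enumerate(estimates):
        rest = [x for j, x in enumerate(estimates) if j != i]
        res = pool(rest, alpha)
        out.append(replace(res, omitted=e.label if e.label is not None else str(i)))
    return out


class MetaAnalysis:
    """Meta-analysis model for one polymorphism's case-control studies.

    Built either from per-study effect estimates or from raw 2x2 allele
    tables (in which case Mantel-Haenszel fixed-effects pooling becomes
    available and is the fixed-effects default, being robust to sparse
    cells).

    Parameters
    ----------
    estimates
        Per-study log-OR estimates.  Computed from ``tables`` when omitted.
    tables
        Per-study 2x2 allele-count tables.
    labels
        Study identifiers, used to label sensitivity re-fits.
    alpha
        Significance level for every CI and test (default 0.05).
    """

    def __init__(self, estimates: Sequence[EffectEstimate] | None = None,
                 tables: Sequence[ContingencyTable] | None = None,
                 labels: Sequence[str] | None = None, alpha: float = 0.05):
        if estimates is None and tables is None:
            raise ValueError("provide estimates and/or tables")
        if labels is None and estimates is not None:
            labels = [e.label or str(i) for i, e in enumerate(estimates)]
        elif labels is None:
            labels = [str(i) for i in range(len(tables))]
        if estimates is None:
            estimates = [study_odds_ratio(t, alpha, label=lab)
                         for t, lab in zip(tables, labels)]
        self.estimates = list(estimates)
        self.tables = list(tables) if tables is not None else None
        self.labels = list(labels)
        self.alpha = alpha
        if self.tables is not None and len(self.tables) != len(self.estimates):
            raise ValueError("tables and estimates must have equal length")

    @classmethod
    def from_studies(cls, studies: Sequence[StudyRecord], alpha: float = 0.05)\
            -> "MetaAnalysis":
        """Build the model from :class:`StudyRecord` objects."""
        return cls(tables=[s.table for s in studies],
                   labels=[s.study_id for s in studies], alpha=alpha)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, alpha: float = 0.05) -> "MetaAnalysis":
        """Build the model from a DataFrame with the study-table columns."""
        tables = [ContingencyTable(int(r.case_risk), int(r.case_other),
                                   int(r.control_risk), int(r.control_other))
                  for r in df.itertuples(index=False)]
        labels = [str(x) for x in (df["study_id"] if "study_id" in df else df.index)]
        return cls(tables=tables, labels=labels, alpha=alpha)

    @property
    def k(self) -> int:
        return len(self.estimates)

    def heterogeneity(self):
        """Cochran's Q and I-squared for the collection (k >= 2)."""
        from .bias import cochran_q
        return cochran_q(self.estimates)

    def fit(self, method: str = "auto",
            heterogeneity_p_threshold: float = 0.10) -> "MetaAnalysisResults":
        """Pool the studies and return a results object.

        ``method`` is one of ``auto``, ``fixed``, ``fixed_iv``, ``fixed_mh``
        or ``random_dl``.  Under ``auto`` the random-effects model is
        selected when the heterogeneity Q-test p-value falls below
        ``heterogeneity_p_threshold`` (a deliberately liberal level, the
        Q-test having low power at small k); otherwise fixed effects:
        Mantel-Haenszel when raw tables are available, inverse-variance
        otherwise.
        """
        het = self.heterogeneity() if self.k >= 2 else None
        if method == "auto":
            if het is not None and het.p_value < heterogeneity_p_threshold:
                method = "random_dl"
            else:
                method = "fixed"
        if method == "fixed":
            method = "fixed_mh" if self.tables is not None else "fixed_iv"
        if method == "fixed_iv":
            pooled = pool_fixed_iv(self.estimates, self.alpha)
        elif method == "fixed_mh":
            if self.tables is None:
                raise ValueError("Mantel-Haenszel pooling requires raw tables")
            pooled = pool_mantel_haenszel(self.tables, self.alpha)
        elif method == "random_dl":
            pooled = pool_random_dl(self.estimates, self.alpha)
        else:
            raise ValueError(f"unknown pooling method {method!r}")
        return MetaAnalysisResults(self, pooled, het)


class MetaAnalysisResults:
    """Fitted pooled estimate plus diagnostic and sensitivity methods."""

    def __init__(self, model: MetaAnalysis, pooled: PooledResult, heterogeneity):
        self.model = model
        self.pooled = pooled
        self.heterogeneity = heterogeneity

    # -- convenience accessors -------------------------------------------
    @property
    def or_value(self) -> float:
        return self.pooled.or_value

    @property
    def ci(self) -> tuple[float, float]:
        return (self.pooled.ci_low, self.pooled.ci_high)

    @property
    def p_value(self) -> float:
        return self.pooled.p_value

    # -- diagnostics ------------------------------------------------------
    def egger_test(self):
        from .bias import egger_test
        return egger_test(self.model.estimates)

    def begg_test(self):
        from .bias import begg_test
        return begg_test(self.model.estimates)

    def trim_and_fill(self, side: str = "auto"):
        from .bias import trim_and_fill
        model = self.pooled.model if self.pooled.model in ("fixed_iv", "random_dl") \
            else "fixed_iv"
        return trim_and_fill(self.model.estimates, side=side,
                             alpha=self.model.alpha, model=model)

    def power(self, delta: float | None = None) -> float:
        """Approximate power of the pooled Z-test for true log-OR ``delta``
        (defaults to the observed pooled estimate)."""
        from .bias import power_approximation
        if delta is None:
            delta = self.pooled.pooled_log_or
        return power_approximation(delta, self.pooled.pooled_se, self.model.alpha)

    def leave_one_out(self) -> list[PooledResult]:
        model = self.pooled.model if self.pooled.model != "fixed_mh" else "fixed_iv"
        return leave_one_out(self.model.estimates, model=model, alpha=self.model.alpha)

    def risk_conversion(self, pre_test_risk: float = 0.08):
        from .risk import pre_to_post
        return pre_to_post(pre_test_risk, self.pooled.or_value)

    def plot_funnel(self, ax=None, path=None):
        from .bias import funnel_plot
        return funnel_plot(self.model.estimates, center=self.pooled.pooled_log_or,
                           ax=ax, path=path)

    def summary(self) -> str:
        """Plain-text summary table in the style of statsmodels results."""
        p = self.pooled
        lines = [
            "Meta-analysis of case-control odds ratios",
            "=" * 57,
            f"model:          {p.model:>12}    studies (k):   {p.k:>8d}",
            f"pooled OR:      {p.or_value:>12.4f}    log OR:        {p.pooled_log_or:>8.4f}",
            f"{(1 - self.model.alpha) * 100:.0f}% CI:         "
            f"({p.ci_low:.4f}, {p.ci_high:.4f})",
            f"Z:              {p.z:>12.4f}    p-value:       {p.p_value:>8.4g}",
            f"tau^2:          {p.tau2:>12.4f}",
        ]
        if self.heterogeneity is not None:
            h = self.heterogeneity
            lines.append(
                f"Cochran Q:      {h.q:>12.4f}    df: {h.df:>3d}   p: {h.p_value:.4g}   "
                f"I^2: {h.i2:.1%}")
        lines.append("=" * 57)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        p = self.pooled
        return (f"<MetaAnalysisResults {p.model} k={p.k} "
                f"OR={p.or_value:.3f} CI=({p.ci_low:.3f}, {p.ci_high:.3f})>")
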
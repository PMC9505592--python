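"""Heterogeneity, power and publication-bias diagnostics.

Cochran's Q with I-squared, the Hedges-Pigott normal-approximation power of
the pooled Z-test, Egger's regression asymmetry test, the Begg-Mazumdar
rank-correlation test, and the Duval-Tweedie trim-and-fill adjustment
(L0 estimator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .meta import PooledResult, pool_fixed_iv, pool_random_dl
from .stats import EffectEstimate

__all__ = [
    "HeterogeneityResult",
    "EggerResult",
    "BeggResult",
    "TrimFillResult",
    "BiasAssessment",
    "cochran_q",
    "power_approximation",
    "egger_test",
    "begg_test",
    "trim_and_fill",
    "funnel_plot",
]


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q, its chi-square p-value and I^2 = max(0, 1 - df/Q)."""

    q: float
    df: int
    p_value: float
    i2: float

    def __post_init__(self) -> None:
        if self.q < -1e-12:
            raise ValueError("Q must be non-negative")
        if not 0 <= self.i2 <= 1:
            raise ValueError("I^2 must lie in [0, 1]")


@dataclass(frozen=True)
class EggerResult:
    """Egger regression-intercept asymmetry test components."""

    intercept: float
    se: float
    t: float
    df: int
    p_value: float
    slope: float


@dataclass(frozen=True)
class BeggResult:
    """Begg-Mazumdar rank correlation (Kendall tau-b) components."""

    tau: float
    p_value: float

    def __post_init__(self) -> None:
        if not -1 <= self.tau <= 1:
            raise ValueError("tau must lie in [-1, 1]")


@dataclass(frozen=True)
class TrimFillResult:
    """Trim-and-fill imputation outcome.

    ``k0`` is the estimated number of suppressed studies, ``side`` the side
    of the funnel they are imputed on, ``adjusted`` the re-pooled result
    over observed plus filled studies, and ``filled_estimates`` the mirror
    studies themselves (empty when k0 = 0).
    """

    k0: int
    side: str
    adjusted: PooledResult
    filled_estimates: tuple[EffectEstimate, ...]
    converged: bool

    def __post_init__(self) -> None:
        if self.k0 < 0:
            raise ValueError("k0 must be non-negative")
        if len(self.filled_estimates) != self.k0:
            raise ValueError("filled_estimates must have exactly k0 entries")


@dataclass(frozen=True)
class BiasAssessment:
    """Bundle of the publication-bias diagnostics for one polymorphism."""

    egger: EggerResult | None
    begg: BeggResult | None
    trim_fill: TrimFillResult | None


def cochran_q(estimates: Sequence[EffectEstimate]) -> HeterogeneityResult:
    """Cochran's heterogeneity Q and I^2 over a study collection.

    Q is the inverse-variance weighted sum of squared deviations of the
    per-study log-ORs from the fixed-effects pooled log-OR, referred to a
    chi-square distribution with k - 1 df.  I^2 = 1 - df/Q, clamped to
    [0, 1], expresses the fraction of observed variation attributable to
    between-study heterogeneity rather than sampling error.
    """
    k = len(estimates)
    if k < 2:
        raise ValueError("heterogeneity requires at least 2 studies")
    theta = np.array([e.log_or for e in estimates])
    w = np.array([1.0 / e.se**2 for e in estimates])
    pooled = (w * theta).sum() / w.sum()
    q = float((w * (theta - pooled) ** 2).sum())
    df = k - 1
    i2 = max(0.0, 1.0 - df / q) if q > 0 else 0.0
    return HeterogeneityResult(q=q, df=df, p_value=float(sps.chi2.sf(q, df)),
                               i2=min(1.0, i2))


def power_approximation(delta: float, pooled_se: float, alpha: float = 0.05) -> float:
    """Approximate power of the two-sided pooled Z-test.

    For an assumed true log-OR ``delta`` and the meta-analysis' pooled
    standard error, the noncentrality is lambda = delta/se and
    power = 1 - Phi(z_{1-a/2} - lambda) + Phi(-z_{1-a/2} - lambda).
    """
    if not pooled_se > 0:
        raise ValueError("pooled_se must be positive")
    lam = delta / pooled_se
    z = sps.norm.ppf(1 - alpha / 2)
    return float(sps.norm.sf(z - lam) + sps.norm.cdf(-z - lam))


def egger_test(estimates: Sequence[EffectEstimate]) -> EggerResult:
    """Egger's regression test for funnel-plot asymmetry.

    Ordinary least squares of the standardized effect log_or/se on the
    precision 1/se; a nonzero intercept indicates that small (imprecise)
    studies report systematically different effects.  The intercept is
    tested with a t statistic on k - 2 df.
    """
    k = len(estimates)
    if k < 3:
        raise ValueError("Egger's test requires at least 3 studies")
    prec = np.array([1.0 / e.se for e in estimates])
    z = np.array([e.log_or / e.se for e in estimates])
    if np.ptp(prec) == 0:
        raise ValueError("Egger's test undefined when all standard errors are equal")
    fit = sps.linregress(prec, z)
    if fit.intercept_stderr > 0:
        t = fit.intercept / fit.intercept_stderr
        p = float(2 * sps.t.sf(abs(t), k - 2))
    else:  # exact fit: intercept known without error
        t = math.copysign(math.inf, fit.intercept) if fit.intercept else 0.0
        p = 0.0 if fit.intercept else 1.0
    return EggerResult(
        intercept=float(fit.intercept), se=float(fit.intercept_stderr),
        t=float(t), df=k - 2, p_value=p, slope=float(fit.slope),
    )


def begg_test(estimates: Sequence[EffectEstimate]) -> BeggResult:
    """Begg-Mazumdar rank-correlation test for publication bias.

    Each study's deviation from the fixed-effects pooled log-OR is
    variance-stabilized (dividing by the variance of that deviation,
    se_i^2 - 1/sum(w)), then Kendall's tau-b between the standardized
    deviations and the variances is tested: exact enumeration for k <= 8
    tie-free collections, normal approximation otherwise.
    """
    k = len(estimates)
    if k < 3:
        raise ValueError("Begg's test requires at least 3 studies")
    theta = np.array([e.log_or for e in estimates])
    v = np.array([e.se**2 for e in estimates])
    w = 1.0 / v
    pooled = (w * theta).sum() / w.sum()
    v_star = v - 1.0 / w.sum()
    v_star = np.maximum(v_star, np.finfo(float).tiny)
    t_star = (theta - pooled) / np.sqrt(v_star)
    has_ties = (len(np.unique(t_star)) < k) or (len(np.unique(v)) < k)
    method = "exact" if (k <= 8 and not has_ties) else "asymptotic"
    res = sps.kendalltau(t_star, v, method=method)
    tau = 0.0 if math.isnan(res.statistic) else float(res.statistic)
    p = 1.0 if math.isnan(res.pvalue) else float(min(res.pvalue, 1.0))
    return BeggResult(tau=tau, p_value=p)


def _fixed_center(estimates: Sequence[EffectEstimate]) -> float:
    theta = np.array([e.log_or for e in estimates])
    w = np.array([1.0 / e.se**2 for e in estimates])
    return float((w * theta).sum() / w.sum())


def _l0_iterate(estimates: list[EffectEstimate], sign: float,
                max_iter: int) -> tuple[int, float, bool]:
    """Run the L0 trim iteration for suppression on one side.

    ``sign`` = +1 treats the *left* side as suppressed (observed studies
    pushed right); -1 the converse.  Returns (k0, final center, converged).
    """
    n = len(estimates)
    order = np.argsort([sign * e.log_or for e in estimates])  # ascending
    k0 = 0
    center = _fixed_center(estimates)
    for _ in range(max_iter):
        kept = [estimates[i] for i in order[: n - k0]] if k0 else list(estimates)
        center = _fixed_center(kept)
        dev = np.array([sign * (e.log_or - center) for e in estimates])
        ranks = sps.rankdata(np.abs(dev))
        t_n = float(ranks[dev > 0].sum())
        k0_new = max(0, int(round((4 * t_n - n * (n + 1)) / (2 * n - 1))))
        k0_new = min(k0_new, n - 1)
        if k0_new == k0:
            return k0, center, True
        k0 = k0_new
    return k0, center, False


def trim_and_fill(estimates: Sequence[EffectEstimate], side: str = "auto",
                  alpha: float = 0.05, model: str = "fixed_iv",
                  max_iter: int = 20) -> TrimFillResult:
    """Duval-Tweedie trim-and-fill adjustment for funnel asymmetry.

    Iteratively: pool, rank absolute deviations from the pooled center,
    estimate the number of suppressed studies with the L0 estimator
    k0 = (4 T_n - n(n+1)) / (2n - 1) (T_n the rank-sum of the unsuppressed
    side), trim the k0 most extreme studies on that side and re-pool, until
    k0 stabilizes or ``max_iter`` passes.  The trimmed studies are then
    mirrored about the final center to impute the presumed missing ones and
    the full (observed + filled) set is re-pooled with ``model``.

    ``side`` names the side of the funnel presumed suppressed; ``auto``
    runs both directions and keeps the one with the larger k0.
    """
    if len(estimates) < 3:
        raise ValueError("trim-and-fill requires at least 3 studies")
    estimates = list(estimates)
    if side == "auto":
        left = _l0_iterate(estimates, +1.0, max_iter)
        right = _l0_iterate(estimates, -1.0, max_iter)
        side, (k0, center, converged) = (
            ("left", left) if left[0] >= right[0] else ("right", right))
    elif side in ("left", "right"):
        k0, center, converged = _l0_iterate(
            estimates, +1.0 if side == "left" else -1.0, max_iter)
    else:
        raise ValueError("side must be 'left', 'right' or 'auto'")

    sign = +1.0 if side == "left" else -1.0
    order = np.argsort([sign * e.log_or for e in estimates])
    trimmed_idx = order[len(estimates) - k0:] if k0 else np.array([], dtype=int)
    filled = tuple(
        replace(estimates[i],
                log_or=2 * center - estimates[i].log_or,
                or_value=math.exp(2 * center - estimates[i].log_or),
                ci_low=math.exp(2 * center - estimates[i].log_or
                                - sps.norm.ppf(1 - alpha / 2) * estimates[i].se),
                ci_high=math.exp(2 * center - estimates[i].log_or
                                 + sps.norm.ppf(1 - alpha / 2) * estimates[i].se),
                label=f"filled:{estimates[i].label or i}")
        for i in trimmed_idx)
    pool = {"fixed_iv": pool_fixed_iv, "random_dl": pool_random_dl}[model]
    adjusted = pool(estimates + list(filled), alpha)
    return TrimFillResult(k0=k0, side=side, adjusted=adjusted,
                          filled_estimates=filled, converged=converged)


def funnel_plot(estimates: Sequence[EffectEstimate],
                filled: Sequence[EffectEstimate] = (),
                center: float | None = None, ax=None, path=None):
    """Funnel plot of per-study log-OR against precision (1/se).

    Observed studies are solid points; trim-and-fill imputations, if any,
    are open points.  Purely diagnostic output.
    """
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    x = [e.log_or for e in estimates]
    y = [1.0 / e.se for e in estimates]
    ax.scatter(x, y, s=18, c="k", label="observed")
    if filled:
        ax.scatter([e.log_or for e in filled], [1.0 / e.se for e in filled],
                   s=24, facecolors="none", edgecolors="crimson", label="filled")
    if center is None and estimates:
        center = _fixed_center(estimates)
    if center is not None:
        ax.axvline(center, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("log odds ratio")
    ax.set_ylabel("precision (1/SE)")
    if filled:
        ax.legend(frameon=False, fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
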
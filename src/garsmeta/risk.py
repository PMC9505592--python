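"""Pre-test to post-test risk conversion and risk-allele panel scoring.

A pooled odds ratio is translated into an individual's updated disease
probability through odds space: post-test odds = OR x pre-test odds, and
post-test risk = post-test odds / (1 + post-test odds).  The panel score is
the per-subject count of risk alleles across the eleven-allele reward-gene
panel, dichotomized against clinical cutoffs (defaults: 4 for drug risk,
7 for alcohol-use-disorder risk).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import PANEL_ALLELES, RunConfig

__all__ = [
    "RiskConversion",
    "PanelScore",
    "pre_to_post",
    "score_panel",
    "score_panel_table",
    "build_report",
]


@dataclass(frozen=True)
class RiskConversion:
    """Pre-test risk updated by an odds ratio into a post-test risk."""

    pre_test_risk: float
    pre_test_odds: float
    or_value: float
    post_test_odds: float
    post_test_risk: float
    gain: float

    def __post_init__(self) -> None:
        if not 0 < self.post_test_risk < 1:
            raise ValueError("post_test_risk must lie in (0, 1)")


@dataclass(frozen=True)
class PanelScore:
    """A subject's risk-allele count and its clinical dichotomization."""

    subject_id: str
    allele_count: int
    drug_risk_flag: bool
    aud_risk_flag: bool

    def __post_init__(self) -> None:
        if not 0 <= self.allele_count <= 2 * len(PANEL_ALLELES):
            raise ValueError("allele_count out of range for the panel")


def pre_to_post(pre_test_risk: float, or_value: float) -> RiskConversion:
    """Convert a baseline disease probability through an odds ratio.

    pre-test odds = risk / (1 - risk); post-test odds = OR x pre-test odds;
    post-test risk = post-test odds / (1 + post-test odds).  All arithmetic
    is kept at full precision; rounding is a presentation concern.
    """
    if not 0 < pre_test_risk < 1:
        raise ValueError(f"pre_test_risk must lie strictly in (0, 1), got {pre_test_risk}")
    if not or_value > 0:
        raise ValueError(f"or_value must be positive, got {or_value}")
    pre_odds = pre_test_risk / (1 - pre_test_risk)
    post_odds = or_value * pre_odds
    post_risk = post_odds / (1 + post_odds)
    return RiskConversion(
        pre_test_risk=pre_test_risk, pre_test_odds=pre_odds, or_value=or_value,
        post_test_odds=post_odds, post_test_risk=post_risk,
        gain=post_risk - pre_test_risk,
    )


def score_panel(dosages: Sequence[int], config: RunConfig | None = None,
                subject_id: str = "") -> PanelScore:
    """Score one subject's eleven risk-allele dosages against the cutoffs.

    In the default ``dosage`` mode the score is the plain sum of allele
    dosages (0-22); in ``carrier`` mode each allele contributes at most 1
    (0-11).  A score at or above the configured threshold raises the
    corresponding risk flag; with the default cutoffs (4 drugs, 7 AUD) the
    AUD flag implies the drug flag.
    """
    config = config or RunConfig()
    arr = np.asarray(dosages)
    if arr.shape != (len(PANEL_ALLELES),):
        raise ValueError(
            f"expected {len(PANEL_ALLELES)} allele dosages, got {arr.shape}")
    if not np.isin(arr, (0, 1, 2)).all():
        raise ValueError("dosages must be 0, 1 or 2")
    if config.panel_mode == "carrier":
        arr = np.minimum(arr, 1)
    count = int(arr.sum())
    return PanelScore(
        subject_id=subject_id,
        allele_count=count,
        drug_risk_flag=count >= config.drug_threshold,
        aud_risk_flag=count >= config.aud_threshold,
    )


def score_panel_table(subjects: pd.DataFrame,
                      config: RunConfig | None = None) -> pd.DataFrame:
    """Score every row of a subject-dosage table (as read by
    :func:`garsmeta.data.read_subject_genotypes`)."""
    scores = [score_panel(row.to_numpy(), config, subject_id=str(idx))
              for idx, row in subjects.iterrows()]
    return pd.DataFrame(
        {"subject_id": [s.subject_id for s in scores],
         "allele_count": [s.allele_count for s in scores],
         "drug_risk_flag": [s.drug_risk_flag for s in scores],
         "aud_risk_flag": [s.aud_risk_flag for s in scores]})


_REPORT_COLUMNS = [
    "gene", "polymorphism", "k", "model", "OR", "ci_low", "ci_high", "z", "p",
    "p_bonferroni", "Q", "I2", "tau2", "egger_p", "begg_p", "k0", "power",
    "post_risk", "flags",
]


def _fmt(x, digits=2):
    return "" if x is None or (isinstance(x, float) and math.isnan(x)) \
        else round(float(x), digits)


def build_report(per_gene: Mapping[str, object],
                 config: RunConfig | None = None) -> pd.DataFrame:
    """Assemble the per-polymorphism summary table.

    ``per_gene`` maps gene symbol to either a bare pooled result or a
    pipeline ``GeneAnalysis`` bundle; genes with too little data to pool
    are flagged ``insufficient_data`` and keep their row (with the OR
    shown but no post-test risk) rather than being dropped.  ORs, CI
    bounds and risks are rounded to two decimals for display; callers
    needing full precision should use the JSON sidecar.
    """
    if not per_gene:
        raise ValueError("report requires at least one gene")
    config = config or RunConfig()
    rows = []
    for gene, res in per_gene.items():
        pooled = getattr(res, "pooled", res)
        het = getattr(res, "heterogeneity", None)
        egger = getattr(res, "egger", None)
        begg = getattr(res, "begg", None)
        tf = getattr(res, "trim_fill", None)
        power = getattr(res, "power", None)
        p_bonf = getattr(res, "p_bonferroni", None)
        flags = list(getattr(res, "flags", ()))
        insufficient = "insufficient_data" in flags
        risk = None
        if pooled is not None and not insufficient:
            risk = pre_to_post(config.pre_test_risk, pooled.or_value)
        rows.append({
            "gene": gene,
            "polymorphism": getattr(res, "polymorphism", ""),
            "k": pooled.k if pooled is not None else 0,
            "model": pooled.model if pooled is not None else "",
            "OR": _fmt(pooled.or_value) if pooled is not None else "",
            "ci_low": _fmt(pooled.ci_low) if pooled is not None else "",
            "ci_high": _fmt(pooled.ci_high) if pooled is not None else "",
            "z": _fmt(pooled.z, 3) if pooled is not None else "",
            "p": _fmt(pooled.p_value, 4) if pooled is not None else "",
            "p_bonferroni": _fmt(p_bonf, 4) if p_bonf is not None else "",
            "Q": _fmt(het.q, 3) if het is not None else "",
            "I2": _fmt(het.i2, 3) if het is not None else "",
            "tau2": _fmt(pooled.tau2, 4) if pooled is not None else "",
            "egger_p": _fmt(egger.p_value, 4) if egger is not None else "",
            "begg_p": _fmt(begg.p_value, 4) if begg is not None else "",
            "k0": tf.k0 if tf is not None else "",
            "power": _fmt(power, 3) if power is not None else "",
            "post_risk": _fmt(risk.post_test_risk) if risk is not None else "",
            "flags": ";".join(flags),
        })
    return pd.DataFrame(rows, columns=_REPORT_COLUMNS)
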
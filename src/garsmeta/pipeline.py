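"""End-to-end per-gene analysis over a study collection.

For each polymorphism: per-study odds ratios (with continuity-correction
flags), Hardy-Weinberg checks where genotype counts are present, Cochran's
Q / I-squared, model selection by the heterogeneity rule, pooling, the
Z-test with Bonferroni adjustment across polymorphisms, leave-one-out
sensitivity, Egger and Begg bias tests, trim-and-fill when bias is
indicated, power approximation, and the pre-test to post-test risk
conversion.  Every correction or exclusion is surfaced in the warnings
list; no study is ever dropped silently.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .bias import (BiasAssessment, BeggResult, EggerResult, HeterogeneityResult,
                   TrimFillResult, begg_test, egger_test, trim_and_fill)
from .data import RunConfig, StudyRecord
from .meta import MetaAnalysis, MetaAnalysisResults, PooledResult, bonferroni
from .risk import RiskConversion, build_report, pre_to_post
from .stats import EffectEstimate, TestResult, hwe_test

logger = logging.getLogger(__name__)

__all__ = ["GeneAnalysis", "AnalysisRun", "run_analysis", "stratified_analysis"]


@dataclass
class GeneAnalysis:
    """Everything the pipeline computed for one polymorphism."""

    gene: str
    polymorphism: str
    k: int
    estimates: list[EffectEstimate]
    pooled: PooledResult | None = None
    heterogeneity: HeterogeneityResult | None = None
    p_bonferroni: float | None = None
    leave_one_out: list[PooledResult] = field(default_factory=list)
    egger: EggerResult | None = None
    begg: BeggResult | None = None
    trim_fill: TrimFillResult | None = None
    hwe_cases: list[TestResult] = field(default_factory=list)
    hwe_controls: list[TestResult] = field(default_factory=list)
    power: float | None = None
    risk: RiskConversion | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def bias(self) -> BiasAssessment:
        return BiasAssessment(egger=self.egger, begg=self.begg,
                              trim_fill=self.trim_fill)


@dataclass
class AnalysisRun:
    """One full pipeline execution: per-gene results plus global warnings."""

    config: RunConfig
    per_gene: dict[str, GeneAnalysis]
    warnings: list[str] = field(default_factory=list)

    def report(self):
        """The per-polymorphism summary table (two-decimal presentation)."""
        return build_report(self.per_gene, self.config)

    def to_json(self, indent: int = 2) -> str:
        """Full-precision machine-readable dump of the whole run."""

        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: enc(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if isinstance(obj, float) and obj != obj:  # NaN -> null
                return None
            return obj

        payload = {"config": enc(self.config),
                   "per_gene": {g: enc(r) for g, r in self.per_gene.items()},
                   "warnings": list(self.warnings)}
        return json.dumps(payload, indent=indent, sort_keys=True)


def _analyze_gene(gene: str, studies: Sequence[StudyRecord],
                  config: RunConfig, warnings: list[str]) -> GeneAnalysis:
    model = MetaAnalysis.from_studies(studies, alpha=config.alpha)
    res = GeneAnalysis(gene=gene, polymorphism=studies[0].polymorphism,
                       k=model.k, estimates=model.estimates)
    for est in model.estimates:
        if est.corrected:
            msg = f"{gene}/{est.label}: continuity correction (0.5) applied"
            res.flags.append("continuity_correction")
            warnings.append(msg)
            logger.info(msg)
    for s in studies:
        for arm, gt in (("cases", s.genotypes_cases), ("controls", s.genotypes_controls)):
            if gt is None:
                continue
            t = hwe_test(gt)
            getattr(res, f"hwe_{arm}").append(t)
            if t.note == "monomorphic":
                warnings.append(f"{gene}/{s.study_id}: HWE undefined (monomorphic {arm})")
            elif t.p_value < config.alpha:
                msg = f"{gene}/{s.study_id}: HWE deviation in {arm} (p={t.p_value:.3g})"
                res.flags.append("hwe_deviation")
                warnings.append(msg)
                logger.info(msg)

    if model.k < 2:
        res.flags.append("insufficient_data")
        warnings.append(f"{gene}: only {model.k} usable study; pooled estimate "
                        "reported but flagged insufficient")
        fitted = model.fit(method="fixed")
        res.pooled = fitted.pooled
        return res

    fitted: MetaAnalysisResults = model.fit(
        method="auto", heterogeneity_p_threshold=config.heterogeneity_p_threshold)
    res.pooled = fitted.pooled
    res.heterogeneity = fitted.heterogeneity
    logger.info("%s: k=%d model=%s OR=%.3f", gene, model.k, res.pooled.model,
                res.pooled.or_value)
    res.leave_one_out = fitted.leave_one_out()
    if model.k >= 3:
        try:
            res.egger = fitted.egger_test()
        except ValueError as exc:
            warnings.append(f"{gene}: Egger test skipped ({exc})")
        res.begg = fitted.begg_test()
        bias_found = ((res.egger is not None and res.egger.p_value < config.alpha)
                      or res.begg.p_value < config.alpha)
        if bias_found:
            res.trim_fill = fitted.trim_and_fill()
            res.flags.append("publication_bias")
            warnings.append(f"{gene}: publication bias indicated; trim-and-fill "
                            f"imputed k0={res.trim_fill.k0} studies")
            if not res.trim_fill.converged:
                res.flags.append("trim_fill_nonconverged")
                warnings.append(f"{gene}: trim-and-fill did not converge in 20 "
                                "iterations; last iterate reported")
    res.power = fitted.power(config.power_delta)
    res.risk = pre_to_post(config.pre_test_risk, res.pooled.or_value)
    return res


def run_analysis(studies: Sequence[StudyRecord],
                 config: RunConfig | None = None) -> AnalysisRun:
    """Run the full validation pipeline, one meta-analysis per gene.

    Genes with a single usable study are reported but flagged insufficient
    (no heterogeneity, bias or risk figures); the Bonferroni adjustment
    spans all pooled polymorphisms, with m at least ``config.bonferroni_m``
    when set.
    """
    if not studies:
        raise ValueError("cannot analyze an empty study collection")
    config = config or RunConfig()
    warnings: list[str] = []
    by_gene: dict[str, list[StudyRecord]] = {}
    for s in studies:
        by_gene.setdefault(s.gene, []).append(s)

    per_gene = {gene: _analyze_gene(gene, recs, config, warnings)
                for gene, recs in by_gene.items()}

    pooled_genes = [g for g, r in per_gene.items()
                    if r.pooled is not None and "insufficient_data" not in r.flags]
    if pooled_genes:
        m = max(config.bonferroni_m or 0, len(pooled_genes))
        adjusted = bonferroni([per_gene[g].pooled.p_value for g in pooled_genes], m)
        for g, p_adj in zip(pooled_genes, adjusted):
            per_gene[g].p_bonferroni = p_adj
    return AnalysisRun(config=config, per_gene=per_gene, warnings=warnings)


def stratified_analysis(studies: Sequence[StudyRecord], stratify_by: str,
                        config: RunConfig | None = None) -> dict[str, AnalysisRun]:
    """Re-run the pipeline within each level of a metadata covariate.

    Studies lacking the key are analyzed under an explicit ``unknown``
    stratum; a key present in no study at all is an error.
    """
    if not any(stratify_by in s.metadata for s in studies):
        raise ValueError(f"metadata key {stratify_by!r} present in no study")
    strata: dict[str, list[StudyRecord]] = {}
    for s in studies:
        strata.setdefault(str(s.metadata.get(stratify_by, "unknown")), []).append(s)
    return {level: run_analysis(recs, config)
            for level, recs in sorted(strata.items())}
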
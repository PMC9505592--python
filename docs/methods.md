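# Methods

This note documents the statistical procedures implemented in `garsmeta`,
the choices made where conventions differ, and what the synthetic-data
calibrations do and do not demonstrate.

## Model

The unit of analysis is a published case–control study of one biallelic
(or dichotomized) polymorphism, reduced to a 2×2 allele-count table with
cells a (case, risk allele), b (case, other), c (control, risk),
d (control, other). Carrier-based tables travel through the identical
code path — the arithmetic is the same; the distinction is recorded in
study metadata. The per-study effect is the log odds ratio
θ̂ᵢ = ln(aᵢdᵢ/bᵢcᵢ) with variance estimated by Woolf's formula
1/a + 1/b + 1/c + 1/d.

Pooling across the kᵢ studies of one polymorphism follows the standard
two-stage hierarchy: under the fixed-effects assumption all studies share
one true θ and differ only by sampling noise; under random effects the
true study effects are exchangeable draws θᵢ ~ N(θ, τ²). The
DerSimonian–Laird moment estimator
τ̂² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)), with fixed-effects weights
w = 1/se² and Cochran's Q, feeds random-effects weights 1/(se² + τ̂²).
Significance of the pooled log-OR uses the standard normal Z-test; no
Knapp–Hartung small-sample adjustment is applied (out of scope).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `pre_test_risk` | 0.08 | baseline AUD prevalence used in the odds-space risk update |
| `alpha` | 0.05 | level for every CI and test |
| `heterogeneity_p_threshold` | 0.10 | Q-test p below which the random-effects model is selected |
| `drug_threshold` / `aud_threshold` | 4 / 7 | panel-score cutoffs for the drug-risk and AUD-risk flags |
| `bonferroni_m` | n. of pooled polymorphisms (≥ floor if set) | multiplicity correction span |
| `power_delta` | observed pooled log-OR | assumed true effect in the power approximation |

The 0.10 heterogeneity level is the conventional choice for the Q-test,
whose power is low at small k; it is deliberately more liberal than the
reporting α. The fixed-effects default is Mantel–Haenszel when raw tables
are available (robust with sparse cells, no continuity correction needed)
and inverse-variance when only estimate-level data exist; both are exposed.

## Numerical and procedural choices

- **Zero cells.** 0.5 is added to all four cells of a study's table
  (Haldane–Anscombe) before the Woolf OR/SE; the estimate is flagged and
  the pipeline surfaces a warning. A table with an entire zero *column*
  leaves the OR undefined and is an error. Mantel–Haenszel pooling uses
  the raw counts without correction.
- **Fisher two-sidedness.** Point-probability rule (sum of all
  margin-preserving tables no more probable than the observed one), the
  convention of mainstream implementations; verified against exact
  integer enumeration on every table with total ≤ 40.
- **Hardy–Weinberg.** Pearson's 1-df χ² against expected proportions at
  the observed allele frequency; when any expected genotype count is
  below 5 the χ² approximation is anti-conservative, so an exact test
  conditional on the allele counts is substituted (flagged `exact`).
  Monomorphic samples are flagged, not errors. HWE deviations flag the
  study in the report; no automatic exclusion is performed, since the
  appropriate action (genotyping error vs. true structure) is a judgment
  call.
- **Wilcoxon.** Mid-ranks for ties; exact enumeration when the combined
  sample is ≤ 10 and tie-free, otherwise the tie-corrected normal
  approximation without continuity correction.
- **Egger.** OLS of the standardized effect on precision; intercept t-test
  with k − 2 df. Requires k ≥ 3 and unequal standard errors.
- **Begg.** Deviations from the fixed-effects pooled estimate are
  variance-stabilized by se² − 1/Σw; Kendall's τ-b with tie correction,
  exact p for tie-free k ≤ 8, normal approximation otherwise, no
  continuity correction.
- **Trim-and-fill.** The L0 estimator, k₀ = (4Tₙ − n(n+1))/(2n−1),
  iterated to convergence (k₀ stable) or 20 passes, then mirror-filling
  about the final fixed-effects center; the adjusted estimate re-pools
  observed plus filled studies with the same model as the primary
  analysis. `side="auto"` evaluates both directions and keeps the one
  with the larger estimated k₀. Non-convergence returns the last iterate
  with a flag. The iteration matches R `metafor::trimfill(estimator="L0")`
  on shared fixtures. In the pipeline, trim-and-fill runs only when Egger
  or Begg is significant at α (configurable).
- **Power.** Hedges–Pigott normal approximation,
  1 − Φ(z₁₋α/₂ − λ) + Φ(−z₁₋α/₂ − λ) with λ = δ/se. The assumed δ is a
  user input; when unset, the observed pooled log-OR is used and the
  figure must be read as observed (post-hoc) power.
- **Critical values** come from the normal quantile function, never a
  hard-coded 1.96.
- **Rounding** to two decimals happens only in the presentation-layer
  report; the JSON sidecar retains full precision.

One sentence in the source description of the heterogeneity rule states
the I² inequality in the direction opposite to universal convention
("evidence of heterogeneity … if I² < 0.4"). The package uses the
conventional direction — large I² (equivalently, small Q-test p) indicates
heterogeneity — with the threshold configurable.

The panel cutoffs are likewise printed as "≤ 4" / "≤ 7" in the source
while the clinical framing (a count that *reaches* the level loads onto
risk, higher counts meaning higher risk) implies ≥; the flags use ≥ with
both thresholds configurable. Panel scores default to summed allele
dosages (0–2 per allele, 0–22 total); a carrier mode (0/1 per allele)
is provided because the counting rule is not stated in the source. The
panel spans ten genes and eleven alleles, DRD4 contributing both its
promoter −521C variant and the exon-III 7-repeat VNTR.

## The synthetic generator

`generate_studies` draws, per study, a true log-OR from N(ln OR, τ²), an
exposure probability for controls (the risk-allele frequency p₀) and for
cases via odds(p₁) = OR·odds(p₀), arm sizes uniform in configured ranges
(counts are allele counts, two per subject), and binomial allele counts.
Publication bias is a study-level suppression rule: a study whose
two-sided per-study p exceeds a threshold survives with probability
1 − suppression_prob, and the pool simply shrinks. Genotype fixtures use
the inbreeding parameterization (p² + fpq, 2pq(1−f), q² + fpq); panel
subjects are independent Binomial(2, freq) dosages per allele.

Per-gene presets mirror the published evidence base's scale (e.g. DRD2:
118 studies, 18,290 cases vs. 19,809 controls; GABRB3: 6 studies, 171 vs.
45), so small-literature behaviour — wide intervals, non-significance —
reproduces qualitatively.

What the generator does *not* emulate: confounding by ancestry or
population stratification, linkage disequilibrium between panel loci,
genotyping error, overlapping samples between studies, or outcome
heterogeneity across AUD diagnostic criteria. Calibrations passing on
synthetic data therefore validate the statistical machinery, not the
epidemiological robustness of any particular published pooled estimate.

## Calibration results the suite verifies

All on fixed seeds, computed at test time, never asserted from stored
numbers: DerSimonian–Laird 95% CI coverage of a true OR 1.5 within ±3pp
of nominal over 500 replicates (k = 30, τ² = 0.05); median τ̂² within 30%
of 0.1 at k = 40; Egger type-I error within ±2pp of 5% under the null
generator (k = 20, 1000 replicates); exact k₀ recovery on a constructed
10-study funnel with three suppressed studies; and, under one-sided
significance suppression, the trim-and-fill adjusted OR falling between
the biased observed OR and the truth in ≥ 80% of replicates. Replicate
counts were chosen to keep Monte-Carlo error well inside each tolerance
while the full suite runs in about a minute.

## Known limitations

- The published per-gene pooled ORs cannot be recomputed without the
  underlying primary-study tables; only the risk-conversion arithmetic of
  the published table is directly reproducible, and for several genes the
  published post-test risks are not consistent with the stated conversion
  formula applied to their published ORs at 8% pre-test risk. The formula
  is implemented as stated; the inconsistent values are not imitated.
- τ² estimation is DerSimonian–Laird only (no REML/Paule–Mandel); no
  meta-regression, no selection-model bias adjustments (Copas,
  Vevea–Hedges), no PET-PEESE.
- The Begg exact p-value is available only for small tie-free collections;
  ties force the normal approximation at any k.
- Trim-and-fill inherits the known weaknesses of the method: it estimates
  at most n − 1 missing studies, assumes suppression is the sole source of
  asymmetry, and can under-correct when the funnel is distorted by true
  heterogeneity.
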
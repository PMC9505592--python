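"""Domain types and validated I/O for case-control study collections.

The unit of analysis is a published case-control study of one polymorphism:
a 2x2 allele-count table (risk allele vs. other allele, cases vs. controls),
optionally accompanied by genotype counts for Hardy-Weinberg checks.  Study
collections travel as tab-separated tables; run configuration travels as a
JSON mapping.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "GenotypeCounts",
    "StudyRecord",
    "RunConfig",
    "PANEL_ALLELES",
    "read_study_table",
    "write_study_table",
    "read_subject_genotypes",
    "validate_config",
]

#: The risk-allele panel: ten reward-pathway genes, eleven risk alleles
#: (DRD4 contributes both the -521 C promoter variant and the exon-III
#: 7-repeat VNTR).  Subject genotype tables carry one dosage column per
#: allele, named ``<GENE>_<allele>``.
PANEL_ALLELES: tuple[str, ...] = (
    "DRD1_G",
    "DRD2_A1",
    "DRD3_C",
    "DRD4_C",
    "DRD4_7R",
    "DAT1_A9",
    "COMT_G",
    "OPRM1_G",
    "GABRB3_181",
    "MAOA_4R",
    "HTT_S",
)

_TABLE_COLUMNS = ("case_risk", "case_other", "control_risk", "control_other")
_GENOTYPE_COLUMNS = (
    "case_AA", "case_Aa", "case_aa",
    "control_AA", "control_Aa", "control_aa",
)
_CORE_COLUMNS = ("study_id", "gene", "polymorphism") + _TABLE_COLUMNS


@dataclass(frozen=True)
class ContingencyTable:
    """Allele (or carrier) counts for one study's 2x2 exposure table.

    Rows are cases/controls, columns are risk allele / other allele.
    """

    case_risk: int
    case_other: int
    control_risk: int
    control_other: int

    def __post_init__(self) -> None:
        for name in _TABLE_COLUMNS:
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise TypeError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.case_risk + self.case_other <= 0:
            raise ValueError("case margin must be positive")
        if self.control_risk + self.control_other <= 0:
            raise ValueError("control margin must be positive")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        """(a, b, c, d) = (case_risk, case_other, control_risk, control_other)."""
        return (self.case_risk, self.case_other, self.control_risk, self.control_other)

    @property
    def total(self) -> int:
        return sum(self.cells)

    def as_array(self) -> np.ndarray:
        return np.array([[self.case_risk, self.case_other],
                         [self.control_risk, self.control_other]], dtype=float)


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one sample at a biallelic locus."""

    n_hom_risk: int
    n_het: int
    n_hom_other: int

    def __post_init__(self) -> None:
        for name in ("n_hom_risk", "n_het", "n_hom_other"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise TypeError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.total <= 0:
            raise ValueError("genotype counts must sum to a positive total")

    @property
    def total(self) -> int:
        return self.n_hom_risk + self.n_het + self.n_hom_other

    @property
    def allele_freq(self) -> float:
        """Risk-allele frequency implied by the genotype counts."""
        return (2 * self.n_hom_risk + self.n_het) / (2 * self.total)


@dataclass(frozen=True)
class StudyRecord:
    """One published case-control study of one polymorphism."""

    study_id: str
    gene: str
    polymorphism: str
    table: ContingencyTable
    genotypes_cases: GenotypeCounts | None = None
    genotypes_controls: GenotypeCounts | None = None
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.study_id:
            raise ValueError("study_id must be non-empty")
        if not self.gene or not self.polymorphism:
            raise ValueError("gene and polymorphism must be non-empty")


@dataclass(frozen=True)
class RunConfig:
    """Analysis-wide settings.

    pre_test_risk is the assumed baseline disease prevalence (default 8%)
    used to convert a pooled odds ratio into a post-test risk.  The
    random-effects model is selected when the heterogeneity Q-test p-value
    falls below ``heterogeneity_p_threshold``.  ``power_delta`` is the
    assumed true log-odds-ratio for the power approximation; when None,
    power is reported at the observed pooled estimate.
    """

    pre_test_risk: float = 0.08
    alpha: float = 0.05
    heterogeneity_p_threshold: float = 0.10
    bonferroni_m: int | None = None
    drug_threshold: int = 4
    aud_threshold: int = 7
    power_delta: float | None = None
    panel_mode: str = "dosage"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.pre_test_risk < 1:
            raise ValueError(f"pre_test_risk must be in (0, 1), got {self.pre_test_risk}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.heterogeneity_p_threshold < 1:
            raise ValueError("heterogeneity_p_threshold must be in (0, 1)")
        for name in ("drug_threshold", "aud_threshold"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.drug_threshold > self.aud_threshold:
            raise ValueError("drug_threshold must not exceed aud_threshold")
        if self.bonferroni_m is not None and self.bonferroni_m < 1:
            raise ValueError("bonferroni_m must be a positive integer")
        if self.panel_mode not in ("dosage", "carrier"):
            raise ValueError("panel_mode must be 'dosage' or 'carrier'")


def validate_config(raw: Mapping[str, object]) -> RunConfig:
    """Build a :class:`RunConfig` from a raw mapping, filling defaults.

    Unknown keys are ignored with a warning so configuration files can
    carry extra annotations without breaking the run.
    """
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        warnings.warn(f"ignoring unknown config keys: {sorted(unknown)}", stacklevel=2)
    kwargs = {k: v for k, v in raw.items() if k in known}
    return RunConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Read a JSON run-configuration file."""
    with open(path, encoding="utf-8") as fh:
        return validate_config(json.load(fh))


def _parse_count(value: object, row: int, column: str) -> int:
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise ValueError(f"row {row}: column {column!r} is not an integer: {value!r}") from None
    if not float(f).is_integer():
        raise ValueError(f"row {row}: column {column!r} is not an integer: {value!r}")
    n = int(f)
    if n < 0:
        raise ValueError(f"row {row}: column {column!r} is negative: {n}")
    return n


def read_study_table(path: str | Path) -> list[StudyRecord]:
    """Read a study-collection TSV into :class:`StudyRecord` objects.

    Required columns: ``study_id gene polymorphism case_risk case_other
    control_risk control_other`` (any order).  The six optional genotype
    columns ``case_AA .. control_aa`` populate the HWE inputs; every other
    column is carried verbatim into ``metadata``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _CORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"study table {path} is missing columns: {missing}")
    if df.empty:
        logger.warning("study table %s contains a header but no rows", path)
        return []
    dup = df["study_id"][df["study_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate study_id values: {sorted(dup.unique())}")

    has_genotypes = all(c in df.columns for c in _GENOTYPE_COLUMNS)
    meta_cols = [c for c in df.columns
                 if c not in _CORE_COLUMNS and c not in _GENOTYPE_COLUMNS]

    records: list[StudyRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        counts = {c: _parse_count(row_d[c], i, c) for c in _TABLE_COLUMNS}
        table = ContingencyTable(**counts)
        gt_cases = gt_controls = None
        if has_genotypes and all(pd.notna(row_d[c]) for c in _GENOTYPE_COLUMNS):
            g = {c: _parse_count(row_d[c], i, c) for c in _GENOTYPE_COLUMNS}
            gt_cases = GenotypeCounts(g["case_AA"], g["case_Aa"], g["case_aa"])
            gt_controls = GenotypeCounts(g["control_AA"], g["control_Aa"], g["control_aa"])
        metadata = {c: row_d[c] for c in meta_cols if pd.notna(row_d[c])}
        records.append(StudyRecord(
            study_id=str(row_d["study_id"]),
            gene=str(row_d["gene"]),
            polymorphism=str(row_d["polymorphism"]),
            table=table,
            genotypes_cases=gt_cases,
            genotypes_controls=gt_controls,
            metadata=metadata,
        ))
    return records


def write_study_table(records: Sequence[StudyRecord], path: str | Path) -> None:
    """Write studies back to the TSV schema that :func:`read_study_table` reads."""
    rows = []
    meta_keys: list[str] = []
    for r in records:
        for k in r.metadata:
            if k not in meta_keys:
                meta_keys.append(k)
    has_genotypes = any(r.genotypes_cases is not None for r in records)
    for r in records:
        row: dict[str, object] = {
            "study_id": r.study_id,
            "gene": r.gene,
            "polymorphism": r.polymorphism,
            **dict(zip(_TABLE_COLUMNS, r.table.cells)),
        }
        if has_genotypes:
            gc, gk = r.genotypes_cases, r.genotypes_controls
            if gc is not None and gk is not None:
                row.update(case_AA=gc.n_hom_risk, case_Aa=gc.n_het, case_aa=gc.n_hom_other,
                           control_AA=gk.n_hom_risk, control_Aa=gk.n_het,
                           control_aa=gk.n_hom_other)
        for k in meta_keys:
            row[k] = r.metadata.get(k, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_subject_genotypes(path: str | Path,
                           alleles: Sequence[str] = PANEL_ALLELES) -> pd.DataFrame:
    """Read a per-subject allele-dosage TSV.

    Expects a ``subject_id`` column plus one column per panel allele with
    dosage values in {0, 1, 2}.  Returns a DataFrame indexed by subject_id
    with the allele columns in panel order.
    """
    df = pd.read_csv(path, sep="\t")
    if "subject_id" not in df.columns:
        raise ValueError(f"subject table {path} is missing the subject_id column")
    missing = [a for a in alleles if a not in df.columns]
    if missing:
        raise ValueError(f"subject table {path} is missing allele columns: {missing}")
    out = df.set_index("subject_id")[list(alleles)]
    for col in alleles:
        bad = out.index[~out[col].isin((0, 1, 2))]
        if len(bad):
            raise ValueError(
                f"subject {bad[0]!r}, column {col!r}: dosage must be 0, 1 or 2, "
                f"got {out.loc[bad[0], col]!r}")
    return out.astype(int)
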
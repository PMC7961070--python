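"""Tumour-only somatic SNV filtering and panel-based TMB.

Variants called from a targeted tumour panel without a matched normal are a
mixture of somatic mutations, germline polymorphisms and technical artifacts.
The cascade implemented here first removes low-confidence sites (depth, call
quality, uncalled-base fraction, strand bias, allele frequency), then removes
likely germline polymorphisms (heterozygous/homozygous VAF windows combined
with a nonzero population minor-allele frequency), and finally restricts to
single-nucleotide variants.  Tumour mutational burden (TMB) is the retained
somatic SNV count normalised by the panel footprint in megabases
(0.524 Mb for the 170-gene panel these defaults target).

Every input record receives an auditable verdict: it is either retained as a
somatic SNV or carries at least one named failure reason.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantClass",
    "Consequence",
    "VariantRecord",
    "FilterReason",
    "FilterThresholds",
    "FilterVerdict",
    "SomaticCallSet",
    "TmbResult",
    "GeneSubsetReport",
    "apply_site_filters",
    "apply_germline_filter",
    "audit_records",
    "call_somatic",
    "compute_tmb",
    "gene_mutation_matrix",
    "gene_subset_report",
]


class VariantClass(str, Enum):
    SNV = "SNV"
    INDEL = "INDEL"
    MNV = "MNV"


class Consequence(str, Enum):
    SYNONYMOUS = "synonymous"
    NON_SYNONYMOUS = "non_synonymous"
    OTHER = "other"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class VariantRecord:
    """One called variant with the caller/annotation metrics the cascade needs.

    ``pop_maf_enf`` is the population minor-allele frequency (European
    non-Finnish); ``None`` means the variant is absent from the population
    database, which is semantically distinct from an observed frequency of 0.
    """

    patient_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: VariantClass
    depth: int
    call_quality: float
    nc_fraction: float
    strand_bias: float | None
    vaf: float
    pop_maf_enf: float | None = None
    gene: str = ""
    consequence: Consequence = Consequence.UNKNOWN
    clinical_significance: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must be in [0, 1], got {self.vaf}")
        if not 0.0 <= self.nc_fraction <= 1.0:
            raise ValueError(f"nc_fraction must be in [0, 1], got {self.nc_fraction}")
        if self.depth < 0 or int(self.depth) != self.depth:
            raise ValueError(f"depth must be a nonnegative integer, got {self.depth}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.call_quality < 0:
            raise ValueError(f"call_quality must be >= 0, got {self.call_quality}")
        if self.pop_maf_enf is not None and not 0.0 <= self.pop_maf_enf <= 1.0:
            raise ValueError(f"pop_maf_enf must be in [0, 1], got {self.pop_maf_enf}")
        if self.variant_class is VariantClass.SNV and not (
            len(self.ref) == len(self.alt) == 1
        ):
            raise ValueError("SNV requires single-base ref and alt alleles")

    @property
    def key(self) -> tuple[str, str, int, str, str]:
        return (self.patient_id, self.chrom, self.pos, self.ref, self.alt)


class FilterReason(str, Enum):
    LOW_DEPTH = "LOW_DEPTH"
    LOW_QUALITY = "LOW_QUALITY"
    HIGH_NC = "HIGH_NC"
    STRAND_BIAS = "STRAND_BIAS"
    LOW_VAF = "LOW_VAF"
    GERMLINE_VAF_MAF = "GERMLINE_VAF_MAF"
    NOT_SNV = "NOT_SNV"
    # extensions beyond the core cascade
    MISSING_METRIC = "MISSING_METRIC"
    NOT_NONSYNONYMOUS = "NOT_NONSYNONYMOUS"


@dataclass(frozen=True)
class FilterThresholds:
    """Cascade thresholds.

    Boundary conventions: depth < ``min_depth`` fails (99 fails, 100 passes);
    NC fraction >= ``max_nc_snv`` fails (inclusive, SNVs only); strand-bias
    score > ``strand_bias_cut`` fails (more negative = less biased); VAF <
    ``min_vaf`` fails (0.05 passes).  The germline window is the closed
    interval [``germline_vaf_low``, ``germline_vaf_high``] plus the open tail
    (> ``germline_vaf_upper``); a variant inside it with a positive population
    MAF is called germline.  With ``maf_always_excludes`` any positive
    population MAF excludes regardless of VAF.
    """

    min_depth: int = 100
    min_quality: float = 40.0
    max_nc_snv: float = 0.03
    strand_bias_cut: float = -80.0
    min_vaf: float = 0.05
    germline_vaf_low: float = 0.40
    germline_vaf_high: float = 0.60
    germline_vaf_upper: float = 0.80
    panel_mb: float = 0.524
    maf_always_excludes: bool = False
    count_only_nonsynonymous: bool = False
    fail_open_on_missing: bool = False

    def __post_init__(self) -> None:
        if not (
            0.0
            <= self.min_vaf
            < self.germline_vaf_low
            < self.germline_vaf_high
            <= self.germline_vaf_upper
            <= 1.0
        ):
            raise ValueError(
                "require 0 <= min_vaf < germline_vaf_low < germline_vaf_high "
                "<= germline_vaf_upper <= 1"
            )
        if self.panel_mb <= 0:
            raise ValueError(f"panel_mb must be > 0, got {self.panel_mb}")


@dataclass(frozen=True)
class FilterVerdict:
    record: VariantRecord
    reasons: frozenset[FilterReason]

    @property
    def passed(self) -> bool:
        return not self.reasons


@dataclass(frozen=True)
class SomaticCallSet:
    patient_id: str
    records: tuple[VariantRecord, ...]

    def __post_init__(self) -> None:
        for r in self.records:
            if r.variant_class is not VariantClass.SNV:
                raise ValueError("SomaticCallSet admits SNVs only")

    @property
    def n_somatic_snv(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class TmbResult:
    patient_id: str
    n_somatic_snv: int
    panel_mb: float
    tmb: float


def site_filter_reasons(
    record: VariantRecord, thresholds: FilterThresholds = FilterThresholds()
) -> frozenset[FilterReason]:
    """Site-quality failure reasons for one record (order-independent)."""
    reasons: set[FilterReason] = set()
    if record.depth < thresholds.min_depth:
        reasons.add(FilterReason.LOW_DEPTH)
    if record.call_quality < thresholds.min_quality:
        reasons.add(FilterReason.LOW_QUALITY)
    # the uncalled-base filter applies to SNVs only
    if (
        record.variant_class is VariantClass.SNV
        and record.nc_fraction >= thresholds.max_nc_snv
    ):
        reasons.add(FilterReason.HIGH_NC)
    if record.strand_bias is None:
        if not thresholds.fail_open_on_missing:
            warnings.warn(
                f"{record.key}: strand-bias score missing; failing closed",
                stacklevel=2,
            )
            reasons.add(FilterReason.MISSING_METRIC)
    elif record.strand_bias > thresholds.strand_bias_cut:
        reasons.add(FilterReason.STRAND_BIAS)
    if record.vaf < thresholds.min_vaf:
        reasons.add(FilterReason.LOW_VAF)
    return frozenset(reasons)


def germline_filter_reasons(
    record: VariantRecord, thresholds: FilterThresholds = FilterThresholds()
) -> frozenset[FilterReason]:
    """Germline-polymorphism failure reasons for one record.

    A record is flagged germline when its population MAF is present and
    positive AND its VAF lies in the heterozygous window [low, high] or above
    the homozygous bound (> upper).  With ``maf_always_excludes`` the VAF
    windows are ignored and any positive MAF excludes.
    """
    maf = record.pop_maf_enf
    if maf is None or maf <= 0:
        return frozenset()
    in_window = (
        thresholds.germline_vaf_low <= record.vaf <= thresholds.germline_vaf_high
        or record.vaf > thresholds.germline_vaf_upper
    )
    if thresholds.maf_always_excludes or in_window:
        return frozenset({FilterReason.GERMLINE_VAF_MAF})
    return frozenset()


def apply_site_filters(
    records: Iterable[VariantRecord],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[FilterVerdict]:
    return [FilterVerdict(r, site_filter_reasons(r, thresholds)) for r in records]


def apply_germline_filter(
    records: Iterable[VariantRecord],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[FilterVerdict]:
    return [FilterVerdict(r, germline_filter_reasons(r, thresholds)) for r in records]


def _all_reasons(
    record: VariantRecord, thresholds: FilterThresholds
) -> frozenset[FilterReason]:
    reasons = set(site_filter_reasons(record, thresholds))
    reasons |= germline_filter_reasons(record, thresholds)
    if record.variant_class is not VariantClass.SNV:
        reasons.add(FilterReason.NOT_SNV)
    if (
        thresholds.count_only_nonsynonymous
        and record.consequence is not Consequence.NON_SYNONYMOUS
    ):
        reasons.add(FilterReason.NOT_NONSYNONYMOUS)
    return frozenset(reasons)


def audit_records(
    records: Iterable[VariantRecord],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[FilterVerdict]:
    """Full-cascade verdict for every record (site + germline + SNV-only)."""
    return [FilterVerdict(r, _all_reasons(r, thresholds)) for r in records]


def call_somatic(
    records: Iterable[VariantRecord],
    thresholds: FilterThresholds = FilterThresholds(),
    patient_id: str | None = None,
) -> SomaticCallSet:
    """Retain somatic SNVs for one patient through the full cascade."""
    records = list(records)
    if patient_id is None:
        ids = {r.patient_id for r in records}
        if len(ids) > 1:
            raise ValueError(
                f"records span multiple patients {sorted(ids)}; pass patient_id "
                "or call per patient"
            )
        patient_id = ids.pop() if ids else ""
    retained = tuple(
        r
        for r in records
        if r.patient_id == patient_id and not _all_reasons(r, thresholds)
    )
    return SomaticCallSet(patient_id=patient_id, records=retained)


def call_somatic_cohort(
    records: Iterable[VariantRecord],
    thresholds: FilterThresholds = FilterThresholds(),
    patient_ids: Sequence[str] | None = None,
) -> list[SomaticCallSet]:
    records = list(records)
    if patient_ids is None:
        patient_ids = sorted({r.patient_id for r in records})
    return [call_somatic(records, thresholds, patient_id=p) for p in patient_ids]


def compute_tmb(callset: SomaticCallSet, panel_mb: float = 0.524) -> TmbResult:
    """TMB = somatic SNVs per megabase of panel footprint (full precision)."""
    if panel_mb <= 0:
        raise ValueError(f"panel_mb must be > 0, got {panel_mb}")
    return TmbResult(
        patient_id=callset.patient_id,
        n_somatic_snv=callset.n_somatic_snv,
        panel_mb=panel_mb,
        tmb=callset.n_somatic_snv / panel_mb,
    )


@dataclass(frozen=True)
class GeneMutationMatrix:
    """Oncoprint-style summary: which patients carry somatic SNVs in which genes."""

    matrix: pd.DataFrame  # patients x genes, boolean
    percent_patients: pd.Series  # per gene, % of patients with >=1 somatic SNV
    total_mutations: pd.Series  # per gene, total somatic SNVs across cohort


def gene_mutation_matrix(callsets: Sequence[SomaticCallSet]) -> GeneMutationMatrix:
    patients = [c.patient_id for c in callsets]
    genes = sorted(
        {r.gene for c in callsets for r in c.records if r.gene}
    )
    matrix = pd.DataFrame(False, index=patients, columns=genes, dtype=bool)
    totals = pd.Series(0, index=genes, dtype=int)
    for c in callsets:
        for r in c.records:
            if not r.gene:
                raise ValueError(f"record {r.key} has no gene symbol")
            matrix.loc[c.patient_id, r.gene] = True
            totals[r.gene] += 1
    pct = 100.0 * matrix.sum(axis=0) / max(len(patients), 1)
    return GeneMutationMatrix(matrix=matrix, percent_patients=pct, total_mutations=totals)


@dataclass(frozen=True)
class GeneSubsetReport:
    n_variants: int
    n_genes_affected: int
    per_patient: pd.Series  # variant count per patient
    mean: float
    sd: float  # sample SD across patients (SEM if sem=True was requested)


def gene_subset_report(
    records_by_patient: Mapping[str, Sequence[VariantRecord]],
    gene_list: Iterable[str],
    sem: bool = False,
) -> GeneSubsetReport:
    """Count variants falling in a configured gene list (e.g. DDR genes).

    Operates on whatever variant collection the caller supplies (all called
    variants or post-cascade somatic sets).  Dispersion is the sample SD
    across patients by default; standard error of the mean with ``sem=True``.
    """
    genes = set(gene_list)
    if not genes:
        raise ValueError("gene_list must be nonempty")
    counts = {}
    affected: set[str] = set()
    total = 0
    for pid, recs in records_by_patient.items():
        hits = [r for r in recs if r.gene in genes]
        counts[pid] = len(hits)
        affected |= {r.gene for r in hits}
        total += len(hits)
    per_patient = pd.Series(counts, dtype=float).sort_index()
    n = len(per_patient)
    mean = float(per_patient.mean()) if n else 0.0
    sd = float(per_patient.std(ddof=1)) if n > 1 else 0.0
    if sem and n > 1:
        sd = sd / np.sqrt(n)
    return GeneSubsetReport(
        n_variants=total,
        n_genes_affected=len(affected),
        per_patient=per_patient,
        mean=mean,
        sd=sd,
    )


def verdicts_frame(verdicts: Sequence[FilterVerdict]) -> pd.DataFrame:
    """Audit table: one row per variant, pass flag and ;-joined reasons."""
    rows = []
    for v in verdicts:
        r = v.record
        rows.append(
            {
                "patient_id": r.patient_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "variant_class": r.variant_class.value,
                "gene": r.gene,
                "vaf": r.vaf,
                "passed": v.passed,
                "reasons": ";".join(sorted(x.value for x in v.reasons)),
            }
        )
    return pd.DataFrame(rows)
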
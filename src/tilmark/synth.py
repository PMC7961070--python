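"""Synthetic cohort generator with known ground truth.

Generates every input the pipeline consumes — per-patient variant tables,
a gene × sample count matrix, ELISPOT plates with a confirmatory CD137
readout, cytometry gating counts and multiplex-IF field tables — from a
single seeded specification, together with a ground-truth manifest.  The
default ten-patient cohort mirrors the study conditions: five
tumour-reactive (TR) and five non-reactive (NTR) patients, somatic SNV
counts spanning 0–8 so the TMB distribution has median 3.8 and maximum 15.3
per Mb, reactivity confined to the PD-1ʰⁱ fraction, and two TR
sub-scenarios (TMB-high and GEP-high) so the OR-rule stratification is
genuinely exercised.

Randomness is isolated per stage: each stage draws from a seed derived from
(master seed, stage code), so changing e.g. only the ELISPOT seed leaves
variant and expression outputs untouched.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .reactivity import Cd137Assay, ElispotPlate
from .signatures import CountMatrix, load_signatures
from .tissue import IF_PHENOTYPES, GatingTree
from .variants import Consequence, VariantClass, VariantRecord

__all__ = [
    "VariantSimSpec",
    "ExpressionSimSpec",
    "ElispotSimSpec",
    "GatingSimSpec",
    "IFSimSpec",
    "SyntheticCohortSpec",
    "Cohort",
    "simulate_variants",
    "simulate_expression",
    "simulate_elispot",
    "simulate_gating",
    "simulate_if_fields",
    "simulate_cohort",
    "generator_consistent_cuts",
]

_STAGE = {"variants": 11, "expression": 22, "elispot": 33, "gating": 44, "if": 55}

CANCER_GENES = (
    "TP53", "BRCA1", "BRCA2", "ATM", "FBXW7", "ERCC2", "PIK3CA", "KRAS",
    "NRAS", "ARID1A", "PTEN", "RB1", "CDKN2A", "NF1", "CTNNB1", "SMARCA4",
    "MSH2", "MLH1", "CHEK2", "PALB2", "RAD51", "BARD1", "CDK12", "AKT1",
    "EGFR", "MYC",
)

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class VariantSimSpec:
    """Per-patient variant-table composition.

    Somatic SNVs carry clean caller metrics, VAF in ``somatic_vaf`` and no
    population MAF; germline polymorphisms sit in the heterozygous
    [0.40, 0.60] or homozygous (0.80, 1] VAF window with a positive
    population MAF; each artifact violates exactly one named site filter.
    """

    n_germline: int = 30
    n_artifact: int = 5
    n_somatic_indel: int = 0
    somatic_vaf: tuple[float, float] = (0.05, 0.35)
    germline_het_window: tuple[float, float] = (0.40, 0.60)
    germline_hom_window: tuple[float, float] = (0.801, 1.0)
    germline_maf_range: tuple[float, float] = (0.001, 0.40)


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Probe-count model: negative-binomial endogenous/housekeeping counts,
    a geometric positive-control ladder, low-mean negative controls, and a
    shared per-sample size factor that housekeeping normalisation can undo."""

    n_endogenous: int = 120  # includes the signature genes
    n_hk: int = 10
    n_neg: int = 8
    endo_base_mean: float = 200.0
    gene_mean_sigma: float = 1.0  # lognormal spread of per-gene baselines
    sig_base_mean: float = 150.0
    hk_mean: float = 500.0
    nb_size: float = 20.0  # NB dispersion: var = m + m^2/size
    nb_size_hk: float = 200.0
    delta_log10: float = 0.5  # TR shift of signature genes
    size_factor_sd: float = 0.2
    pos_ladder: tuple[float, ...] = (25600.0, 6400.0, 1600.0, 400.0, 100.0, 25.0)
    neg_mean: float = 2.0


@dataclass(frozen=True)
class ElispotSimSpec:
    """Poisson replicate spot counts (per 5×10⁴ effectors)."""

    lam_target_reactive: float = 150.0
    lam_target_nonreactive: float = 10.0
    lam_medium: float = 10.0
    lam_unrelated: float = 10.0
    lam_blocked_reactive: float = 15.0
    lam_pos_control: float = 500.0
    replicates: int = 3


@dataclass(frozen=True)
class GatingSimSpec:
    """Binomial gating chain; (TR, NTR) branch probabilities per node."""

    n_living: int = 50_000
    tree: tuple[tuple[str, str | None], ...] = (
        ("living", None),
        ("CD45", "living"),
        ("CD3", "CD45"),
        ("CD8", "CD3"),
        ("CD4", "CD3"),
        ("PD1hi_CD8", "CD8"),
        ("CD137_CD8", "PD1hi_CD8"),
        ("PD1hi_CD4", "CD4"),
        ("CD137_CD4", "PD1hi_CD4"),
    )
    probs: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "CD45": (0.30, 0.30),
            "CD3": (0.55, 0.45),
            "CD8": (0.30, 0.12),
            "CD4": (0.35, 0.20),
            "PD1hi_CD8": (0.35, 0.12),
            "CD137_CD8": (0.15, 0.03),
            "PD1hi_CD4": (0.25, 0.20),
            "CD137_CD4": (0.05, 0.05),
        }
    )


def _default_if_probs() -> dict[tuple[str, str], dict[str, float]]:
    # (group, compartment) -> phenotype probability; remainder is "other".
    return {
        ("TR", "stroma"): {
            "CD8": 0.060, "CD4": 0.080, "PD1_CD8": 0.030, "PD1_CD4": 0.030,
            "CD137_PD1_CD8": 0.0020, "CD137_PD1_CD4": 0.0010, "FOXP3": 0.010,
        },
        ("NTR", "stroma"): {
            "CD8": 0.020, "CD4": 0.030, "PD1_CD8": 0.010, "PD1_CD4": 0.010,
            "CD137_PD1_CD8": 0.0005, "CD137_PD1_CD4": 0.0010, "FOXP3": 0.010,
        },
        ("TR", "epithelium"): {
            "CD8": 0.030, "CD4": 0.020, "PD1_CD8": 0.015, "PD1_CD4": 0.010,
            "CD137_PD1_CD8": 0.0040, "CD137_PD1_CD4": 0.0008, "FOXP3": 0.008,
        },
        ("NTR", "epithelium"): {
            "CD8": 0.010, "CD4": 0.010, "PD1_CD8": 0.004, "PD1_CD4": 0.004,
            "CD137_PD1_CD8": 0.0004, "CD137_PD1_CD4": 0.0008, "FOXP3": 0.008,
        },
    }


@dataclass(frozen=True)
class IFSimSpec:
    """Multinomial per-field phenotype counts in stroma and epithelium."""

    n_fields: int = 20
    cells_per_field_mean: float = 1000.0
    probs: Mapping[tuple[str, str], Mapping[str, float]] = field(
        default_factory=_default_if_probs
    )


_STUDY_SOMATIC = {
    "P01": 2, "P02": 8, "P03": 0, "P04": 0, "P05": 6,
    "P06": 7, "P07": 1, "P08": 2, "P09": 2, "P10": 1,
}
_STUDY_TR = ("P01", "P02", "P04", "P05", "P06")
# TR sub-scenarios: prediction must come from TMB for these, from GEP for the rest
_STUDY_TMB_HIGH = ("P02", "P05", "P06")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Everything needed to generate one cohort deterministically.

    The defaults are the study conditions: 10 patients split 5 TR / 5 NTR,
    somatic SNV counts giving TMB median 3.8 and range 0–15.3 per Mb with
    the top loads in the TR group, GEP shift Δlog10 = 0.5 for GEP-high TR
    patients and a mild 0.15 for TMB-high ones, ELISPOT reactivity confined
    to the PD-1ʰⁱ fraction, and 20 IF fields per compartment.
    """

    seed: int = 0
    n_patients: int = 10
    n_controls: int = 4
    tr_patients: tuple[str, ...] | None = None
    somatic_snv_counts: Mapping[str, int] | None = None
    gep_shift_overrides: Mapping[str, float] | None = None
    variants: VariantSimSpec = field(default_factory=VariantSimSpec)
    expression: ExpressionSimSpec = field(default_factory=ExpressionSimSpec)
    elispot: ElispotSimSpec = field(default_factory=ElispotSimSpec)
    gating: GatingSimSpec = field(default_factory=GatingSimSpec)
    if_fields: IFSimSpec = field(default_factory=IFSimSpec)
    # optional per-stage seed overrides (default: derived from master seed)
    seed_variants: int | None = None
    seed_expression: int | None = None
    seed_elispot: int | None = None
    seed_gating: int | None = None
    seed_if: int | None = None

    @classmethod
    def study_default(cls, seed: int = 0) -> "SyntheticCohortSpec":
        """The ten-patient cohort mirroring the study's printed anchors."""
        return cls(
            seed=seed,
            tr_patients=_STUDY_TR,
            somatic_snv_counts=dict(_STUDY_SOMATIC),
            gep_shift_overrides={p: 0.15 for p in _STUDY_TMB_HIGH},
        )

    @property
    def patient_ids(self) -> tuple[str, ...]:
        return tuple(f"P{i:02d}" for i in range(1, self.n_patients + 1))

    @property
    def control_ids(self) -> tuple[str, ...]:
        return tuple(f"C{i:02d}" for i in range(11, 11 + self.n_controls))

    def tr_set(self) -> frozenset[str]:
        if self.tr_patients is not None:
            return frozenset(self.tr_patients)
        return frozenset(self.patient_ids[: self.n_patients // 2])

    def group_of(self, patient_id: str) -> str:
        return "TR" if patient_id in self.tr_set() else "NTR"

    def n_somatic(self, patient_id: str) -> int:
        if self.somatic_snv_counts is not None:
            return self.somatic_snv_counts[patient_id]
        tr_cycle, ntr_cycle = (8, 2, 7, 0, 6), (0, 1, 2, 2, 1)
        trs = [p for p in self.patient_ids if self.group_of(p) == "TR"]
        ntrs = [p for p in self.patient_ids if self.group_of(p) == "NTR"]
        if patient_id in trs:
            return tr_cycle[trs.index(patient_id) % len(tr_cycle)]
        return ntr_cycle[ntrs.index(patient_id) % len(ntr_cycle)]

    def gep_shift(self, patient_id: str) -> float:
        if self.group_of(patient_id) != "TR":
            return 0.0
        if self.gep_shift_overrides and patient_id in self.gep_shift_overrides:
            return self.gep_shift_overrides[patient_id]
        return self.expression.delta_log10

    def stage_rng(self, stage: str, index: int = 0) -> np.random.Generator:
        override = getattr(self, f"seed_{'if' if stage == 'if' else stage}", None)
        entropy = override if override is not None else self.seed
        return np.random.default_rng(
            np.random.SeedSequence([int(entropy), _STAGE[stage], int(index)])
        )


@dataclass(frozen=True)
class VariantGroundTruth:
    somatic_snv_keys: tuple[tuple, ...]
    somatic_indel_keys: tuple[tuple, ...]
    germline_keys: tuple[tuple, ...]
    artifact_keys: tuple[tuple, ...]
    artifact_reasons: tuple[str, ...]


def _random_snv_alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref, alt = rng.choice(len(_BASES), size=2, replace=False)
    return _BASES[ref], _BASES[alt]


def simulate_variants(
    spec: SyntheticCohortSpec, patient_id: str
) -> tuple[list[VariantRecord], VariantGroundTruth]:
    """One patient's variant table: somatic + germline + labelled artifacts."""
    vs = spec.variants
    idx = spec.patient_ids.index(patient_id)
    rng = spec.stage_rng("variants", idx)
    records: list[VariantRecord] = []
    truth: dict[str, list] = {"somatic": [], "indel": [], "germline": [], "artifact": []}
    artifact_reasons: list[str] = []
    pos = 0

    def clean_metrics() -> dict:
        return {
            "depth": int(rng.integers(120, 1000)),
            "call_quality": float(rng.uniform(50, 200)),
            "nc_fraction": float(rng.uniform(0.0, 0.029)),
            "strand_bias": float(rng.uniform(-200, -81)),
        }

    def next_site() -> tuple[str, int]:
        nonlocal pos
        pos += int(rng.integers(1_000, 50_000))
        return f"chr{int(rng.integers(1, 23))}", pos

    for _ in range(spec.n_somatic(patient_id)):
        chrom, p = next_site()
        ref, alt = _random_snv_alleles(rng)
        rec = VariantRecord(
            patient_id=patient_id, chrom=chrom, pos=p, ref=ref, alt=alt,
            variant_class=VariantClass.SNV,
            vaf=float(rng.uniform(*vs.somatic_vaf)),
            pop_maf_enf=None,
            gene=str(rng.choice(CANCER_GENES)),
            consequence=Consequence.NON_SYNONYMOUS,
            **clean_metrics(),
        )
        records.append(rec)
        truth["somatic"].append(rec.key)

    for _ in range(vs.n_somatic_indel):
        chrom, p = next_site()
        rec = VariantRecord(
            patient_id=patient_id, chrom=chrom, pos=p, ref="AT", alt="A",
            variant_class=VariantClass.INDEL,
            vaf=float(rng.uniform(*vs.somatic_vaf)),
            pop_maf_enf=None,
            gene=str(rng.choice(CANCER_GENES)),
            consequence=Consequence.NON_SYNONYMOUS,
            **clean_metrics(),
        )
        records.append(rec)
        truth["indel"].append(rec.key)

    for i in range(vs.n_germline):
        chrom, p = next_site()
        ref, alt = _random_snv_alleles(rng)
        window = vs.germline_het_window if i % 2 == 0 else vs.germline_hom_window
        rec = VariantRecord(
            patient_id=patient_id, chrom=chrom, pos=p, ref=ref, alt=alt,
            variant_class=VariantClass.SNV,
            vaf=float(rng.uniform(*window)),
            pop_maf_enf=float(rng.uniform(*vs.germline_maf_range)),
            gene=str(rng.choice(CANCER_GENES)),
            consequence=Consequence.SYNONYMOUS,
            **clean_metrics(),
        )
        records.append(rec)
        truth["germline"].append(rec.key)

    breakers = ("LOW_DEPTH", "LOW_QUALITY", "HIGH_NC", "STRAND_BIAS", "LOW_VAF")
    for i in range(vs.n_artifact):
        chrom, p = next_site()
        ref, alt = _random_snv_alleles(rng)
        m = clean_metrics()
        vaf = float(rng.uniform(*vs.somatic_vaf))
        reason = breakers[i % len(breakers)]
        if reason == "LOW_DEPTH":
            m["depth"] = int(rng.integers(0, 100))
        elif reason == "LOW_QUALITY":
            m["call_quality"] = float(rng.uniform(0, 39.9))
        elif reason == "HIGH_NC":
            m["nc_fraction"] = float(rng.uniform(0.03, 0.3))
        elif reason == "STRAND_BIAS":
            m["strand_bias"] = float(rng.uniform(-79, 0))
        else:
            vaf = float(rng.uniform(0.0, 0.049))
        rec = VariantRecord(
            patient_id=patient_id, chrom=chrom, pos=p, ref=ref, alt=alt,
            variant_class=VariantClass.SNV, vaf=vaf, pop_maf_enf=None,
            gene=str(rng.choice(CANCER_GENES)),
            consequence=Consequence.UNKNOWN,
            **m,
        )
        records.append(rec)
        truth["artifact"].append(rec.key)
        artifact_reasons.append(reason)

    return records, VariantGroundTruth(
        somatic_snv_keys=tuple(truth["somatic"]),
        somatic_indel_keys=tuple(truth["indel"]),
        germline_keys=tuple(truth["germline"]),
        artifact_keys=tuple(truth["artifact"]),
        artifact_reasons=tuple(artifact_reasons),
    )


def simulate_expression(
    spec: SyntheticCohortSpec,
) -> tuple[CountMatrix, dict[str, float]]:
    """Count matrix for all patients plus healthy-ovary controls.

    Returns the matrix and the per-sample true Δlog10 shift applied to
    signature genes.  Signature genes carry their published symbols so the
    packaged signature YAML scores them directly.
    """
    es = spec.expression
    rng = spec.stage_rng("expression")
    sig_genes = sorted(
        set().union(*(s.gene_symbols for s in load_signatures().values()))
    )
    n_filler = max(es.n_endogenous - len(sig_genes), 0)
    filler = [f"ENDO{i:03d}" for i in range(n_filler)]
    hk = [f"HK{i:02d}" for i in range(es.n_hk)]
    pos = [f"POS_{chr(65 + i)}" for i in range(len(es.pos_ladder))]
    neg = [f"NEG_{chr(65 + i)}" for i in range(es.n_neg)]
    genes = sig_genes + filler + hk + pos + neg
    gene_class = pd.Series(
        ["endogenous"] * (len(sig_genes) + n_filler)
        + ["housekeeping"] * len(hk)
        + ["positive"] * len(pos)
        + ["negative"] * len(neg),
        index=genes,
    )
    samples = list(spec.patient_ids) + list(spec.control_ids)
    groups = pd.Series(
        [spec.group_of(p) for p in spec.patient_ids]
        + ["control"] * spec.n_controls,
        index=samples,
    )
    base = pd.Series(0.0, index=genes)
    base[sig_genes] = es.sig_base_mean
    base[filler] = es.endo_base_mean * np.exp(
        rng.normal(0.0, es.gene_mean_sigma, size=n_filler)
    )
    base[hk] = es.hk_mean * np.exp(rng.normal(0.0, 0.3, size=len(hk)))
    shifts = {s: (spec.gep_shift(s) if s in spec.patient_ids else 0.0)
              for s in samples}

    def nb(mean: np.ndarray, size: float) -> np.ndarray:
        mean = np.maximum(mean, 1e-9)
        p = size / (size + mean)
        return rng.negative_binomial(size, p)

    counts = pd.DataFrame(0.0, index=genes, columns=samples)
    size_factors = np.exp(rng.normal(0.0, es.size_factor_sd, size=len(samples)))
    for j, s in enumerate(samples):
        f = size_factors[j]
        mu_endo = base[sig_genes + filler].to_numpy() * f
        # signature genes shifted multiplicatively in TR samples
        mu_endo[: len(sig_genes)] *= 10.0 ** shifts[s]
        counts.loc[sig_genes + filler, s] = nb(mu_endo, es.nb_size)
        counts.loc[hk, s] = nb(base[hk].to_numpy() * f, es.nb_size_hk)
        counts.loc[pos, s] = rng.poisson(np.asarray(es.pos_ladder) * f)
        counts.loc[neg, s] = rng.poisson(es.neg_mean * f, size=len(neg))
    return CountMatrix.from_frames(counts, gene_class, groups), shifts


def simulate_elispot(
    spec: SyntheticCohortSpec,
    patient_id: str,
    fraction: str,
    reactive: bool | None = None,
    index: int | None = None,
) -> tuple[ElispotPlate, Cd137Assay, bool]:
    """One product's ELISPOT plate and CD137 assay, plus true reactivity.

    By default only the PD-1ʰⁱ fraction of TR patients is reactive.
    """
    el = spec.elispot
    if index is None:
        index = spec.patient_ids.index(patient_id) * 2 + (fraction == "PD1_hi")
    rng = spec.stage_rng("elispot", index)
    if reactive is None:
        reactive = spec.group_of(patient_id) == "TR" and fraction == "PD1_hi"
    n = el.replicates
    lam_auto = el.lam_target_reactive if reactive else el.lam_target_nonreactive
    lam_block = el.lam_blocked_reactive if reactive else el.lam_target_nonreactive
    plate = ElispotPlate(
        product_id=patient_id,
        fraction=fraction,
        conditions={
            "medium": tuple(int(x) for x in rng.poisson(el.lam_medium, n)),
            "autologous_tumour": tuple(int(x) for x in rng.poisson(lam_auto, n)),
            "autologous_tumour_plus_HLAblock": tuple(
                int(x) for x in rng.poisson(lam_block, n)
            ),
            "unrelated_tumour": tuple(int(x) for x in rng.poisson(el.lam_unrelated, n)),
            "antiCD3_positive_control": tuple(
                int(x) for x in rng.poisson(el.lam_pos_control, n)
            ),
        },
    )
    alone = float(rng.uniform(0.1, 0.5))
    tumour = float(rng.uniform(3.0, 8.0)) if reactive else float(rng.uniform(0.1, 0.6))
    cd137 = Cd137Assay(
        product_id=patient_id,
        fraction=fraction,
        percent={
            "alone": alone,
            "autologous_tumour": tumour,
            "unrelated_tumour": float(rng.uniform(0.1, 0.5)),
        },
    )
    return plate, cd137, bool(reactive)


def simulate_gating(spec: SyntheticCohortSpec, patient_id: str) -> dict[str, int]:
    """Binomial gating chain honouring child <= parent by construction."""
    gs = spec.gating
    idx = spec.patient_ids.index(patient_id)
    rng = spec.stage_rng("gating", idx)
    tr = spec.group_of(patient_id) == "TR"
    counts: dict[str, int] = {}
    for node, parent in gs.tree:
        if parent is None:
            counts[node] = gs.n_living
        else:
            p_tr, p_ntr = gs.probs[node]
            counts[node] = int(rng.binomial(counts[parent], p_tr if tr else p_ntr))
    return counts


def simulate_if_fields(spec: SyntheticCohortSpec, patient_id: str) -> pd.DataFrame:
    """Multinomial per-field phenotype counts for both tissue compartments."""
    fs = spec.if_fields
    idx = spec.patient_ids.index(patient_id)
    rng = spec.stage_rng("if", idx)
    group = spec.group_of(patient_id)
    rows = []
    for compartment in ("stroma", "epithelium"):
        probs = fs.probs[(group, compartment)]
        phenos = [p for p in IF_PHENOTYPES if p != "other"]
        pvec = np.array([probs.get(p, 0.0) for p in phenos])
        pvec = np.append(pvec, 1.0 - pvec.sum())  # "other"
        for f in range(1, fs.n_fields + 1):
            total = max(int(rng.poisson(fs.cells_per_field_mean)), 1)
            draw = rng.multinomial(total, pvec)
            for pheno, count in zip(phenos + ["other"], draw):
                rows.append(
                    {
                        "patient_id": patient_id,
                        "field_id": f,
                        "compartment": compartment,
                        "phenotype": pheno,
                        "cell_count": int(count),
                        "total_cells_in_field": total,
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class Cohort:
    """In-memory bundle of every generated input plus ground truth."""

    spec: SyntheticCohortSpec
    variant_records: dict[str, list[VariantRecord]]
    variant_truth: dict[str, VariantGroundTruth]
    expression: CountMatrix
    expression_shifts: dict[str, float]
    plates: list[ElispotPlate]
    cd137: list[Cd137Assay]
    reactive_truth: dict[tuple[str, str], bool]
    gating: pd.DataFrame
    gating_tree: GatingTree
    if_table: pd.DataFrame

    def manifest(self) -> dict:
        patients = {}
        for pid in self.spec.patient_ids:
            vt = self.variant_truth[pid]
            patients[pid] = {
                "tr_label": self.spec.group_of(pid),
                "scenario": (
                    "ntr"
                    if self.spec.group_of(pid) == "NTR"
                    else (
                        "tmb_high"
                        if self.spec.gep_shift(pid) < self.spec.expression.delta_log10
                        else "gep_high"
                    )
                ),
                "n_somatic_snv": len(vt.somatic_snv_keys),
                "somatic_snv_keys": [list(k) for k in vt.somatic_snv_keys],
                "gep_delta_log10": self.spec.gep_shift(pid),
                "reactive_products": {
                    frac: self.reactive_truth[(pid, frac)]
                    for frac in ("PD1_neg", "PD1_hi")
                },
            }
        return {"seed": self.spec.seed, "patients": patients}


def simulate_cohort(
    spec: SyntheticCohortSpec,
    out_dir: str | None = None,
    force: bool = False,
) -> Cohort:
    """Generate the full cohort; optionally write every stage's input files."""
    variant_records: dict[str, list[VariantRecord]] = {}
    variant_truth: dict[str, VariantGroundTruth] = {}
    for pid in spec.patient_ids:
        recs, truth = simulate_variants(spec, pid)
        variant_records[pid] = recs
        variant_truth[pid] = truth
    expression, shifts = simulate_expression(spec)
    plates, cd137s = [], []
    reactive_truth: dict[tuple[str, str], bool] = {}
    for pid in spec.patient_ids:
        for frac in ("PD1_neg", "PD1_hi"):
            plate, cd, reactive = simulate_elispot(spec, pid, frac)
            plates.append(plate)
            cd137s.append(cd)
            reactive_truth[(pid, frac)] = reactive
    gating_rows = []
    for pid in spec.patient_ids:
        for node, count in simulate_gating(spec, pid).items():
            gating_rows.append({"patient_id": pid, "node": node, "count": count})
    gating = pd.DataFrame(gating_rows)
    tree = GatingTree(parent=dict(spec.gating.tree))
    if_table = pd.concat(
        [simulate_if_fields(spec, pid) for pid in spec.patient_ids],
        ignore_index=True,
    )
    cohort = Cohort(
        spec=spec,
        variant_records=variant_records,
        variant_truth=variant_truth,
        expression=expression,
        expression_shifts=shifts,
        plates=plates,
        cd137=cd137s,
        reactive_truth=reactive_truth,
        gating=gating,
        gating_tree=tree,
        if_table=if_table,
    )
    if out_dir is not None:
        _write_cohort(cohort, out_dir, force)
    return cohort


def _write_cohort(cohort: Cohort, out_dir: str, force: bool) -> None:
    if os.path.isdir(out_dir) and os.listdir(out_dir) and not force:
        raise FileExistsError(f"{out_dir} exists and is not empty (use force)")
    os.makedirs(out_dir, exist_ok=True)
    spec = cohort.spec

    var_rows = []
    for pid in spec.patient_ids:
        for r in cohort.variant_records[pid]:
            var_rows.append(
                {
                    "patient_id": r.patient_id, "chrom": r.chrom, "pos": r.pos,
                    "ref": r.ref, "alt": r.alt,
                    "variant_class": r.variant_class.value, "depth": r.depth,
                    "call_quality": r.call_quality, "nc_fraction": r.nc_fraction,
                    "strand_bias": r.strand_bias, "vaf": r.vaf,
                    "pop_maf_enf": "" if r.pop_maf_enf is None else r.pop_maf_enf,
                    "gene": r.gene, "consequence": r.consequence.value,
                }
            )
    pd.DataFrame(var_rows).to_csv(
        os.path.join(out_dir, "variants.tsv"), sep="\t", index=False
    )

    counts = cohort.expression.counts.copy()
    counts.insert(0, "gene_class", cohort.expression.gene_class.loc[counts.index])
    counts.insert(0, "gene", counts.index)
    counts.to_csv(os.path.join(out_dir, "counts.csv"), index=False)
    pd.DataFrame(
        {
            "sample_id": cohort.expression.groups.index,
            "group": cohort.expression.groups.values,
        }
    ).to_csv(os.path.join(out_dir, "groups.csv"), index=False)

    eli_rows = []
    for plate in cohort.plates:
        for cond, reps in plate.conditions.items():
            for i, s in enumerate(reps, start=1):
                eli_rows.append(
                    {
                        "product_id": plate.product_id, "fraction": plate.fraction,
                        "condition": cond, "replicate": i, "spots": s,
                    }
                )
    pd.DataFrame(eli_rows).to_csv(os.path.join(out_dir, "elispot.csv"), index=False)
    cd_rows = [
        {
            "product_id": cd.product_id, "fraction": cd.fraction,
            "condition": cond, "percent": pct,
        }
        for cd in cohort.cd137
        for cond, pct in cd.percent.items()
    ]
    pd.DataFrame(cd_rows).to_csv(os.path.join(out_dir, "cd137.csv"), index=False)

    cohort.gating.to_csv(os.path.join(out_dir, "gating.csv"), index=False)
    with open(os.path.join(out_dir, "gating_tree.yaml"), "w") as fh:
        yaml.safe_dump(dict(spec.gating.tree), fh, sort_keys=True)
    cohort.if_table.to_csv(os.path.join(out_dir, "if_fields.csv"), index=False)

    with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
        json.dump(cohort.manifest(), fh, sort_keys=True, indent=1)


def generator_consistent_cuts(
    cohort: Cohort,
    tmb_by_patient: Mapping[str, float],
    gep_by_patient: Mapping[str, float],
) -> tuple[float, float]:
    """Stratification cuts placed between the generated low/high biomarker modes.

    The TMB cut is the midpoint between the largest TMB outside the TMB-high
    scenario and the smallest within it; the GEP cut likewise for the
    GEP-high scenario.
    """
    manifest = cohort.manifest()["patients"]
    tmb_high = [p for p, m in manifest.items() if m["scenario"] == "tmb_high"]
    gep_high = [p for p, m in manifest.items() if m["scenario"] == "gep_high"]
    if not tmb_high or not gep_high:
        raise ValueError("cohort lacks one of the TR sub-scenarios")
    lo_t = max(v for p, v in tmb_by_patient.items() if p not in tmb_high)
    hi_t = min(tmb_by_patient[p] for p in tmb_high)
    lo_g = max(v for p, v in gep_by_patient.items() if p not in gep_high)
    hi_g = min(gep_by_patient[p] for p in gep_high)
    return (lo_t + hi_t) / 2.0, (lo_g + hi_g) / 2.0
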
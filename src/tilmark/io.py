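"""Readers and writers for the tabular formats the pipeline consumes.

Variant tables come either as VCF (metrics pulled from configurable
INFO/FORMAT keys, one record per ALT allele) or as tab-delimited text with a
header.  Expression matrices, ELISPOT plates, cytometry gating counts and
multiplex-IF field tables are plain CSV.  Column mappings may be supplied via
a YAML config so exported tables from arbitrary callers can be ingested
without editing.
"""

from __future__ import annotations

import math
from typing import Mapping

import pandas as pd
import yaml

from .variants import Consequence, VariantClass, VariantRecord

__all__ = [
    "VariantTableError",
    "read_variant_table",
    "read_counts",
    "read_groups",
    "read_elispot",
    "read_cd137",
    "read_gating",
    "read_gating_tree",
    "read_if_fields",
    "load_yaml_config",
]


class VariantTableError(ValueError):
    """Malformed or unmappable variant-table input."""


#: default TSV column names -> VariantRecord fields (identity mapping)
DEFAULT_TSV_COLUMNS = {
    "patient_id": "patient_id",
    "chrom": "chrom",
    "pos": "pos",
    "ref": "ref",
    "alt": "alt",
    "variant_class": "variant_class",
    "depth": "depth",
    "call_quality": "call_quality",
    "nc_fraction": "nc_fraction",
    "strand_bias": "strand_bias",
    "vaf": "vaf",
    "pop_maf_enf": "pop_maf_enf",
    "gene": "gene",
    "consequence": "consequence",
}

#: default VCF INFO keys -> VariantRecord fields; call_quality=None uses QUAL
DEFAULT_VCF_KEYS = {
    "depth": "DP",
    "call_quality": None,
    "nc_fraction": "NC",
    "strand_bias": "SB",
    "vaf": "VAF",
    "pop_maf_enf": "MAF_ENF",
    "gene": "GENE",
    "consequence": "CSQ_CLASS",
}

_OPTIONAL_TSV = {"gene", "consequence", "clinical_significance", "strand_bias"}


def _to_optional_float(value, what: str, line: int) -> float | None:
    if value is None:
        return None
    if isinstance(value, str) and value.strip() in ("", "NA", "."):
        return None
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise VariantTableError(f"line {line}: malformed {what}: {value!r}") from None
    if math.isnan(out):
        return None
    return out


def _required_float(value, what: str, line: int) -> float:
    out = _to_optional_float(value, what, line)
    if out is None:
        raise VariantTableError(f"line {line}: missing {what}")
    return out


def read_variant_table(
    path: str,
    dialect: str = "tsv",
    column_map: Mapping[str, str] | None = None,
    vcf_keys: Mapping[str, str | None] | None = None,
) -> list[VariantRecord]:
    """Read one variant table into ``VariantRecord`` objects.

    ``dialect`` is ``"tsv"`` or ``"vcf"``.  A missing/empty population-MAF
    field maps to ``None`` (absent from the database), never to 0.  Malformed
    numeric fields raise :class:`VariantTableError` naming the offending line.
    """
    if dialect == "tsv":
        return _read_tsv(path, column_map)
    if dialect == "vcf":
        return _read_vcf(path, vcf_keys)
    raise VariantTableError(f"unknown dialect {dialect!r} (expected 'vcf' or 'tsv')")


def _read_tsv(path: str, column_map: Mapping[str, str] | None) -> list[VariantRecord]:
    colmap = dict(DEFAULT_TSV_COLUMNS)
    if column_map:
        colmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [
        col
        for fld, col in colmap.items()
        if col not in df.columns and fld not in _OPTIONAL_TSV
    ]
    if missing:
        raise VariantTableError(
            f"{path}: required column(s) not found: {', '.join(sorted(missing))}"
        )
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        get = lambda fld: getattr(row, colmap[fld]) if colmap[fld] in df.columns else ""
        try:
            rec = VariantRecord(
                patient_id=str(get("patient_id")),
                chrom=str(get("chrom")),
                pos=int(_required_float(get("pos"), "pos", i)),
                ref=str(get("ref")),
                alt=str(get("alt")),
                variant_class=VariantClass(str(get("variant_class"))),
                depth=int(_required_float(get("depth"), "depth", i)),
                call_quality=_required_float(get("call_quality"), "call_quality", i),
                nc_fraction=_required_float(get("nc_fraction"), "nc_fraction", i),
                strand_bias=_to_optional_float(get("strand_bias"), "strand_bias", i),
                vaf=_required_float(get("vaf"), "vaf", i),
                pop_maf_enf=_to_optional_float(get("pop_maf_enf"), "pop_maf_enf", i),
                gene=str(get("gene")),
                consequence=Consequence(str(get("consequence")))
                if str(get("consequence"))
                else Consequence.UNKNOWN,
            )
        except (ValueError, KeyError) as exc:
            raise VariantTableError(f"{path} line {i}: {exc}") from exc
        records.append(rec)
    return records


def _classify_alleles(ref: str, alt: str) -> VariantClass:
    if len(ref) == len(alt) == 1:
        return VariantClass.SNV
    if len(ref) == len(alt):
        return VariantClass.MNV
    return VariantClass.INDEL


def _read_vcf(path: str, vcf_keys: Mapping[str, str | None] | None) -> list[VariantRecord]:
    from cyvcf2 import VCF  # deferred: only needed for the VCF dialect

    keys = dict(DEFAULT_VCF_KEYS)
    if vcf_keys:
        keys.update(vcf_keys)
    records = []
    vcf = VCF(path)
    samples = vcf.samples
    patient_default = samples[0] if samples else ""
    for var in vcf:
        alts = var.ALT or []
        for ai, alt in enumerate(alts):
            def info(field: str, per_allele: bool = False):
                key = keys.get(field)
                if key is None:
                    return None
                val = var.INFO.get(key)
                if isinstance(val, (tuple, list)):
                    val = val[ai] if per_allele and ai < len(val) else val[0]
                return val

            qual = info("call_quality")
            if qual is None:
                qual = var.QUAL if var.QUAL is not None else 0.0
            line = f"{var.CHROM}:{var.POS}"
            try:
                rec = VariantRecord(
                    patient_id=str(info("patient_id") or patient_default),
                    chrom=var.CHROM,
                    pos=var.POS,
                    ref=var.REF,
                    alt=alt,
                    variant_class=_classify_alleles(var.REF, alt),
                    depth=int(_required_float(info("depth"), "depth", 0)),
                    call_quality=float(qual),
                    nc_fraction=_required_float(info("nc_fraction"), "nc_fraction", 0),
                    strand_bias=_to_optional_float(info("strand_bias"), "strand_bias", 0),
                    vaf=_required_float(info("vaf", per_allele=True), "vaf", 0),
                    pop_maf_enf=_to_optional_float(
                        info("pop_maf_enf", per_allele=True), "pop_maf_enf", 0
                    ),
                    gene=str(info("gene") or ""),
                    consequence=Consequence(str(info("consequence")))
                    if info("consequence")
                    else Consequence.UNKNOWN,
                )
            except (ValueError, KeyError) as exc:
                raise VariantTableError(f"{path} at {line}: {exc}") from exc
            records.append(rec)
    return records


def read_counts(path: str):
    """Gene x sample count matrix CSV with ``gene`` and ``gene_class`` columns."""
    from .signatures import CountMatrix

    df = pd.read_csv(path)
    if "gene" not in df.columns or "gene_class" not in df.columns:
        raise ValueError(f"{path}: expected 'gene' and 'gene_class' columns")
    gene_class = pd.Series(df["gene_class"].values, index=df["gene"].values)
    counts = df.drop(columns=["gene", "gene_class"]).set_axis(df["gene"].values, axis=0)
    return CountMatrix.from_frames(counts=counts, gene_class=gene_class)


def read_groups(path: str) -> pd.Series:
    df = pd.read_csv(path)
    return pd.Series(df["group"].values, index=df["sample_id"].values)


def read_elispot(path: str) -> pd.DataFrame:
    """Long-format plate table: product_id, fraction, condition, replicate, spots."""
    df = pd.read_csv(path)
    need = {"product_id", "fraction", "condition", "replicate", "spots"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    return df


def read_cd137(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"product_id", "fraction", "condition", "percent"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    return df


def read_gating(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"patient_id", "node", "count"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    return df


def read_gating_tree(path: str) -> dict[str, str | None]:
    with open(path) as fh:
        tree = yaml.safe_load(fh)
    if not isinstance(tree, dict):
        raise ValueError(f"{path}: gating tree YAML must map node -> parent")
    return tree


def read_if_fields(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {
        "patient_id",
        "field_id",
        "compartment",
        "phenotype",
        "cell_count",
        "total_cells_in_field",
    }
    if not need <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    return df


def load_yaml_config(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
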
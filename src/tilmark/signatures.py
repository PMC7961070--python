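"""Expression normalisation, immune signature scores, differential expression.

Raw probe counts from a multiplexed expression panel are normalised in three
steps, mirroring the standard nCounter scheme: (1) per-sample scaling by the
geometric mean of positive-control probes, (2) background flooring at
mean + 2 SD of negative-control probes, and (3) per-sample scaling by the
geometric mean of the most stable housekeeping genes.  Signature scores (the
GEP) are the arithmetic mean of log10 normalised expression over a defined
gene set; differential expression between the tumour-reactive (TR) and
non-tumour-reactive (NTR) groups uses Welch's t-test on log10 values with
fold-change gating, and the heatmap layout reproduces unsupervised
hierarchical clustering on z-scored rows.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as st
import yaml

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "SignatureDefinition",
    "SignatureCoverageError",
    "load_signatures",
    "positive_control_normalize",
    "background_floor",
    "select_stable_hk",
    "hk_normalize",
    "normalize",
    "score_signature",
    "score_all_signatures",
    "differential_expression",
    "heatmap_prepare",
    "HeatmapLayout",
]

GENE_CLASSES = ("endogenous", "housekeeping", "positive", "negative")


@dataclass(frozen=True)
class CountMatrix:
    """Genes x samples raw counts with per-gene class labels.

    ``gene_class`` maps every gene to one of endogenous / housekeeping /
    positive / negative; ``groups`` (optional) maps samples to TR / NTR /
    control / unknown.
    """

    counts: pd.DataFrame
    gene_class: pd.Series
    groups: pd.Series | None = None

    @classmethod
    def from_frames(
        cls,
        counts: pd.DataFrame,
        gene_class: pd.Series,
        groups: pd.Series | None = None,
    ) -> "CountMatrix":
        if counts.index.has_duplicates:
            dupes = counts.index[counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene symbols: {dupes}")
        if (counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        missing = counts.index.difference(gene_class.index)
        if len(missing):
            raise ValueError(f"genes without a class label: {list(missing)}")
        bad = set(gene_class.loc[counts.index]) - set(GENE_CLASSES)
        if bad:
            raise ValueError(f"unknown gene classes: {sorted(bad)}")
        return cls(
            counts=counts.astype(float),
            gene_class=gene_class.loc[counts.index],
            groups=groups,
        )

    def genes_of(self, klass: str) -> pd.Index:
        return self.counts.index[self.gene_class.loc[self.counts.index] == klass]

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns


@dataclass(frozen=True)
class NormalizedMatrix:
    """Normalised expression (linear scale) plus the steps that produced it."""

    values: pd.DataFrame
    gene_class: pd.Series
    groups: pd.Series | None = None
    provenance: tuple[str, ...] = ()

    def genes_of(self, klass: str) -> pd.Index:
        return self.values.index[self.gene_class.loc[self.values.index] == klass]

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def log10(self) -> pd.DataFrame:
        return np.log10(self.values)


def _as_norm(matrix: CountMatrix | NormalizedMatrix) -> NormalizedMatrix:
    if isinstance(matrix, CountMatrix):
        return NormalizedMatrix(
            values=matrix.counts, gene_class=matrix.gene_class, groups=matrix.groups
        )
    return matrix


def _geomean(frame: pd.DataFrame) -> pd.Series:
    """Per-sample geometric mean over the rows of ``frame``."""
    return np.exp(np.log(frame).mean(axis=0))


def positive_control_normalize(
    matrix: CountMatrix | NormalizedMatrix,
) -> NormalizedMatrix:
    """Scale each sample by cohort-mean / per-sample positive-control geomean."""
    m = _as_norm(matrix)
    pos = m.values.loc[m.genes_of("positive")]
    if pos.empty:
        raise ValueError("no positive-control genes in matrix")
    zero = pos.columns[(pos <= 0).any(axis=0)]
    if len(zero):
        raise ValueError(
            f"nonpositive positive-control counts in sample(s): {list(zero)}"
        )
    gm = _geomean(pos)
    factors = gm.mean() / gm
    return replace(
        m,
        values=m.values.mul(factors, axis=1),
        provenance=m.provenance + ("positive_control_normalize",),
    )


def background_floor(matrix: CountMatrix | NormalizedMatrix) -> NormalizedMatrix:
    """Floor endogenous/HK values at per-sample mean(neg) + 2 SD(neg), min 1.

    The floor never drops below 1 so log10 stays nonnegative downstream.
    """
    m = _as_norm(matrix)
    neg = m.values.loc[m.genes_of("negative")]
    if neg.empty:
        raise ValueError("no negative-control genes in matrix")
    sd = neg.std(axis=0, ddof=1).fillna(0.0) if len(neg) > 1 else 0.0
    floor = (neg.mean(axis=0) + 2.0 * sd).clip(lower=1.0)
    target = m.gene_class.loc[m.values.index].isin(["endogenous", "housekeeping"])
    values = m.values.copy()
    values.loc[target] = values.loc[target].clip(lower=floor, axis=1)
    return replace(m, values=values, provenance=m.provenance + ("background_floor",))


def select_stable_hk(matrix: CountMatrix | NormalizedMatrix, k: int) -> list[str]:
    """Top-``k`` housekeeping genes by ascending CV of log10 values.

    Stability is the coefficient of variation of log10 expression across
    samples (SD / |mean|); ties break alphabetically.  Run the
    positive-control and background steps first so values are positive.
    """
    m = _as_norm(matrix)
    hk = m.values.loc[m.genes_of("housekeeping")]
    if k > len(hk):
        raise ValueError(f"k={k} exceeds the {len(hk)} housekeeping genes present")
    if (hk <= 0).any().any():
        raise ValueError("housekeeping values must be positive; floor background first")
    logs = np.log10(hk)
    mean = logs.mean(axis=1)
    sd = logs.std(axis=1, ddof=1).fillna(0.0)
    cv = sd / mean.abs().replace(0.0, np.nan)
    cv = cv.fillna(np.inf).where(sd > 0, 0.0)  # constant genes are maximally stable
    order = sorted(hk.index, key=lambda g: (cv[g], g))
    return order[:k]


#: fixed reference level (counts) the full chain anchors HK geomeans to
DEFAULT_HK_TARGET = 500.0


def hk_normalize(
    matrix: CountMatrix | NormalizedMatrix,
    hk_genes: Sequence[str],
    target: float | None = None,
) -> NormalizedMatrix:
    """Scale each sample so its housekeeping geomean hits the target level.

    ``target=None`` anchors to the cohort arithmetic mean of per-sample HK
    geometric means (the lane-relative convention).  A fixed numeric target
    makes normalised expression comparable across cohorts and — because this
    is the last per-sample scaling — exactly cancels any per-sample
    multiplicative factor on the raw counts.
    """
    m = _as_norm(matrix)
    missing = [g for g in hk_genes if g not in m.values.index]
    if missing:
        raise ValueError(f"housekeeping genes absent from matrix: {missing}")
    hk = m.values.loc[list(hk_genes)]
    if (hk <= 0).any().any():
        raise ValueError("nonpositive housekeeping value; run background_floor first")
    gm = _geomean(hk)
    anchor = gm.mean() if target is None else float(target)
    factors = anchor / gm
    return replace(
        m,
        values=m.values.mul(factors, axis=1),
        provenance=m.provenance + (f"hk_normalize(k={len(hk_genes)}, target={anchor:g})",),
    )


def normalize(
    matrix: CountMatrix,
    hk_k: int | None = None,
    hk_target: float | None = DEFAULT_HK_TARGET,
) -> NormalizedMatrix:
    """Full chain: positive controls -> background floor -> stable-HK scaling.

    The housekeeping step anchors to ``hk_target`` (fixed level by default,
    which makes signature scores invariant to per-sample scaling of the raw
    counts; pass ``hk_target=None`` for the cohort-mean convention).
    """
    if len(matrix.genes_of("housekeeping")) < 2:
        raise ValueError("full normalisation requires >= 2 housekeeping genes")
    m = positive_control_normalize(matrix)
    m = background_floor(m)
    n_hk = len(m.genes_of("housekeeping"))
    k = min(hk_k, n_hk) if hk_k is not None else min(10, n_hk)
    hk = select_stable_hk(m, k)
    return hk_normalize(m, hk, target=hk_target)


@dataclass(frozen=True)
class SignatureDefinition:
    name: str
    gene_symbols: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_symbols:
            raise ValueError(f"signature {self.name!r} has no genes")


class SignatureCoverageError(ValueError):
    """Too few signature genes present in the matrix to score faithfully."""


def load_signatures(path: str | None = None) -> dict[str, SignatureDefinition]:
    """Load signature gene sets from YAML (packaged defaults when path is None)."""
    if path is None:
        ref = importlib.resources.files("tilmark.data").joinpath("signatures.yaml")
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return {
        name: SignatureDefinition(name=name, gene_symbols=frozenset(genes))
        for name, genes in raw.items()
    }


def score_signature(
    norm: NormalizedMatrix,
    signature: SignatureDefinition,
    coverage_fraction: float = 0.8,
) -> pd.DataFrame:
    """Mean log10 normalised expression over the signature's present genes.

    Returns one row per sample: sample_id, signature, score, n_genes,
    missing_genes.  Raises :class:`SignatureCoverageError` when fewer than
    ``coverage_fraction`` of the signature's genes are in the matrix.
    """
    present = sorted(signature.gene_symbols & set(norm.values.index))
    missing = sorted(signature.gene_symbols - set(norm.values.index))
    coverage = len(present) / len(signature.gene_symbols)
    if coverage < coverage_fraction:
        raise SignatureCoverageError(
            f"signature {signature.name!r}: only {len(present)}/"
            f"{len(signature.gene_symbols)} genes present "
            f"(< {coverage_fraction:.0%}); missing: {missing}"
        )
    scores = np.log10(norm.values.loc[present]).mean(axis=0)
    return pd.DataFrame(
        {
            "sample_id": scores.index,
            "signature": signature.name,
            "score": scores.values,
            "n_genes": len(present),
            "missing_genes": [";".join(missing)] * len(scores),
        }
    ).reset_index(drop=True)


def score_all_signatures(
    norm: NormalizedMatrix,
    signatures: dict[str, SignatureDefinition] | None = None,
    coverage_fraction: float = 0.8,
) -> pd.DataFrame:
    if signatures is None:
        signatures = load_signatures()
    return pd.concat(
        [score_signature(norm, s, coverage_fraction) for s in signatures.values()],
        ignore_index=True,
    )


def _flag(fc: float, p: float, fc_up: float = 2.0, fc_down: float = 0.5,
          alpha: float = 0.05) -> str:
    if p < alpha and fc > fc_up:
        return "up"
    if p < alpha and fc < fc_down:
        return "down"
    return "ns"


def differential_expression(
    norm: NormalizedMatrix,
    group_a: str = "TR",
    group_b: str = "NTR",
    test: str = "welch",
) -> pd.DataFrame:
    """Per-endogenous-gene fold change (A/B geometric-mean ratio) and p-value.

    ``test`` is ``"welch"`` (t-test on log10 values, unequal variances) or
    ``"mannwhitney"``.  Flags follow the volcano-plot convention: ``up`` for
    fold change > 2 at p < 0.05, ``down`` for fold change < 0.5 at p < 0.05,
    else ``ns``.  Raw p-values gate the flags; Benjamini–Hochberg q-values
    are reported alongside.
    """
    if norm.groups is None:
        raise ValueError("matrix has no sample-group labels")
    a_cols = norm.samples[norm.groups.loc[norm.samples] == group_a]
    b_cols = norm.samples[norm.groups.loc[norm.samples] == group_b]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("need >= 2 samples per group for differential expression")
    endo = norm.genes_of("endogenous")
    logs = np.log10(norm.values.loc[endo])
    rows = []
    degenerate = False
    for gene in endo:
        xa = logs.loc[gene, a_cols].to_numpy()
        xb = logs.loc[gene, b_cols].to_numpy()
        fc = 10.0 ** (xa.mean() - xb.mean())
        pooled = np.concatenate([xa, xb])
        if np.allclose(pooled, pooled[0]):
            p = 1.0
            degenerate = True
        elif test == "welch":
            p = float(st.ttest_ind(xa, xb, equal_var=False).pvalue)
        elif test == "mannwhitney":
            p = float(st.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
        else:
            raise ValueError(f"unknown test {test!r}")
        if np.isnan(p):
            p = 1.0
        rows.append({"gene": gene, "fold_change": fc, "p_value": p})
    if degenerate:
        warnings.warn("constant gene(s) across both groups: p set to 1", stacklevel=2)
    out = pd.DataFrame(rows)
    out["q_value"] = st.false_discovery_control(out["p_value"].to_numpy())
    out["flag"] = [_flag(fc, p) for fc, p in zip(out["fold_change"], out["p_value"])]
    return out


@dataclass(frozen=True)
class HeatmapLayout:
    standardized: pd.DataFrame  # genes x samples, z-scored log10 rows
    row_order: tuple[str, ...]
    col_order: tuple[str, ...]


def heatmap_prepare(
    norm: NormalizedMatrix,
    deg_genes: Sequence[str],
    zscore: bool = True,
) -> HeatmapLayout:
    """Row-standardised matrix plus dendrogram leaf orders.

    Each gene row is centred by its cross-sample mean on the log10 scale and,
    with ``zscore`` (default), divided by its cross-sample SD.  Rows and
    columns are ordered by agglomerative clustering (Euclidean distance,
    average linkage); leaf order is deterministic, breaking ties by input
    order.  With a single sample, column clustering is skipped with a warning.
    """
    if not len(deg_genes):
        raise ValueError("deg_genes must be nonempty")
    mat = np.log10(norm.values.loc[list(deg_genes)])
    centred = mat.sub(mat.mean(axis=1), axis=0)
    if zscore:
        sd = mat.std(axis=1, ddof=1).replace(0.0, np.nan).fillna(1.0)
        centred = centred.div(sd, axis=0)

    def leaf_order(frame: pd.DataFrame) -> tuple[str, ...]:
        if len(frame) < 2:
            return tuple(frame.index)
        link = sch.linkage(frame.to_numpy(), method="average", metric="euclidean")
        return tuple(frame.index[i] for i in sch.leaves_list(link))

    rows = leaf_order(centred)
    if centred.shape[1] < 2:
        warnings.warn("single sample: column clustering skipped", stacklevel=2)
        cols = tuple(centred.columns)
    else:
        cols = leaf_order(centred.T)
    return HeatmapLayout(standardized=centred, row_order=rows, col_order=cols)
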
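"""Flow-cytometry subset frequencies and multiplex-IF field quantification.

Cytometry counts arrive pre-gated along a declared gating tree (e.g. living →
CD45⁺ → CD3⁺ → CD8⁺ → PD-1ʰⁱ → CD137⁺); frequencies are reported relative to
the immediate parent population or to living cells.  Multiplex
immunofluorescence data arrive as per-field phenotype counts in two tissue
compartments (stroma / epithelium); the per-patient summary is the unweighted
mean of per-field percentages — deliberately not the pooled-count ratio,
which differs whenever field totals vary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from . import stats as _stats

__all__ = [
    "GatingTree",
    "GatingCounts",
    "subset_frequency",
    "frequency_table",
    "if_percentages",
    "compare_groups",
]

IF_PHENOTYPES = (
    "CD8",
    "CD4",
    "PD1_CD8",
    "PD1_CD4",
    "CD137_PD1_CD8",
    "CD137_PD1_CD4",
    "FOXP3",
    "other",
)


@dataclass(frozen=True)
class GatingTree:
    """Gating hierarchy as node -> parent (root has parent None)."""

    parent: Mapping[str, str | None]

    def __post_init__(self) -> None:
        roots = [n for n, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"gating tree needs exactly one root, found {roots}")
        for node, par in self.parent.items():
            if par is not None and par not in self.parent:
                raise ValueError(f"node {node!r} has unknown parent {par!r}")

    @property
    def root(self) -> str:
        return next(n for n, p in self.parent.items() if p is None)


@dataclass(frozen=True)
class GatingCounts:
    """Event counts per gating node for one patient."""

    patient_id: str
    counts: Mapping[str, int]

    def validate(self, tree: GatingTree) -> None:
        for node, count in self.counts.items():
            if count < 0:
                raise ValueError(f"{self.patient_id}/{node}: negative count")
            par = tree.parent.get(node)
            if par is not None and par in self.counts and count > self.counts[par]:
                raise ValueError(
                    f"{self.patient_id}: count({node})={count} exceeds "
                    f"parent {par}={self.counts[par]}"
                )


def subset_frequency(
    counts: GatingCounts,
    tree: GatingTree,
    node: str,
    reference: str = "parent",
) -> float | None:
    """Percent of ``node`` events within the reference population.

    ``reference`` is ``"parent"`` (the node's immediate parent) or the name
    of any ancestor node (e.g. the living-cell root).  Returns None when the
    reference population is empty — an empty parent yields no frequency, not
    0%.
    """
    if node not in counts.counts:
        raise KeyError(f"{counts.patient_id}: no count for node {node!r}")
    if reference == "parent":
        ref = tree.parent.get(node)
        if ref is None:
            raise ValueError(f"node {node!r} has no parent")
    else:
        ref = reference
    if ref not in counts.counts:
        raise KeyError(f"{counts.patient_id}: no count for reference {ref!r}")
    denom = counts.counts[ref]
    if denom == 0:
        return None
    return 100.0 * counts.counts[node] / denom


def frequency_table(
    gating: pd.DataFrame,
    tree: GatingTree,
    reference: str = "parent",
) -> pd.DataFrame:
    """Per-patient frequencies for every non-root node (validates the tree)."""
    rows = []
    for pid, sub in gating.groupby("patient_id", sort=True):
        gc = GatingCounts(
            patient_id=str(pid),
            counts=dict(zip(sub["node"], sub["count"].astype(int))),
        )
        gc.validate(tree)
        for node in gc.counts:
            if tree.parent.get(node) is None:
                continue
            freq = subset_frequency(gc, tree, node, reference)
            rows.append(
                {
                    "patient_id": str(pid),
                    "node": node,
                    "reference": tree.parent[node] if reference == "parent" else reference,
                    "percent": freq,
                }
            )
    return pd.DataFrame(rows)


def if_percentages(table: pd.DataFrame) -> pd.DataFrame:
    """Field-averaged phenotype percentages per (patient, compartment).

    Per-field percent = 100 × cell_count / total_cells_in_field; the summary
    is the unweighted arithmetic mean across fields (fields with zero cells
    of a phenotype contribute 0%), with the sample SD and field count.
    """
    t = table.copy()
    bad = t.loc[t["total_cells_in_field"] <= 0]
    if len(bad):
        raise ValueError("total_cells_in_field must be > 0 for every field")
    over = (
        t.groupby(["patient_id", "compartment", "field_id"])["cell_count"].sum()
        > t.groupby(["patient_id", "compartment", "field_id"])[
            "total_cells_in_field"
        ].first()
    )
    if over.any():
        raise ValueError("phenotype counts exceed field total in some field(s)")
    t["percent"] = 100.0 * t["cell_count"] / t["total_cells_in_field"]
    out = (
        t.groupby(["patient_id", "compartment", "phenotype"])["percent"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n_fields="count")
        .reset_index()
    )
    out["sd"] = out["sd"].fillna(0.0)
    return out


def compare_groups(
    values_tr: Sequence[float],
    values_ntr: Sequence[float],
    tail: str = "two",
    method: str = "exact",
    n_perm: int = 100_000,
    seed: int = 0,
    confidence_level: float = 0.95,
) -> _stats.GroupComparison:
    """TR-vs-NTR comparison, delegating to the exact/Monte-Carlo Mann–Whitney.

    Tail and confidence level follow the reporting convention of the figure
    being reproduced (two-tailed 95% for cytometry frequencies; one-tailed
    90% with Monte Carlo estimation for IF field percentages).
    """
    if method == "exact":
        res = _stats.exact_mann_whitney(values_tr, values_ntr, tail=tail)
    elif method == "monte_carlo":
        res = _stats.monte_carlo_p(
            values_tr, values_ntr, tail=tail, n_perm=n_perm, seed=seed
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return _stats.GroupComparison(
        statistic=res.statistic,
        p_value=res.p_value,
        tail=res.tail,
        method=res.method,
        n_x=res.n_x,
        n_y=res.n_y,
        n_permutations=res.n_permutations,
        mc_ci_95=res.mc_ci_95,
        confidence_level=confidence_level,
    )
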
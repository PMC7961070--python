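"""Exact small-sample nonparametric tests and two-biomarker stratification.

With cohorts of five patients per group, asymptotic p-values are unreliable,
so the Mann–Whitney and Wilcoxon signed-rank tests here are exact: the
Mann–Whitney null distribution is taken over all C(n, nx) assignments of the
pooled observations to groups (mid-ranks handle ties), and the signed-rank
distribution over all 2^n sign assignments.  Both are computed by a
subset-sum dynamic program over doubled mid-ranks — integer arithmetic, so
p-values are exact ratios of arrangement counts.  A seeded Monte Carlo
estimator with the add-one (permutation-valid) correction covers larger
inputs.  The stratification step predicts tumour-reactivity from TMB and GEP
with an OR rule: a patient above either cut is predicted TR.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

__all__ = [
    "GroupComparison",
    "PatientProfile",
    "StratificationResult",
    "exact_mann_whitney",
    "monte_carlo_p",
    "wilcoxon_signed_rank_exact",
    "stratify",
    "suggest_cuts",
]

MAX_EXACT_GROUP = 12


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    p_value: float
    tail: str  # "two", "greater", "less"
    method: str  # "exact_enumeration" or "monte_carlo"
    n_x: int
    n_y: int
    n_permutations: int | None = None
    mc_ci_95: tuple[float, float] | None = None
    confidence_level: float = 0.95


def _check_tail(tail: str) -> str:
    if tail not in ("two", "greater", "less"):
        raise ValueError(f"tail must be 'two', 'greater' or 'less', got {tail!r}")
    return tail


def _doubled_midranks(values: np.ndarray) -> np.ndarray:
    """Mid-ranks scaled by 2 so tied averages stay integral."""
    r2 = np.rint(2.0 * st.rankdata(values)).astype(np.int64)
    return r2


def _subset_sum_counts(items: np.ndarray, size: int) -> np.ndarray:
    """counts[s] = number of ``size``-subsets of ``items`` with sum s.

    Equivalent to enumerating all C(n, size) subsets; the DP keeps it
    polynomial while preserving exact integer counts (float64 holds the
    counts exactly for n <= 24).
    """
    total = int(items.sum())
    table = np.zeros((size + 1, total + 1))
    table[0, 0] = 1.0
    for item in items:
        item = int(item)
        for j in range(size, 0, -1):
            table[j, item:] += table[j - 1, : total + 1 - item]
    return table[size]


def exact_mann_whitney(
    x: Sequence[float], y: Sequence[float], tail: str = "two"
) -> GroupComparison:
    """Exact Mann–Whitney U test by enumeration of group assignments.

    U is computed from mid-ranks of the pooled sample.  The two-tailed
    p-value is P(|U − μU| ≥ |u_obs − μU|) over all C(nx+ny, nx) assignments
    of the observed pooled multiset; ``greater`` means x tends larger than y.
    Groups larger than 12 fall back to seeded Monte Carlo with a warning.
    """
    _check_tail(tail)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    if x.size > MAX_EXACT_GROUP or y.size > MAX_EXACT_GROUP:
        warnings.warn(
            f"group sizes ({x.size}, {y.size}) exceed the exact-enumeration "
            "limit; switching to Monte Carlo",
            stacklevel=2,
        )
        return monte_carlo_p(x, y, tail=tail)
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    r2 = _doubled_midranks(pooled)
    # doubled U: U2 = 2*U = sum of doubled x-ranks - nx(nx+1)
    u2_obs = int(r2[:nx].sum()) - nx * (nx + 1)
    counts = _subset_sum_counts(r2, nx)
    n_arr = math.comb(nx + ny, nx)
    sums = np.arange(counts.size)
    u2 = sums - nx * (nx + 1)
    mu2 = nx * ny  # doubled mean of U
    if tail == "two":
        extreme = np.abs(u2 - mu2) >= abs(u2_obs - mu2)
    elif tail == "greater":
        extreme = u2 >= u2_obs
    else:
        extreme = u2 <= u2_obs
    p = float(counts[extreme].sum() / n_arr)
    return GroupComparison(
        statistic=u2_obs / 2.0,
        p_value=p,
        tail=tail,
        method="exact_enumeration",
        n_x=nx,
        n_y=ny,
    )


def monte_carlo_p(
    x: Sequence[float],
    y: Sequence[float],
    tail: str = "two",
    n_perm: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> GroupComparison:
    """Monte Carlo Mann–Whitney p with the add-one estimator.

    p̂ = (1 + #extreme permutations) / (1 + n_perm), so p̂ > 0 always and the
    estimate is itself a valid permutation p-value.  The 95% CI uses the
    normal approximation.  Fully reproducible given the seed.
    """
    _check_tail(tail)
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    r2 = _doubled_midranks(pooled)
    u2_obs = int(r2[:nx].sum()) - nx * (nx + 1)
    mu2 = nx * ny
    # permute in blocks to bound memory
    n_extreme = 0
    block = 20_000
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        perms = rng.permuted(np.tile(r2, (b, 1)), axis=1)
        u2 = perms[:, :nx].sum(axis=1) - nx * (nx + 1)
        if tail == "two":
            n_extreme += int(np.sum(np.abs(u2 - mu2) >= abs(u2_obs - mu2)))
        elif tail == "greater":
            n_extreme += int(np.sum(u2 >= u2_obs))
        else:
            n_extreme += int(np.sum(u2 <= u2_obs))
        done += b
    p = (1 + n_extreme) / (1 + n_perm)
    half = 1.96 * math.sqrt(p * (1 - p) / n_perm)
    return GroupComparison(
        statistic=u2_obs / 2.0,
        p_value=p,
        tail=tail,
        method="monte_carlo",
        n_x=nx,
        n_y=ny,
        n_permutations=n_perm,
        mc_ci_95=(max(0.0, p - half), min(1.0, p + half)),
    )


def wilcoxon_signed_rank_exact(
    paired_a: Sequence[float], paired_b: Sequence[float], tail: str = "two"
) -> GroupComparison:
    """Exact Wilcoxon matched-pair signed-rank test.

    Zero differences are dropped (with a warning).  W is the positive-rank
    sum from mid-ranks of |differences|; the exact p enumerates all 2^n sign
    assignments.  ``greater`` means a tends larger than b.
    """
    _check_tail(tail)
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.size != b.size or a.size == 0:
        raise ValueError("paired inputs must have equal nonzero length")
    d = a - b
    nonzero = d != 0
    if not nonzero.all():
        warnings.warn(f"dropping {int((~nonzero).sum())} zero difference(s)",
                      stacklevel=2)
    d = d[nonzero]
    if d.size == 0:
        warnings.warn("all differences zero: p = 1", stacklevel=2)
        return GroupComparison(statistic=0.0, p_value=1.0, tail=tail,
                               method="exact_enumeration", n_x=0, n_y=0)
    r2 = _doubled_midranks(np.abs(d))
    w2_obs = int(r2[d > 0].sum())
    t2 = int(r2.sum())
    # distribution of the doubled positive-rank sum over all 2^n sign flips
    counts = np.zeros(t2 + 1)
    counts[0] = 1.0
    for item in r2:
        item = int(item)
        shifted = np.zeros_like(counts)
        shifted[item:] = counts[: t2 + 1 - item]
        counts = counts + shifted
    total = 2.0 ** d.size
    w2 = np.arange(counts.size)
    if tail == "two":
        extreme = np.abs(2 * w2 - t2) >= abs(2 * w2_obs - t2)
    elif tail == "greater":
        extreme = w2 >= w2_obs
    else:
        extreme = w2 <= w2_obs
    p = float(counts[extreme].sum() / total)
    return GroupComparison(
        statistic=w2_obs / 2.0,
        p_value=p,
        tail=tail,
        method="exact_enumeration",
        n_x=int(d.size),
        n_y=int(d.size),
    )


@dataclass(frozen=True)
class PatientProfile:
    """Per-patient biomarker aggregate used by stratification."""

    patient_id: str
    tmb: float | None  # somatic SNVs per Mb
    gep_scores: dict[str, float] = field(default_factory=dict)
    tr_label: str = "unknown"  # TR / NTR / unknown

    def __post_init__(self) -> None:
        if self.tmb is not None and self.tmb < 0:
            raise ValueError(f"tmb must be >= 0, got {self.tmb}")


QUADRANTS = (
    "highTMB_highGEP",
    "highTMB_lowGEP",
    "lowTMB_highGEP",
    "lowTMB_lowGEP",
)


@dataclass(frozen=True)
class StratificationResult:
    table: pd.DataFrame  # patient_id, tmb, gep, quadrant, predicted, tr_label
    tmb_cut: float
    gep_cut: float
    signature: str
    confusion: dict[str, int]  # TP/FP/TN/FN over labelled patients
    concordance: float | None  # (TP+TN)/n, None when no labelled patients
    excluded: tuple[str, ...] = ()


def stratify(
    profiles: Sequence[PatientProfile],
    tmb_cut: float,
    gep_cut: float,
    signature: str = "TcellInflamed",
) -> StratificationResult:
    """OR-rule biomarker stratification: predicted TR iff TMB or GEP above cut.

    A patient missing one biomarker is predicted from the other (the OR rule
    short-circuits); a patient missing both is excluded with a warning.
    Quadrants treat a missing biomarker as low.  Concordance is (TP+TN)/n
    over patients with a TR/NTR label.
    """
    rows = []
    excluded = []
    conf = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
    for p in profiles:
        gep = p.gep_scores.get(signature)
        if p.tmb is None and gep is None:
            excluded.append(p.patient_id)
            continue
        tmb_high = p.tmb is not None and p.tmb > tmb_cut
        gep_high = gep is not None and gep > gep_cut
        quadrant = (
            f"{'high' if tmb_high else 'low'}TMB_{'high' if gep_high else 'low'}GEP"
        )
        predicted = "TR" if (tmb_high or gep_high) else "NTR"
        if p.tr_label in ("TR", "NTR"):
            key = ("T" if predicted == p.tr_label else "F") + (
                "P" if predicted == "TR" else "N"
            )
            conf[key] += 1
        rows.append(
            {
                "patient_id": p.patient_id,
                "tmb": p.tmb,
                "gep": gep,
                "quadrant": quadrant,
                "predicted": predicted,
                "tr_label": p.tr_label,
            }
        )
    if excluded:
        warnings.warn(
            f"excluded (no biomarkers): {', '.join(excluded)}", stacklevel=2
        )
    n_labelled = sum(conf.values())
    concordance = (
        (conf["TP"] + conf["TN"]) / n_labelled if n_labelled else None
    )
    return StratificationResult(
        table=pd.DataFrame(rows),
        tmb_cut=tmb_cut,
        gep_cut=gep_cut,
        signature=signature,
        confusion=conf,
        concordance=concordance,
        excluded=tuple(excluded),
    )


def suggest_cuts(
    profiles: Sequence[PatientProfile], signature: str = "TcellInflamed"
) -> tuple[float, float, float]:
    """Exploratory grid search for (tmb_cut, gep_cut) maximising concordance.

    Scans midpoints between consecutive observed values of each biomarker.
    Returned cuts are descriptive of this cohort only — a desk-scale aid, not
    a validated threshold; never applied silently.
    """
    tmbs = sorted({p.tmb for p in profiles if p.tmb is not None})
    geps = sorted({p.gep_scores.get(signature) for p in profiles
                   if p.gep_scores.get(signature) is not None})

    def midpoints(vals: list[float]) -> list[float]:
        if not vals:
            return [0.0]
        inner = [(a + b) / 2 for a, b in zip(vals, vals[1:])]
        return [vals[0] - 1.0] + inner + [vals[-1] + 1.0]

    best = (-1.0, 0.0, 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tc in midpoints(tmbs):
            for gc in midpoints(geps):
                res = stratify(profiles, tc, gc, signature)
                if res.concordance is not None and res.concordance > best[0]:
                    best = (res.concordance, tc, gc)
    return best[1], best[2], best[0]
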
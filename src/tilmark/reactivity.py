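"""ELISPOT reactivity statistic and TR/NTR patient classification.

Expanded TIL products (one per sorted fraction, PD-1⁻ or PD-1ʰⁱ) are tested
by IFN-γ ELISPOT against autologous tumour cells, with medium-only wells as
background, an HLA-I blocking condition, and an unrelated tumour line as a
specificity control.  The target-specific spot count is

    specific = mean(target wells) − 2 × mean(medium wells)

and a product is called positive when the autologous-tumour statistic exceeds
30 spots (per 5×10⁴ effectors).  A patient is tumour-reactive (TR) when any
fraction's product is positive; HLA-I restriction, tumour specificity and the
confirmatory CD137-upregulation readout are recorded as flags and never
change the label.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ElispotPlate",
    "ReactivityCall",
    "Cd137Assay",
    "PatientReactivityProfile",
    "specific_spots",
    "call_positive",
    "hla_restriction",
    "tumour_specificity",
    "cd137_call",
    "assess_plate",
    "classify_patient",
    "classify_from_table",
]

POSITIVITY_THRESHOLD = 30.0

CONDITIONS = (
    "medium",
    "autologous_tumour",
    "autologous_tumour_plus_HLAblock",
    "unrelated_tumour",
    "antiCD3_positive_control",
)


@dataclass(frozen=True)
class ElispotPlate:
    """Replicate spot counts per condition for one TIL product."""

    product_id: str
    fraction: str  # PD1_neg or PD1_hi
    conditions: Mapping[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        if "medium" not in self.conditions:
            raise ValueError(f"{self.product_id}: medium condition is required")
        for cond, reps in self.conditions.items():
            if not reps:
                raise ValueError(f"{self.product_id}/{cond}: no replicates")
            if any(r < 0 for r in reps):
                raise ValueError(f"{self.product_id}/{cond}: negative spot count")


@dataclass(frozen=True)
class ReactivityCall:
    product_id: str
    fraction: str
    specific: dict[str, float]  # per target condition
    positive: bool
    hla_restricted: bool | None  # None = not assessed
    tumour_specific: bool | None
    cd137_positive: bool | None = None


@dataclass(frozen=True)
class Cd137Assay:
    """Percent CD137+ of gated CD8 blasts per co-culture condition."""

    product_id: str
    fraction: str
    percent: Mapping[str, float]  # conditions: alone / autologous_tumour / unrelated_tumour

    def __post_init__(self) -> None:
        for cond, p in self.percent.items():
            if not 0.0 <= p <= 100.0:
                raise ValueError(f"{self.product_id}/{cond}: percent {p} outside [0,100]")


@dataclass(frozen=True)
class PatientReactivityProfile:
    patient_id: str
    calls: tuple[ReactivityCall, ...]
    label: str  # TR or NTR
    flags: tuple[str, ...] = ()


def _aggregate(counts: Sequence[float], how: str = "mean") -> float:
    if how == "mean":
        return float(np.mean(counts))
    if how == "median":
        return float(median(counts))
    raise ValueError(f"unknown aggregation {how!r}")


def specific_spots(
    target_counts: Sequence[float],
    medium_counts: Sequence[float],
    aggregate: str = "mean",
) -> float:
    """Target-specific spots: mean(target) − 2 × mean(medium).

    May be negative; the raw value feeds positivity without clipping.
    """
    if not len(target_counts) or not len(medium_counts):
        raise ValueError("replicate sets must be nonempty")
    return _aggregate(target_counts, aggregate) - 2.0 * _aggregate(
        medium_counts, aggregate
    )


def call_positive(specific: float, threshold: float = POSITIVITY_THRESHOLD) -> bool:
    """Positive iff strictly more than ``threshold`` specific spots."""
    return specific > threshold


def hla_restriction(
    specific_unblocked: float,
    specific_blocked: float | None,
    reduction_fraction: float = 0.5,
) -> bool | None:
    """HLA-I-restricted iff blockade removes >= ``reduction_fraction`` of signal.

    Returns None (not assessed) when the blocked condition was not measured.
    """
    if specific_blocked is None:
        return None
    return (
        specific_unblocked > 0
        and specific_blocked <= (1.0 - reduction_fraction) * specific_unblocked
    )


def tumour_specificity(
    specific_autologous: float,
    specific_unrelated: float | None,
    threshold: float = POSITIVITY_THRESHOLD,
) -> bool | None:
    """Specific iff positive against autologous tumour but not the unrelated line."""
    if specific_unrelated is None:
        return None
    return call_positive(specific_autologous, threshold) and not call_positive(
        specific_unrelated, threshold
    )


def cd137_call(
    assay: Cd137Assay,
    fold_threshold: float = 2.0,
    min_percent: float = 1.0,
) -> bool:
    """CD137 upregulation: co-culture percent >= fold x baseline and >= floor."""
    if "alone" not in assay.percent or "autologous_tumour" not in assay.percent:
        raise ValueError(f"{assay.product_id}: need 'alone' and 'autologous_tumour'")
    alone = assay.percent["alone"]
    tumour = assay.percent["autologous_tumour"]
    return tumour >= fold_threshold * alone and tumour >= min_percent


def assess_plate(
    plate: ElispotPlate,
    threshold: float = POSITIVITY_THRESHOLD,
    reduction_fraction: float = 0.5,
    cd137: Cd137Assay | None = None,
    aggregate: str = "mean",
) -> ReactivityCall:
    """All reactivity statistics and calls for one product's plate."""
    medium = plate.conditions["medium"]
    specific = {
        cond: specific_spots(reps, medium, aggregate)
        for cond, reps in plate.conditions.items()
        if cond != "medium"
    }
    if "autologous_tumour" not in specific:
        raise ValueError(f"{plate.product_id}: no autologous_tumour condition")
    auto = specific["autologous_tumour"]
    return ReactivityCall(
        product_id=plate.product_id,
        fraction=plate.fraction,
        specific=specific,
        positive=call_positive(auto, threshold),
        hla_restricted=hla_restriction(
            auto,
            specific.get("autologous_tumour_plus_HLAblock"),
            reduction_fraction,
        ),
        tumour_specific=tumour_specificity(
            auto, specific.get("unrelated_tumour"), threshold
        ),
        cd137_positive=cd137_call(cd137) if cd137 is not None else None,
    )


def classify_patient(
    patient_id: str, calls: Sequence[ReactivityCall]
) -> PatientReactivityProfile:
    """TR iff any fraction's product is positive against autologous tumour.

    A positive but non-HLA-restricted response (e.g. from the PD-1⁻ fraction)
    is flagged but still counts toward the TR label.
    """
    if not calls:
        raise ValueError(f"{patient_id}: no autologous-tumour ELISPOT calls")
    flags = []
    for c in calls:
        if c.positive and c.hla_restricted is False:
            flags.append(f"{c.fraction}: non-HLA-restricted response")
        if c.positive and c.tumour_specific is False:
            flags.append(f"{c.fraction}: responds to unrelated tumour")
    label = "TR" if any(c.positive for c in calls) else "NTR"
    return PatientReactivityProfile(
        patient_id=patient_id, calls=tuple(calls), label=label, flags=tuple(flags)
    )


def plates_from_table(table: pd.DataFrame) -> list[ElispotPlate]:
    """Build plates from a long-format table (product_id, fraction, condition,
    replicate, spots)."""
    plates = []
    for (pid, frac), sub in table.groupby(["product_id", "fraction"], sort=True):
        conditions = {
            cond: tuple(int(s) for s in grp.sort_values("replicate")["spots"])
            for cond, grp in sub.groupby("condition")
        }
        plates.append(ElispotPlate(product_id=str(pid), fraction=str(frac),
                                   conditions=conditions))
    return plates


def classify_from_table(
    elispot: pd.DataFrame,
    cd137: pd.DataFrame | None = None,
    threshold: float = POSITIVITY_THRESHOLD,
    reduction_fraction: float = 0.5,
) -> list[PatientReactivityProfile]:
    """End-to-end: long-format plate table -> per-patient TR/NTR profiles.

    ``product_id`` is taken as the patient identifier; each (product,
    fraction) pair is one plate.
    """
    cd_by_key: dict[tuple[str, str], Cd137Assay] = {}
    if cd137 is not None:
        for (pid, frac), sub in cd137.groupby(["product_id", "fraction"]):
            cd_by_key[(str(pid), str(frac))] = Cd137Assay(
                product_id=str(pid),
                fraction=str(frac),
                percent=dict(zip(sub["condition"], sub["percent"])),
            )
    calls_by_patient: dict[str, list[ReactivityCall]] = {}
    for plate in plates_from_table(elispot):
        call = assess_plate(
            plate,
            threshold=threshold,
            reduction_fraction=reduction_fraction,
            cd137=cd_by_key.get((plate.product_id, plate.fraction)),
        )
        calls_by_patient.setdefault(plate.product_id, []).append(call)
    return [
        classify_patient(pid, calls)
        for pid, calls in sorted(calls_by_patient.items())
    ]
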
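"""Soil→plant transfer indices and BCR fraction profiles.

Two ratios quantify transfer.  The bioaccumulation coefficient

    BAC = C_plant / C_soil

relates the tissue concentration to the *pseudo-total* soil
concentration, while the bioconcentration coefficient

    BC = C_plant / C_soil,available

uses only the *labile* pool: the sum of the first three BCR
sequential-extraction steps (exchangeable/carbonate-bound, reducible,
oxidizable).  Because labile ≤ pseudo-total, BC ≥ BAC whenever both are
defined from the same soil.  BAC values are binned into the customary
decade classes (very weak / weak / moderate absorption, strong
accumulation at BAC ≥ 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import pandas as pd

from .core import (
    ELEMENTS,
    Element,
    PlantSample,
    SoilSample,
    UndefinedRatioError,
    ValidationError,
)

#: recovery tolerance before a BCR row is flagged (routine sequential-
#: extraction QA accepts sums within ±10% of the pseudo-total)
RECOVERY_TOLERANCE = 0.10


@dataclass(frozen=True)
class FractionProfile:
    """BCR step percentages of the pseudo-total for one soil/element."""

    element: Element
    pct_s1: float
    pct_s2: float
    pct_s3: float
    pct_residual: float
    labile_pct: float
    labile_conc: float  # mg kg⁻¹
    recovery_warning: bool = False


class BACClass(str, Enum):
    VERY_WEAK_ABSORPTION = "very_weak_absorption"
    WEAK_ABSORPTION = "weak_absorption"
    MODERATE_ABSORPTION = "moderate_absorption"
    STRONG_ACCUMULATION = "strong_accumulation"


@dataclass(frozen=True)
class TransferResult:
    plant_id: str
    element: Element
    bac: float
    bac_class: BACClass
    bc: Optional[float] = None
    censored_input: bool = False


def fraction_profile(
    s1: float, s2: float, s3: float, pseudo_total: float, element: Element
) -> FractionProfile:
    """Express BCR steps as percentages of the pseudo-total.

    The residual percentage is the complement of the three steps, so
    the four percentages sum to 100 by construction.  A labile sum more
    than 10% above the pseudo-total trips a recovery warning but the
    percentages are still computed.
    """
    if pseudo_total <= 0:
        raise ValidationError("pseudo_total must be strictly positive")
    if min(s1, s2, s3) < 0:
        raise ValidationError("extraction steps must be non-negative")
    labile_conc = s1 + s2 + s3
    pct_s1 = 100.0 * s1 / pseudo_total
    pct_s2 = 100.0 * s2 / pseudo_total
    pct_s3 = 100.0 * s3 / pseudo_total
    labile_pct = pct_s1 + pct_s2 + pct_s3
    return FractionProfile(
        element=element,
        pct_s1=pct_s1,
        pct_s2=pct_s2,
        pct_s3=pct_s3,
        pct_residual=100.0 - labile_pct,
        labile_pct=labile_pct,
        labile_conc=labile_conc,
        recovery_warning=labile_conc > pseudo_total * (1.0 + RECOVERY_TOLERANCE),
    )


def bioaccumulation(c_plant: float, c_soil: float) -> float:
    """BAC = C_plant / C_soil (pseudo-total), both in mg kg⁻¹."""
    if c_soil <= 0:
        raise UndefinedRatioError("soil concentration must be positive for BAC")
    if c_plant < 0:
        raise ValidationError("plant concentration must be non-negative")
    return c_plant / c_soil


def bioconcentration(c_plant: float, labile_conc: float) -> float:
    """BC = C_plant / labile soil concentration (BCR S1+S2+S3)."""
    if labile_conc <= 0:
        raise UndefinedRatioError("labile concentration must be positive for BC")
    if c_plant < 0:
        raise ValidationError("plant concentration must be non-negative")
    return c_plant / labile_conc


#: left-closed decade cutoffs for the BAC classes
_BAC_CUTOFFS = (0.01, 0.1, 1.0)


def classify_bac(bac: float) -> BACClass:
    """Bin a BAC into the decade classes (boundaries left-closed)."""
    if bac < 0:
        raise ValidationError("BAC must be non-negative")
    if bac < _BAC_CUTOFFS[0]:
        return BACClass.VERY_WEAK_ABSORPTION
    if bac < _BAC_CUTOFFS[1]:
        return BACClass.WEAK_ABSORPTION
    if bac < _BAC_CUTOFFS[2]:
        return BACClass.MODERATE_ABSORPTION
    return BACClass.STRONG_ACCUMULATION


def transfer_table(
    pairs: list[tuple[PlantSample, Optional[SoilSample]]],
    bcr_rows: list[dict] | None = None,
) -> pd.DataFrame:
    """Per-sample, per-element transfer indices as a tidy frame.

    Columns: plant_id, element, c_plant, c_soil, bac, bac_class,
    labile_conc, labile_pct, bc, censored_input.  BC is NaN where the
    paired soil has no BCR row for the element; rows without a paired
    soil (or with a zero soil concentration) are omitted.
    """
    labile: dict[tuple[str, Element], FractionProfile] = {}
    for row in bcr_rows or []:
        prof = fraction_profile(
            row["s1"], row["s2"], row["s3"], row["pseudo_total"], row["element"]
        )
        labile[(row["soil_sample_id"], row["element"])] = prof

    records = []
    for plant, soil in pairs:
        if soil is None:
            continue
        for element in ELEMENTS:
            mp = plant.measurements.get(element)
            ms = soil.measurements.get(element)
            if mp is None or ms is None:
                continue
            c_plant = plant.concentration(element)
            c_soil = soil.concentration(element)
            if c_soil is None or c_soil <= 0 or c_plant is None:
                continue
            bac = bioaccumulation(c_plant, c_soil)
            prof = labile.get((soil.sample_id, element))
            bc = (
                bioconcentration(c_plant, prof.labile_conc)
                if prof is not None and prof.labile_conc > 0
                else None
            )
            records.append(
                {
                    "plant_id": plant.sample_id,
                    "element": element.value,
                    "c_plant": c_plant,
                    "c_soil": c_soil,
                    "bac": bac,
                    "bac_class": classify_bac(bac).value,
                    "labile_conc": prof.labile_conc if prof else float("nan"),
                    "labile_pct": prof.labile_pct if prof else float("nan"),
                    "bc": bc if bc is not None else float("nan"),
                    "censored_input": mp.censored or ms.censored,
                }
            )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "plant_id", "element", "c_plant", "c_soil", "bac", "bac_class",
            "labile_conc", "labile_pct", "bc", "censored_input",
        ],
    )
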
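"""Dietary exposure and risk cascade: DIR → ADD → HQ / CR.

For each food and element the daily intake rate is

    DIR = Σ_foods C_food × IR_food / BW

with C_food in mg kg⁻¹, IR in g person⁻¹ day⁻¹ and BW in kg.  In the
``as_published`` unit mode the gram-based IR is used as-is, which is
the convention of the published intake tables this cascade reproduces;
``unit_consistent`` applies the g→kg factor 10⁻³.  The average daily
dose folds in exposure frequency EF (d y⁻¹), duration ED (y) and the
averaging time AT:

    ADD = DIR × 10⁻³ × (EF × ED) / AT

with AT = ED × 365 d for non-carcinogens and lifetime × 365 d for
carcinogens (so with EF = 365, ADD_nc = DIR×10⁻³ and
ADD_c = ADD_nc × ED/lifetime).  Non-carcinogenic hazard is HQ =
ADD_nc/RfD, summed over elements into the hazard index HQt (threshold
1); carcinogenic risk is CR = ADD_c × SF, summed into CRt (thresholds
10⁻⁶ per element, 10⁻⁴ total).  Elements without an RfD or SF are
excluded from the respective sums rather than imputed.

DIR values are additionally screened against provisional maximum
tolerable daily intakes (PMTDI), and leaf-group mean concentrations
against ruminant feed limits (Cu, Zn).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import pandas as pd

from .core import (
    ELEMENTS,
    CensoredMeasurement,
    Element,
    substitute_censored,
)
from .io import ExposureParams, LivestockLimits, ToxTable

Mode = Literal["non_carcinogenic", "carcinogenic"]

HQ_THRESHOLD = 1.0
CR_THRESHOLD = 1e-6
CRT_THRESHOLD = 1e-4


@dataclass(frozen=True)
class FoodItem:
    """A food with post-substitution concentrations in mg kg⁻¹."""

    label: str
    concentrations: dict[Element, float]
    ir_label: Optional[str] = None  # intake-rate key if != label
    censored: frozenset[Element] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for e, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"{self.label}/{e.value}: negative concentration")

    @classmethod
    def from_measurements(
        cls,
        label: str,
        measurements: dict[Element, CensoredMeasurement],
        ir_label: str | None = None,
    ) -> "FoodItem":
        return cls(
            label=label,
            concentrations={e: substitute_censored(m) for e, m in measurements.items()},
            ir_label=ir_label,
            censored=frozenset(e for e, m in measurements.items() if m.censored),
        )

    @property
    def intake_key(self) -> str:
        return self.ir_label or self.label


def daily_intake_rate(
    c_food: float, intake_rate: float, body_weight: float,
    unit_mode: str = "as_published",
) -> float:
    """Per-food DIR contribution C_food × IR / BW."""
    if c_food < 0:
        raise ValueError("concentration must be non-negative")
    dir_value = c_food * intake_rate / body_weight
    if unit_mode == "unit_consistent":
        dir_value *= 1e-3
    elif unit_mode != "as_published":
        raise ValueError(f"unknown unit_mode {unit_mode!r}")
    return dir_value


def average_daily_dose(
    dir_value: float, params: ExposureParams, mode: Mode
) -> float:
    """ADD from an as-published DIR, for either averaging-time mode."""
    if dir_value < 0:
        raise ValueError("DIR must be non-negative")
    if mode == "non_carcinogenic":
        at_days = params.exposure_duration * 365.0
    elif mode == "carcinogenic":
        at_days = params.lifetime * 365.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    ef_ed = params.exposure_frequency * params.exposure_duration
    return dir_value * 1e-3 * ef_ed / at_days


def hazard_quotient(add_nc: float, rfd: float) -> float:
    """HQ = ADD_nc / RfD."""
    if rfd <= 0:
        raise ValueError("RfD must be positive")
    return add_nc / rfd


def hazard_index(hqs: Iterable[Optional[float]]) -> float:
    """HQt: sum of the defined hazard quotients."""
    return sum(h for h in hqs if h is not None)


def carcinogenic_risk(add_c: float, sf: float) -> float:
    """CR = ADD_c × SF."""
    if sf <= 0:
        raise ValueError("slope factor must be positive")
    return add_c * sf


def total_cr(crs: Iterable[Optional[float]]) -> float:
    """CRt: sum of the defined carcinogenic risks."""
    return sum(c for c in crs if c is not None)


def pmtdi_screen(dir_value: float, pmtdi: float) -> bool:
    """True when the as-published DIR strictly exceeds the PMTDI."""
    return dir_value > pmtdi


def assess(
    foods: list[FoodItem],
    exposure: ExposureParams,
    tox: ToxTable,
) -> "RiskResult":
    """Run the full cascade for a set of foods.

    Returns per-food/per-element DIR, ADD (both modes), HQ and CR with
    exceedance flags, per-food HQt/CRt, and the diet-total row summing
    DIR contributions over foods as the Σ in the DIR/ADD definitions.
    """
    records = []
    for food in foods:
        ir = exposure.intake_rate(food.intake_key)
        for element in ELEMENTS:
            if element not in food.concentrations:
                continue
            c = food.concentrations[element]
            dir_pub = daily_intake_rate(c, ir, exposure.body_weight, "as_published")
            dir_out = (
                dir_pub * 1e-3 if exposure.unit_mode == "unit_consistent" else dir_pub
            )
            add_nc = average_daily_dose(dir_pub, exposure, "non_carcinogenic")
            add_c = average_daily_dose(dir_pub, exposure, "carcinogenic")
            rfd = tox.rfd(element)
            sf = tox.sf(element)
            pmtdi = tox.pmtdi(element)
            hq = hazard_quotient(add_nc, rfd) if rfd is not None else None
            cr = carcinogenic_risk(add_c, sf) if sf is not None else None
            records.append(
                {
                    "food": food.label,
                    "element": element.value,
                    "concentration": c,
                    "censored_input": element in food.censored,
                    "dir": dir_out,
                    "add_nc": add_nc,
                    "add_c": add_c,
                    "hq": hq,
                    "cr": cr,
                    "hq_exceeds": (hq is not None and hq > HQ_THRESHOLD),
                    "cr_exceeds": (cr is not None and cr > CR_THRESHOLD),
                    "pmtdi_exceeded": (
                        pmtdi_screen(dir_pub, pmtdi) if pmtdi is not None else None
                    ),
                }
            )
    table = pd.DataFrame.from_records(
        records,
        columns=[
            "food", "element", "concentration", "censored_input", "dir",
            "add_nc", "add_c", "hq", "cr", "hq_exceeds", "cr_exceeds",
            "pmtdi_exceeded",
        ],
    )
    per_food = []
    for label, grp in table.groupby("food", sort=False):
        hqt = hazard_index(grp["hq"].dropna())
        crt = total_cr(grp["cr"].dropna())
        per_food.append(
            {
                "food": label,
                "hqt": hqt,
                "crt": crt,
                "hqt_exceeds": hqt > HQ_THRESHOLD,
                "crt_exceeds": crt > CRT_THRESHOLD,
            }
        )
    aggregates = pd.DataFrame.from_records(
        per_food, columns=["food", "hqt", "crt", "hqt_exceeds", "crt_exceeds"]
    )
    diet_total = (
        table.groupby("element", sort=False)[["dir", "add_nc", "add_c"]]
        .sum()
        .reset_index()
        if not table.empty
        else pd.DataFrame(columns=["element", "dir", "add_nc", "add_c"])
    )
    return RiskResult(table=table, aggregates=aggregates, diet_total=diet_total)


@dataclass
class RiskResult:
    """Cascade output: tidy per-food table, per-food sums, diet totals."""

    table: pd.DataFrame
    aggregates: pd.DataFrame
    diet_total: pd.DataFrame

    def dir_of(self, food: str, element: Element) -> float:
        row = self.table[
            (self.table["food"] == food) & (self.table["element"] == element.value)
        ]
        if row.empty:
            raise KeyError(f"no result for {food}/{element.value}")
        return float(row["dir"].iloc[0])

    def hq_of(self, food: str, element: Element) -> float:
        row = self.table[
            (self.table["food"] == food) & (self.table["element"] == element.value)
        ]
        if row.empty or pd.isna(row["hq"].iloc[0]):
            raise KeyError(f"no HQ for {food}/{element.value}")
        return float(row["hq"].iloc[0])


def livestock_screen(
    mean_conc_by_group: dict[str, dict[Element, float]],
    limits: LivestockLimits | None = None,
) -> pd.DataFrame:
    """Screen leaf-group mean Cu/Zn concentrations against feed limits.

    ``mean_conc_by_group`` maps a forage group label (e.g. "grass") to
    per-element mean concentrations in mg kg⁻¹.  Flags use strict
    exceedance of the Cu complete-feed maximum and the Zn daily dietary
    requirement for cattle.
    """
    limits = limits or LivestockLimits()
    thresholds = {
        Element.CU: limits.max_cu_feed,
        Element.ZN: limits.zn_daily_requirement,
    }
    records = []
    for group, means in mean_conc_by_group.items():
        for element, limit in thresholds.items():
            if element not in means:
                continue
            mean = means[element]
            records.append(
                {
                    "group": group,
                    "element": element.value,
                    "mean_concentration": mean,
                    "limit": limit,
                    "exceeds": mean > limit,
                }
            )
    return pd.DataFrame.from_records(
        records, columns=["group", "element", "mean_concentration", "limit", "exceeds"]
    )
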
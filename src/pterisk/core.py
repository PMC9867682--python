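"""Domain types shared by every pipeline stage.

The pipeline tracks six potentially toxic elements (PTEs) in paired
plant/soil samples.  Concentrations are canonically expressed in
mg kg⁻¹ dry weight; total mercury is conventionally reported in
ng g⁻¹ and converted on the way in.  Values below the analytical
detection limit (DL) are *left-censored*: the only information carried
is the DL itself.  Every downstream computation substitutes DL/2 for a
censored value — the standard simple-substitution rule for trace-level
environmental data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class ValidationError(ValueError):
    """Raised when an input value violates a domain invariant."""


class UndefinedRatioError(ZeroDivisionError):
    """Raised when a transfer index denominator is zero."""


class Unit(str, Enum):
    """Concentration units accepted by the pipeline."""

    MG_PER_KG = "mg/kg"
    NG_PER_G = "ng/g"


#: ng g⁻¹ → mg kg⁻¹
_NG_G_TO_MG_KG = 1e-3


class Element(str, Enum):
    """The six PTEs tracked by the pipeline.

    Any other symbol is rejected: the analytical campaign this models
    measured exactly Cu, Zn, As, Sb, Ba and total Hg.
    """

    CU = "Cu"
    ZN = "Zn"
    AS = "As"
    SB = "Sb"
    BA = "Ba"
    HG = "Hg"

    @property
    def reporting_unit(self) -> Unit:
        """Unit used in input tables and rendered reports (Hg in ng g⁻¹)."""
        return Unit.NG_PER_G if self is Element.HG else Unit.MG_PER_KG

    @classmethod
    def parse(cls, symbol: str) -> "Element":
        try:
            return cls(symbol)
        except ValueError:
            raise ValidationError(f"unknown element symbol: {symbol!r}") from None


#: Canonical element ordering used in tables and reports.
ELEMENTS: tuple[Element, ...] = tuple(Element)


def to_canonical_units(value: float, unit: Unit | str) -> float:
    """Convert a concentration to mg kg⁻¹.

    ng g⁻¹ values are divided by 1000; mg kg⁻¹ passes through.
    """
    try:
        unit = Unit(unit)
    except ValueError:
        raise ValidationError(f"unrecognised unit: {unit!r}") from None
    v = float(value)
    if unit is Unit.NG_PER_G:
        return v * _NG_G_TO_MG_KG
    return v


@dataclass(frozen=True)
class CensoredMeasurement:
    """A concentration that is either observed or below a detection limit.

    Invariants: ``censored`` is true iff ``raw_value`` is absent; a
    censored measurement must carry a positive ``detection_limit``; the
    ng g⁻¹ unit is only permitted for Hg.
    """

    element: Element
    raw_value: Optional[float]
    detection_limit: Optional[float]
    censored: bool
    unit: Unit

    def __post_init__(self) -> None:
        if self.censored != (self.raw_value is None):
            raise ValidationError(
                f"{self.element.value}: censored must be true exactly when "
                "raw_value is absent"
            )
        if self.censored:
            if self.detection_limit is None:
                raise ValidationError(
                    f"{self.element.value}: censored value lacks a detection limit"
                )
        else:
            assert self.raw_value is not None
            if self.raw_value < 0:
                raise ValidationError(
                    f"{self.element.value}: negative concentration {self.raw_value}"
                )
        if self.detection_limit is not None and self.detection_limit <= 0:
            raise ValidationError(
                f"{self.element.value}: detection limit must be positive"
            )
        if self.unit is Unit.NG_PER_G and self.element is not Element.HG:
            raise ValidationError(
                f"{self.element.value}: ng/g is only permitted for Hg"
            )

    # -- constructors -------------------------------------------------

    @classmethod
    def observed(
        cls, element: Element, value: float, unit: Unit | None = None
    ) -> "CensoredMeasurement":
        unit = unit or element.reporting_unit
        return cls(element, float(value), None, False, Unit(unit))

    @classmethod
    def below_dl(
        cls, element: Element, detection_limit: float, unit: Unit | None = None
    ) -> "CensoredMeasurement":
        unit = unit or element.reporting_unit
        return cls(element, None, float(detection_limit), True, Unit(unit))

    @classmethod
    def parse(
        cls, element: Element, cell: str | float, unit: Unit | None = None
    ) -> "CensoredMeasurement":
        """Parse a table cell: a plain number, or ``<DL`` as in ``<0.1``."""
        if isinstance(cell, str):
            text = cell.strip()
            m = re.fullmatch(r"<\s*([0-9.eE+-]+)", text)
            if m:
                try:
                    dl = float(m.group(1))
                except ValueError:
                    raise ValidationError(f"malformed censored cell: {cell!r}") from None
                return cls.below_dl(element, dl, unit)
            try:
                value = float(text)
            except ValueError:
                raise ValidationError(f"malformed numeric cell: {cell!r}") from None
            return cls.observed(element, value, unit)
        return cls.observed(element, float(cell), unit)

    # -- rendering ----------------------------------------------------

    def as_cell(self) -> str:
        """Render back to the table dialect (``<DL`` for censored)."""
        if self.censored:
            return f"<{self.detection_limit:g}"
        return repr(self.raw_value)


def substitute_censored(m: CensoredMeasurement) -> float:
    """Resolve a measurement to a number in mg kg⁻¹, applying DL/2.

    Observed values pass through (unit-converted); censored values
    become half the detection limit.  The substitute is always strictly
    below the DL, so summaries computed on substituted data remain a
    conservative but defensible stand-in for the unknown true value.
    """
    if m.censored:
        assert m.detection_limit is not None
        return to_canonical_units(m.detection_limit / 2.0, m.unit)
    assert m.raw_value is not None
    return to_canonical_units(m.raw_value, m.unit)


def substitute_censored_reporting(m: CensoredMeasurement) -> float:
    """DL/2-resolved value kept in the measurement's reporting unit."""
    if m.censored:
        assert m.detection_limit is not None
        return m.detection_limit / 2.0
    assert m.raw_value is not None
    return m.raw_value


VALID_TISSUES = ("leaf", "grain", "tuber", "tea_leaf")
EDIBLE_TISSUES = ("grain", "tuber", "tea_leaf")


@dataclass
class PlantSample:
    """One plant tissue sample with per-element measurements."""

    sample_id: str
    taxon: str
    family: str
    tissue: str
    edible: bool
    measurements: dict[Element, CensoredMeasurement] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tissue not in VALID_TISSUES:
            raise ValidationError(
                f"{self.sample_id}: unknown tissue {self.tissue!r} "
                f"(expected one of {VALID_TISSUES})"
            )
        if self.tissue in EDIBLE_TISSUES and not self.edible:
            raise ValidationError(
                f"{self.sample_id}: tissue {self.tissue!r} implies edible"
            )

    def concentration(self, element: Element) -> Optional[float]:
        """DL/2-substituted concentration in mg kg⁻¹, or None if absent."""
        m = self.measurements.get(element)
        return None if m is None else substitute_censored(m)


@dataclass
class SoilSample:
    """Pseudo-total soil concentrations paired with a plant sample."""

    sample_id: str
    paired_plant_id: str
    measurements: dict[Element, CensoredMeasurement] = field(default_factory=dict)

    def concentration(self, element: Element) -> Optional[float]:
        m = self.measurements.get(element)
        return None if m is None else substitute_censored(m)
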
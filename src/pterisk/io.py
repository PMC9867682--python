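"""Readers/writers for sample, BCR and food tables, and validated parameters.

All tables are plain CSV.  Concentration cells are either numbers or
the ``<DL`` dialect (e.g. ``<0.1``) marking a value below the stated
detection limit; Hg columns are headed ``Hg_ng_g`` because total
mercury is reported in ng g⁻¹.

Exposure and toxicity parameters default to a standard adult-resident
scenario (body weight 70 kg, daily exposure over 30 years, 70-year
lifetime) with food intake rates, oral reference doses (RfD), cancer
slope factors (SF) and provisional maximum tolerable daily intakes
(PMTDI) for the six elements.  A flat YAML file with dotted keys
(``ir.rice``, ``exposure.body_weight``, ``tox.rfd.As``, ``pmtdi.Cu``)
overrides individual defaults so parameter provenance stays auditable.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .core import (
    ELEMENTS,
    CensoredMeasurement,
    Element,
    PlantSample,
    SoilSample,
    ValidationError,
)

# -- tabular schemas ----------------------------------------------------

ELEMENT_COLUMNS = ["Cu", "Zn", "As", "Sb", "Ba", "Hg_ng_g"]
PLANT_COLUMNS = ["sample_id", "taxon", "family", "tissue", "edible"] + ELEMENT_COLUMNS
SOIL_COLUMNS = ["sample_id", "plant_id"] + ELEMENT_COLUMNS
BCR_COLUMNS = ["soil_sample_id", "element", "s1", "s2", "s3", "pseudo_total"]
FOOD_COLUMNS = ["food_label"] + ELEMENT_COLUMNS

_COLUMN_TO_ELEMENT = {
    "Cu": Element.CU,
    "Zn": Element.ZN,
    "As": Element.AS,
    "Sb": Element.SB,
    "Ba": Element.BA,
    "Hg_ng_g": Element.HG,
}
ELEMENT_TO_COLUMN = {e: c for c, e in _COLUMN_TO_ELEMENT.items()}


class ParseError(ValueError):
    """A malformed cell or header, with row/column context."""


def _read_rows(path: str | Path, expected: list[str], optional: set[str] | None = None):
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        required = [c for c in expected if not (optional and c in optional)]
        missing = [c for c in required if c not in header]
        if missing:
            raise ParseError(f"{path}: missing columns {missing}")
        return list(reader)


def _parse_measurements(row: dict, row_no: int, path) -> dict[Element, CensoredMeasurement]:
    out: dict[Element, CensoredMeasurement] = {}
    for col, element in _COLUMN_TO_ELEMENT.items():
        cell = row.get(col)
        if cell is None or str(cell).strip() == "":
            continue
        try:
            out[element] = CensoredMeasurement.parse(element, cell)
        except ValidationError as exc:
            raise ParseError(f"{path} row {row_no}, column {col}: {exc}") from exc
    return out


_TRUE = {"true", "1", "yes", "t"}


def read_samples(
    plant_path: str | Path, soil_path: str | Path | None = None
) -> list[tuple[PlantSample, Optional[SoilSample]]]:
    """Read paired plant/soil tables into validated sample pairs.

    The soil table is optional; without it the soil member of each pair
    is ``None`` and soil-dependent stages (BAC) are unavailable.  Every
    soil row must reference an existing plant ``sample_id``.
    """
    pairs: dict[str, tuple[PlantSample, Optional[SoilSample]]] = {}
    for i, row in enumerate(_read_rows(plant_path, PLANT_COLUMNS), start=2):
        sid = row["sample_id"].strip()
        if sid in pairs:
            raise ValidationError(f"duplicate sample_id {sid!r}")
        plant = PlantSample(
            sample_id=sid,
            taxon=row["taxon"].strip(),
            family=row["family"].strip(),
            tissue=row["tissue"].strip(),
            edible=row["edible"].strip().lower() in _TRUE,
            measurements=_parse_measurements(row, i, plant_path),
        )
        pairs[sid] = (plant, None)
    if soil_path is not None:
        for i, row in enumerate(_read_rows(soil_path, SOIL_COLUMNS), start=2):
            pid = row["plant_id"].strip()
            if pid not in pairs:
                raise ValidationError(
                    f"soil sample {row['sample_id']!r} references unknown plant {pid!r}"
                )
            soil = SoilSample(
                sample_id=row["sample_id"].strip(),
                paired_plant_id=pid,
                measurements=_parse_measurements(row, i, soil_path),
            )
            pairs[pid] = (pairs[pid][0], soil)
    return list(pairs.values())


def write_samples(
    pairs: list[tuple[PlantSample, Optional[SoilSample]]],
    plant_path: str | Path,
    soil_path: str | Path | None = None,
) -> None:
    """Write pairs back to CSV, preserving the ``<DL`` dialect."""
    with Path(plant_path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PLANT_COLUMNS)
        for plant, _ in pairs:
            cells = [
                plant.measurements[e].as_cell() if e in plant.measurements else ""
                for e in ELEMENTS
            ]
            writer.writerow(
                [plant.sample_id, plant.taxon, plant.family, plant.tissue,
                 str(plant.edible).lower()] + cells
            )
    if soil_path is not None:
        with Path(soil_path).open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(SOIL_COLUMNS)
            for plant, soil in pairs:
                if soil is None:
                    continue
                cells = [
                    soil.measurements[e].as_cell() if e in soil.measurements else ""
                    for e in ELEMENTS
                ]
                writer.writerow([soil.sample_id, soil.paired_plant_id] + cells)


def read_bcr(path: str | Path) -> list[dict]:
    """Read a BCR sequential-extraction table.

    Columns: soil_sample_id, element, s1, s2, s3, pseudo_total (all
    concentrations mg kg⁻¹).  Steps must be non-negative and the
    pseudo-total strictly positive.
    """
    rows = []
    for i, row in enumerate(_read_rows(path, BCR_COLUMNS), start=2):
        try:
            rec = {
                "soil_sample_id": row["soil_sample_id"].strip(),
                "element": Element.parse(row["element"].strip()),
                "s1": float(row["s1"]),
                "s2": float(row["s2"]),
                "s3": float(row["s3"]),
                "pseudo_total": float(row["pseudo_total"]),
            }
        except (ValueError, ValidationError) as exc:
            raise ParseError(f"{path} row {i}: {exc}") from exc
        if min(rec["s1"], rec["s2"], rec["s3"]) < 0:
            raise ValidationError(f"{path} row {i}: negative extraction step")
        if rec["pseudo_total"] <= 0:
            raise ValidationError(f"{path} row {i}: pseudo_total must be positive")
        rows.append(rec)
    return rows


def read_foods(path: str | Path):
    """Read a food-concentration table into :class:`~pterisk.risk.FoodItem`s.

    An optional ``ir_label`` column maps a row to its intake-rate entry
    when the row label itself (e.g. a per-sample tea id) is not an
    intake-rate key.
    """
    from .risk import FoodItem  # deferred to avoid an import cycle

    items = []
    for i, row in enumerate(
        _read_rows(path, FOOD_COLUMNS, optional={"ir_label"}), start=2
    ):
        ms = _parse_measurements(row, i, path)
        items.append(
            FoodItem.from_measurements(
                label=row["food_label"].strip(),
                measurements=ms,
                ir_label=(row.get("ir_label") or "").strip() or None,
            )
        )
    return items


# -- parameters ---------------------------------------------------------

DEFAULT_INTAKE_RATES = {"rice": 125.2, "corn": 50.0, "cassava": 42.0, "tea": 10.9}

DEFAULT_RFD = {
    Element.CU: 4.0e-2,
    Element.ZN: 3.0e-1,
    Element.AS: 3.0e-4,
    Element.SB: 4.0e-4,
    Element.BA: 2.0e-1,
    Element.HG: 3.0e-4,
}
DEFAULT_SF = {Element.CU: 1.7, Element.AS: 1.5}
DEFAULT_PMTDI = {
    Element.CU: 0.5,
    Element.ZN: 1.0,
    Element.AS: 0.0021,
    Element.SB: 0.006,
    Element.BA: 0.02,
    Element.HG: 0.0006,
}


class ExposureParams(BaseModel):
    """Adult dietary exposure scenario.

    ``unit_mode`` selects the DIR convention: ``as_published`` keeps the
    intake rate in g person⁻¹ day⁻¹ inside DIR = C·IR/BW (the published
    table convention); ``unit_consistent`` applies the g→kg factor so
    DIR is dimensionally commensurate with PMTDI.  ADD, HQ and CR are
    identical in both modes because the 10⁻³ already enters ADD.
    """

    intake_rates: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_INTAKE_RATES)
    )
    body_weight: float = 70.0  # kg
    exposure_frequency: float = 365.0  # d y⁻¹
    exposure_duration: float = 30.0  # y
    lifetime: float = 70.0  # y
    unit_mode: Literal["as_published", "unit_consistent"] = "as_published"

    @field_validator("body_weight", "exposure_frequency", "exposure_duration", "lifetime")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("exposure parameters must be strictly positive")
        return v

    @field_validator("intake_rates")
    @classmethod
    def _ir_positive(cls, v: dict[str, float]) -> dict[str, float]:
        for k, ir in v.items():
            if ir <= 0:
                raise ValueError(f"intake rate for {k!r} must be strictly positive")
        return v

    @model_validator(mode="after")
    def _duration_within_lifetime(self) -> "ExposureParams":
        if self.exposure_duration > self.lifetime:
            raise ValueError("exposure_duration must not exceed lifetime")
        return self

    def intake_rate(self, label: str) -> float:
        try:
            return self.intake_rates[label]
        except KeyError:
            raise KeyError(
                f"no intake rate configured for food {label!r}; "
                f"known foods: {sorted(self.intake_rates)}"
            ) from None


class ToxEntry(BaseModel):
    rfd: Optional[float] = None  # mg kg⁻¹ d⁻¹
    sf: Optional[float] = None  # (mg kg⁻¹ d⁻¹)⁻¹
    pmtdi: Optional[float] = None  # mg kg⁻¹ bw d⁻¹


class ToxTable(BaseModel):
    """Per-element toxicity constants (RfD, SF, PMTDI)."""

    entries: dict[Element, ToxEntry] = Field(
        default_factory=lambda: {
            e: ToxEntry(
                rfd=DEFAULT_RFD.get(e),
                sf=DEFAULT_SF.get(e),
                pmtdi=DEFAULT_PMTDI.get(e),
            )
            for e in ELEMENTS
        }
    )

    def rfd(self, element: Element) -> Optional[float]:
        return self.entries[element].rfd

    def sf(self, element: Element) -> Optional[float]:
        return self.entries[element].sf

    def pmtdi(self, element: Element) -> Optional[float]:
        return self.entries[element].pmtdi


class LivestockLimits(BaseModel):
    """Ruminant feed screening levels (complete-feed basis, mg kg⁻¹)."""

    max_cu_feed: float = 10.0
    zn_daily_requirement: float = 22.8

    @field_validator("max_cu_feed", "zn_daily_requirement")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("livestock limits must be positive")
        return v


def load_default_parameters() -> tuple[ExposureParams, ToxTable]:
    """The default adult exposure scenario and toxicity table."""
    return ExposureParams(), ToxTable()


def load_parameters(path: str | Path | None = None) -> tuple[ExposureParams, ToxTable]:
    """Load parameters, applying overrides from a flat YAML file.

    Only keys present in the file are replaced; everything else keeps
    its default.  Recognised keys::

        ir.<food>: <g/day>          exposure.body_weight: <kg>
        exposure.exposure_frequency  exposure.exposure_duration
        exposure.lifetime            exposure.unit_mode
        tox.rfd.<El>  tox.sf.<El>    pmtdi.<El>
    """
    exposure, tox = load_default_parameters()
    if path is None:
        return exposure, tox
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh) or {}

    flat: dict[str, object] = {}

    def _flatten(prefix: str, node) -> None:
        if isinstance(node, dict):
            for k, v in node.items():
                _flatten(f"{prefix}{k}.", v)
        else:
            flat[prefix[:-1]] = node

    _flatten("", raw)

    exposure_updates: dict[str, object] = {}
    ir = dict(exposure.intake_rates)
    entries = {e: tox.entries[e].model_copy() for e in ELEMENTS}
    for key, value in flat.items():
        parts = key.split(".")
        if parts[0] == "ir" and len(parts) == 2:
            ir[parts[1]] = float(value)  # type: ignore[arg-type]
        elif parts[0] == "exposure" and len(parts) == 2:
            exposure_updates[parts[1]] = value
        elif parts[0] == "tox" and len(parts) == 3 and parts[1] in ("rfd", "sf"):
            setattr(entries[Element.parse(parts[2])], parts[1], float(value))  # type: ignore[arg-type]
        elif parts[0] == "pmtdi" and len(parts) == 2:
            entries[Element.parse(parts[1])].pmtdi = float(value)  # type: ignore[arg-type]
        else:
            raise KeyError(f"unrecognised parameter key: {key!r}")
    exposure_updates["intake_rates"] = ir
    exposure = exposure.model_copy(update=exposure_updates)
    exposure = ExposureParams.model_validate(exposure.model_dump())
    return exposure, ToxTable(entries=entries)
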
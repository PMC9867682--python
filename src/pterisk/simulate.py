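"""Seedable generator of plant/soil/BCR/food tables.

The generator emulates the statistical structure a mining-impacted
soil–plant survey exhibits, so every pipeline stage has a recoverable
ground truth without the original field data:

* soil pseudo-totals are log-normal, calibrated per element so the
  natural-scale mean and SD match the published survey summary
  (e.g. Cu mean 70.3, SD 61.1 mg kg⁻¹; Hg in ng g⁻¹);
* elements are coupled through a Gaussian copula with two correlation
  blocks — the essential pair {Cu, Zn} and the mineralisation suite
  {As, Sb, Ba, Hg} — so the clustering stage has a known split;
* plant concentration = transfer_factor × soil × log-normal noise,
  with transfer factors defaulting to the survey's mean BACs;
* BCR steps are a Dirichlet partition of the pseudo-total whose
  expectations reproduce the published labile shares (Cu ≈ 17.94%
  labile, As ≈ 1.82%), and S1+S2+S3+residual = pseudo_total exactly;
* values below the element's detection limit are written as ``<DL``.

Everything is driven by one ``numpy`` Generator, so a fixed seed gives
byte-identical output tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .core import Element
from .io import ELEMENT_TO_COLUMN, FOOD_COLUMNS, PLANT_COLUMNS, SOIL_COLUMNS


class ElementSim(BaseModel):
    """Per-element generating parameters.

    ``soil_mean``/``soil_sd`` are the *natural-scale* moments the
    log-normal soil marginal must reproduce (reporting units);
    ``transfer_factor`` is the median soil→plant ratio and
    ``transfer_logsd`` the SD of its log-normal scatter;
    ``dl_plant``/``dl_soil`` are detection limits in reporting units.
    """

    soil_mean: float
    soil_sd: float
    transfer_factor: float
    transfer_logsd: float = 0.6
    dl_plant: float = 0.0
    dl_soil: float = 0.0

    @field_validator("soil_mean", "soil_sd", "transfer_factor", "transfer_logsd")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("generator scale parameters must be positive")
        return v

    def log_params(self) -> tuple[float, float]:
        """(mu, sigma) of ln(soil) matching the natural-scale moments."""
        m, s = self.soil_mean, self.soil_sd
        sigma2 = np.log1p((s / m) ** 2)
        mu = np.log(m) - sigma2 / 2.0
        return float(mu), float(np.sqrt(sigma2))


def _default_elements() -> dict[str, ElementSim]:
    # soil means/SDs and transfer factors follow the survey summary;
    # DLs are the analytical limits the survey reported (Hg in ng/g)
    return {
        "Cu": ElementSim(soil_mean=70.3, soil_sd=61.1, transfer_factor=0.46,
                         dl_plant=0.5, dl_soil=5.0),
        "Zn": ElementSim(soil_mean=54.4, soil_sd=27.5, transfer_factor=0.70,
                         dl_plant=0.5, dl_soil=5.0),
        "As": ElementSim(soil_mean=110.6, soil_sd=171.0, transfer_factor=0.06,
                         dl_plant=0.1, dl_soil=0.8),
        "Sb": ElementSim(soil_mean=16.1, soil_sd=6.3, transfer_factor=0.48,
                         dl_plant=1.0, dl_soil=0.6),
        "Ba": ElementSim(soil_mean=310.9, soil_sd=166.8, transfer_factor=0.14,
                         dl_plant=5.0, dl_soil=5.0),
        "Hg": ElementSim(soil_mean=276.1, soil_sd=797.7, transfer_factor=0.27,
                         dl_plant=0.1, dl_soil=5.0),
    }


def _default_bcr_fractions() -> dict[str, list[float]]:
    # expected (S1, S2, S3, residual) shares; Cu labile 17.94%, As 1.83%
    return {
        "Cu": [0.0445, 0.0915, 0.0434, 0.8206],
        "As": [0.0004, 0.0040, 0.0139, 0.9817],
    }


class GeneratorConfig(BaseModel):
    """Configuration for one synthetic survey."""

    n_samples: int = 75
    n_bcr: int = 12
    seed: int = 0
    elements: dict[str, ElementSim] = Field(default_factory=_default_elements)
    correlation_blocks: list[list[str]] = Field(
        default_factory=lambda: [["Cu", "Zn"], ["As", "Sb", "Ba", "Hg"]]
    )
    rho: float = 0.7
    bcr_fractions: dict[str, list[float]] = Field(
        default_factory=_default_bcr_fractions
    )
    #: Dirichlet concentration: alpha = concentration × expected shares
    bcr_concentration: float = 60.0
    food_labels: dict[str, str] = Field(
        default_factory=lambda: {
            "rice": "rice", "corn": "corn", "cassava": "cassava",
            "tea_pm1": "tea", "tea_pm4": "tea",
        }
    )

    @field_validator("n_samples", "n_bcr")
    @classmethod
    def _positive_counts(cls, v: int) -> int:
        if v <= 0:
            raise ValueError("sample counts must be positive")
        return v

    @field_validator("rho")
    @classmethod
    def _valid_rho(cls, v: float) -> float:
        if not (0.0 <= v < 1.0):
            raise ValueError("rho must be in [0, 1)")
        return v

    @field_validator("bcr_fractions")
    @classmethod
    def _valid_fractions(cls, v: dict[str, list[float]]) -> dict[str, list[float]]:
        for el, shares in v.items():
            if len(shares) != 4 or min(shares) <= 0:
                raise ValueError(f"{el}: need 4 positive Dirichlet shares")
            if abs(sum(shares) - 1.0) > 1e-6:
                raise ValueError(f"{el}: Dirichlet shares must sum to 1")
        return v


@dataclass
class SimulatedDataset:
    """Generated tables plus the generating truth for recovery tests."""

    plants: pd.DataFrame
    soils: pd.DataFrame
    bcr: pd.DataFrame
    foods: pd.DataFrame
    truth: dict
    config: GeneratorConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "plants": out / "plants.csv",
            "soils": out / "soils.csv",
            "bcr": out / "bcr.csv",
            "foods": out / "foods.csv",
        }
        self.plants.to_csv(paths["plants"], index=False)
        self.soils.to_csv(paths["soils"], index=False)
        self.bcr.to_csv(paths["bcr"], index=False)
        self.foods.to_csv(paths["foods"], index=False)
        return paths


def _correlation_matrix(config: GeneratorConfig, order: list[str]) -> np.ndarray:
    k = len(order)
    R = np.eye(k)
    for block in config.correlation_blocks:
        idx = [order.index(e) for e in block if e in order]
        for i in idx:
            for j in idx:
                if i != j:
                    R[i, j] = config.rho
    return R


def _censor_column(values: np.ndarray, dl: float) -> list[str]:
    return [f"<{dl:g}" if (dl > 0 and v < dl) else repr(float(v)) for v in values]


def generate(config: GeneratorConfig) -> SimulatedDataset:
    """Generate one synthetic survey; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    order = list(config.elements)
    k = len(order)

    R = _correlation_matrix(config, order)
    L = np.linalg.cholesky(R)
    z_soil = rng.standard_normal((config.n_samples, k)) @ L.T

    soil = np.empty((config.n_samples, k))
    plant = np.empty((config.n_samples, k))
    for j, symbol in enumerate(order):
        sim = config.elements[symbol]
        mu, sigma = sim.log_params()
        soil[:, j] = np.exp(mu + sigma * z_soil[:, j])
        noise = np.exp(sim.transfer_logsd * rng.standard_normal(config.n_samples))
        plant[:, j] = sim.transfer_factor * soil[:, j] * noise

    ids = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    plant_rows = []
    soil_rows = []
    for i, sid in enumerate(ids):
        plant_rows.append([sid, "synthetic taxon", "synthetic", "leaf", "false"])
        soil_rows.append([f"{sid}-soil", sid])
    plants = pd.DataFrame(plant_rows, columns=PLANT_COLUMNS[:5])
    soils = pd.DataFrame(soil_rows, columns=SOIL_COLUMNS[:2])
    for j, symbol in enumerate(order):
        sim = config.elements[symbol]
        col = ELEMENT_TO_COLUMN[Element.parse(symbol)]
        plants[col] = _censor_column(plant[:, j], sim.dl_plant)
        soils[col] = _censor_column(soil[:, j], sim.dl_soil)

    # BCR: Dirichlet partition of the pseudo-total; residual closes the
    # balance so the four parts sum to the pseudo-total exactly
    bcr_rows = []
    n_bcr = min(config.n_bcr, config.n_samples)
    for symbol, shares in config.bcr_fractions.items():
        j = order.index(symbol)
        alpha = config.bcr_concentration * np.asarray(shares)
        fracs = rng.dirichlet(alpha, size=n_bcr)
        for i in range(n_bcr):
            pt = soil[i, j]
            s1, s2, s3 = (fracs[i, :3] * pt).tolist()
            bcr_rows.append([f"{ids[i]}-soil", symbol, s1, s2, s3, pt])
    bcr = pd.DataFrame(bcr_rows, columns=["soil_sample_id", "element", "s1", "s2", "s3", "pseudo_total"])

    # foods: one edible row per configured label, drawn with the same
    # soil→plant mechanism from a fresh soil realisation
    food_rows = []
    for label in config.food_labels:
        row: list[object] = [label]
        for symbol in order:
            sim = config.elements[symbol]
            mu, sigma = sim.log_params()
            s = float(np.exp(mu + sigma * rng.standard_normal()))
            c = sim.transfer_factor * s * float(
                np.exp(sim.transfer_logsd * rng.standard_normal())
            )
            row.append(f"<{sim.dl_plant:g}" if (sim.dl_plant > 0 and c < sim.dl_plant) else repr(c))
        row.append(config.food_labels[label])
        food_rows.append(row)
    foods = pd.DataFrame(food_rows, columns=FOOD_COLUMNS + ["ir_label"])

    truth = {
        "soil": pd.DataFrame(soil, columns=order, index=ids),
        "plant": pd.DataFrame(plant, columns=order, index=ids),
        "transfer_factors": {s: config.elements[s].transfer_factor for s in order},
    }
    return SimulatedDataset(
        plants=plants, soils=soils, bcr=bcr, foods=foods, truth=truth, config=config
    )
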
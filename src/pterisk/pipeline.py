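"""End-to-end orchestration and report rendering.

``run_all`` wires the stages together: read tables → descriptive
summaries + correlations + clustering → transfer indices → dietary
risk cascade → consolidated exceedance flags — and writes one output
bundle (CSV/JSON plus a human-readable report) together with a run
manifest recording inputs, the parameter snapshot and per-stage row
counts.  Stored values keep full floating precision; rounding (3
decimals for DIR/HQ, 2 for indices) happens only in the rendered
report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .core import ELEMENTS, Element
from .io import (
    ExposureParams,
    LivestockLimits,
    ToxTable,
    read_bcr,
    read_foods,
    read_samples,
)
from .risk import CRT_THRESHOLD, CR_THRESHOLD, HQ_THRESHOLD, assess, livestock_screen
from .stats import concentration_frame, element_summaries, pearson_matrix, ward_cluster
from .transfer import transfer_table

logger = logging.getLogger("pterisk")


@dataclass
class RunManifest:
    """Provenance record written alongside every output bundle."""

    inputs: dict[str, Optional[str]]
    parameters: dict
    unit_mode: str
    seed: Optional[int] = None
    version: str = __version__
    row_counts: dict[str, int] = field(default_factory=dict)
    censored_substitutions: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def render_value(x: float, element: Element | str | None = None, decimals: int = 3) -> float:
    """Report-rendering rounding: Hg intake values keep 5 decimals."""
    if element is not None and Element(element) is Element.HG and decimals == 3:
        return round(x, 5)
    return round(x, decimals)


_FLAG_COLUMNS = ["scope", "subject", "element", "metric", "value", "threshold", "exceeded"]


def _collect_flags(risk_result, livestock: pd.DataFrame) -> pd.DataFrame:
    rows = []
    table = risk_result.table if risk_result is not None else pd.DataFrame()
    aggregates = risk_result.aggregates if risk_result is not None else pd.DataFrame()
    for _, r in table.iterrows():
        if r["hq"] is not None and not pd.isna(r["hq"]):
            rows.append(("food", r["food"], r["element"], "HQ", r["hq"],
                         HQ_THRESHOLD, bool(r["hq_exceeds"])))
        if r["cr"] is not None and not pd.isna(r["cr"]):
            rows.append(("food", r["food"], r["element"], "CR", r["cr"],
                         CR_THRESHOLD, bool(r["cr_exceeds"])))
        if r["pmtdi_exceeded"] is not None and not pd.isna(r["pmtdi_exceeded"]):
            rows.append(("food", r["food"], r["element"], "DIR_vs_PMTDI", r["dir"],
                         float("nan"), bool(r["pmtdi_exceeded"])))
    for _, r in aggregates.iterrows():
        rows.append(("food", r["food"], "", "HQt", r["hqt"], HQ_THRESHOLD,
                     bool(r["hqt_exceeds"])))
        rows.append(("food", r["food"], "", "CRt", r["crt"], CRT_THRESHOLD,
                     bool(r["crt_exceeds"])))
    for _, r in livestock.iterrows():
        rows.append(("forage_group", r["group"], r["element"], "feed_limit",
                     r["mean_concentration"], r["limit"], bool(r["exceeds"])))
    return pd.DataFrame(rows, columns=_FLAG_COLUMNS)


def run_all(
    plant_path: str | Path,
    soil_path: str | Path | None,
    foods_path: str | Path | None,
    out_dir: str | Path,
    bcr_path: str | Path | None = None,
    exposure: ExposureParams | None = None,
    tox: ToxTable | None = None,
    livestock_limits: LivestockLimits | None = None,
    forage_groups: dict | None = None,
    seed: int | None = None,
) -> RunManifest:
    """Run every stage on the given tables and write the output bundle.

    Writes ``summary.csv``, ``pearson_r.csv``, ``dendro.json``,
    ``indices.csv`` (when soils are present), ``risk.csv`` +
    ``risk_foods.csv`` (when foods are present), ``flags.csv``,
    ``manifest.json`` and ``report.txt`` under ``out_dir``.
    """
    from .io import load_default_parameters

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if exposure is None or tox is None:
        d_exposure, d_tox = load_default_parameters()
        exposure = exposure or d_exposure
        tox = tox or d_tox

    pairs = read_samples(plant_path, soil_path)
    n_censored = sum(
        m.censored
        for plant, soil in pairs
        for s in (plant, soil)
        if s is not None
        for m in s.measurements.values()
    )
    logger.info("read %d sample pairs (%d censored cells, DL/2 substituted)",
                len(pairs), n_censored)

    # descriptive layer
    summary = element_summaries(pairs)
    summary.to_csv(out / "summary.csv", index=False)
    frame = concentration_frame(pairs, kind="plant").dropna(axis=1, how="any")
    report_lines = [f"pterisk v{__version__} report", ""]
    row_counts = {"samples": len(pairs), "summary": len(summary)}
    if frame.shape[1] >= 2 and frame.shape[0] >= 3:
        r, p = pearson_matrix(frame)
        r.to_csv(out / "pearson_r.csv")
        p.to_csv(out / "pearson_p.csv")
        dendro = ward_cluster(frame)
        (out / "dendro.json").write_text(json.dumps(dendro.to_dict(), indent=2))
        two_groups = dendro.cut(2)
        report_lines.append(
            "Element association (Ward, standardized): "
            + " | ".join("{" + ", ".join(sorted(g)) + "}" for g in two_groups)
        )
        row_counts["clustered_elements"] = frame.shape[1]

    # transfer indices
    bcr_rows = read_bcr(bcr_path) if bcr_path else []
    indices = transfer_table(pairs, bcr_rows)
    if not indices.empty:
        write_cols = list(indices.columns)
        if not bcr_rows:
            write_cols = [c for c in write_cols if c not in ("bc", "labile_conc", "labile_pct")]
        indices[write_cols].to_csv(out / "indices.csv", index=False)
        row_counts["indices"] = len(indices)
        mean_bac = indices.groupby("element")["bac"].mean()
        report_lines.append("Mean BAC per element (2 dp): " + ", ".join(
            f"{el}={render_value(v, decimals=2)}" for el, v in mean_bac.items()))

    # dietary risk
    livestock = pd.DataFrame(columns=["group", "element", "mean_concentration", "limit", "exceeds"])
    if forage_groups:
        livestock = livestock_screen(forage_groups, livestock_limits)
    result = None
    if foods_path:
        foods = read_foods(foods_path)
        result = assess(foods, exposure, tox)
        result.table.to_csv(out / "risk.csv", index=False)
        result.aggregates.to_csv(out / "risk_foods.csv", index=False)
        row_counts["risk"] = len(result.table)
        for _, r in result.table.iterrows():
            report_lines.append(
                f"{r['food']:>10s} {r['element']:>2s}: "
                f"DIR={render_value(r['dir'], r['element'])}"
                + (f" HQ={render_value(r['hq'])}" if pd.notna(r["hq"]) else "")
            )
    flags = _collect_flags(result, livestock)
    flags.to_csv(out / "flags.csv", index=False)
    row_counts["flags"] = len(flags)

    manifest = RunManifest(
        inputs={
            "plants": str(plant_path),
            "soils": str(soil_path) if soil_path else None,
            "bcr": str(bcr_path) if bcr_path else None,
            "foods": str(foods_path) if foods_path else None,
        },
        parameters={
            "exposure": exposure.model_dump(),
            "tox": {e.value: tox.entries[e].model_dump() for e in ELEMENTS},
        },
        unit_mode=exposure.unit_mode,
        seed=seed,
        row_counts=row_counts,
        censored_substitutions=n_censored,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    report_lines.append("")
    report_lines.append(f"censored cells substituted at DL/2: {n_censored}")
    report_lines.append(f"unit mode: {exposure.unit_mode}")
    (out / "report.txt").write_text("\n".join(report_lines) + "\n")
    return manifest
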
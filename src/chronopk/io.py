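"""File formats and configuration shared across the command-line tools.

Concentration data travel as tidy CSV (``patient_id, analyte, time_h,
conc_mg_per_L``; times may also be clock strings "HH:MM" resolved against a
per-drug infusion start), pump programs as YAML, fits and clusters as JSON.
All loaders validate and report offending rows by number; writers are
round-trip stable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from chronopk.pk import ConcentrationSeries
from chronopk.pump import (
    DEFAULT_REFERENCE_BSA,
    DEFAULT_TUBE,
    DeliveryProfile,
    InfusionSegment,
    PumpProgram,
    TubeSpec,
    clock_to_hours,
)

__all__ = [
    "RunConfig",
    "load_config",
    "load_concentration_csv",
    "save_concentration_csv",
    "load_program_yaml",
    "save_program_yaml",
    "save_delivery_csv",
    "load_delivery_csv",
    "setup_logging",
]

log = logging.getLogger("chronopk")

CONC_COLUMNS = ["patient_id", "analyte", "time_h", "conc_mg_per_L"]


def setup_logging(level: int = logging.INFO) -> None:
    """Structured JSON-lines logging with module and seed stamps."""
    handler = logging.StreamHandler()

    class _JsonFormatter(logging.Formatter):
        def format(self, record: logging.LogRecord) -> str:
            payload = {
                "module": record.name,
                "level": record.levelname,
                "message": record.getMessage(),
            }
            for key in ("seed", "drug", "patient_id"):
                if hasattr(record, key):
                    payload[key] = getattr(record, key)
            return json.dumps(payload)

    handler.setFormatter(_JsonFormatter())
    logging.basicConfig(level=level, handlers=[handler], force=True)


@dataclass(frozen=True)
class RunConfig:
    """Run-wide settings: every random operation reads its seed from here."""

    seed: int = 0
    reference_bsa: float = DEFAULT_REFERENCE_BSA
    tube: TubeSpec = DEFAULT_TUBE
    error_cv: float = 0.10
    lloq_mg_l: float = 1e-3
    paths: dict[str, str] = field(default_factory=dict)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    tube = _tube_from_mapping(raw.get("tube", {}))
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        reference_bsa=float(raw.get("reference_bsa", DEFAULT_REFERENCE_BSA)),
        tube=tube,
        error_cv=float(raw.get("error_cv", 0.10)),
        lloq_mg_l=float(raw.get("lloq_mg_l", 1e-3)),
        paths={k: str(v) for k, v in raw.get("paths", {}).items()},
    )


# --------------------------------------------------------------------------
# Concentration CSV
# --------------------------------------------------------------------------

def load_concentration_csv(
    path: str | Path,
    hai_start_clock: str | None = None,
) -> dict[tuple[str, str], ConcentrationSeries]:
    """Load a tidy concentration CSV into per-(patient, analyte) series.

    ``time_h`` may be numeric hours post-HAI or clock strings "HH:MM"; the
    latter require ``hai_start_clock`` and wrap across midnight.  Malformed
    rows are rejected with their (1-based, header-inclusive) line numbers.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "analyte": str})
    missing = [c for c in CONC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    times = np.empty(len(df))
    for i, v in enumerate(df["time_h"]):
        if isinstance(v, str) and ":" in v:
            if hai_start_clock is None:
                raise ValueError(
                    f"{path}: row {i + 2}: clock time {v!r} needs hai_start_clock"
                )
            times[i] = (clock_to_hours(v) - clock_to_hours(hai_start_clock)) % 24.0
        else:
            times[i] = float(v)
    df = df.assign(time_h=times)

    bad = df.index[df["conc_mg_per_L"].astype(float) < 0]
    if len(bad):
        raise ValueError(f"{path}: negative concentration at rows {[int(b) + 2 for b in bad]}")
    dup = df.duplicated(subset=["patient_id", "analyte", "time_h"])
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (patient, analyte, time) at rows "
            f"{[int(b) + 2 for b in df.index[dup]]}"
        )

    out: dict[tuple[str, str], ConcentrationSeries] = {}
    for (pid, analyte), grp in df.groupby(["patient_id", "analyte"], sort=True):
        grp = grp.sort_values("time_h")
        out[(pid, analyte)] = ConcentrationSeries(
            analyte=analyte,
            times_h=grp["time_h"].to_numpy(dtype=float),
            values_mg_l=grp["conc_mg_per_L"].to_numpy(dtype=float),
            patient_id=pid,
        )
    return out


def save_concentration_csv(
    series: Sequence[ConcentrationSeries], path: str | Path
) -> None:
    rows = []
    for s in series:
        for t, v in zip(s.times_h, s.values_mg_l):
            rows.append((s.patient_id, s.analyte, float(t), float(v)))
    pd.DataFrame(rows, columns=CONC_COLUMNS).to_csv(path, index=False)


# --------------------------------------------------------------------------
# Pump program YAML
# --------------------------------------------------------------------------

def _tube_from_mapping(raw: Mapping[str, Any]) -> TubeSpec:
    if "radius_mm" in raw and "length_mm" in raw:
        return TubeSpec.from_geometry(float(raw["radius_mm"]), float(raw["length_mm"]))
    if "volume_ml" in raw:
        kwargs = {"volume_ml": float(raw["volume_ml"])}
        if "length_mm" in raw:
            kwargs["length_mm"] = float(raw["length_mm"])
        return TubeSpec(**kwargs)
    return DEFAULT_TUBE


def _segment_to_mapping(seg: InfusionSegment) -> dict[str, Any]:
    d = {
        "start_h": seg.start_h,
        "duration_h": seg.duration_h,
        "shape": seg.shape,
        "peak_rate_ml_h": seg.peak_rate_ml_h,
        "solution": seg.solution,
        "stock_mg_per_ml": seg.stock_mg_ml,
    }
    if seg.sin2_origin_h is not None:
        d["sin2_origin_h"] = seg.sin2_origin_h
    if seg.sin2_period_h is not None:
        d["sin2_period_h"] = seg.sin2_period_h
    return d


def _segment_from_mapping(raw: Mapping[str, Any], reference_bsa: float) -> InfusionSegment:
    if "peak_rate_ml_h" in raw:
        peak = float(raw["peak_rate_ml_h"])
    elif "peak_rate_ml_per_m2_h" in raw:
        peak = float(raw["peak_rate_ml_per_m2_h"]) * reference_bsa
    else:
        raise ValueError("segment needs peak_rate_ml_h or peak_rate_ml_per_m2_h")
    start = raw.get("start_h", raw.get("start"))
    if isinstance(start, str):
        start = clock_to_hours(start)
    return InfusionSegment(
        start_h=float(start),
        duration_h=float(raw["duration_h"]),
        shape=str(raw["shape"]),
        peak_rate_ml_h=peak,
        solution=str(raw.get("solution", "drug")),
        stock_mg_ml=float(raw.get("stock_mg_per_ml", 0.0)),
        sin2_origin_h=(None if raw.get("sin2_origin_h") is None else float(raw["sin2_origin_h"])),
        sin2_period_h=(None if raw.get("sin2_period_h") is None else float(raw["sin2_period_h"])),
    )


def load_program_yaml(path: str | Path) -> PumpProgram:
    raw = yaml.safe_load(Path(path).read_text())
    bsa = float(raw.get("reference_bsa", DEFAULT_REFERENCE_BSA))
    segments = tuple(_segment_from_mapping(s, bsa) for s in raw["segments"])
    return PumpProgram(
        segments=segments,
        tube=_tube_from_mapping(raw.get("tube", {})),
        drug=raw.get("drug"),
        nominal_dose_mg=(None if raw.get("nominal_dose_mg") is None else float(raw["nominal_dose_mg"])),
        reference_bsa=bsa if "reference_bsa" in raw else None,
    )


def save_program_yaml(program: PumpProgram, path: str | Path) -> None:
    doc: dict[str, Any] = {
        "drug": program.drug,
        "tube": {"volume_ml": program.tube.volume_ml, "length_mm": program.tube.length_mm},
        "segments": [_segment_to_mapping(s) for s in program.segments],
    }
    if program.nominal_dose_mg is not None:
        doc["nominal_dose_mg"] = program.nominal_dose_mg
    if program.reference_bsa is not None:
        doc["reference_bsa"] = program.reference_bsa
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# --------------------------------------------------------------------------
# Delivery profile CSV
# --------------------------------------------------------------------------

def save_delivery_csv(profile: DeliveryProfile, path: str | Path) -> None:
    pd.DataFrame({
        "time_h": profile.times_h,
        "rate_mg_h": profile.rate_mg_h,
        "cumulative_mg": profile.cumulative_mg,
    }).to_csv(path, index=False)


def load_delivery_csv(path: str | Path) -> DeliveryProfile:
    df = pd.read_csv(path)
    for c in ("time_h", "rate_mg_h", "cumulative_mg"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c}")
    return DeliveryProfile(
        times_h=df["time_h"].to_numpy(dtype=float),
        rate_mg_h=df["rate_mg_h"].to_numpy(dtype=float),
        cumulative_mg=df["cumulative_mg"].to_numpy(dtype=float),
    )
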
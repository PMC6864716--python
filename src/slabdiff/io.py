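"""Measurement CSV format and run configuration.

Measurement files are plain UTF-8 CSV with the exact header

    scenario,time_s,position_mm,concentration_mg_per_L

one record per row, positions in millimetres externally (metres
internally).  Run configuration is a JSON document validated against a
strict schema (unknown keys rejected) with a ``schema_version`` field.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Literal, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .errors import ConfigurationError, DomainError
from .fitting import MeasurementSet
from .forward import Geometry1D

MEASUREMENT_COLUMNS = ["scenario", "time_s", "position_mm", "concentration_mg_per_L"]
SCENARIO_KINDS = {"inward", "outward", "internal"}
DAY_S = 86400.0


def read_measurements(path, geometry: Optional[Geometry1D] = None) -> MeasurementSet:
    """Read a measurement CSV into a MeasurementSet (positions mm -> m).

    The file must contain a single scenario kind.  Malformed rows are
    reported with their 1-based line number.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"measurement file not found: {path}")
    text = path.read_text(encoding="utf-8").strip()
    if not text:
        raise ConfigurationError(f"{path}: empty measurement file")
    lines = text.splitlines()
    header = [h.strip() for h in lines[0].split(",")]
    if header != MEASUREMENT_COLUMNS:
        raise ConfigurationError(
            f"{path}:1: bad header {lines[0]!r}, expected {','.join(MEASUREMENT_COLUMNS)}"
        )
    if len(lines) == 1:
        raise ConfigurationError(f"{path}: no data rows")

    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != 4:
            raise ConfigurationError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
        kind = parts[0]
        if kind not in SCENARIO_KINDS:
            raise ConfigurationError(f"{path}:{lineno}: unknown scenario {kind!r}")
        try:
            t, x_mm, c = float(parts[1]), float(parts[2]), float(parts[3])
        except ValueError as exc:
            raise ConfigurationError(f"{path}:{lineno}: unparseable number ({exc})") from None
        if t < 0:
            raise DomainError(f"{path}:{lineno}: negative time {t}")
        if c < 0:
            raise DomainError(f"{path}:{lineno}: negative concentration {c}")
        rows.append((kind, t, x_mm * 1e-3, c, lineno))

    kinds = {r[0] for r in rows}
    if len(kinds) > 1:
        raise ConfigurationError(f"{path}: mixed scenario kinds {sorted(kinds)}")
    df = pd.DataFrame(rows, columns=["scenario", "time_s", "position_m", "concentration", "line"])
    return MeasurementSet(kind=rows[0][0], geometry=geometry,
                          records=df[["time_s", "position_m", "concentration", "line"]].copy())


def write_measurements(mset: MeasurementSet, path) -> None:
    """Write a MeasurementSet as CSV (positions m -> mm, 12 significant digits)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(",".join(MEASUREMENT_COLUMNS) + "\n")
        for _, row in mset.records.iterrows():
            fh.write(
                f"{mset.kind},{row['time_s']:.12g},{row['position_m'] * 1e3:.12g},"
                f"{row['concentration']:.12g}\n"
            )


# ---------------------------------------------------------------------------
# Run configuration (strict JSON schema)
# ---------------------------------------------------------------------------


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_StrictModel):
    length_mm: float


class ScenarioConfig(_StrictModel):
    kind: Literal["inward", "outward", "internal"]
    D_m2_s: float
    n0_mg_L: Optional[float] = None
    C0_mg_L: Optional[float] = None
    # internal scenarios build their initial profile from knots (mm, mg/L)
    initial_knots_mm: Optional[List[float]] = None
    initial_knots_mg_L: Optional[List[float]] = None

    @model_validator(mode="after")
    def _check_kind_params(self):
        if self.kind == "inward" and self.n0_mg_L is None:
            raise ValueError("inward scenario requires n0_mg_L")
        if self.kind == "outward" and self.C0_mg_L is None:
            raise ValueError("outward scenario requires C0_mg_L")
        if self.kind == "internal" and (self.initial_knots_mm is None
                                        or self.initial_knots_mg_L is None):
            raise ValueError("internal scenario requires initial knots")
        return self


class SeriesSettings(_StrictModel):
    n_terms: int = 501
    tail_cutoff: float = 1e-15


class GridSettings(_StrictModel):
    n_cells: int = 200
    dt_s: Optional[float] = None


class FitSettings(_StrictModel):
    free: List[Literal["D", "n0", "C0"]] = ["D"]
    subset_labels: Optional[List[str]] = None


class DesignSettings(_StrictModel):
    D_m2_s: float
    length_mm: float
    soak_conc_n0_mg_L: float
    target_conc_c0_mg_L: float
    eps_mg_L: float


class CouplingSettings(_StrictModel):
    q_max_mg_L: float
    K_L_per_mg: float
    phi: float = 1.0


class SyntheticSettings(_StrictModel):
    positions_mm: Optional[List[float]] = None
    times_days: Optional[List[float]] = None
    noise_sd_mg_L: float = 0.0
    seed: int = 0
    coupling: Optional[CouplingSettings] = None


class LabcalcSettings(_StrictModel):
    gel_volume_L: float
    soak_conc_g_per_L: float
    carrier_mass_g: float
    weight_loss_loaded_pct: float
    weight_loss_blank_pct: float


class RunConfig(_StrictModel):
    """Top-level run configuration; sections are optional per subcommand."""

    schema_version: int = 1
    geometry: Optional[GeometryConfig] = None
    scenario: Optional[ScenarioConfig] = None
    series: SeriesSettings = SeriesSettings()
    grid: GridSettings = GridSettings()
    fit: FitSettings = FitSettings()
    design: Optional[DesignSettings] = None
    synthetic: SyntheticSettings = SyntheticSettings()
    labcalc: Optional[LabcalcSettings] = None

    @model_validator(mode="after")
    def _check_version(self):
        if self.schema_version != 1:
            raise ValueError(f"unsupported schema_version {self.schema_version}")
        return self


def load_config(path) -> RunConfig:
    """Load and validate a JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ConfigurationError(f"{path}: invalid JSON ({exc})") from None
    try:
        return RunConfig.model_validate(payload)
    except ValidationError as exc:
        raise ConfigurationError(f"{path}: {exc}") from None
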
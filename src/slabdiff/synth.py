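"""Synthetic measurement generator emulating the cuvette diffusion experiments.

Produces (time, position, concentration) datasets with the statistical
structure the inverse analysis assumes: forward-model concentrations on
the five-position sampling layout (labels A-E from the open face
inward), additive homoscedastic Gaussian measurement noise, and an
optional equilibrium Langmuir adsorption term that biases the apparent
signal at low concentration — the mechanism that makes the fitted D an
*apparent* diffusion coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError
from .fitting import MeasurementSet
from .forward import (
    DiffusionScenario,
    SeriesConfig,
    inward_concentration,
    outward_concentration,
)
from .pde import BoundarySpec, GridConfig, solve_diffusion

DAY_S = 86400.0

#: Cuvette sampling positions (mm from the open face) and their labels.
DEFAULT_POSITIONS_MM = (3.5, 7.0, 10.5, 14.0, 17.5)
POSITION_LABELS = ("A", "B", "C", "D", "E")


@dataclass(frozen=True)
class SamplingGrid:
    """Where and when concentrations are read off the gel.

    Defaults mirror the cuvette layout: five equispaced optical windows
    at 3.5-17.5 mm, read once a day for a week.
    """

    positions_m: tuple = tuple(p * 1e-3 for p in DEFAULT_POSITIONS_MM)
    times_s: tuple = tuple(d * DAY_S for d in range(1, 8))
    labels: tuple = POSITION_LABELS

    def __post_init__(self) -> None:
        if len(self.positions_m) == 0 or len(self.times_s) == 0:
            raise ConfigurationError("sampling grid must be non-empty")
        if len(self.labels) != len(self.positions_m):
            raise ConfigurationError("one label per position required")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian measurement noise, mg/L, with a reproducibility seed."""

    sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigurationError("noise sd must be >= 0")


@dataclass(frozen=True)
class LangmuirCoupling:
    """Equilibrium Langmuir adsorption folded into the apparent signal.

    The optical measurement cannot distinguish pore-liquid drug from
    drug adsorbed on the gel skeleton, so the apparent concentration is
    c_free + phi * q_max * K * c_free / (1 + K * c_free): ``q_max`` is
    the saturating adsorbed contribution (mg/L-equivalent), ``K`` the
    affinity (L/mg) and ``phi`` in [0, 1] the weight with which the
    adsorbed pool enters the signal.
    """

    q_max: float
    K: float
    phi: float = 1.0

    def __post_init__(self) -> None:
        if self.q_max < 0 or self.K < 0:
            raise ConfigurationError("q_max and K must be >= 0")
        if not (0 <= self.phi <= 1):
            raise ConfigurationError("phi must be in [0, 1]")


def apply_adsorption_coupling(c_free, coupling: LangmuirCoupling):
    """Apparent concentration from free concentration under Langmuir coupling.

    Monotone increasing in c_free; the adsorbed excess saturates at
    phi * q_max; identity when phi = 0 or q_max = 0.
    """
    c = np.asarray(c_free, dtype=float)
    if np.any(c < 0):
        raise DomainError("free concentration must be >= 0")
    out = c + coupling.phi * coupling.q_max * coupling.K * c / (1.0 + coupling.K * c)
    return out if np.ndim(c_free) else float(out)


def generate_dataset(scenario: DiffusionScenario, grid: SamplingGrid = SamplingGrid(),
                     noise: NoiseSpec = NoiseSpec(),
                     coupling: Optional[LangmuirCoupling] = None,
                     series_cfg: SeriesConfig = SeriesConfig(),
                     pde_grid: GridConfig = GridConfig()) -> MeasurementSet:
    """Simulate one cuvette experiment and return it as a MeasurementSet.

    The forward model (series solution for inward/outward, Crank-Nicolson
    for internal) is evaluated at every grid point; the Langmuir coupling
    is applied to the clean signal, then seeded Gaussian noise is added
    and the result clamped at zero.  Ground-truth parameters are recorded
    in the metadata so recovery can be checked downstream.
    """
    L = scenario.geometry.length_m
    xs = np.asarray(grid.positions_m, dtype=float)
    if np.any(xs < 0) or np.any(xs > L):
        raise DomainError("sampling positions outside the gel")
    ts = np.asarray(grid.times_s, dtype=float)

    if scenario.kind == "inward":
        clean = np.stack([inward_concentration(xs, t, scenario, series_cfg) for t in ts])
    elif scenario.kind == "outward":
        clean = np.stack([outward_concentration(xs, t, scenario, series_cfg) for t in ts])
    else:
        traj = solve_diffusion(scenario.initial_profile, BoundarySpec.sealed(), scenario.D,
                               scenario.geometry, np.sort(ts), pde_grid)
        clean = np.stack([traj.at(t, xs) for t in ts])

    if coupling is not None:
        clean = apply_adsorption_coupling(clean, coupling)

    rng = np.random.default_rng(noise.seed)
    values = clean + rng.normal(0.0, noise.sd, size=clean.shape) if noise.sd > 0 else clean
    values = np.clip(values, 0.0, None)

    records = pd.DataFrame({
        "time_s": np.repeat(ts, xs.size),
        "position_m": np.tile(xs, ts.size),
        "concentration": values.ravel(),
        "label": np.tile(np.asarray(grid.labels, dtype=object), ts.size),
    })
    metadata = {
        "true_D": scenario.D,
        "kind": scenario.kind,
        "length_m": L,
        "n0": scenario.n0,
        "C0": scenario.C0,
        "noise_sd": noise.sd,
        "seed": noise.seed,
        "coupling": None if coupling is None else {
            "q_max": coupling.q_max, "K": coupling.K, "phi": coupling.phi,
        },
    }
    return MeasurementSet(
        kind=scenario.kind, records=records, geometry=scenario.geometry,
        known_n0=scenario.n0, known_C0=scenario.C0, metadata=metadata,
    )
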
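"""Drug-loading protocol design: soak time t1 and homogenization time t2.

The two-step loading protocol: (1) soak the gel in a bath at
concentration n0 until the length-averaged load reaches the target c0 —
the soak time t1 solves mean_inward_concentration(t1) = c0, which is
well-posed because the mean load increases strictly from 0 to n0;
(2) seal the gel and let the graded profile relax under zero-flux
boundaries until the spread max(c) - min(c) falls below a uniformity
tolerance eps (mg/L) — the homogenization time t2.  True uniformity
takes infinite time; eps is the operational stopping criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigurationError, InfeasibleDesignError
from .forward import (
    ConcentrationProfile,
    DiffusionScenario,
    Geometry1D,
    SeriesConfig,
    inward_concentration,
    mean_inward_concentration,
)
from .pde import BoundarySpec, GridConfig, InitialProfile, solve_diffusion

log = logging.getLogger(__name__)

#: Grid used to materialise analytic profiles for reporting.
_N_PROFILE = 201


@dataclass(frozen=True)
class DesignSpec:
    """Inputs to the loading design: transport, geometry and targets."""

    D: float
    geometry: Geometry1D
    soak_conc_n0: float
    target_conc_c0: float
    eps: float

    def __post_init__(self) -> None:
        if not (self.D > 0):
            raise ConfigurationError("D must be positive")
        if not (self.eps > 0):
            raise ConfigurationError("eps must be positive")
        if not (0 < self.target_conc_c0):
            raise ConfigurationError("target concentration must be positive")
        if self.soak_conc_n0 <= 0:
            raise ConfigurationError("soak concentration must be positive")


@dataclass(frozen=True)
class DesignResult:
    t1_s: float
    t2_s: float
    profile_after_soak: ConcentrationProfile
    final_profile: ConcentrationProfile
    achieved_mean: float
    achieved_spread: float


def compute_soak_time(spec: DesignSpec, series_cfg: SeriesConfig = SeriesConfig()
                      ) -> tuple[float, ConcentrationProfile]:
    """Solve mean load(t1) = c0 by bisection on the strictly increasing series mean.

    Returns (t1 seconds, inward concentration profile at t1).
    Raises InfeasibleDesignError when c0 >= n0 (the mean load approaches
    n0 only asymptotically).
    """
    n0, c0 = spec.soak_conc_n0, spec.target_conc_c0
    if c0 >= n0:
        raise InfeasibleDesignError(
            f"target mean {c0} mg/L unreachable: soak bath is {n0} mg/L"
        )
    scenario = DiffusionScenario(spec.geometry, "inward", spec.D, n0=n0)

    def f(t: float) -> float:
        return mean_inward_concentration(t, scenario, series_cfg) - c0

    t_scale = spec.geometry.length_m**2 / spec.D
    t_hi = t_scale
    while f(t_hi) < 0:
        t_hi *= 2.0
    t_lo = t_hi * 1e-12
    while f(t_lo) > 0:
        t_lo *= 1e-3
    t1 = brentq(f, t_lo, t_hi, rtol=1e-9, maxiter=200)
    xs = np.linspace(0.0, spec.geometry.length_m, _N_PROFILE)
    profile = ConcentrationProfile(xs, inward_concentration(xs, t1, scenario, series_cfg), t1)
    return float(t1), profile


def compute_homogenization_time(profile: InitialProfile, D: float, geometry: Geometry1D,
                                eps: float, grid: GridConfig = GridConfig()
                                ) -> tuple[float, ConcentrationProfile]:
    """Earliest time at which the sealed-gel spread max-min drops below eps.

    The profile is marched under Neumann-Neumann boundaries; the spread
    is non-increasing, so the first step crossing eps brackets t2.  The
    march uses a step no coarser than 0.5% of the elapsed time, giving
    t2 to about 1% relative precision; if the crossing happens within the
    first 200 steps the march is repeated with a finer step.
    """
    if not (eps > 0):
        raise ConfigurationError("eps must be positive")
    L = geometry.length_m
    n_nodes = grid.n_cells + 1
    xs = np.linspace(0.0, L, n_nodes)
    c0_vals = profile(xs)
    if float(np.max(c0_vals) - np.min(c0_vals)) < eps:
        return 0.0, ConcentrationProfile(xs, c0_vals, 0.0)

    dx = L / grid.n_cells
    dt_cap = grid.dt_s if grid.dt_s is not None else grid.max_diffusion_number * dx**2 / D

    def march(dt: float, t_max: float):
        """Step until spread < eps or t_max; return (t_cross or None, profile)."""
        times = np.arange(dt, t_max + 0.5 * dt, dt)
        traj = solve_diffusion(profile, BoundarySpec.sealed(), D, geometry, times, grid)
        spreads = traj.values.max(axis=1) - traj.values.min(axis=1)
        hit = np.nonzero(spreads < eps)[0]
        if hit.size == 0:
            return None, None
        i = int(hit[0])
        return float(times[i]), ConcentrationProfile(xs, traj.values[i], float(times[i]))

    t_scale = L**2 / (np.pi**2 * D)  # slowest-mode decay time
    dt = dt_cap
    t_max = 4.0 * t_scale
    while True:
        t2, final = march(dt, t_max)
        if t2 is not None:
            break
        t_max *= 4.0
    # refine if the crossing fell too early for 1% step resolution
    while dt / t2 > 0.005:
        dt = max(t2 / 400.0, 1e-9 * t_scale)
        t2, final = march(dt, 2.0 * t2)
        if t2 is None:  # cannot happen: spread is non-increasing
            raise RuntimeError("homogenization refinement lost the crossing")
    return t2, final


def design_protocol(spec: DesignSpec, series_cfg: SeriesConfig = SeriesConfig(),
                    grid: GridConfig = GridConfig()) -> DesignResult:
    """Full two-step loading design: soak to the target mean, then equilibrate.

    The soak-end profile is passed to the homogenization step as the
    analytic series evaluation (not a re-simulated copy) so the second
    step starts from the exact inward solution.
    """
    t1, soak_profile = compute_soak_time(spec, series_cfg)
    scenario = DiffusionScenario(spec.geometry, "inward", spec.D, n0=spec.soak_conc_n0)

    initial = InitialProfile.from_callable(
        lambda x: inward_concentration(x, t1, scenario, series_cfg), spec.geometry.length_m
    )
    t2, final = compute_homogenization_time(initial, spec.D, spec.geometry, spec.eps, grid)
    achieved_mean = final.mean
    if abs(achieved_mean - spec.target_conc_c0) > 1e-3 * spec.target_conc_c0:
        log.warning("final mean %.6g deviates from target %.6g", achieved_mean,
                    spec.target_conc_c0)
    return DesignResult(
        t1_s=t1, t2_s=t2,
        profile_after_soak=soak_profile, final_profile=final,
        achieved_mean=achieved_mean, achieved_spread=final.spread,
    )
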
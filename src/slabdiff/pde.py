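"""Crank-Nicolson solver for 1D diffusion with mixed boundary conditions.

Handles the sealed-gel ("internal") redistribution scenario, whose
arbitrary initial profile has no closed-form solution, and doubles as an
independent numerical oracle for the series solutions.

The scheme is Crank-Nicolson finite differences on a uniform node grid
x_i = i*dx, i = 0..N.  Zero-flux (Neumann) ends use mirror ghost nodes,
keeping second-order accuracy; Dirichlet nodes are pinned exactly.  The
scheme is unconditionally stable and, with Neumann-Neumann ends,
conserves the trapezoidal mass integral to round-off.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.linalg import solve_banded

from .errors import ConfigurationError, DomainError, SolverError
from .forward import ConcentrationProfile, Geometry1D

log = logging.getLogger(__name__)


class InitialProfile:
    """Initial concentration distribution F(x) on [0, L], mg/L.

    Wraps either an analytic callable or a monotone shape-preserving
    piecewise-cubic (PCHIP) interpolant through measured knots.  Outside
    the knot range the interpolant is extended as a constant, which gives
    the zero end-slopes required for compatibility with sealed (Neumann)
    boundaries.
    """

    def __init__(self, func: Callable[[np.ndarray], np.ndarray], length_m: float):
        self._func = func
        self.length_m = length_m

    @classmethod
    def from_callable(cls, func: Callable, length_m: float) -> "InitialProfile":
        return cls(func, length_m)

    @classmethod
    def from_knots(cls, positions_m: Sequence[float], values: Sequence[float],
                   length_m: float) -> "InitialProfile":
        x = np.asarray(positions_m, dtype=float)
        c = np.asarray(values, dtype=float)
        if np.any(c < 0):
            raise DomainError("knot concentrations must be non-negative")
        if np.any(x < 0) or np.any(x > length_m):
            raise DomainError("knots outside [0, L]")
        interp = PchipInterpolator(x, c, extrapolate=False)
        lo, hi = x[0], x[-1]
        clo, chi = c[0], c[-1]

        def f(xq: np.ndarray) -> np.ndarray:
            xq = np.asarray(xq, dtype=float)
            out = interp(np.clip(xq, lo, hi))
            out = np.where(xq < lo, clo, out)
            return np.where(xq > hi, chi, out)

        return cls(f, length_m)

    @classmethod
    def from_profile(cls, profile: ConcentrationProfile, length_m: float) -> "InitialProfile":
        return cls.from_knots(profile.positions, profile.values, length_m)

    def __call__(self, x) -> np.ndarray:
        vals = np.asarray(self._func(np.atleast_1d(np.asarray(x, dtype=float))), dtype=float)
        if not np.all(np.isfinite(vals)):
            raise DomainError("initial profile evaluated to non-finite values")
        return vals


@dataclass(frozen=True)
class BoundaryCondition:
    kind: str  # "dirichlet" | "neumann_zero"
    value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind == "dirichlet":
            if self.value is None:
                raise ConfigurationError("dirichlet boundary needs a value")
        elif self.kind == "neumann_zero":
            if self.value is not None:
                raise ConfigurationError("neumann_zero boundary takes no value")
        else:
            raise ConfigurationError(f"unknown boundary kind {self.kind!r}")


@dataclass(frozen=True)
class BoundarySpec:
    """Boundary conditions at x = 0 (left) and x = L (right)."""

    left: BoundaryCondition
    right: BoundaryCondition

    @classmethod
    def inward(cls, n0: float) -> "BoundarySpec":
        """Bath at the open face, sealed far end."""
        return cls(BoundaryCondition("dirichlet", n0), BoundaryCondition("neumann_zero"))

    @classmethod
    def outward(cls) -> "BoundarySpec":
        """Pure-solvent sink at the open face, sealed far end."""
        return cls(BoundaryCondition("dirichlet", 0.0), BoundaryCondition("neumann_zero"))

    @classmethod
    def sealed(cls) -> "BoundarySpec":
        """Zero flux at both ends (internal redistribution)."""
        return cls(BoundaryCondition("neumann_zero"), BoundaryCondition("neumann_zero"))


@dataclass(frozen=True)
class GridConfig:
    """Spatial/temporal resolution of the Crank-Nicolson solver.

    ``n_cells`` spatial intervals (n_cells + 1 nodes).  ``dt_s`` caps the
    time step; when None it is chosen so that the diffusion number
    D*dt/dx^2 <= ``max_diffusion_number`` (stability is unconditional;
    the cap keeps temporal error commensurate with spatial error).
    """

    n_cells: int = 200
    dt_s: Optional[float] = None
    max_diffusion_number: float = 2.0

    def __post_init__(self) -> None:
        if self.n_cells < 10:
            raise ConfigurationError("n_cells must be >= 10")
        if self.dt_s is not None and self.dt_s <= 0:
            raise ConfigurationError("dt_s must be positive")


@dataclass(frozen=True)
class Trajectory:
    """Numerical solution on a shared grid: values[i, j] = c(positions[j], times[i])."""

    times: np.ndarray
    positions: np.ndarray
    values: np.ndarray

    def profile(self, i: int) -> ConcentrationProfile:
        return ConcentrationProfile(self.positions, self.values[i], float(self.times[i]))

    @property
    def profiles(self) -> list[ConcentrationProfile]:
        return [self.profile(i) for i in range(len(self.times))]

    def at(self, time: float, positions) -> np.ndarray:
        """Linear interpolation in x at one stored time."""
        idx = np.nonzero(np.isclose(self.times, time, rtol=1e-12, atol=1e-9))[0]
        if idx.size == 0:
            raise DomainError(f"time {time} not in trajectory")
        return np.interp(np.asarray(positions, dtype=float), self.positions, self.values[idx[0]])


def _build_operator(n_nodes: int, r: float, bc: BoundarySpec):
    """Banded LHS/RHS matrices for one Crank-Nicolson step of size dt.

    Rows implement (I - r/2 T) c_new = (I + r/2 T) c_old with T the
    discrete Laplacian scaled by dx^2; Neumann rows use the mirrored
    ghost node (T row = [-2, 2]), Dirichlet rows are identities.
    """
    lower = np.full(n_nodes - 1, -0.5 * r)
    diag = np.full(n_nodes, 1.0 + r)
    upper = np.full(n_nodes - 1, -0.5 * r)
    rl = np.full(n_nodes - 1, 0.5 * r)
    rd = np.full(n_nodes, 1.0 - r)
    ru = np.full(n_nodes - 1, 0.5 * r)

    if bc.left.kind == "neumann_zero":
        upper[0] = -r
        ru[0] = r
    else:
        diag[0], upper[0] = 1.0, 0.0
        rd[0], ru[0] = 1.0, 0.0
    if bc.right.kind == "neumann_zero":
        lower[-1] = -r
        rl[-1] = r
    else:
        diag[-1], lower[-1] = 1.0, 0.0
        rd[-1], rl[-1] = 1.0, 0.0

    ab = np.zeros((3, n_nodes))
    ab[0, 1:] = upper
    ab[1, :] = diag
    ab[2, :-1] = lower
    return ab, (rl, rd, ru)


def _apply_rhs(c: np.ndarray, rhs) -> np.ndarray:
    rl, rd, ru = rhs
    out = rd * c
    out[:-1] += ru * c[1:]
    out[1:] += rl * c[:-1]
    return out


def solve_diffusion(initial: InitialProfile, bc: BoundarySpec, D: float,
                    geometry: Geometry1D, times, grid: GridConfig = GridConfig()) -> Trajectory:
    """Evolve an initial profile under 1D diffusion and return c on the grid.

    Parameters
    ----------
    times : array-like
        Strictly increasing output times (s), times[0] >= 0.  The solver
        substeps between outputs so every requested time is hit exactly.
    """
    if not (D > 0):
        raise ConfigurationError(f"D must be positive, got {D}")
    times = np.asarray(times, dtype=float)
    if times.size == 0 or np.any(np.diff(times) <= 0) or times[0] < 0:
        raise DomainError("times must be non-empty, sorted strictly increasing, >= 0")

    L = geometry.length_m
    n_nodes = grid.n_cells + 1
    x = np.linspace(0.0, L, n_nodes)
    dx = L / grid.n_cells
    dt_cap = grid.dt_s if grid.dt_s is not None else grid.max_diffusion_number * dx**2 / D

    c = initial(x).astype(float).copy()
    for side, node in ((bc.left, 0), (bc.right, -1)):
        if side.kind == "dirichlet":
            if abs(c[node] - side.value) > 1e-9 * max(1.0, abs(side.value)):
                log.warning(
                    "initial profile (%g) incompatible with dirichlet value (%g) at node %d; "
                    "boundary value takes precedence", c[node], side.value, node,
                )
            c[node] = side.value

    out = np.empty((times.size, n_nodes))
    t_now = 0.0
    for i, t_target in enumerate(times):
        span = t_target - t_now
        if span > 0:
            k = max(1, math.ceil(span / dt_cap))
            dt = span / k
            r = D * dt / dx**2
            ab, rhs = _build_operator(n_nodes, r, bc)
            for _ in range(k):
                b = _apply_rhs(c, rhs)
                if bc.left.kind == "dirichlet":
                    b[0] = bc.left.value
                if bc.right.kind == "dirichlet":
                    b[-1] = bc.right.value
                c = solve_banded((1, 1), ab, b)
            t_now = t_target
        if not np.all(np.isfinite(c)):
            raise SolverError(f"non-finite solution at t = {t_target}")
        out[i] = c
    return Trajectory(times=times, positions=x, values=out)


def total_mass(profile: ConcentrationProfile) -> float:
    """Areal drug mass: trapezoidal integral of c over x, mg*m/L."""
    return float(np.trapezoid(profile.values, profile.positions))
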
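"""Closed-form series solutions of 1D Fickian diffusion in a gel slab.

The gel occupies 0 <= x <= L along the diffusion axis. x = 0 is the open
face in contact with the bath and x = L is the sealed end (zero flux).
Three transport scenarios are supported:

* ``inward``  — drug enters from a bath held at constant concentration n0
  (Dirichlet at x = 0), starting from an empty gel:

  .. math::

     c(x,t) = n_0\\Big[1 - \\sum_{n \\ge 0}
        \\frac{2}{(n+\\tfrac12)\\pi}
        e^{-((n+\\tfrac12)\\pi/L)^2 D t}
        \\sin\\frac{(n+\\tfrac12)\\pi x}{L}\\Big]

* ``outward`` — drug leaves into a pure-solvent sink (Dirichlet 0 at
  x = 0) from a uniformly loaded gel at C0; its series is the exact
  complement of the inward one.

* ``internal`` — sealed redistribution, handled numerically in
  :mod:`slabdiff.pde`.

All concentrations are mg/L, positions metres, times seconds, and D m²/s.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from scipy.special import erfc

from .errors import ConfigurationError, DomainError

log = logging.getLogger(__name__)

ScenarioKind = Literal["inward", "outward", "internal"]

#: Dimensionless time Dt/L^2 above which the short-time (semi-infinite
#: medium) closed form is considered degraded.
SHORTTIME_LIMIT = 0.1


@dataclass(frozen=True)
class Geometry1D:
    """Gel geometry along the diffusion axis.

    Parameters
    ----------
    length_m : float
        Gel length L in metres (cuvette gels here are 20-34 mm).
    """

    length_m: float

    def __post_init__(self) -> None:
        if not (self.length_m > 0):
            raise DomainError(f"gel length must be positive, got {self.length_m}")

    @classmethod
    def from_mm(cls, length_mm: float) -> "Geometry1D":
        return cls(length_m=length_mm * 1e-3)


@dataclass(frozen=True)
class SeriesConfig:
    """Truncation policy for the Fourier series.

    ``n_terms`` sums indices n = 0 ... n_terms-1 (default 501, i.e.
    n = 0...500).  Terms whose exponential damping factor falls below
    ``tail_cutoff`` are dropped; at the default 1e-15 this changes
    nothing numerically but speeds up late-time evaluation.
    """

    n_terms: int = 501
    tail_cutoff: float = 1e-15

    def __post_init__(self) -> None:
        if self.n_terms < 1:
            raise ConfigurationError("n_terms must be >= 1")
        if self.tail_cutoff < 0:
            raise ConfigurationError("tail_cutoff must be >= 0")


@dataclass(frozen=True)
class DiffusionScenario:
    """One diffusion experiment: geometry, boundary kind and parameters.

    Exactly the concentration parameter required by ``kind`` must be set:
    ``n0`` (bath concentration, mg/L) for inward, ``C0`` (uniform initial
    gel concentration, mg/L) for outward, and ``initial_profile`` (an
    ``InitialProfile`` from :mod:`slabdiff.pde`) for internal.
    """

    geometry: Geometry1D
    kind: ScenarioKind
    D: float
    n0: Optional[float] = None
    C0: Optional[float] = None
    initial_profile: object = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (self.D > 0):
            raise ConfigurationError(f"D must be positive, got {self.D}")
        if self.kind == "inward":
            if self.n0 is None or self.n0 < 0:
                raise ConfigurationError("inward scenario requires n0 >= 0")
            if self.C0 is not None or self.initial_profile is not None:
                raise ConfigurationError("inward scenario takes only n0")
        elif self.kind == "outward":
            if self.C0 is None or self.C0 < 0:
                raise ConfigurationError("outward scenario requires C0 >= 0")
            if self.n0 is not None or self.initial_profile is not None:
                raise ConfigurationError("outward scenario takes only C0")
        elif self.kind == "internal":
            if self.initial_profile is None:
                raise ConfigurationError("internal scenario requires initial_profile")
            if self.n0 is not None or self.C0 is not None:
                raise ConfigurationError("internal scenario takes only initial_profile")
        else:
            raise ConfigurationError(f"unknown scenario kind {self.kind!r}")


@dataclass(frozen=True)
class ConcentrationProfile:
    """Concentration c(x) at a single time on the gel domain."""

    positions: np.ndarray
    values: np.ndarray
    time: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        val = np.asarray(self.values, dtype=float)
        if pos.shape != val.shape:
            raise DomainError("positions and values must have equal length")
        if pos.size >= 2 and not np.all(np.diff(pos) > 0):
            raise DomainError("positions must be strictly increasing")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "values", val)

    @property
    def spread(self) -> float:
        """Max - min concentration over the profile (uniformity measure)."""
        return float(np.max(self.values) - np.min(self.values))

    @property
    def mean(self) -> float:
        """Length-averaged concentration by trapezoidal quadrature."""
        L = self.positions[-1] - self.positions[0]
        return float(np.trapezoid(self.values, self.positions) / L)


def _check_domain(x: np.ndarray, t: float, L: float) -> None:
    if t < 0:
        raise DomainError(f"time must be >= 0, got {t}")
    if np.any(x < 0) or np.any(x > L):
        raise DomainError(f"position outside [0, {L}]")


def _series_sum(x: np.ndarray, t: float, D: float, L: float, cfg: SeriesConfig) -> np.ndarray:
    """S(x,t) = sum_n 2/((n+1/2)pi) exp(-((n+1/2)pi/L)^2 D t) sin((n+1/2)pi x / L).

    The inward solution is n0*(1 - S), the outward solution C0*S.
    Only call with t > 0 (t = 0 is special-cased by the callers).
    """
    n = np.arange(cfg.n_terms)
    lam = (n + 0.5) * np.pi / L
    damp = np.exp(-(lam**2) * D * t)
    keep = damp >= cfg.tail_cutoff
    if not np.any(keep):
        return np.zeros_like(x)
    lam, damp, n = lam[keep], damp[keep], n[keep]
    coeff = 2.0 / ((n + 0.5) * np.pi)
    # (n_pos, n_terms) outer product of sines
    return np.sin(np.outer(x, lam)) @ (coeff * damp)


def _clamp(values: np.ndarray, lo: float, hi: float, what: str) -> np.ndarray:
    out = np.clip(values, lo, hi)
    n_clamped = int(np.sum(out != values))
    if n_clamped:
        log.debug("clamped %d %s value(s) to [%g, %g]", n_clamped, what, lo, hi)
    return out


def inward_concentration(x, t: float, scenario: DiffusionScenario,
                         cfg: SeriesConfig = SeriesConfig()):
    """Concentration c(x, t) for the inward (bath-loading) scenario, mg/L.

    At t = 0 the analytic initial condition is returned (0 inside the gel,
    n0 at the open face) rather than the truncated series, which would
    show Gibbs oscillations.  Output is clamped to [0, n0].
    """
    if scenario.kind != "inward":
        raise ConfigurationError(f"expected inward scenario, got {scenario.kind}")
    L, n0 = scenario.geometry.length_m, scenario.n0
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    _check_domain(xs, t, L)
    if t == 0:
        vals = np.where(xs == 0.0, n0, 0.0)
    else:
        vals = n0 * (1.0 - _series_sum(xs, t, scenario.D, L, cfg))
        vals = _clamp(vals, 0.0, n0, "inward")
        # Dirichlet face is exact: every sine term vanishes at x = 0
        vals = np.where(xs == 0.0, n0, vals)
    return vals if np.ndim(x) else float(vals[0])


def outward_concentration(x, t: float, scenario: DiffusionScenario,
                          cfg: SeriesConfig = SeriesConfig()):
    """Concentration c(x, t) for the outward (release into sink) scenario, mg/L.

    At t = 0 returns C0 for x > 0 and 0 at the open face.  Output clamped
    to [0, C0].
    """
    if scenario.kind != "outward":
        raise ConfigurationError(f"expected outward scenario, got {scenario.kind}")
    L, C0 = scenario.geometry.length_m, scenario.C0
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    _check_domain(xs, t, L)
    if t == 0:
        vals = np.where(xs == 0.0, 0.0, C0)
    else:
        vals = C0 * _series_sum(xs, t, scenario.D, L, cfg)
        vals = _clamp(vals, 0.0, C0, "outward")
        vals = np.where(xs == 0.0, 0.0, vals)
    return vals if np.ndim(x) else float(vals[0])


def mean_inward_concentration(t: float, scenario: DiffusionScenario,
                              cfg: SeriesConfig = SeriesConfig()) -> float:
    """Length-averaged gel concentration (1/L) * integral of c dx for inward loading.

    Term-wise integration of the inward series gives

        mean(t) = n0 * [1 - sum_n 2/((n+1/2)^2 pi^2) exp(-((n+1/2)pi/L)^2 D t)]

    which increases strictly from 0 (empty gel) to n0 (equilibrium with the
    bath).  This is the quantity the soak-time design step inverts.
    """
    if scenario.kind != "inward":
        raise ConfigurationError(f"expected inward scenario, got {scenario.kind}")
    if t < 0:
        raise DomainError(f"time must be >= 0, got {t}")
    if t == 0:
        return 0.0
    L, n0 = scenario.geometry.length_m, scenario.n0
    # At very short times the truncated series floors at ~n0 * 2/(pi^2 n_terms)
    # instead of vanishing; there the semi-infinite-medium mean
    # (2/L) * sqrt(D t / pi) * n0 is exact to O(exp(-L^2/4Dt)).
    if scenario.D * t / L**2 <= 1e-5:
        return float(n0 * 2.0 * np.sqrt(scenario.D * t / np.pi) / L)
    n = np.arange(cfg.n_terms)
    lam = (n + 0.5) * np.pi / L
    damp = np.exp(-(lam**2) * scenario.D * t)
    keep = damp >= cfg.tail_cutoff
    coeff = 2.0 / (((n + 0.5) ** 2) * np.pi**2)
    total = float(np.sum(coeff[keep] * damp[keep]))
    return float(np.clip(n0 * (1.0 - total), 0.0, n0))


def shorttime_inward_closed_form(x, t: float, scenario: DiffusionScenario):
    """Semi-infinite-medium closed form n0*erfc(x / (2*sqrt(D t))).

    Valid while the diffusion front has not felt the sealed end, i.e.
    Dt/L^2 < 0.1; a warning is emitted beyond that.  Intended as an
    independent oracle for the series solution, not for production use.
    """
    if scenario.kind != "inward":
        raise ConfigurationError(f"expected inward scenario, got {scenario.kind}")
    L, n0, D = scenario.geometry.length_m, scenario.n0, scenario.D
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    _check_domain(xs, t, L)
    tau = D * t / L**2
    if tau >= SHORTTIME_LIMIT:
        warnings.warn(
            f"short-time approximation degraded: Dt/L^2 = {tau:.3g} >= {SHORTTIME_LIMIT}",
            stacklevel=2,
        )
    if t == 0:
        vals = np.where(xs == 0.0, n0, 0.0)
    else:
        vals = n0 * erfc(xs / (2.0 * np.sqrt(D * t)))
    return vals if np.ndim(x) else float(vals[0])
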
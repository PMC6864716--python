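"""Least-squares estimation of the apparent diffusion coefficient.

Fits the scenario forward model (series solution for inward/outward,
Crank-Nicolson solution for internal) to (time, position, concentration)
records by ordinary least squares.  The headline estimate is D; the
boundary concentration n0 (inward) or initial concentration C0 (outward)
can optionally be freed, which is the standard diagnostic for an
interface effect depressing the concentration at the open face.

The estimator is deterministic: a bounded golden-section search on
log10(D) for D-only fits, refined by Nelder-Mead when concentration
parameters are freed.  No random initialisation is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .errors import ConfigurationError, DomainError, IdentifiabilityError
from .forward import (
    DiffusionScenario,
    Geometry1D,
    SeriesConfig,
    inward_concentration,
    outward_concentration,
)
from .pde import GridConfig, solve_diffusion, BoundarySpec

#: log10(D / m^2 s^-1) search window for the apparent diffusion coefficient.
LOG10_D_BOUNDS = (-13.0, -7.0)


@dataclass
class MeasurementSet:
    """Observed (time, position, concentration) records for one experiment.

    ``records`` columns: ``time_s``, ``position_m``, ``concentration``
    (mg/L) and optionally ``label`` (position letters A-E, A nearest the
    open face).
    """

    kind: str
    records: pd.DataFrame
    geometry: Optional[Geometry1D] = None
    known_n0: Optional[float] = None
    known_C0: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        req = {"time_s", "position_m", "concentration"}
        missing = req - set(self.records.columns)
        if missing:
            raise ConfigurationError(f"records missing columns {sorted(missing)}")
        df = self.records
        if (df["time_s"] < 0).any():
            raise DomainError("negative times in measurement set")
        if (df["concentration"] < 0).any():
            raise DomainError("negative concentrations in measurement set")
        if self.geometry is not None and (
            (df["position_m"] < 0).any() or (df["position_m"] > self.geometry.length_m).any()
        ):
            raise DomainError("positions outside [0, L]")

    @property
    def n_obs(self) -> int:
        return len(self.records)

    def subset(self, labels: Iterable[str]) -> "MeasurementSet":
        """Restrict to records at the given position labels."""
        labels = list(labels)
        if not labels:
            raise DomainError("empty position subset")
        if "label" not in self.records.columns:
            raise ConfigurationError("measurement set has no position labels")
        sub = self.records[self.records["label"].isin(labels)].reset_index(drop=True)
        if sub.empty:
            raise DomainError(f"no records at labels {labels}")
        return replace(self, records=sub)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a least-squares diffusion fit."""

    D_hat: float
    free_params: dict
    r_squared: float
    residuals: np.ndarray  # measured - fitted, mg/L
    fitted: np.ndarray
    n_obs: int
    converged: bool
    diagnostics: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ResidualTable:
    """Per-position residual diagnostics at one sampling time.

    ``percentage`` is 100 * residual / measured, NaN where measured = 0;
    ``percentage_1dp`` is the same rounded to one decimal for reporting.
    """

    time_s: float
    table: pd.DataFrame


def r_squared(measured, fitted) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot about the mean."""
    m = np.asarray(measured, dtype=float)
    f = np.asarray(fitted, dtype=float)
    if m.size == 0 or m.shape != f.shape:
        raise DomainError("measured and fitted must be equal-length and non-empty")
    ss_tot = float(np.sum((m - m.mean()) ** 2))
    if ss_tot == 0.0:
        raise DomainError("R^2 undefined: all measured values identical")
    return 1.0 - float(np.sum((m - f) ** 2)) / ss_tot


def _model_values(kind: str, D: float, conc_param: float, geometry: Geometry1D,
                  times: np.ndarray, x_obs: np.ndarray,
                  t_obs: np.ndarray, series_cfg: SeriesConfig,
                  initial_profile, grid: GridConfig) -> np.ndarray:
    """Forward model at the observation points for candidate parameters."""
    if kind == "inward":
        sc = DiffusionScenario(geometry, "inward", D, n0=conc_param)
        return np.concatenate(
            [inward_concentration(x_obs[t_obs == t], t, sc, series_cfg) for t in times]
        )
    if kind == "outward":
        sc = DiffusionScenario(geometry, "outward", D, C0=conc_param)
        return np.concatenate(
            [outward_concentration(x_obs[t_obs == t], t, sc, series_cfg) for t in times]
        )
    # internal: numerical solution from the supplied initial profile
    traj = solve_diffusion(initial_profile, BoundarySpec.sealed(), D, geometry, times, grid)
    return np.concatenate([traj.at(t, x_obs[t_obs == t]) for t in times])


def fit_diffusion_coefficient(data: MeasurementSet, scenario_template: DiffusionScenario,
                              free: Iterable[str] = ("D",),
                              series_cfg: SeriesConfig = SeriesConfig(),
                              grid: GridConfig = GridConfig(),
                              _relaxed: bool = False) -> FitResult:
    """Estimate D (and optionally n0 or C0) by ordinary least squares.

    ``scenario_template`` supplies the geometry, the scenario kind, the
    fixed concentration parameters and (for internal) the initial
    profile; its D is ignored.  ``free`` is {"D"} optionally extended by
    "n0" (inward) or "C0" (outward).
    """
    free = set(free)
    kind = scenario_template.kind
    if data.kind != kind:
        raise ConfigurationError(f"data kind {data.kind!r} != template kind {kind!r}")
    if "D" not in free:
        raise ConfigurationError("D must always be a free parameter")
    extra = free - {"D", "n0", "C0"}
    if extra:
        raise ConfigurationError(f"unknown free parameters {sorted(extra)}")
    if "n0" in free and kind != "inward":
        raise ConfigurationError("n0 can be freed only for inward fits")
    if "C0" in free and kind != "outward":
        raise ConfigurationError("C0 can be freed only for outward fits")
    if kind == "internal" and scenario_template.initial_profile is None:
        raise ConfigurationError("internal fit requires an initial profile")

    df = data.records.sort_values(["time_s", "position_m"], kind="mergesort").reset_index(drop=True)
    t_obs = df["time_s"].to_numpy(dtype=float)
    x_obs = df["position_m"].to_numpy(dtype=float)
    c_obs = df["concentration"].to_numpy(dtype=float)
    n_times = len(np.unique(t_obs))
    n_pos = len(np.unique(np.round(x_obs, 12)))
    if _relaxed:
        if n_times == 1 and n_pos == 1:
            raise IdentifiabilityError("single position at a single time cannot constrain D")
    elif n_times < 2 or n_pos < 2:
        raise IdentifiabilityError(
            f"need >= 2 distinct times and positions, got {n_times} time(s), {n_pos} position(s)"
        )

    geometry = scenario_template.geometry
    times = np.unique(t_obs)

    # Fixed concentration parameter (scale of the forward model).
    if kind == "inward":
        conc_fixed = scenario_template.n0
    elif kind == "outward":
        conc_fixed = scenario_template.C0
    else:
        conc_fixed = None
    free_conc = ("n0" in free) or ("C0" in free)

    def predict(log10_D: float, conc: Optional[float]) -> np.ndarray:
        return _model_values(kind, 10.0**log10_D, conc, geometry, times,
                             x_obs, t_obs, series_cfg, scenario_template.initial_profile, grid)

    def sse_d_only(log10_D: float) -> float:
        r = c_obs - predict(log10_D, conc_fixed)
        return float(r @ r)

    res1 = minimize_scalar(sse_d_only, bounds=LOG10_D_BOUNDS, method="bounded",
                           options={"xatol": 1e-7})
    log10_D = float(res1.x)
    diagnostics = {"stage1_nfev": int(res1.nfev), "stage1_sse": float(res1.fun)}
    converged = bool(res1.success)
    free_params: dict = {}

    if free_conc:
        pname = "n0" if kind == "inward" else "C0"
        conc_start = conc_fixed if conc_fixed is not None else float(np.max(c_obs))

        def sse_joint(p: np.ndarray) -> float:
            lD, conc = p
            if conc <= 0 or not (LOG10_D_BOUNDS[0] <= lD <= LOG10_D_BOUNDS[1]):
                return 1e30
            r = c_obs - predict(lD, conc)
            return float(r @ r)

        res2 = minimize(sse_joint, x0=np.array([log10_D, conc_start]), method="Nelder-Mead",
                        options={"xatol": 1e-9, "fatol": 1e-14, "maxiter": 2000})
        log10_D, conc_hat = float(res2.x[0]), float(res2.x[1])
        free_params[pname] = conc_hat
        converged = converged and bool(res2.success)
        diagnostics["stage2_nfev"] = int(res2.nfev)
        fitted = predict(log10_D, conc_hat)
    else:
        fitted = predict(log10_D, conc_fixed)

    D_hat = 10.0**log10_D
    free_params["D"] = D_hat
    resid = c_obs - fitted
    r2 = r_squared(c_obs, fitted)
    fit_df = df.assign(fitted=fitted, residual=resid)
    return FitResult(
        D_hat=D_hat, free_params=free_params, r_squared=r2,
        residuals=resid, fitted=fitted, n_obs=len(c_obs),
        converged=converged,
        diagnostics={**diagnostics, "records": fit_df},
    )


def subset_fit(data: MeasurementSet, positions: Iterable[str],
               scenario_template: DiffusionScenario,
               series_cfg: SeriesConfig = SeriesConfig(),
               grid: GridConfig = GridConfig()) -> FitResult:
    """Fit restricted to the given position labels (e.g. high-C {"A","B"}
    vs low-C {"D","E"}): the standard probe for adsorption-induced
    concentration dependence of the apparent D."""
    sub = data.subset(positions)
    return fit_diffusion_coefficient(sub, scenario_template, free=("D",),
                                     series_cfg=series_cfg, grid=grid, _relaxed=True)


def residual_table(data: MeasurementSet, fit: FitResult, at_time: float) -> ResidualTable:
    """Per-position residuals (measured - fitted) at one sampling time.

    Percentage is 100 * residual / measured; positive residuals mean the
    measurement sits above the fitted surface (the adsorption signature
    at the far, low-concentration positions).
    """
    rec = fit.diagnostics.get("records")
    if rec is None:
        raise ConfigurationError("fit result carries no per-record table")
    rows = rec[np.isclose(rec["time_s"], at_time, rtol=1e-12, atol=1e-9)]
    if rows.empty:
        raise DomainError(f"time {at_time} not present in the fitted data")
    meas = rows["concentration"].to_numpy(dtype=float)
    resid = rows["residual"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(meas != 0, 100.0 * resid / meas, np.nan)
    table = pd.DataFrame({
        "position_m": rows["position_m"].to_numpy(dtype=float),
        "measured": meas,
        "fitted": rows["fitted"].to_numpy(dtype=float),
        "residual": resid,
        "percentage": pct,
        "percentage_1dp": np.round(pct, 1),
    })
    if "label" in rows.columns:
        table.insert(0, "label", rows["label"].to_numpy())
    return ResidualTable(time_s=float(at_time), table=table.reset_index(drop=True))
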
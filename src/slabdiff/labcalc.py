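"""Scalar laboratory calculations: Beer-Lambert conversion and loading arithmetic.

Covers the bench-side numbers around the diffusion experiments: the
absorbance-to-concentration calibration (strong drug absorption at
306 nm, blank-cuvette zeroing, 1 cm optical path folded into the slope)
and the drug-loading bookkeeping from thermogravimetric (TG) weight
losses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

from .errors import ConfigurationError, DomainError

log = logging.getLogger(__name__)

TGConvention = Literal["difference", "blank_corrected"]


@dataclass(frozen=True)
class AbsorbanceCalibration:
    """Linear Beer-Lambert calibration at the drug's absorption peak.

    ``slope`` is mg/L per absorbance unit (path length included);
    ``zero_offset`` is the blank-cuvette absorbance subtracted before
    conversion.
    """

    slope: float
    zero_offset: float = 0.0

    def __post_init__(self) -> None:
        if not (self.slope > 0):
            raise ConfigurationError(f"calibration slope must be positive, got {self.slope}")


@dataclass(frozen=True)
class LoadingReport:
    """Drug-loading bookkeeping: expected vs TG-measured mass."""

    expected_mass_g: float
    actual_mass_g: float
    loading_fraction: float
    inputs: dict

    def __post_init__(self) -> None:
        if self.expected_mass_g < 0 or self.actual_mass_g < 0:
            raise DomainError("masses must be non-negative")
        if not (0 <= self.loading_fraction <= 1):
            raise DomainError("loading fraction must be in [0, 1]")


def concentration_from_absorbance(absorbance: float, calib: AbsorbanceCalibration) -> float:
    """Convert absorbance to concentration (mg/L): slope * (A - zero_offset).

    Readings below the blank are clamped to zero with a warning.
    """
    delta = absorbance - calib.zero_offset
    if delta < 0:
        log.warning("absorbance %.4g below blank %.4g; clamping concentration to 0",
                    absorbance, calib.zero_offset)
        return 0.0
    return calib.slope * delta


def expected_load_mass(gel_volume_L: float, soak_conc_g_per_L: float) -> float:
    """Nominal drug load: gel pore volume times soak concentration, grams."""
    if gel_volume_L < 0 or soak_conc_g_per_L < 0:
        raise DomainError("volume and concentration must be non-negative")
    return gel_volume_L * soak_conc_g_per_L


def actual_load_mass(carrier_mass_g: float, loading_fraction: float) -> float:
    """TG-measured drug load: carrier mass times loading fraction, grams."""
    if carrier_mass_g < 0:
        raise DomainError("carrier mass must be non-negative")
    if not (0 <= loading_fraction <= 1):
        raise DomainError("loading fraction must be in [0, 1]")
    return carrier_mass_g * loading_fraction


def loading_fraction_from_tg(weight_loss_loaded_pct: float, weight_loss_blank_pct: float,
                             convention: TGConvention = "difference") -> float:
    """Drug mass fraction from TG weight losses over the decomposition window.

    ``difference``: (loaded - blank)/100, attributing the blank's loss
    (surface water) to both samples additively. ``blank_corrected``:
    (loaded - blank)/(100 - blank), treating the blank loss as a fraction
    of the non-drug matter. The two conventions differ at the third
    decimal for typical inputs; reports should print both.
    """
    if not (0 <= weight_loss_blank_pct <= weight_loss_loaded_pct <= 100):
        raise DomainError("need 0 <= blank <= loaded <= 100 (percent)")
    if convention == "difference":
        return (weight_loss_loaded_pct - weight_loss_blank_pct) / 100.0
    if convention == "blank_corrected":
        return (weight_loss_loaded_pct - weight_loss_blank_pct) / (100.0 - weight_loss_blank_pct)
    raise ConfigurationError(f"unknown TG convention {convention!r}")


def loading_report(gel_volume_L: float, soak_conc_g_per_L: float, carrier_mass_g: float,
                   weight_loss_loaded_pct: float, weight_loss_blank_pct: float,
                   convention: TGConvention = "difference") -> LoadingReport:
    """Assemble the expected-vs-actual loading comparison.

    Masses are reported at full precision; round to two decimals for
    bench-style presentation.
    """
    frac = loading_fraction_from_tg(weight_loss_loaded_pct, weight_loss_blank_pct, convention)
    return LoadingReport(
        expected_mass_g=expected_load_mass(gel_volume_L, soak_conc_g_per_L),
        actual_mass_g=actual_load_mass(carrier_mass_g, frac),
        loading_fraction=frac,
        inputs={
            "gel_volume_L": gel_volume_L,
            "soak_conc_g_per_L": soak_conc_g_per_L,
            "carrier_mass_g": carrier_mass_g,
            "weight_loss_loaded_pct": weight_loss_loaded_pct,
            "weight_loss_blank_pct": weight_loss_blank_pct,
            "convention": convention,
        },
    )
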
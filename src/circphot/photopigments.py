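"""Photopigment templates, pre-retinal lens filtering and photometry.

The five human photopigments are modelled as Gaussian-in-wavelength
sensitivity templates with a common full width at half maximum of 80 nm,
peaking at the classical λmax values: rhodopsin (rod) 498 nm, melanopsin
(ipRGC) 480 nm, and the L/M/S cone opsins at 565/535/430 nm.  Templates are
retinal sensitivities; corneal sensitivities are obtained by multiplying in
the crystalline-lens transmittance and re-normalizing to unit peak.

Photometric weighting uses the bundled CIE luminous-efficiency tables:
scotopic V'(λ) (peak 1 at 507 nm, 1700 lm·W⁻¹) and photopic V(λ) (peak 1 at
555 nm, 683 lm·W⁻¹).  The lens table is a synthetic analytic stand-in for a
standard-observer crystalline-lens transmittance curve (optical density
decaying exponentially with wavelength); see ``data/``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

from .spectra import (
    DEFAULT_GRID,
    SpectralDistribution,
    ValidationError,
    WavelengthGrid,
)

__all__ = [
    "PhotopigmentSpec",
    "LensModel",
    "DEFAULT_PIGMENTS",
    "pigment_template",
    "lens_transmittance",
    "corneal_sensitivity",
    "scotopic_illuminance",
    "photopic_illuminance",
    "SCOTOPIC_LM_PER_W",
    "PHOTOPIC_LM_PER_W",
]

SCOTOPIC_LM_PER_W = 1700.0
PHOTOPIC_LM_PER_W = 683.0

PIGMENT_NAMES = ("rod", "mel", "L", "M", "S")


@dataclass(frozen=True)
class PhotopigmentSpec:
    """One photoreceptor class: peak wavelength and template bandwidth."""

    name: str
    lambda_max: float
    half_bandwidth: float = 80.0

    def __post_init__(self) -> None:
        if self.name not in PIGMENT_NAMES:
            raise ValidationError(
                f"unknown pigment {self.name!r}; expected one of {PIGMENT_NAMES}"
            )
        if self.half_bandwidth <= 0:
            raise ValidationError("half_bandwidth must be positive")


#: Default pigment set: classical human λmax values, 80 nm half-bandwidth.
DEFAULT_PIGMENTS: tuple[PhotopigmentSpec, ...] = (
    PhotopigmentSpec("rod", 498.0),
    PhotopigmentSpec("mel", 480.0),
    PhotopigmentSpec("L", 565.0),
    PhotopigmentSpec("M", 535.0),
    PhotopigmentSpec("S", 430.0),
)


@dataclass(frozen=True)
class LensModel:
    """Crystalline-lens transmittance (dimensionless, 0-1) on a grid."""

    transmittance: SpectralDistribution
    source: str

    def __post_init__(self) -> None:
        t = self.transmittance.values
        if np.any(t < 0) or np.any(t > 1 + 1e-12):
            raise ValidationError("lens transmittance must lie in [0, 1]")


def pigment_template(
    spec: PhotopigmentSpec, grid: WavelengthGrid = DEFAULT_GRID
) -> SpectralDistribution:
    """Peak-normalized Gaussian opsin template with FWHM = half_bandwidth."""
    if not (grid.start_nm <= spec.lambda_max <= grid.stop_nm):
        raise ValidationError(
            f"lambda_max {spec.lambda_max} nm outside grid "
            f"[{grid.start_nm}, {grid.stop_nm}]"
        )
    wl = grid.wavelengths
    values = np.exp(
        -4.0 * math.log(2.0) * ((wl - spec.lambda_max) / spec.half_bandwidth) ** 2
    )
    return SpectralDistribution(grid, values, kind="sensitivity")


@lru_cache(maxsize=None)
def _load_table(name: str) -> tuple[np.ndarray, np.ndarray]:
    text = resources.files("circphot.data").joinpath(name).read_text()
    wl, val = [], []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        a, b = line.split(",")
        wl.append(float(a))
        val.append(float(b))
    return np.asarray(wl), np.asarray(val)


def _table_on_grid(name: str, grid: WavelengthGrid) -> np.ndarray:
    wl, val = _load_table(name)
    return np.interp(grid.wavelengths, wl, val)


def lens_transmittance(
    grid: WavelengthGrid = DEFAULT_GRID, source: str = "bundled-table"
) -> LensModel:
    """Lens transmittance model: the bundled table, or unity for ablation."""
    if source == "unity":
        values = np.ones(grid.n_points)
    elif source == "bundled-table":
        values = np.clip(
            _table_on_grid("lens_transmittance_synthetic.csv", grid), 0.0, 1.0
        )
    else:
        raise ValidationError(f"unknown lens source {source!r}")
    return LensModel(
        SpectralDistribution(grid, values, kind="sensitivity"), source=source
    )


def corneal_sensitivity(
    template: SpectralDistribution, lens: LensModel
) -> SpectralDistribution:
    """Pre-retinally filtered sensitivity: template × lens, re-peaked to 1.

    If the sampled maximum is attained at several grid points the first
    (shortest-wavelength) index is the nominal peak.
    """
    if template.grid != lens.transmittance.grid:
        raise ValidationError("template and lens must share one grid")
    values = template.values * lens.transmittance.values
    peak = values.max()
    if peak <= 0:
        raise ValidationError("cannot normalize an all-zero sensitivity")
    return SpectralDistribution(
        template.grid, values / peak, kind="sensitivity"
    )


def _illuminance(spd: SpectralDistribution, table: str, lm_per_w: float) -> float:
    if spd.kind != "irradiance":
        raise ValidationError("illuminance requires an irradiance-kind SPD")
    weight = SpectralDistribution(
        spd.grid, _table_on_grid(table, spd.grid), kind="sensitivity"
    )
    return lm_per_w * spd.weighted_integral(weight)


def scotopic_illuminance(spd: SpectralDistribution) -> float:
    """Scotopic illuminance in lx: 1700 × ∫ V'(λ) E(λ) dλ."""
    return _illuminance(spd, "scotopic_luminous_efficiency.csv", SCOTOPIC_LM_PER_W)


def photopic_illuminance(spd: SpectralDistribution) -> float:
    """Photopic illuminance in lx: 683 × ∫ V(λ) E(λ) dλ."""
    return _illuminance(spd, "photopic_luminous_efficiency.csv", PHOTOPIC_LM_PER_W)


def scotopic_efficiency(grid: WavelengthGrid = DEFAULT_GRID) -> np.ndarray:
    """The bundled V'(λ) values sampled on ``grid`` (helper for criteria)."""
    return _table_on_grid("scotopic_luminous_efficiency.csv", grid)
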
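"""Spectral-sensitivity curves at a fixed criterion level, and curve metrics.

An action-spectrum-style curve is built by presenting, at every wavelength
of the evaluation span, a monochromatic line scaled so its *scotopic*
illuminance equals the criterion level (default 300 scotopic lx — the level
at which rod shunting controls the circuit threshold), computing the
circadian drive, and dividing by the line's corneal irradiance.  The
resulting per-irradiance sensitivity is peak-normalized.  The
``melanopsin_only`` variant runs the identical pipeline with the circuit
reduced to the intrinsic ipRGC response, and serves as the reference
against which the short-wavelength enhancement, the 470–500 nm reduction
and the ~500 nm discontinuity ("notch") are measured.

Because excitations are linear in the stimulus and a monochromatic line
excites each class by exactly ``sensitivity × power``, the curve is
evaluated from a precomputed table of corneal sensitivities; this is
algebraically identical to running the full per-stimulus pipeline at every
wavelength (a property the test suite checks directly).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .circuit import (
    CircuitParams,
    circadian_response,
    corneal_sensitivities,
    params_hash,
)
from .photopigments import (
    DEFAULT_PIGMENTS,
    LensModel,
    PhotopigmentSpec,
    SCOTOPIC_LM_PER_W,
    scotopic_efficiency,
)
from .spectra import (
    DEFAULT_GRID,
    SpectralDistribution,
    ValidationError,
    WavelengthGrid,
    mix,
)

__all__ = [
    "MetricUndefinedError",
    "SensitivityCurve",
    "MonochromaticConditions",
    "mono_conditions",
    "spectral_sensitivity_curve",
    "fwhm",
    "fwhm_of_samples",
    "notch_metrics",
    "subadditivity_index",
    "write_curve",
    "write_metrics",
]

VARIANTS = ("full", "melanopsin_only")

#: Fig.-2-style notch window: reduced-sensitivity band short of the cross-point.
NOTCH_WINDOW_NM = (470.0, 500.0)


class MetricUndefinedError(ValueError):
    """Raised when a curve metric is undefined for the given input."""


@dataclass(frozen=True)
class SensitivityCurve:
    """Normalized model sensitivity vs wavelength at one criterion level.

    ``values`` peak at 1; ``scale`` is the absolute per-irradiance
    sensitivity at the peak, so ``values * scale`` recovers the common
    (unnormalized) scale on which curves from different variants are
    directly comparable.
    """

    grid: WavelengthGrid
    values: np.ndarray
    branch_labels: np.ndarray
    criterion_scotopic_lux: float
    variant: str
    scale: float
    excluded_nm: tuple[float, ...] = ()
    parameter_hash: str = ""

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValidationError(f"unknown curve variant {self.variant!r}")
        if self.values.size and not np.isclose(self.values.max(), 1.0):
            raise ValidationError("curve values must be peak-normalized")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths

    @property
    def absolute_values(self) -> np.ndarray:
        return self.values * self.scale

    def normalized(self) -> "SensitivityCurve":
        """Re-normalize to peak 1 (idempotent by construction)."""
        peak = self.values.max()
        return replace(self, values=self.values / peak, scale=self.scale * peak)

    def branch_switch_nm(self) -> float | None:
        """Wavelength of the first yellow-branch point, if any."""
        yellow = np.flatnonzero(self.branch_labels == "yellow")
        return float(self.wavelengths[yellow[0]]) if yellow.size else None


@dataclass(frozen=True)
class MonochromaticConditions:
    """Precomputed criterion-matched monochromatic stimulus table.

    For each evaluation wavelength: the line power reaching the criterion
    scotopic illuminance and the corneal sensitivities of the five
    photoreceptor classes.  Wavelengths where V'(λ) = 0 on the grid cannot
    reach a scotopic criterion and are excluded (recorded, never
    interpolated over).
    """

    grid: WavelengthGrid
    power: np.ndarray
    sens: Mapping[str, np.ndarray]
    criterion: float
    excluded_nm: tuple[float, ...]

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths

    def per_irradiance_response(
        self, params: CircuitParams, variant: str = "full"
    ) -> np.ndarray:
        """Absolute sensitivity: circadian drive per unit corneal irradiance."""
        if variant not in VARIANTS:
            raise ValidationError(f"unknown curve variant {variant!r}")
        p = self.power
        x = {name: s * p for name, s in self.sens.items()}
        if variant == "melanopsin_only":
            return x["mel"] / p
        v_ach = x["L"] + x["M"]
        b_y = x["S"] - params.k * v_ach
        x_rod_eff = x["rod"] / (1.0 + params.a3 * v_ach)
        shunt = params.a2 * -np.expm1(-x_rod_eff / params.rod_sat)
        blue = x["mel"] + params.a1 * b_y - shunt
        response = np.where(b_y > 0, np.maximum(0.0, blue), x["mel"])
        return response / p

    def branch_labels(self, params: CircuitParams) -> np.ndarray:
        b_y = self.sens["S"] * self.power - params.k * (
            self.sens["L"] * self.power + self.sens["M"] * self.power
        )
        return np.where(b_y > 0, "blue", "yellow")


def mono_conditions(
    criterion: float = 300.0,
    pigments: Sequence[PhotopigmentSpec] = DEFAULT_PIGMENTS,
    lens: LensModel | None = None,
    grid: WavelengthGrid = DEFAULT_GRID,
    eval_start_nm: float = 400.0,
    eval_stop_nm: float = 650.0,
) -> MonochromaticConditions:
    """Build the criterion-matched monochromatic table over the eval span."""
    if criterion <= 0:
        raise ValidationError("criterion must be positive")
    i0 = grid.index_of(eval_start_nm)
    i1 = grid.index_of(eval_stop_nm)
    eval_grid = WavelengthGrid(eval_start_nm, eval_stop_nm, grid.step_nm)
    v_prime = scotopic_efficiency(grid)[i0 : i1 + 1]
    keep = v_prime > 0
    excluded = tuple(float(w) for w in eval_grid.wavelengths[~keep])
    if excluded:
        # Shrinking the span is only safe when the dead points are at the
        # edges; interior V'=0 points would silently distort the curve.
        raise ValidationError(
            f"V'(λ) vanishes on the grid at {excluded}; cannot reach a "
            "scotopic criterion there — narrow the evaluation span"
        )
    power = criterion / (SCOTOPIC_LM_PER_W * v_prime)
    full_sens = corneal_sensitivities(pigments, lens, grid)
    sens = {name: sd.values[i0 : i1 + 1] for name, sd in full_sens.items()}
    return MonochromaticConditions(
        grid=eval_grid,
        power=power,
        sens=sens,
        criterion=criterion,
        excluded_nm=excluded,
    )


def spectral_sensitivity_curve(
    params: CircuitParams,
    criterion: float = 300.0,
    variant: str = "full",
    pigments: Sequence[PhotopigmentSpec] = DEFAULT_PIGMENTS,
    lens: LensModel | None = None,
    grid: WavelengthGrid = DEFAULT_GRID,
    eval_start_nm: float = 400.0,
    eval_stop_nm: float = 650.0,
) -> SensitivityCurve:
    """Predicted monochromatic spectral sensitivity at the criterion level."""
    cond = mono_conditions(criterion, pigments, lens, grid, eval_start_nm, eval_stop_nm)
    absolute = cond.per_irradiance_response(params, variant)
    scale = float(absolute.max())
    if scale <= 0:
        raise MetricUndefinedError("circuit response is zero at every wavelength")
    return SensitivityCurve(
        grid=cond.grid,
        values=absolute / scale,
        branch_labels=cond.branch_labels(params),
        criterion_scotopic_lux=criterion,
        variant=variant,
        scale=scale,
        excluded_nm=cond.excluded_nm,
        parameter_hash=params_hash(params),
    )


def fwhm_of_samples(wavelengths: np.ndarray, values: np.ndarray) -> float:
    """Full width at half maximum from sampled values.

    The half level is half the global sampled maximum (first index on
    ties); the outermost crossings on each flank are located by linear
    interpolation between the bracketing grid points.  Curves that do not
    fall below the half level on both flanks have no defined width.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise MetricUndefinedError("too few samples for a width")
    peak = values.max()
    if peak <= 0:
        raise MetricUndefinedError("curve has no positive maximum")
    half = 0.5 * peak

    def crossing(i: int, j: int) -> float:
        # linear interpolation of the half level between samples i and j
        return float(
            wavelengths[i]
            + (half - values[i]) * (wavelengths[j] - wavelengths[i]) / (values[j] - values[i])
        )

    up = np.flatnonzero((values[:-1] < half) & (values[1:] >= half))
    down = np.flatnonzero((values[:-1] >= half) & (values[1:] < half))
    if up.size == 0 or values[0] >= half:
        raise MetricUndefinedError("no half-maximum crossing on the short flank")
    if down.size == 0 or values[-1] >= half:
        raise MetricUndefinedError("no half-maximum crossing on the long flank")
    left = crossing(up[0], up[0] + 1)
    right = crossing(down[-1], down[-1] + 1)
    return right - left


def fwhm(curve: "SensitivityCurve | SpectralDistribution") -> float:
    """FWHM (nm) of a sensitivity curve or spectral distribution."""
    if isinstance(curve, SpectralDistribution):
        return fwhm_of_samples(curve.wavelengths, curve.values)
    return fwhm_of_samples(curve.wavelengths, curve.values)


def notch_metrics(
    full: SensitivityCurve, reference: SensitivityCurve
) -> tuple[float, float]:
    """Locate and size the ~500 nm notch against a reference curve.

    Returns ``(notch_wavelength_nm, notch_depth)``.  The notch wavelength
    is the right edge of the largest single-step jump in the full curve —
    at the branch discontinuity this is the first yellow-branch grid point.
    Depth is the largest shortfall of the full curve below the reference
    over 470–500 nm, with both curves on the common absolute scale divided
    by the reference peak; identical curves give depth 0.
    """
    if full.grid != reference.grid:
        raise ValidationError("curves must share one grid")
    if full.criterion_scotopic_lux != reference.criterion_scotopic_lux:
        raise ValidationError("curves must share one criterion level")
    jumps = np.abs(np.diff(full.values))
    j = int(np.argmax(jumps))
    notch_wavelength = float(full.wavelengths[j + 1])

    ref_abs = reference.absolute_values
    full_abs = full.absolute_values
    common = ref_abs.max()
    lo, hi = NOTCH_WINDOW_NM
    window = (full.wavelengths >= lo) & (full.wavelengths <= hi)
    depth = float(max(0.0, np.max((ref_abs[window] - full_abs[window]) / common)))
    return notch_wavelength, depth


def subadditivity_index(
    spd_a: SpectralDistribution,
    spd_b: SpectralDistribution,
    params: CircuitParams,
    pigments: Sequence[PhotopigmentSpec] = DEFAULT_PIGMENTS,
    lens: LensModel | None = None,
) -> float:
    """response(A+B) / (response(A) + response(B)).

    1 for perfectly additive pairs; < 1 when opponent differencing makes
    the mixture drive the circuit less than its parts — the signature of
    polychromatic subadditivity.
    """
    r_a = circadian_response(spd_a, params, pigments, lens)
    r_b = circadian_response(spd_b, params, pigments, lens)
    if r_a + r_b == 0:
        raise MetricUndefinedError("both component responses are zero")
    r_mix = circadian_response(mix([spd_a, spd_b], [1.0, 1.0]), params, pigments, lens)
    return r_mix / (r_a + r_b)


def write_curve(path, curve: SensitivityCurve) -> None:
    """Curve CSV: ``#`` metadata lines then ``wavelength_nm,value`` rows."""
    switch = curve.branch_switch_nm()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# variant: {curve.variant}\n")
        fh.write(f"# criterion_scotopic_lux: {curve.criterion_scotopic_lux:.9g}\n")
        fh.write(f"# branch_switch_nm: {'none' if switch is None else f'{switch:.9g}'}\n")
        fh.write(f"# peak_absolute_sensitivity: {curve.scale:.9g}\n")
        fh.write(f"# params_hash: {curve.parameter_hash}\n")
        if curve.excluded_nm:
            fh.write(f"# excluded_nm: {','.join(f'{w:g}' for w in curve.excluded_nm)}\n")
        fh.write("wavelength_nm,value\n")
        for w, v in zip(curve.wavelengths, curve.values):
            fh.write(f"{w:.9g},{v:.9g}\n")


def write_metrics(path, full: SensitivityCurve, reference: SensitivityCurve) -> None:
    """Metrics JSON accompanying a full/reference curve pair."""
    notch_wavelength, notch_depth = notch_metrics(full, reference)
    payload = {
        "fwhm_nm": fwhm(full),
        "notch_wavelength_nm": notch_wavelength,
        "notch_depth": notch_depth,
        "criterion_scotopic_lux": full.criterion_scotopic_lux,
        "params_hash": full.parameter_hash,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
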
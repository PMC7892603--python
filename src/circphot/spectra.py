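"""Wavelength grids, spectral distributions, file I/O and synthetic spectra.

Every quantity in the package is carried as a :class:`SpectralDistribution`
on a shared :class:`WavelengthGrid` — corneal spectral irradiance in
W·m⁻²·nm⁻¹ for stimuli, dimensionless values for sensitivity functions.
All other modules resample to one grid at entry; the default grid is
380–780 nm at 1 nm, which covers the support of all five photopigment
templates and resolves the ~500 nm discontinuity in circadian spectral
sensitivity.

Quadrature convention
---------------------
Continuous spectra are integrated by the trapezoid rule; generated line
spectra (single nonzero bin) carry a ``rectangle`` tag and are integrated
as ``sum(values) * step`` so that a monochromatic line of nominal power P
always integrates to exactly P, including lines placed at a grid endpoint.
For any line strictly inside the grid the two rules agree.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "SPDFormatError",
    "WavelengthGrid",
    "SpectralDistribution",
    "DEFAULT_GRID",
    "read_spd",
    "write_spd",
    "make_monochromatic",
    "make_gaussian_band",
    "make_blackbody",
    "mix",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class SPDFormatError(ValidationError):
    """Raised when an SPD file cannot be parsed; names the offending line."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid in nanometres, inclusive of both ends."""

    start_nm: float = 380.0
    stop_nm: float = 780.0
    step_nm: float = 1.0

    def __post_init__(self) -> None:
        if not self.start_nm < self.stop_nm:
            raise ValidationError("grid requires start_nm < stop_nm")
        if self.step_nm <= 0:
            raise ValidationError("grid requires step_nm > 0")
        span = (self.stop_nm - self.start_nm) / self.step_nm
        if abs(span - round(span)) > 1e-9:
            raise ValidationError(
                "grid span (stop_nm - start_nm) must be an integer multiple of step_nm"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_points)

    def index_of(self, wavelength_nm: float) -> int:
        """Index of an on-grid wavelength; off-grid requests fail loudly.

        No silent snapping: a request half a step off the grid would corrupt
        any test that localizes spectral features to one grid bin.
        """
        pos = (wavelength_nm - self.start_nm) / self.step_nm
        if pos < -1e-9 or pos > self.n_points - 1 + 1e-9:
            raise ValidationError(
                f"wavelength {wavelength_nm} nm outside grid "
                f"[{self.start_nm}, {self.stop_nm}]"
            )
        if abs(pos - round(pos)) > 1e-9:
            raise ValidationError(
                f"wavelength {wavelength_nm} nm is not on the {self.step_nm} nm grid"
            )
        return int(round(pos))


DEFAULT_GRID = WavelengthGrid(380.0, 780.0, 1.0)


@dataclass(frozen=True)
class SpectralDistribution:
    """Nonnegative values indexed by wavelength on a common grid.

    ``kind`` is ``irradiance`` (W·m⁻²·nm⁻¹) for stimuli and ``sensitivity``
    (dimensionless) for weighting functions.  ``quadrature`` records the
    integration convention (see module docstring).
    """

    grid: WavelengthGrid
    values: np.ndarray
    kind: str = "irradiance"
    quadrature: str = "trapezoid"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.kind not in ("irradiance", "sensitivity"):
            raise ValidationError(f"unknown kind {self.kind!r}")
        if self.quadrature not in ("trapezoid", "rectangle"):
            raise ValidationError(f"unknown quadrature {self.quadrature!r}")
        if values.ndim != 1 or values.size != self.grid.n_points:
            raise ValidationError(
                f"values length {values.size} does not match grid "
                f"({self.grid.n_points} points)"
            )
        if not np.all(np.isfinite(values)):
            raise ValidationError("spectral values must be finite")
        if np.any(values < 0):
            raise ValidationError("spectral values must be nonnegative")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths

    def integral(self) -> float:
        """Total over wavelength under this distribution's quadrature rule."""
        if self.quadrature == "rectangle":
            return float(self.values.sum() * self.grid.step_nm)
        return float(np.trapezoid(self.values, dx=self.grid.step_nm))

    def weighted_integral(self, weight: "SpectralDistribution") -> float:
        """∫ w(λ)·v(λ) dλ with this distribution's quadrature rule."""
        if weight.grid != self.grid:
            raise ValidationError("weighted_integral requires matching grids")
        prod = self.values * weight.values
        if self.quadrature == "rectangle":
            return float(prod.sum() * self.grid.step_nm)
        return float(np.trapezoid(prod, dx=self.grid.step_nm))

    def value_at(self, wavelength_nm: float) -> float:
        return float(self.values[self.grid.index_of(wavelength_nm)])

    def scaled(self, factor: float) -> "SpectralDistribution":
        if factor < 0:
            raise ValidationError("scale factor must be nonnegative")
        return replace(self, values=self.values * factor)


def _parse_spd_rows(path) -> tuple[np.ndarray, np.ndarray]:
    wavelengths: list[float] = []
    irradiances: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise SPDFormatError(
                    f"{path}: line {lineno}: expected two columns, got {raw!r}"
                )
            try:
                w, e = float(parts[0]), float(parts[1])
            except ValueError:
                raise SPDFormatError(
                    f"{path}: line {lineno}: unparseable numbers in {raw!r}"
                ) from None
            if e < 0:
                raise ValidationError(
                    f"{path}: line {lineno}: negative irradiance {e}"
                )
            wavelengths.append(w)
            irradiances.append(e)
    return np.asarray(wavelengths), np.asarray(irradiances)


def read_spd(path, grid: WavelengthGrid = DEFAULT_GRID) -> SpectralDistribution:
    """Read a two-column (wavelength nm, irradiance W·m⁻²·nm⁻¹) text file.

    Columns may be comma- or whitespace-delimited; ``#`` starts a comment.
    Values are linearly interpolated onto ``grid``; grid points outside the
    file's wavelength range are zero-filled (and a warning is logged, since
    the missing region contributes nothing to any excitation integral).
    """
    wl, irr = _parse_spd_rows(path)
    if wl.size < 2:
        raise ValidationError(f"{path}: need at least 2 rows, got {wl.size}")
    if np.any(np.diff(wl) <= 0):
        raise ValidationError(f"{path}: wavelengths must be strictly increasing")
    target = grid.wavelengths
    values = np.interp(target, wl, irr, left=0.0, right=0.0)
    if wl[0] > grid.start_nm or wl[-1] < grid.stop_nm:
        logger.warning(
            "%s covers %g-%g nm; grid points outside were zero-filled",
            path, wl[0], wl[-1],
        )
    return SpectralDistribution(grid, values, kind="irradiance")


def write_spd(path, spd: SpectralDistribution, metadata: dict | None = None) -> None:
    """Write an SPD as two-column CSV with ``#`` metadata header lines."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# kind: {spd.kind}\n# quadrature: {spd.quadrature}\n")
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write("# wavelength_nm,value\n")
        for w, v in zip(spd.wavelengths, spd.values):
            fh.write(f"{w:.9g},{v:.9g}\n")


def make_monochromatic(
    lambda0_nm: float,
    power_w_m2: float,
    grid: WavelengthGrid = DEFAULT_GRID,
) -> SpectralDistribution:
    """Monochromatic line: one nonzero bin of height power/step at lambda0.

    Under the rectangle rule for line spectra the distribution integrates to
    exactly ``power_w_m2``.  ``lambda0_nm`` must lie on the grid.
    """
    if power_w_m2 < 0:
        raise ValidationError("power must be nonnegative")
    idx = grid.index_of(lambda0_nm)
    values = np.zeros(grid.n_points)
    values[idx] = power_w_m2 / grid.step_nm
    return SpectralDistribution(grid, values, kind="irradiance", quadrature="rectangle")


def make_gaussian_band(
    center_nm: float,
    fwhm_nm: float,
    power_w_m2: float,
    grid: WavelengthGrid = DEFAULT_GRID,
) -> SpectralDistribution:
    """Gaussian narrowband stimulus normalized to total power ``power_w_m2``.

    Emulates the narrowband (interference-filter) stimuli used in the
    melatonin-suppression action-spectrum experiments.
    """
    if fwhm_nm <= 0:
        raise ValidationError("fwhm must be positive")
    if power_w_m2 < 0:
        raise ValidationError("power must be nonnegative")
    wl = grid.wavelengths
    shape = np.exp(-4.0 * math.log(2.0) * ((wl - center_nm) / fwhm_nm) ** 2)
    total = np.trapezoid(shape, dx=grid.step_nm)
    if total <= 0:
        raise ValidationError("band has no support on the grid")
    return SpectralDistribution(grid, shape * (power_w_m2 / total), kind="irradiance")


# Wien displacement constant b in nm·K (lambda_max = b / T)
_WIEN_B_NM_K = 2.897772e6


def make_blackbody(
    temperature_k: float,
    grid: WavelengthGrid = DEFAULT_GRID,
    scale: float = 1.0,
) -> SpectralDistribution:
    """Planck blackbody spectrum, peak-normalized shape times ``scale``.

    The shape is the Planck spectral radiance B(λ, T) sampled on the grid and
    divided by its maximum, so ``scale`` sets the peak spectral irradiance in
    W·m⁻²·nm⁻¹.  Low temperatures give "warm" (long-wavelength-rich) spectra,
    high temperatures "cool" ones.
    """
    if temperature_k <= 0:
        raise ValidationError("temperature must be positive")
    if scale < 0:
        raise ValidationError("scale must be nonnegative")
    wl_m = grid.wavelengths * 1e-9
    h, c, kb = 6.62607015e-34, 2.99792458e8, 1.380649e-23
    with np.errstate(over="ignore"):
        radiance = 1.0 / (wl_m**5 * np.expm1(h * c / (wl_m * kb * temperature_k)))
    peak = radiance.max()
    values = (radiance / peak) * scale if peak > 0 else np.zeros_like(radiance)
    return SpectralDistribution(grid, values, kind="irradiance")


def mix(
    spds: Sequence[SpectralDistribution],
    weights: Iterable[float],
) -> SpectralDistribution:
    """Pointwise weighted sum of SPDs on a common grid.

    The mixture is tagged ``rectangle`` only if every component is a line
    spectrum; mixing a line into a continuous spectrum reverts to trapezoid
    integration (exact for interior lines).
    """
    spds = list(spds)
    weights = list(weights)
    if not spds:
        raise ValidationError("mix requires at least one SPD")
    if len(spds) != len(weights):
        raise ValidationError("one weight per SPD required")
    if any(w < 0 for w in weights):
        raise ValidationError("weights must be nonnegative")
    grid = spds[0].grid
    for spd in spds[1:]:
        if spd.grid != grid:
            raise ValidationError("all SPDs in a mixture must share one grid")
    values = np.zeros(grid.n_points)
    for spd, w in zip(spds, weights):
        values += w * spd.values
    quadrature = (
        "rectangle" if all(s.quadrature == "rectangle" for s in spds) else "trapezoid"
    )
    return SpectralDistribution(grid, values, kind="irradiance", quadrature=quadrature)
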
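"""The circadian phototransduction circuit of the human retina.

The model follows the M1 ipRGC and the retinal neurons that shape its
output to the suprachiasmatic nuclei:

* **Excitations** — each photoreceptor class integrates the corneal
  spectral irradiance against its lens-filtered sensitivity.  The
  achromatic (luminance-like) channel ``V_ach = X_L + X_M`` stands for the
  combined L+M cone drive through the H1 horizontal cell.
* **Spectral opponency** — H2 horizontal-cell feedback makes the S-cone
  bipolar (SB) blue-ON/yellow-OFF: ``b − y = X_S − k·V_ach``.  The gain
  ``k`` is calibrated so a monochromatic line at the cross-point
  (default 500 nm) yields exactly zero; ``b − y ≤ 0`` is the "yellow"
  (warm) branch.
* **Rod shunting** — the AII amacrine bleeds off ipRGC depolarizing
  current in proportion to a saturating rod drive,
  ``shunt = a2·(1 − exp(−X_rod_eff / rod_sat))`` with divisive cone
  release ``X_rod_eff = X_rod / (1 + a3·V_ach)``.  This sets the
  circuit's elevated threshold and shrinks as cones silence rods.
* **A18 decoupling and rectification** — when the SB signals yellow the
  dopaminergic A18 amacrine disconnects the shunt entirely (a hard,
  diode-like switch), and the S-cone amacrine eliminates the yellow-OFF
  signal before it reaches the ipRGC, so the opponent term never enters
  with a negative sign.  The circadian drive is therefore piecewise::

      blue   (b − y > 0):  R = max(0, X_mel + a1·(b − y) − shunt)
      yellow (b − y ≤ 0):  R = X_mel

M1 and displaced M1 ipRGCs are treated as one functional unit, and only
ON signals propagate — both standing assumptions of the circuit model.
"""

from __future__ import annotations

import hashlib
import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .photopigments import (
    DEFAULT_PIGMENTS,
    LensModel,
    PhotopigmentSpec,
    corneal_sensitivity,
    lens_transmittance,
    pigment_template,
)
from .spectra import (
    DEFAULT_GRID,
    SpectralDistribution,
    ValidationError,
    WavelengthGrid,
)

__all__ = [
    "PhotoreceptorExcitations",
    "OpponentSignal",
    "CircuitParams",
    "CalibrationError",
    "corneal_sensitivities",
    "excitations",
    "excitations_from_sensitivities",
    "opponent_by",
    "rod_shunt",
    "response_from_excitations",
    "circadian_response",
    "calibrate_cross_point",
    "calibrate_gains",
    "calibrated_params",
    "params_hash",
    "save_params",
    "load_params",
]


@dataclass(frozen=True)
class PhotoreceptorExcitations:
    """Template-weighted irradiance integrals (W·m⁻²) for one stimulus."""

    X_S: float
    X_M: float
    X_L: float
    X_rod: float
    X_mel: float

    @property
    def V_ach(self) -> float:
        """Achromatic channel: combined L+M cone drive (unit weights)."""
        return self.X_L + self.X_M


@dataclass(frozen=True)
class OpponentSignal:
    """Signed blue-minus-yellow SB output; b − y ≤ 0 is the warm branch."""

    b_minus_y: float

    @property
    def branch(self) -> str:
        return "blue" if self.b_minus_y > 0 else "yellow"


@dataclass(frozen=True)
class CircuitParams:
    """Free gains of the circuit.

    k        opponent balance gain (dimensionless), from the cross-point
    a1       SB→ipRGC input gain (dimensionless)
    a2       maximum shunt amplitude (excitation units, W·m⁻²)
    a3       cone release gain (per unit V_ach)
    rod_sat  rod half-saturation constant (excitation units, W·m⁻²)
    """

    k: float
    a1: float
    a2: float
    a3: float
    rod_sat: float

    def __post_init__(self) -> None:
        for name in ("k", "a1", "a2", "a3", "rod_sat"):
            if getattr(self, name) < 0:
                raise ValidationError(f"circuit parameter {name} must be >= 0")
        if self.k <= 0 or self.rod_sat <= 0:
            raise ValidationError("k and rod_sat must be strictly positive")


class CalibrationError(RuntimeError):
    """Raised when no parameter set satisfies the calibration constraints."""


def corneal_sensitivities(
    pigments: Sequence[PhotopigmentSpec] = DEFAULT_PIGMENTS,
    lens: LensModel | None = None,
    grid: WavelengthGrid = DEFAULT_GRID,
) -> dict[str, SpectralDistribution]:
    """Lens-filtered, peak-normalized sensitivity per photoreceptor class."""
    if lens is None:
        lens = lens_transmittance(grid)
    out: dict[str, SpectralDistribution] = {}
    for spec in pigments:
        out[spec.name] = corneal_sensitivity(pigment_template(spec, grid), lens)
    missing = {"rod", "mel", "L", "M", "S"} - out.keys()
    if missing:
        raise ValidationError(f"pigment set is missing classes: {sorted(missing)}")
    return out


def excitations_from_sensitivities(
    spd: SpectralDistribution,
    sens: Mapping[str, SpectralDistribution],
) -> PhotoreceptorExcitations:
    def integral(name: str) -> float:
        return spd.weighted_integral(sens[name])

    return PhotoreceptorExcitations(
        X_S=integral("S"),
        X_M=integral("M"),
        X_L=integral("L"),
        X_rod=integral("rod"),
        X_mel=integral("mel"),
    )


def excitations(
    spd: SpectralDistribution,
    pigments: Sequence[PhotopigmentSpec] = DEFAULT_PIGMENTS,
    lens: LensModel | None = None,
) -> PhotoreceptorExcitations:
    """Five excitation integrals X_i = ∫ s_i(λ) E(λ) dλ for a stimulus."""
    if spd.kind != "irradiance":
        raise ValidationError("excitations require an irradiance-kind SPD")
    return excitations_from_sensitivities(
        spd, corneal_sensitivities(pigments, lens, spd.grid)
    )


def opponent_by(exc: PhotoreceptorExcitations, k: float) -> OpponentSignal:
    """SB opponent output: b − y = X_S − k·V_ach."""
    if k <= 0:
        raise ValidationError("opponent gain k must be positive")
    return OpponentSignal(b_minus_y=exc.X_S - k * exc.V_ach)


def rod_shunt(exc: PhotoreceptorExcitations, params: CircuitParams) -> float:
    """AII shunting inhibition magnitude, in excitation units, in [0, a2).

    Saturating in the rod drive; released divisively as the achromatic cone
    signal silences rods.
    """
    x_rod_eff = exc.X_rod / (1.0 + params.a3 * exc.V_ach)
    return params.a2 * -math.expm1(-x_rod_eff / params.rod_sat)


def response_from_excitations(
    exc: PhotoreceptorExcitations, params: CircuitParams
) -> float:
    """Piecewise circadian drive from precomputed excitations."""
    signal = opponent_by(exc, params.k)
    if signal.branch == "yellow":
        # A18 decouples the shunt; rectification removes the yellow-OFF
        # signal, so the ipRGC's intrinsic melanopsin response stands alone.
        return exc.X_mel
    drive = exc.X_mel + params.a1 * signal.b_minus_y - rod_shunt(exc, params)
    return max(0.0, drive)


def circadian_response(
    spd: SpectralDistribution,
    params: CircuitParams,
    pigments: Sequence[PhotopigmentSpec] = DEFAULT_PIGMENTS,
    lens: LensModel | None = None,
) -> float:
    """Circadian drive (nonnegative scalar) for a corneal stimulus.

    Sub-threshold blue-branch stimuli — those whose direct plus SB drive is
    smaller than the rod shunt — produce exactly zero.
    """
    return response_from_excitations(excitations(spd, pigments, lens), params)


def calibrate_cross_point(
    pigments: Sequence[PhotopigmentSpec] = DEFAULT_PIGMENTS,
    lens: LensModel | None = None,
    lambda_cross: float = 500.0,
    grid: WavelengthGrid = DEFAULT_GRID,
) -> float:
    """Opponent gain k placing the monochromatic b−y zero at ``lambda_cross``.

    k = s_S(λc) / (s_L(λc) + s_M(λc)) so that a line at the cross-point
    gives b − y = 0.  k is nudged upward by at most a few ulps so that the
    cross-point line lands on the yellow branch (b − y ≤ 0) even under
    floating-point rounding of the ratio.
    """
    grid.index_of(lambda_cross)
    sens = corneal_sensitivities(pigments, lens, grid)
    s_s = sens["S"].value_at(lambda_cross)
    s_ach = sens["L"].value_at(lambda_cross) + sens["M"].value_at(lambda_cross)
    if s_ach <= 0:
        raise CalibrationError(
            f"achromatic sensitivity vanishes at {lambda_cross} nm; "
            "cannot place the opponent cross-point there"
        )
    k = s_s / s_ach
    for _ in range(4):
        if s_s - k * s_ach <= 0:
            break
        k = math.nextafter(k, math.inf)
    return k


# Deterministic search lattices for the free gains.  Spacing is roughly
# geometric: the curve shape responds to ratios of these gains, not to
# fine absolute steps.
_A1_GRID = (0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6, 2.0)
_A2_GRID = (0.02, 0.05, 0.1, 0.15, 0.2, 0.3, 0.4)
_A3_GRID = (1.0, 3.0, 10.0, 30.0)
_RODSAT_GRID = (0.02, 0.05, 0.1, 0.2)

#: Wavelengths (nm) at which the Fig.-2-style ordinal shape constraints are
#: checked: enhanced sensitivity in the deep blue, reduced sensitivity just
#: short of the cross-point, both relative to the melanopsin-only curve.
_ENHANCED_NM = 460.0
_REDUCED_NM = 490.0
_THRESHOLD_NM = 480.0


def calibrate_gains(
    pigments: Sequence[PhotopigmentSpec] = DEFAULT_PIGMENTS,
    lens: LensModel | None = None,
    target_fwhm: float = 100.0,
    criterion: float = 300.0,
    lambda_cross: float = 500.0,
    grid: WavelengthGrid = DEFAULT_GRID,
) -> CircuitParams:
    """Deterministic grid search for (a1, a2, a3, rod_sat).

    Minimizes |FWHM(full curve at ``criterion`` scotopic lx) − target_fwhm|
    over a fixed lattice, subject to three shape constraints evaluated on
    per-irradiance sensitivities:

    * enhanced:  full(460 nm) > melanopsin-only(460 nm)
    * reduced:   full(490 nm) < melanopsin-only(490 nm)
    * threshold: the low-power shunt slope a2·s_rod/rod_sat exceeds the
      direct-plus-SB drive at 480 nm, so rod shunting genuinely elevates
      the circuit threshold for short-wavelength stimuli.

    The search order is fixed (lexicographic over the lattices) and ties
    keep the earlier candidate, so repeated runs return identical
    parameters.  ``target_fwhm`` must exceed the 80 nm single-opsin width.
    """
    from .sensitivity import MetricUndefinedError, fwhm_of_samples, mono_conditions

    if target_fwhm <= 80.0:
        raise ValidationError(
            "target_fwhm must exceed the 80 nm single-opsin half-bandwidth"
        )
    if criterion <= 0:
        raise ValidationError("criterion must be positive")

    k = calibrate_cross_point(pigments, lens, lambda_cross, grid)
    cond = mono_conditions(criterion, pigments, lens, grid)
    sens = corneal_sensitivities(pigments, lens, grid)

    def at(name: str, nm: float) -> float:
        return sens[name].value_at(nm)

    mel_only = cond.sens["mel"]  # per-irradiance melanopsin-only sensitivity
    i_enh = int(np.searchsorted(cond.wavelengths, _ENHANCED_NM))
    i_red = int(np.searchsorted(cond.wavelengths, _REDUCED_NM))

    b_y_thresh = at("S", _THRESHOLD_NM) - k * (
        at("L", _THRESHOLD_NM) + at("M", _THRESHOLD_NM)
    )

    best: CircuitParams | None = None
    best_err = math.inf
    violations = {"enhanced": 0, "reduced": 0, "threshold": 0, "fwhm-undefined": 0}
    for a1, a2, a3, rod_sat in itertools.product(
        _A1_GRID, _A2_GRID, _A3_GRID, _RODSAT_GRID
    ):
        params = CircuitParams(k=k, a1=a1, a2=a2, a3=a3, rod_sat=rod_sat)
        if a2 * at("rod", _THRESHOLD_NM) / rod_sat <= at("mel", _THRESHOLD_NM) + a1 * max(
            0.0, b_y_thresh
        ):
            violations["threshold"] += 1
            continue
        full = cond.per_irradiance_response(params)
        if not full[i_enh] > mel_only[i_enh]:
            violations["enhanced"] += 1
            continue
        if not full[i_red] < mel_only[i_red]:
            violations["reduced"] += 1
            continue
        try:
            width = fwhm_of_samples(cond.wavelengths, full)
        except MetricUndefinedError:
            violations["fwhm-undefined"] += 1
            continue
        err = abs(width - target_fwhm)
        if err < best_err:
            best, best_err = params, err
    if best is None:
        worst = max(violations, key=violations.get)
        raise CalibrationError(
            "no parameter set satisfies the calibration constraints "
            f"(most-violated: {worst}; counts {violations})"
        )
    return best


_CALIBRATION_CACHE: dict[tuple, CircuitParams] = {}


def calibrated_params(
    target_fwhm: float = 100.0,
    criterion: float = 300.0,
    lambda_cross: float = 500.0,
    lens_source: str = "bundled-table",
    grid: WavelengthGrid = DEFAULT_GRID,
) -> CircuitParams:
    """Default-pigment calibrated parameters, memoized per configuration."""
    key = (target_fwhm, criterion, lambda_cross, lens_source, grid)
    if key not in _CALIBRATION_CACHE:
        lens = lens_transmittance(grid, lens_source)
        _CALIBRATION_CACHE[key] = calibrate_gains(
            DEFAULT_PIGMENTS, lens, target_fwhm, criterion, lambda_cross, grid
        )
    return _CALIBRATION_CACHE[key]


def params_hash(params: CircuitParams) -> str:
    """Short stable hash tying curve outputs to the parameters that made them."""
    canon = ",".join(
        f"{name}={getattr(params, name):.12g}"
        for name in ("k", "a1", "a2", "a3", "rod_sat")
    )
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def save_params(path, params: CircuitParams, extra: Mapping[str, object] | None = None) -> None:
    """Write a flat ``key = value`` parameter file (byte-stable across runs)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# circphot circuit parameters\n")
        for name in ("k", "a1", "a2", "a3", "rod_sat"):
            fh.write(f"{name} = {getattr(params, name)!r}\n")
        for key in sorted(extra or {}):
            fh.write(f"{key} = {extra[key]}\n")
        fh.write(f"params_hash = {params_hash(params)}\n")


def load_params(path) -> tuple[CircuitParams, dict[str, str]]:
    """Read a parameter file; returns the params and any extra fields."""
    fields: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"{path}: malformed parameter line {raw!r}")
            key, val = (part.strip() for part in line.split("=", 1))
            fields[key] = val
    try:
        params = CircuitParams(
            k=float(fields.pop("k")),
            a1=float(fields.pop("a1")),
            a2=float(fields.pop("a2")),
            a3=float(fields.pop("a3")),
            rod_sat=float(fields.pop("rod_sat")),
        )
    except KeyError as exc:
        raise ValidationError(f"{path}: missing parameter {exc}") from None
    return params, fields
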
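"""Spectral response correction (SRC).

Detectors and collection optics have wavelength-dependent sensitivity; a
multiplicative correction factor C(ṽ) flattens it. Three pathways produce
the factor:

* **white light** — ratio of a manufacturer-tabulated radiance profile
  (fitted with a polynomial and evaluated on the measured axis, converted
  to nm) to the smoothed measured lamp spectrum, both normalized at a
  common centre wavelength;
* **NIST SRM** — ratio of the certified fifth-order luminescence
  polynomial of a fluorescent-glass standard to the measured SRM
  spectrum, normalized the same way and smoothed after the ratio;
* **precomputed** — loaded from disk (see ``spectral_io``).

All three return the same :class:`CorrectionFactor` contract, so the
pipeline's P2 stage treats them interchangeably.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial
from scipy.signal import savgol_filter

from .errors import DomainError, SpectralRangeError, SpectrumValidationError
from .spectrum import AxisKind, Spectrum


@dataclass(frozen=True)
class CorrectionFactor:
    """Multiplicative response-correction curve on its own axis."""

    axis: np.ndarray
    factor: np.ndarray
    axis_unit: str = "raman_shift"  # or "wavelength"

    def __post_init__(self):
        axis = np.asarray(self.axis, dtype=float)
        factor = np.asarray(self.factor, dtype=float)
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "factor", factor)
        if self.axis_unit not in ("raman_shift", "wavelength"):
            raise SpectrumValidationError(f"unknown axis unit {self.axis_unit!r}")
        if axis.size != factor.size or axis.size < 2:
            raise SpectrumValidationError("axis/factor must pair with length >= 2")
        if np.any(np.diff(axis) <= 0):
            raise SpectrumValidationError("correction axis must be strictly increasing")
        if not np.all(np.isfinite(factor)) or np.any(factor <= 0):
            raise SpectrumValidationError("correction factor must be finite and positive")

    def __len__(self):
        return int(self.axis.size)


@dataclass(frozen=True)
class RadianceTable:
    """Manufacturer-provided lamp radiance: wavelength (nm) vs relative
    radiance."""

    wavelength: np.ndarray
    radiance: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelength, dtype=float)
        rad = np.asarray(self.radiance, dtype=float)
        object.__setattr__(self, "wavelength", wl)
        object.__setattr__(self, "radiance", rad)
        if wl.size != rad.size or wl.size < 2:
            raise SpectrumValidationError("radiance table needs paired columns, >= 2 rows")
        if np.any(np.diff(wl) <= 0):
            raise SpectrumValidationError("radiance wavelengths must be strictly increasing")
        if np.any(rad <= 0):
            raise SpectrumValidationError("radiance values must be positive")


@dataclass(frozen=True)
class SrmCertificate:
    """Certified quintic luminescence shape of a NIST SRM glass.

    ``variable_convention`` states the variable the quintic is defined in
    (different SRMs use Raman shift in cm⁻¹ or wavelength in nm).
    """

    coeffs: np.ndarray  # 6 values, ascending powers
    valid_range: tuple[float, float]  # cm-1
    variable_convention: str = "raman_shift_cm-1"  # or "wavelength_nm"

    def __post_init__(self):
        coeffs = np.asarray(self.coeffs, dtype=float)
        object.__setattr__(self, "coeffs", coeffs)
        if coeffs.size != 6:
            raise ValueError(f"SRM certificate needs exactly 6 coefficients, got {coeffs.size}")
        if self.variable_convention not in ("raman_shift_cm-1", "wavelength_nm"):
            raise ValueError(f"unknown variable convention {self.variable_convention!r}")
        lo, hi = self.valid_range
        if not lo < hi:
            raise ValueError("valid_range must be an increasing interval")


@dataclass(frozen=True)
class SmoothParams:
    """Savitzky–Golay smoothing parameters used inside the SRC pathways."""

    window: int = 15
    polyorder: int = 3

    def apply(self, values: np.ndarray) -> np.ndarray:
        window = min(self.window, values.size if values.size % 2 else values.size - 1)
        if window <= self.polyorder:
            return values
        return savgol_filter(values, window, self.polyorder)


def raman_shift_to_wavelength(delta, laser_wavelength_nm: float):
    """Scattered wavelength λ = 1e7 / (1e7/λ_laser − Δṽ), nm."""
    delta = np.asarray(delta, dtype=float)
    denom = 1e7 / laser_wavelength_nm - delta
    if np.any(denom <= 0):
        raise DomainError("Raman shift at or beyond the laser wavenumber")
    result = 1e7 / denom
    return result if result.ndim else float(result)


def wavelength_to_raman_shift(wavelength_nm, laser_wavelength_nm: float):
    """Inverse of :func:`raman_shift_to_wavelength`."""
    wavelength_nm = np.asarray(wavelength_nm, dtype=float)
    if np.any(wavelength_nm <= 0):
        raise DomainError("wavelength must be positive")
    result = 1e7 / laser_wavelength_nm - 1e7 / wavelength_nm
    return result if result.ndim else float(result)


def _center_index(axis: np.ndarray, center: float | None) -> int:
    target = (axis[0] + axis[-1]) / 2.0 if center is None else center
    return int(np.argmin(np.abs(axis - target)))


def white_light_correction(
    measured: Spectrum,
    radiance: RadianceTable,
    laser_wavelength_nm: float,
    smooth_params: SmoothParams | None = SmoothParams(),
    poly_order: int = 5,
    center_wavelength_nm: float | None = None,
) -> CorrectionFactor:
    """Correction factor from a measured broadband (white-light) spectrum.

    The measured spectrum (Raman-shift axis) is smoothed and its axis
    converted to nm; the radiance table is fitted with a ``poly_order``
    polynomial and evaluated on that converted axis ("true" profile); both
    profiles are scaled to 1 at the sample nearest ``center_wavelength_nm``
    (default: the converted-axis midpoint); the factor is true/measured,
    reported on the original Raman-shift axis.
    """
    if measured.axis_kind is not AxisKind.RAMAN_SHIFT:
        raise ValueError("white-light measurement must be on a Raman-shift axis")
    wavelengths = raman_shift_to_wavelength(measured.axis, laser_wavelength_nm)
    if wavelengths.min() < radiance.wavelength[0] or wavelengths.max() > radiance.wavelength[-1]:
        raise SpectralRangeError(
            f"radiance table [{radiance.wavelength[0]:.1f}, {radiance.wavelength[-1]:.1f}] nm "
            f"does not cover the measured span [{wavelengths.min():.1f}, {wavelengths.max():.1f}] nm"
        )
    meas = np.asarray(measured.intensity, dtype=float)
    if smooth_params is not None:
        meas = smooth_params.apply(meas)
    if np.any(meas <= 0):
        raise DomainError("measured white-light intensity must be positive after smoothing")

    true_fit = Polynomial.fit(radiance.wavelength, radiance.radiance, deg=poly_order)
    true = true_fit(wavelengths)
    if np.any(true <= 0):
        raise DomainError("fitted radiance profile non-positive on the measured span")

    ic = _center_index(wavelengths, center_wavelength_nm)
    true = true / true[ic]
    meas = meas / meas[ic]
    return CorrectionFactor(measured.axis, true / meas, axis_unit="raman_shift")


def srm_correction(
    measured: Spectrum,
    cert: SrmCertificate,
    smooth_params: SmoothParams | None = SmoothParams(),
    laser_wavelength_nm: float | None = None,
) -> CorrectionFactor:
    """Correction factor from a measured NIST SRM fluorescent-glass
    spectrum against its certified quintic shape.

    Both profiles are normalized at the centre sample (same convention as
    the white-light pathway); the ratio true/measured is then smoothed
    with ``smooth_params``.
    """
    if measured.axis_kind is not AxisKind.RAMAN_SHIFT:
        raise ValueError("SRM measurement must be on a Raman-shift axis")
    lo, hi = cert.valid_range
    if measured.axis[0] < lo or measured.axis[-1] > hi:
        raise SpectralRangeError(
            f"measured axis [{measured.axis[0]:.1f}, {measured.axis[-1]:.1f}] cm-1 "
            f"outside certificate range [{lo:.1f}, {hi:.1f}] cm-1"
        )
    if cert.variable_convention == "wavelength_nm":
        if laser_wavelength_nm is None:
            raise ValueError(
                "a wavelength-convention certificate needs laser_wavelength_nm"
            )
        var = raman_shift_to_wavelength(measured.axis, laser_wavelength_nm)
    else:
        var = measured.axis

    true = np.zeros_like(var)
    for c in cert.coeffs[::-1]:
        true = true * var + c
    if np.any(true <= 0):
        raise DomainError("certified profile non-positive on the measured span")
    meas = np.asarray(measured.intensity, dtype=float)
    if np.any(meas <= 0):
        raise DomainError("measured SRM intensity must be positive")

    ic = _center_index(measured.axis, None)
    ratio = (true / true[ic]) / (meas / meas[ic])
    if smooth_params is not None:
        ratio = smooth_params.apply(ratio)
    if np.any(ratio <= 0):
        raise DomainError("correction factor non-positive after smoothing")
    return CorrectionFactor(measured.axis, ratio, axis_unit="raman_shift")


def resample_factor(cf: CorrectionFactor, target_axis) -> CorrectionFactor:
    """Linearly interpolate a correction factor onto ``target_axis``.

    Extrapolation is refused: the target must lie within the factor's
    span. Linear interpolation between positive values stays positive.
    """
    target_axis = np.asarray(target_axis, dtype=float)
    if target_axis[0] < cf.axis[0] or target_axis[-1] > cf.axis[-1]:
        raise SpectralRangeError(
            f"target axis [{target_axis[0]:.2f}, {target_axis[-1]:.2f}] extends beyond "
            f"the factor span [{cf.axis[0]:.2f}, {cf.axis[-1]:.2f}]"
        )
    return CorrectionFactor(
        target_axis, np.interp(target_axis, cf.axis, cf.factor), axis_unit=cf.axis_unit
    )
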
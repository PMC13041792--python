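"""X-axis calibration: mapping detector pixels to Raman shift.

The procedure mirrors the standard dispersive-spectrometer workflow:

1. measure a Ne–Ar emission lamp, refine the pixel positions of known
   lines (Savitzky–Golay first-derivative span detection + intensity
   centroid),
2. fit a cubic ``ṽ_abs(p) = a0 + a1·p + a2·p² + a3·p³`` by least squares,
3. obtain the excitation wavelength either directly or by averaging
   ``λ = 1e7 / (ṽ_abs(p_i) + Δṽ_ref,i)`` over certified acetaminophen
   bands, and
4. build the per-pixel Raman-shift axis ``Δṽ(p) = 1e7/λ − ṽ_abs(p)``.

The cubic is fitted on a centered/scaled pixel basis for conditioning and
transformed back to raw-pixel coefficients for storage.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from numpy.polynomial import Polynomial
from scipy.signal import savgol_filter

from .errors import (
    DomainError,
    InsufficientDataError,
    NoPeakError,
    SingularFitError,
)
from .spectrum import AxisKind, Spectrum

DEFAULT_SG_WINDOW = 7
DEFAULT_SG_ORDER = 2
DEFAULT_SEARCH_HALF_WIDTH = 15  # px
MIN_CALIBRATION_PEAKS = 4
RECOMMENDED_CALIBRATION_PEAKS = 6


@dataclass(frozen=True)
class ReferenceLineLibrary:
    """Ordered absolute wavenumbers (cm⁻¹) of atomic emission lines."""

    lines: np.ndarray
    source_label: str

    def __post_init__(self):
        lines = np.asarray(self.lines, dtype=float)
        object.__setattr__(self, "lines", lines)
        if np.any(np.diff(lines) <= 0):
            raise ValueError("reference lines must be strictly increasing")

    def __len__(self):
        return int(self.lines.size)


@dataclass(frozen=True)
class RamanReferenceLibrary:
    """Ordered certified Raman shifts (cm⁻¹) of a standard analyte."""

    shifts: np.ndarray
    analyte_label: str

    def __post_init__(self):
        shifts = np.asarray(self.shifts, dtype=float)
        object.__setattr__(self, "shifts", shifts)
        if np.any(np.diff(shifts) <= 0):
            raise ValueError("reference shifts must be strictly increasing")

    def __len__(self):
        return int(self.shifts.size)


def _load_column(name: str) -> np.ndarray:
    text = resources.files("ramanprep.data").joinpath(name).read_text()
    vals = [float(ln) for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    return np.asarray(vals, dtype=float)


def neon_argon_library() -> ReferenceLineLibrary:
    """Bundled Ne–Ar emission library: 52 lines, 9,677.994–12,947.060 cm⁻¹."""
    return ReferenceLineLibrary(_load_column("neon_argon_lines.txt"), "Ne-Ar lamp")


def acetaminophen_library() -> RamanReferenceLibrary:
    """Bundled acetaminophen shift library: 22 bands, 213.3–3,326.6 cm⁻¹."""
    return RamanReferenceLibrary(
        _load_column("acetaminophen_shifts.txt"), "acetaminophen"
    )


@dataclass(frozen=True)
class PeakPick:
    approx_pixel: float
    refined_pixel: float
    matched_reference: float  # cm-1 (absolute wavenumber or Raman shift)


@dataclass(frozen=True)
class PolynomialFit:
    """Cubic pixel→wavenumber fit with residual diagnostics."""

    coeffs: np.ndarray  # a0..a3, ascending powers, raw-pixel basis
    residuals: np.ndarray  # per-pair fit residual (cm-1)
    rms: float


@dataclass(frozen=True)
class LaserEstimate:
    wavelength_nm: float
    per_peak_nm: np.ndarray
    spread_nm: float  # max - min of the per-peak estimates


@dataclass(frozen=True)
class CalibrationRecord:
    coeffs: np.ndarray  # a0..a3 ascending powers
    laser_wavelength_nm: float
    raman_shift_axis: np.ndarray  # Δṽ per pixel, pixel order
    selected_peak_indices: tuple[int, ...]
    calibration_datetime: str  # ISO-8601
    fit_rms: float = 0.0


def refine_peak(
    spectrum: Spectrum,
    approx_pixel: float,
    sg_window: int = DEFAULT_SG_WINDOW,
    sg_order: int = DEFAULT_SG_ORDER,
    search_half_width: int = DEFAULT_SEARCH_HALF_WIDTH,
) -> float:
    """Refine an approximate peak position to a sub-pixel centroid.

    The smoothed first derivative (Savitzky–Golay) defines the peak span:
    the apex is the +→− sign change nearest ``approx_pixel`` within
    ``search_half_width``; the span extends to the flanking derivative
    sign changes on each side. The result is the intensity centroid over
    that span, computed on span-local baseline-corrected intensities so a
    sloping background does not bias the position. The returned position
    always lies inside the detected span.
    """
    if sg_window % 2 == 0 or sg_window <= sg_order or sg_window > len(spectrum):
        raise ValueError(
            f"sg_window must be odd, > sg_order and <= spectrum length "
            f"(got window={sg_window}, order={sg_order}, n={len(spectrum)})"
        )
    axis = spectrum.axis
    if not (axis[0] <= approx_pixel <= axis[-1]):
        raise ValueError(f"approx_pixel {approx_pixel} outside axis range")
    intens = spectrum.intensity
    deriv = savgol_filter(intens, sg_window, sg_order, deriv=1)

    i0 = int(np.argmin(np.abs(axis - approx_pixel)))
    n = len(axis)
    lo = max(0, i0 - search_half_width)
    hi = min(n - 2, i0 + search_half_width)
    crossings = [
        j for j in range(lo, hi + 1) if deriv[j] > 0 and deriv[j + 1] <= 0
    ]
    if not crossings:
        raise NoPeakError(
            f"no peak span (+→− derivative crossing) within "
            f"{search_half_width} px of pixel {approx_pixel}"
        )
    apex = min(crossings, key=lambda j: abs(axis[j] - approx_pixel))

    left = apex
    while left > 0 and deriv[left - 1] > 0:
        left -= 1
    right = apex + 1
    while right < n - 1 and deriv[right + 1] < 0:
        right += 1

    span_axis = axis[left : right + 1]
    weights = intens[left : right + 1] - intens[left : right + 1].min()
    total = weights.sum()
    if total <= 0:
        raise NoPeakError(f"flat span around pixel {approx_pixel}")
    centroid = float(np.dot(span_axis, weights) / total)
    # clip to span: the centroid of in-span weights cannot leave it, but
    # guard against fp rounding at the edges
    return float(np.clip(centroid, span_axis[0], span_axis[-1]))


def fit_pixel_to_wavenumber(pairs) -> PolynomialFit:
    """Least-squares cubic fit of (refined_pixel, reference_wavenumber)
    pairs, returned in ascending-power order on the raw pixel basis."""
    pairs = list(pairs)
    if len(pairs) < MIN_CALIBRATION_PEAKS:
        raise InsufficientDataError(
            f"cubic calibration needs >= {MIN_CALIBRATION_PEAKS} pairs, got {len(pairs)}"
        )
    px = np.asarray([p for p, _ in pairs], dtype=float)
    wn = np.asarray([w for _, w in pairs], dtype=float)
    if np.unique(px).size < MIN_CALIBRATION_PEAKS:
        raise SingularFitError(
            f"need >= {MIN_CALIBRATION_PEAKS} distinct pixel positions"
        )
    # Polynomial.fit centers/scales the abscissa internally; convert back
    # to the raw-pixel basis for storage.
    fit = Polynomial.fit(px, wn, deg=3)
    coeffs = fit.convert().coef
    if coeffs.size < 4:
        coeffs = np.pad(coeffs, (0, 4 - coeffs.size))
    residuals = wn - evaluate_calibration(coeffs, px)
    rms = float(np.sqrt(np.mean(residuals**2)))
    return PolynomialFit(coeffs=coeffs, residuals=residuals, rms=rms)


def evaluate_calibration(coeffs, p):
    """Evaluate the cubic ṽ_abs(p) = Σ a_k p^k (Horner scheme)."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.size != 4:
        raise ValueError(f"expected 4 coefficients a0..a3, got {coeffs.size}")
    p = np.asarray(p, dtype=float)
    result = np.zeros_like(p)
    for c in coeffs[::-1]:
        result = result * p + c
    return result if result.ndim else float(result)


def estimate_laser_wavelength(coeffs, acet_pixels, ref_shifts) -> LaserEstimate:
    """Estimate the excitation wavelength from matched acetaminophen peaks.

    For each matched peak i the laser wavenumber is
    ``ṽ_abs(p_i) + Δṽ_ref,i`` and the per-peak wavelength estimate is
    1e7 over that; the reported wavelength is the arithmetic mean, with
    the per-peak values and their max−min spread retained as diagnostics.
    """
    acet_pixels = np.asarray(acet_pixels, dtype=float)
    ref_shifts = np.asarray(ref_shifts, dtype=float)
    if acet_pixels.size == 0:
        raise InsufficientDataError("need at least one matched acetaminophen peak")
    if acet_pixels.size != ref_shifts.size:
        raise ValueError("pixels and reference shifts must pair one-to-one")
    denom = evaluate_calibration(coeffs, acet_pixels) + ref_shifts
    if np.any(denom <= 0):
        raise DomainError("non-positive laser wavenumber ṽ_abs(p)+Δṽ_ref")
    per_peak = 1e7 / denom
    return LaserEstimate(
        wavelength_nm=float(np.mean(per_peak)),
        per_peak_nm=per_peak,
        spread_nm=float(per_peak.max() - per_peak.min()),
    )


def compute_raman_shift_axis(coeffs, laser_wavelength_nm: float, n_pixels: int):
    """Per-pixel Raman shift Δṽ(p) = 1e7/λ − ṽ_abs(p), p = 0..n_pixels−1.

    Returned in pixel order; because ṽ_abs normally increases with p, the
    shift axis typically decreases with p and is re-sorted ascending when
    paired with intensities (see :func:`calibrate_spectrum`).
    """
    if n_pixels < 2:
        raise ValueError("n_pixels must be >= 2")
    if laser_wavelength_nm <= 0:
        raise ValueError("laser wavelength must be positive")
    p = np.arange(n_pixels, dtype=float)
    return 1e7 / laser_wavelength_nm - evaluate_calibration(coeffs, p)


def calibrate_spectrum(spectrum: Spectrum, record: CalibrationRecord) -> Spectrum:
    """Attach the calibrated Raman-shift axis to a pixel-indexed spectrum,
    sorting to ascending shift with intensities in lockstep."""
    if spectrum.axis_kind is not AxisKind.PIXEL:
        raise ValueError("calibrate_spectrum expects a pixel-axis spectrum")
    if len(spectrum) != record.raman_shift_axis.size:
        raise ValueError(
            f"spectrum has {len(spectrum)} pixels but the calibration record "
            f"covers {record.raman_shift_axis.size}"
        )
    return Spectrum.from_unordered(
        record.raman_shift_axis, spectrum.intensity, AxisKind.RAMAN_SHIFT
    )


def build_calibration_record(
    lamp_spectrum: Spectrum,
    picks,  # sequence of (approx_pixel, library_index)
    library: ReferenceLineLibrary,
    n_pixels: int,
    laser_wavelength_nm: float | None = None,
    acet_spectrum: Spectrum | None = None,
    acet_picks=None,  # sequence of (approx_pixel, raman_library_index)
    acet_library: RamanReferenceLibrary | None = None,
    sg_window: int = DEFAULT_SG_WINDOW,
    sg_order: int = DEFAULT_SG_ORDER,
) -> CalibrationRecord:
    """Compose refine → fit → (accept or estimate λ) → axis into a record.

    Exactly one laser source must be given: a direct ``laser_wavelength_nm``
    or the acetaminophen estimation inputs (spectrum + picks + library).
    """
    import warnings

    picks = list(picks)
    if len(picks) < RECOMMENDED_CALIBRATION_PEAKS:
        warnings.warn(
            f"only {len(picks)} calibration peaks selected; "
            f">= {RECOMMENDED_CALIBRATION_PEAKS} recommended",
            stacklevel=2,
        )
    refined = [
        (refine_peak(lamp_spectrum, approx, sg_window, sg_order), library.lines[idx])
        for approx, idx in picks
    ]
    fit = fit_pixel_to_wavenumber(refined)

    if laser_wavelength_nm is not None:
        if acet_spectrum is not None or acet_picks is not None:
            raise ValueError("give either a direct wavelength or estimation inputs, not both")
        laser = float(laser_wavelength_nm)
    else:
        if acet_spectrum is None or acet_picks is None or acet_library is None:
            raise ValueError(
                "laser estimation needs acet_spectrum, acet_picks and acet_library"
            )
        acet_px = [
            refine_peak(acet_spectrum, approx, sg_window, sg_order)
            for approx, _ in acet_picks
        ]
        shifts = [acet_library.shifts[idx] for _, idx in acet_picks]
        laser = estimate_laser_wavelength(fit.coeffs, acet_px, shifts).wavelength_nm

    axis = compute_raman_shift_axis(fit.coeffs, laser, n_pixels)
    return CalibrationRecord(
        coeffs=fit.coeffs,
        laser_wavelength_nm=laser,
        raman_shift_axis=axis,
        selected_peak_indices=tuple(int(idx) for _, idx in picks),
        calibration_datetime=_dt.datetime.now().isoformat(timespec="seconds"),
        fit_rms=fit.rms,
    )
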
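"""Forward-model generators for every input class the toolkit consumes.

Each generator simulates one arm of the dispersive-Raman measurement
chain with fully known ground truth, so calibration, response correction
and the pipeline can all be exercised and checked against the generating
model without any instrument data:

* emission-lamp spectra whose peaks sit at the pixel roots of a known
  cubic pixel→wavenumber map;
* acetaminophen spectra with peaks at certified Raman shifts for a known
  excitation wavelength;
* sample spectra = peaks + broad polynomial fluorescence + smooth
  instrument gain + Gaussian noise + isolated cosmic-ray spikes;
* white-light measurement/radiance-table pairs related by a known gain.

Everything is a deterministic function of (model, seed): the same model
regenerates byte-identical fixtures. The additive noise is Gaussian
(optionally Poisson); neither detector nonlinearity nor radiometrically
rigorous lamp physics is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from scipy.optimize import brentq

from .calibration import (
    RamanReferenceLibrary,
    ReferenceLineLibrary,
    compute_raman_shift_axis,
    evaluate_calibration,
)
from .errors import GenerationError
from .response_correction import RadianceTable, raman_shift_to_wavelength
from .spectrum import AxisKind, Spectrum

# Default study conditions: a 1340-px NIR detector whose cubic dispersion
# covers both bundled reference libraries at 785 nm-class excitation.
DEFAULT_COEFFS = (9390.0, 2.7, -1.5e-5, 1.0e-9)
DEFAULT_N_PIXELS = 1340


@dataclass(frozen=True)
class PeakShape:
    center: float  # cm-1 (sample peaks) or px (lamp peaks)
    width: float  # Gaussian sigma / Lorentzian HWHM, same units as center
    height: float  # counts
    profile: Literal["gaussian", "lorentzian"] = "gaussian"

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        d = x - self.center
        if self.profile == "gaussian":
            return self.height * np.exp(-0.5 * (d / self.width) ** 2)
        return self.height / (1.0 + (d / self.width) ** 2)


# Sample peaks loosely modelled on common biological Raman bands
# (phenylalanine 1004, C-C/C-N ~1095, amide III ~1250, CH2 1445, amide I
# ~1655 cm-1) so the defaults exercise the fingerprint window.
DEFAULT_SAMPLE_PEAKS = (
    PeakShape(1004.0, 6.0, 800.0),
    PeakShape(1095.0, 10.0, 350.0),
    PeakShape(1250.0, 14.0, 450.0),
    PeakShape(1445.0, 12.0, 600.0),
    PeakShape(1655.0, 13.0, 500.0, "lorentzian"),
)

# Broad, positive quadratic fluorescence over the ~0-3350 cm-1 span.
DEFAULT_BASELINE = (1200.0, -0.8, 1.5e-4)


@dataclass(frozen=True)
class ForwardModel:
    """Ground-truth description of the simulated instrument and sample."""

    true_coeffs: tuple[float, float, float, float] = DEFAULT_COEFFS
    laser_wavelength_nm: float = 785.0
    n_pixels: int = DEFAULT_N_PIXELS
    peak_shapes: tuple[PeakShape, ...] = DEFAULT_SAMPLE_PEAKS
    baseline_coeffs: tuple[float, ...] = DEFAULT_BASELINE
    noise_sigma: float = 2.0  # counts; 0 disables
    noise_model: Literal["gaussian", "poisson"] = "gaussian"
    cosmic_rays: tuple[tuple[int, float], ...] = ()  # (pixel, amplitude)
    response_gain: tuple[float, ...] = (1.0, 0.0, 0.0)  # polynomial in (λ-λ0)/100 nm
    lamp_peak_width_px: float = 2.5
    lamp_peak_height: float = 1000.0
    lamp_baseline: float = 50.0
    seed: int = 0

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, salt]))

    def gain_at_wavelength(self, wavelength_nm: np.ndarray) -> np.ndarray:
        """Smooth positive instrument gain g(λ), a polynomial in
        (λ − λ_laser)/100 for scale-free coefficients."""
        z = (np.asarray(wavelength_nm, dtype=float) - self.laser_wavelength_nm) / 100.0
        g = np.zeros_like(z)
        for c in self.response_gain[::-1]:
            g = g * z + c
        if np.any(g <= 0):
            raise GenerationError("response gain must stay positive over the span")
        return g


def pixel_of_wavenumber(coeffs, target: float, n_pixels: int) -> float:
    """Invert the cubic: the unique pixel p in [0, n−1] with ṽ_abs(p)=target.

    Requires a monotonically increasing map over the detector (a1-dominant
    physical dispersion); lines outside the detector's span are refused.
    """
    lo, hi = 0.0, float(n_pixels - 1)
    grid = np.linspace(lo, hi, 64)
    vals = evaluate_calibration(coeffs, grid)
    if np.any(np.diff(vals) <= 0):
        raise GenerationError("pixel→wavenumber map must be monotone over the detector")
    v_lo, v_hi = vals[0], vals[-1]
    if not (min(v_lo, v_hi) <= target <= max(v_lo, v_hi)):
        raise GenerationError(
            f"wavenumber {target:.3f} cm-1 outside detector span "
            f"[{v_lo:.3f}, {v_hi:.3f}] cm-1"
        )
    return float(brentq(lambda p: evaluate_calibration(coeffs, p) - target, lo, hi))


def _pixel_peak_spectrum(model: ForwardModel, centers_px, salt: int):
    pixels = np.arange(model.n_pixels, dtype=float)
    intensity = np.full(model.n_pixels, model.lamp_baseline, dtype=float)
    for c in centers_px:
        intensity += PeakShape(c, model.lamp_peak_width_px, model.lamp_peak_height).evaluate(
            pixels
        )
    intensity = _add_noise(model, intensity, salt)
    return Spectrum(pixels, intensity, AxisKind.PIXEL)


def _add_noise(model: ForwardModel, intensity: np.ndarray, salt: int) -> np.ndarray:
    if model.noise_sigma <= 0:
        return intensity
    rng = model.rng(salt)
    if model.noise_model == "poisson":
        scale = model.noise_sigma**2
        return rng.poisson(np.clip(intensity, 0, None) / scale) * scale
    return intensity + rng.normal(0.0, model.noise_sigma, intensity.size)


@dataclass(frozen=True)
class LampFixture:
    spectrum: Spectrum
    true_pixels: np.ndarray  # ground-truth peak positions, px
    line_indices: tuple[int, ...]  # indices into the reference library


def gen_lamp_spectrum(
    model: ForwardModel, library: ReferenceLineLibrary, subset
) -> LampFixture:
    """Emission-lamp spectrum with peaks at the pixel positions implied by
    the model's true cubic for the selected library lines."""
    subset = tuple(int(i) for i in subset)
    centers = np.array(
        [pixel_of_wavenumber(model.true_coeffs, library.lines[i], model.n_pixels) for i in subset]
    )
    return LampFixture(
        spectrum=_pixel_peak_spectrum(model, centers, salt=1),
        true_pixels=centers,
        line_indices=subset,
    )


@dataclass(frozen=True)
class AcetFixture:
    spectrum: Spectrum
    true_pixels: np.ndarray
    shift_indices: tuple[int, ...]
    shifts: np.ndarray  # cm-1


def gen_acetaminophen_spectrum(
    model: ForwardModel, library: RamanReferenceLibrary, subset=None
) -> AcetFixture:
    """Acetaminophen reference spectrum: peaks at the pixels whose absolute
    wavenumber is 1e7/λ_laser − Δṽ_ref for each certified shift."""
    if subset is None:
        subset = range(len(library))
    subset = tuple(int(i) for i in subset)
    laser_wn = 1e7 / model.laser_wavelength_nm
    shifts = np.array([library.shifts[i] for i in subset])
    centers = np.array(
        [pixel_of_wavenumber(model.true_coeffs, laser_wn - s, model.n_pixels) for s in shifts]
    )
    return AcetFixture(
        spectrum=_pixel_peak_spectrum(model, centers, salt=2),
        true_pixels=centers,
        shift_indices=subset,
        shifts=shifts,
    )


@dataclass(frozen=True)
class SampleFixture:
    spectrum: Spectrum
    axis: np.ndarray  # ascending Raman-shift axis
    peaks: np.ndarray  # noise-free peak profile on that axis
    baseline: np.ndarray
    gain: np.ndarray
    noise: np.ndarray
    spikes: np.ndarray


def gen_sample_spectrum(model: ForwardModel) -> SampleFixture:
    """Sample spectrum on the model's calibrated Raman-shift axis:
    gain × (peaks + fluorescence baseline) + noise + cosmic-ray spikes,
    with every ground-truth component returned separately."""
    shift_per_pixel = compute_raman_shift_axis(
        model.true_coeffs, model.laser_wavelength_nm, model.n_pixels
    )
    order = np.argsort(shift_per_pixel)
    axis = shift_per_pixel[order]

    peaks = np.zeros_like(axis)
    for shape in model.peak_shapes:
        peaks += shape.evaluate(axis)
    baseline = np.zeros_like(axis)
    for c in model.baseline_coeffs[::-1]:
        baseline = baseline * axis + c
    wavelengths = raman_shift_to_wavelength(axis, model.laser_wavelength_nm)
    gain = model.gain_at_wavelength(wavelengths)

    clean = gain * (peaks + baseline)
    noisy = _add_noise(model, clean, salt=3)
    noise = noisy - clean

    spikes = np.zeros_like(axis)
    for pixel, amplitude in model.cosmic_rays:
        # cosmic rays strike detector pixels; map through the axis sort
        idx = int(np.nonzero(order == int(pixel))[0][0])
        spikes[idx] += amplitude

    spectrum = Spectrum(axis, clean + noise + spikes, AxisKind.RAMAN_SHIFT)
    return SampleFixture(
        spectrum=spectrum,
        axis=axis,
        peaks=peaks,
        baseline=baseline,
        gain=gain,
        noise=noise,
        spikes=spikes,
    )


@dataclass(frozen=True)
class WhitelightFixture:
    measured: Spectrum
    radiance: RadianceTable
    gain: np.ndarray  # true gain on the measured axis


def gen_whitelight_pair(
    model: ForwardModel, n_table_rows: int = 200
) -> WhitelightFixture:
    """White-light measurement plus its manufacturer radiance table.

    The 'true' lamp profile is a smooth quadratic in wavelength; the
    measured spectrum is that profile times the model's response gain,
    sampled on the model's Raman-shift axis.
    """
    shift_per_pixel = compute_raman_shift_axis(
        model.true_coeffs, model.laser_wavelength_nm, model.n_pixels
    )
    axis = np.sort(shift_per_pixel)
    # keep strictly Stokes-side points so the wavelength conversion is defined
    axis = axis[axis > 0]
    wavelengths = raman_shift_to_wavelength(axis, model.laser_wavelength_nm)

    wl_lo, wl_hi = wavelengths.min(), wavelengths.max()
    pad = 0.02 * (wl_hi - wl_lo)
    table_wl = np.linspace(wl_lo - pad, wl_hi + pad, n_table_rows)

    def true_profile(wl):
        z = (wl - wl_lo) / (wl_hi - wl_lo)
        return 1000.0 * (0.6 + 0.8 * z - 0.5 * z**2)

    gain = model.gain_at_wavelength(wavelengths)
    measured = Spectrum(axis, true_profile(wavelengths) * gain, AxisKind.RAMAN_SHIFT)
    return WhitelightFixture(
        measured=measured,
        radiance=RadianceTable(table_wl, true_profile(table_wl)),
        gain=gain,
    )


# ---------------------------------------------------------------------------
# corrupted-file fixtures: exercise the reader/batch error paths

CORRUPT_KINDS = ("non_numeric", "too_few_rows", "duplicate_axis")


def write_corrupt_spectrum(path, kind: str) -> None:
    """Write a deliberately malformed spectrum file of the given kind."""
    from pathlib import Path

    texts = {
        "non_numeric": "900\t10\n901\tNaN?\n902\t12\n",
        "too_few_rows": "900\t10\n",
        "duplicate_axis": "900\t10\n900\t11\n901\t12\n",
    }
    if kind not in texts:
        raise ValueError(f"unknown corruption kind {kind!r}; one of {CORRUPT_KINDS}")
    Path(path).write_text(texts[kind])
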
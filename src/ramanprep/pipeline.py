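"""The deterministic eight-stage preprocessing pipeline (P1–P8).

Stages are applied in a fixed, non-reorderable sequence:

    P1  electronic-baseline shift to zero (subtract the minimum)
    P2  multiplicative spectral response correction (optional)
    P3  cosmic-ray handling — reserved stage, currently an explicit no-op
    P4  truncation to [start, stop] (default 900–1700 cm⁻¹, the
        biological fingerprint region)
    P5  binning onto a uniform grid of width Δb (default 3.5 cm⁻¹) by
        within-bin averaging
    P6  noise smoothing (Savitzky–Golay / moving average / median / none)
    P7  fluorescence background subtraction by iterative polynomial
        fitting with pointwise-minimum update (modpoly-style)
    P8  normalization by mean (default), area or maximum

``run_pipeline`` is a pure function of (spectrum, configuration, factor):
identical inputs give bit-identical outputs, and every stage — including
skipped and no-op ones — is recorded in the provenance log.
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np
from numpy.polynomial import Polynomial
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.ndimage import median_filter, uniform_filter1d
from scipy.signal import savgol_filter

from .errors import (
    BinningError,
    ConfigurationError,
    EmptyRangeError,
    FitError,
    NormalizationError,
    ParameterError,
)
from .provenance import ProvenanceLog, spectrum_hash
from .response_correction import CorrectionFactor, resample_factor
from .spectrum import Spectrum

STAGE_IDS = ("P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8")


class SmoothingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    method: Literal["savgol", "moving_average", "median", "none"] = "none"
    window: int = 5
    polyorder: int = 2

    @model_validator(mode="after")
    def _check(self):
        if self.method != "none":
            if self.window < 3 or self.window % 2 == 0:
                raise ValueError("smoothing window must be odd and >= 3")
            if self.method == "savgol" and self.polyorder >= self.window:
                raise ValueError("savgol polyorder must be < window")
        return self


class FbsConfig(BaseModel):
    """Fluorescence background subtraction (P7) parameters."""

    model_config = ConfigDict(extra="forbid")

    poly_order: int = Field(default=5, ge=0)
    max_iterations: int = Field(default=100, ge=1)
    tolerance: float = Field(default=1e-4, ge=0.0)


class PipelineConfig(BaseModel):
    """Full P1–P8 parameterization; together with the system configuration
    this determines execution completely."""

    model_config = ConfigDict(extra="forbid")

    truncate_start: float = 900.0
    truncate_stop: float = 1700.0
    bin_width: float = Field(default=3.5, gt=0.0)
    smoothing: SmoothingConfig = Field(default_factory=SmoothingConfig)
    fbs: FbsConfig = Field(default_factory=FbsConfig)
    normalization: Literal["mean", "area", "max"] = "mean"
    apply_src: bool = False
    cosmic_ray: Literal["none"] = "none"

    @model_validator(mode="after")
    def _check(self):
        if not self.truncate_start < self.truncate_stop:
            raise ValueError("truncate_start must be < truncate_stop")
        return self


def p1_baseline_subtract(s: Spectrum) -> Spectrum:
    """Shift the electronic baseline to zero: I1 = I_raw − min(I_raw)."""
    return s.with_intensity(s.intensity - s.intensity.min())


def p2_apply_src(
    s: Spectrum, cf: Optional[CorrectionFactor], apply: bool
) -> Spectrum:
    """Apply the response-correction factor multiplicatively (or bypass)."""
    if not apply:
        return s
    if cf is None:
        raise ConfigurationError("SRC application requested but no correction factor given")
    resampled = resample_factor(cf, s.axis)
    return s.with_intensity(s.intensity * resampled.factor)


def p3_cosmic_ray(s: Spectrum) -> Spectrum:
    """Reserved cosmic-ray stage: bit-identical passthrough."""
    return s


def p4_truncate(s: Spectrum, start: float, stop: float) -> Spectrum:
    """Crop to the closed interval [start, stop]."""
    mask = (s.axis >= start) & (s.axis <= stop)
    if mask.sum() < 2:
        raise EmptyRangeError(
            f"truncation to [{start}, {stop}] leaves {int(mask.sum())} point(s)"
        )
    return Spectrum(s.axis[mask], s.intensity[mask], s.axis_kind)


def p5_bin(s: Spectrum, bin_width: float) -> Spectrum:
    """Average onto a uniform grid of spacing ``bin_width``.

    Bins are half-open intervals [v0 + kΔb, v0 + (k+1)Δb) anchored at the
    first axis value; the output axis holds the bin centres
    v0 + (k+0.5)Δb and each output intensity is the arithmetic mean of
    the members. A trailing partial bin is kept if nonempty; an empty
    interior bin means the input grid is coarser than Δb and is an error.
    """
    if bin_width <= 0:
        raise ParameterError("bin width must be positive")
    v0 = s.axis[0]
    idx = np.floor((s.axis - v0) / bin_width).astype(int)
    # the last point of a closed-interval axis can land exactly on a bin
    # edge; fp-floor guard:
    n_bins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=n_bins)
    empty = np.nonzero(counts == 0)[0]
    if empty.size:
        k = int(empty[0])
        raise BinningError(
            f"bin {k} ([{v0 + k * bin_width:.3f}, {v0 + (k + 1) * bin_width:.3f})) "
            f"received no samples; input grid is coarser than Δb={bin_width}"
        )
    sums = np.bincount(idx, weights=s.intensity, minlength=n_bins)
    centers = v0 + (np.arange(n_bins) + 0.5) * bin_width
    return Spectrum(centers, sums / counts, s.axis_kind)


def p6_smooth(s: Spectrum, method: str, window: int, polyorder: int) -> Spectrum:
    """Apply the configured noise filter; ``method="none"`` passes through."""
    if method == "none":
        return s
    if window < 3 or window % 2 == 0 or window > len(s):
        raise ParameterError(
            f"window must be odd, >= 3 and <= spectrum length (got {window}, n={len(s)})"
        )
    if method == "savgol":
        if polyorder >= window:
            raise ParameterError("savgol polyorder must be < window")
        smoothed = savgol_filter(s.intensity, window, polyorder)
    elif method == "moving_average":
        smoothed = uniform_filter1d(s.intensity, size=window, mode="nearest")
    elif method == "median":
        smoothed = median_filter(s.intensity, size=window, mode="nearest")
    else:
        raise ParameterError(f"unknown smoothing method {method!r}")
    return s.with_intensity(smoothed)


def p7_fluorescence_subtract(
    s: Spectrum, poly_order: int, max_iterations: int, tolerance: float
):
    """Iterative-polynomial (modpoly-style) background subtraction.

    Starting from the spectrum itself, repeatedly fit a polynomial of
    ``poly_order`` to the working curve and replace the working curve by
    the pointwise minimum of itself and the fit — the working curve
    descends monotonically onto the lower envelope. Iteration stops when
    the sup-norm change falls below ``tolerance`` × (max − min of the
    input) or after ``max_iterations``. The final fit is the baseline,
    which is subtracted from the input.

    Returns (corrected spectrum, baseline spectrum, iterations_used).
    Polynomials are fitted on the axis mapped to [−1, 1] for conditioning.
    """
    if poly_order >= len(s):
        raise FitError(f"poly_order {poly_order} >= number of points {len(s)}")
    scale = float(s.intensity.max() - s.intensity.min())
    threshold = tolerance * scale
    working = s.intensity.astype(float).copy()
    fit_vals = working
    iterations = 0
    for iterations in range(1, max_iterations + 1):
        try:
            fit = Polynomial.fit(s.axis, working, deg=poly_order)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"degenerate baseline fit: {exc}") from exc
        fit_vals = fit(s.axis)
        updated = np.minimum(working, fit_vals)
        delta = float(np.max(np.abs(updated - working)))
        working = updated
        if delta <= threshold:
            break
    baseline = s.with_intensity(fit_vals)
    corrected = s.with_intensity(s.intensity - fit_vals)
    return corrected, baseline, iterations


def p8_normalize(s: Spectrum, method: str) -> Spectrum:
    """Normalize by mean, trapezoidal area, or maximum intensity."""
    if method == "mean":
        denom = float(np.mean(s.intensity))
    elif method == "area":
        denom = float(np.trapezoid(s.intensity, s.axis))
    elif method == "max":
        denom = float(np.max(s.intensity))
    else:
        raise ParameterError(f"unknown normalization method {method!r}")
    if denom == 0.0:
        raise NormalizationError(f"{method} normalization denominator is zero")
    return s.with_intensity(s.intensity / denom)


def run_pipeline(
    s: Spectrum,
    cfg: PipelineConfig,
    cf: Optional[CorrectionFactor] = None,
) -> tuple[Spectrum, ProvenanceLog]:
    """Run P1–P8 in fixed order, recording every stage in a provenance log.

    Skipped stages (P2 when SRC is off, P6 when smoothing is "none") and
    the P3 no-op are logged with their flags; errors carry the stage id.
    """
    log = ProvenanceLog(pipeline_config=cfg.model_dump(mode="json"))
    log.input_hash = spectrum_hash(s)
    current = s

    def _stage(stage_id, operation, params, func, skipped=False, noop=False):
        nonlocal current
        before = current
        if not skipped:
            try:
                current = func(before)
            except Exception as exc:
                raise type(exc)(f"[{stage_id}] {exc}") from exc
        log.append(stage_id, operation, params, before, current, skipped=skipped, noop=noop)

    _stage("P1", "baseline_subtract", {}, p1_baseline_subtract)
    _stage(
        "P2",
        "apply_src",
        {"apply": cfg.apply_src},
        lambda sp: p2_apply_src(sp, cf, cfg.apply_src),
        skipped=not cfg.apply_src,
    )
    _stage("P3", "cosmic_ray", {"method": cfg.cosmic_ray}, p3_cosmic_ray, noop=True)
    _stage(
        "P4",
        "truncate",
        {"start": cfg.truncate_start, "stop": cfg.truncate_stop},
        lambda sp: p4_truncate(sp, cfg.truncate_start, cfg.truncate_stop),
    )
    _stage(
        "P5",
        "bin",
        {"bin_width": cfg.bin_width},
        lambda sp: p5_bin(sp, cfg.bin_width),
    )
    _stage(
        "P6",
        "smooth",
        cfg.smoothing.model_dump(),
        lambda sp: p6_smooth(
            sp, cfg.smoothing.method, cfg.smoothing.window, cfg.smoothing.polyorder
        ),
        skipped=cfg.smoothing.method == "none",
    )
    _stage(
        "P7",
        "fluorescence_subtract",
        cfg.fbs.model_dump(),
        lambda sp: p7_fluorescence_subtract(
            sp, cfg.fbs.poly_order, cfg.fbs.max_iterations, cfg.fbs.tolerance
        )[0],
    )
    _stage(
        "P8",
        "normalize",
        {"method": cfg.normalization},
        lambda sp: p8_normalize(sp, cfg.normalization),
    )

    log.output_hash = spectrum_hash(current)
    return current, log
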
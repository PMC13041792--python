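"""The Spectrum container: an ordered axis paired with intensities.

A spectrum's axis may live in one of four coordinate systems that occur at
different points of the measurement chain:

* ``pixel`` — raw detector column index (dimensionless, 0-based);
* ``absolute_wavenumber`` — 1e7/λ of the scattered light, in cm⁻¹;
* ``raman_shift`` — laser wavenumber minus absolute wavenumber, in cm⁻¹
  (the canonical x-axis of a Raman spectrum);
* ``wavelength`` — scattered wavelength in nm.

Invariants enforced on construction: axis and intensity have equal length
of at least two, the axis is strictly increasing, and all intensities are
finite.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .errors import SpectrumValidationError


class AxisKind(str, enum.Enum):
    PIXEL = "pixel"
    ABSOLUTE_WAVENUMBER = "absolute_wavenumber"
    RAMAN_SHIFT = "raman_shift"
    WAVELENGTH = "wavelength"


@dataclass(frozen=True)
class Spectrum:
    axis: np.ndarray
    intensity: np.ndarray
    axis_kind: AxisKind = AxisKind.RAMAN_SHIFT

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "intensity", intensity)
        object.__setattr__(self, "axis_kind", AxisKind(self.axis_kind))
        if axis.ndim != 1 or intensity.ndim != 1:
            raise SpectrumValidationError("axis and intensity must be 1-D")
        if axis.size != intensity.size:
            raise SpectrumValidationError(
                f"axis length {axis.size} != intensity length {intensity.size}"
            )
        if axis.size < 2:
            raise SpectrumValidationError("spectrum needs at least 2 points")
        if not np.all(np.isfinite(axis)):
            raise SpectrumValidationError("axis contains non-finite values")
        if not np.all(np.isfinite(intensity)):
            raise SpectrumValidationError("intensity contains non-finite values")
        diffs = np.diff(axis)
        if np.any(diffs <= 0):
            raise SpectrumValidationError(
                "axis must be strictly increasing (duplicates are rejected)"
            )

    def __len__(self) -> int:
        return int(self.axis.size)

    @classmethod
    def from_unordered(
        cls, axis, intensity, axis_kind: AxisKind = AxisKind.RAMAN_SHIFT
    ) -> "Spectrum":
        """Build a spectrum from possibly descending data, sorting the axis
        ascending and reordering intensities in lockstep."""
        axis = np.asarray(axis, dtype=float)
        intensity = np.asarray(intensity, dtype=float)
        order = np.argsort(axis, kind="stable")
        return cls(axis[order], intensity[order], axis_kind)

    def with_intensity(self, intensity) -> "Spectrum":
        return Spectrum(self.axis, intensity, self.axis_kind)

    def equals(self, other: "Spectrum") -> bool:
        return (
            self.axis_kind is other.axis_kind
            and np.array_equal(self.axis, other.axis)
            and np.array_equal(self.intensity, other.intensity)
        )


@dataclass(frozen=True)
class SpectrumDialect:
    """How a delimited spectrum file is laid out on disk.

    ``delimiter``: "tab", "comma", "whitespace" or "auto" (tries the three
    in that order). ``columns``: "axis_then_intensity" or "intensity_only";
    intensity-only files get a 0-based integer pixel axis. ``header_rows``
    leading rows are skipped unconditionally.
    """

    delimiter: str = "auto"
    columns: str = "axis_then_intensity"
    header_rows: int = 0

    def __post_init__(self) -> None:
        if self.delimiter not in ("tab", "comma", "whitespace", "auto"):
            raise ValueError(f"unknown delimiter {self.delimiter!r}")
        if self.columns not in ("axis_then_intensity", "intensity_only"):
            raise ValueError(f"unknown column layout {self.columns!r}")
        if self.header_rows < 0:
            raise ValueError("header_rows must be non-negative")


DEFAULT_DIALECT = SpectrumDialect()
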
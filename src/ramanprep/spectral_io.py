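"""Readers and writers for every on-disk artifact.

Spectra travel as delimited text (two-column axis/intensity or
intensity-only), correction factors as two-column text or XLSX, processed
output as tab-delimited two-column text at full double precision, and
calibration records as MATLAB level-5 ``.mat`` containers (with a JSON
sidecar format, selected by a ``.json`` suffix, carrying the same field
names for toolchains without MAT support).

All floats are written with Python's shortest round-trip representation so
that write→read is lossless and outputs are byte-stable across runs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import scipy.io

from .calibration import CalibrationRecord
from .errors import FormatError, SpectrumValidationError
from .response_correction import CorrectionFactor
from .spectrum import DEFAULT_DIALECT, AxisKind, Spectrum, SpectrumDialect

_DELIMS = {"tab": "\t", "comma": ","}  # "whitespace" -> str.split()

# MAT / JSON field names of a calibration record. The container layout is
# artifact-defined; these names are part of the documented interface.
CALIBRATION_FIELDS = (
    "wavenumber_axis",
    "laser_wavelength_nm",
    "poly_coeffs",
    "calibration_datetime",
    "selected_peak_indices",
    "fit_rms",
)


def _tokenize(line: str, delimiter: str) -> list[str]:
    if delimiter == "whitespace":
        return line.split()
    return [t.strip() for t in line.split(_DELIMS[delimiter])]


def _parse_rows(text: str, dialect: SpectrumDialect, delimiter: str):
    """Parse into (axis, intensity) float lists; raise FormatError with the
    offending 1-based row number on any non-numeric cell."""
    want = 1 if dialect.columns == "intensity_only" else 2
    axis: list[float] = []
    intensity: list[float] = []
    lines = text.splitlines()
    for rowno, raw in enumerate(lines, start=1):
        if rowno <= dialect.header_rows:
            continue
        if not raw.strip():
            continue
        toks = _tokenize(raw, delimiter)
        toks = [t for t in toks if t != ""]
        if len(toks) < want:
            raise FormatError(
                f"row {rowno}: expected {want} column(s), got {len(toks)}"
            )
        try:
            vals = [float(t) for t in toks[:want]]
        except ValueError:
            raise FormatError(f"row {rowno}: non-numeric cell in {raw!r}") from None
        if want == 1:
            axis.append(float(len(intensity)))
            intensity.append(vals[0])
        else:
            axis.append(vals[0])
            intensity.append(vals[1])
    if len(intensity) < 2:
        raise FormatError(f"need at least 2 data rows, found {len(intensity)}")
    return axis, intensity


def read_spectrum(
    path, dialect: SpectrumDialect = DEFAULT_DIALECT, axis_kind: AxisKind | None = None
) -> Spectrum:
    """Read a delimited spectrum file.

    Descending axes are accepted and sorted ascending with intensities
    reordered in lockstep; duplicate axis values are rejected.
    Intensity-only files are given a 0-based pixel axis. ``axis_kind``
    overrides the default kind (pixel for intensity-only files, Raman shift
    otherwise).
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise OSError(f"cannot read spectrum file {path}: {exc}") from exc

    if dialect.delimiter == "auto":
        last_err: Exception | None = None
        for delim in ("tab", "comma", "whitespace"):
            try:
                axis, intensity = _parse_rows(text, dialect, delim)
                break
            except FormatError as exc:
                last_err = exc
        else:
            raise FormatError(f"{path}: no delimiter matched ({last_err})")
    else:
        axis, intensity = _parse_rows(text, dialect, dialect.delimiter)

    if axis_kind is None:
        axis_kind = (
            AxisKind.PIXEL
            if dialect.columns == "intensity_only"
            else AxisKind.RAMAN_SHIFT
        )
    try:
        return Spectrum.from_unordered(axis, intensity, axis_kind)
    except SpectrumValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_processed_spectrum(path, spectrum: Spectrum) -> None:
    """Write a processed spectrum as two-column tab-delimited text.

    Requires a Raman-shift axis (pipeline output contract). Uses shortest
    round-trip float formatting, so re-reading reproduces the values
    bit-for-bit.
    """
    if spectrum.axis_kind is not AxisKind.RAMAN_SHIFT:
        raise SpectrumValidationError(
            f"processed output must be on a Raman-shift axis, got {spectrum.axis_kind.value}"
        )
    path = Path(path)
    lines = [
        f"{float(a)!r}\t{float(i)!r}"
        for a, i in zip(spectrum.axis, spectrum.intensity)
    ]
    path.write_text("\n".join(lines) + "\n")


def write_calibration_record(path, record: CalibrationRecord) -> None:
    """Persist a calibration record.

    A ``.json`` suffix selects the JSON sidecar format; anything else is
    written as a MATLAB level-5 container. Both carry the same variable
    names (``wavenumber_axis``, ``laser_wavelength_nm``, ``poly_coeffs``
    in ascending-power order a0..a3, ``calibration_datetime`` as ISO-8601,
    ``selected_peak_indices``, ``fit_rms``).
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "wavenumber_axis": [float(v) for v in record.raman_shift_axis],
            "laser_wavelength_nm": float(record.laser_wavelength_nm),
            "poly_coeffs": [float(c) for c in record.coeffs],
            "calibration_datetime": record.calibration_datetime,
            "selected_peak_indices": [int(i) for i in record.selected_peak_indices],
            "fit_rms": float(record.fit_rms),
        }
        path.write_text(json.dumps(payload, indent=1))
        return
    scipy.io.savemat(
        str(path),
        {
            "wavenumber_axis": np.asarray(record.raman_shift_axis, dtype=float),
            "laser_wavelength_nm": float(record.laser_wavelength_nm),
            "poly_coeffs": np.asarray(record.coeffs, dtype=float),
            "calibration_datetime": record.calibration_datetime,
            "selected_peak_indices": np.asarray(
                record.selected_peak_indices, dtype=np.int64
            ),
            "fit_rms": float(record.fit_rms),
        },
    )


def read_calibration_record(path) -> CalibrationRecord:
    """Inverse of :func:`write_calibration_record` for both formats."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        missing = [k for k in CALIBRATION_FIELDS if k not in payload]
        if missing:
            raise FormatError(f"{path}: missing calibration fields {missing}")
        return CalibrationRecord(
            coeffs=np.asarray(payload["poly_coeffs"], dtype=float),
            laser_wavelength_nm=float(payload["laser_wavelength_nm"]),
            raman_shift_axis=np.asarray(payload["wavenumber_axis"], dtype=float),
            selected_peak_indices=tuple(int(i) for i in payload["selected_peak_indices"]),
            calibration_datetime=str(payload["calibration_datetime"]),
            fit_rms=float(payload["fit_rms"]),
        )
    data = scipy.io.loadmat(str(path), squeeze_me=True)
    missing = [k for k in CALIBRATION_FIELDS if k not in data]
    if missing:
        raise FormatError(f"{path}: missing calibration fields {missing}")
    return CalibrationRecord(
        coeffs=np.atleast_1d(np.asarray(data["poly_coeffs"], dtype=float)),
        laser_wavelength_nm=float(data["laser_wavelength_nm"]),
        raman_shift_axis=np.atleast_1d(np.asarray(data["wavenumber_axis"], dtype=float)),
        selected_peak_indices=tuple(
            int(i) for i in np.atleast_1d(data["selected_peak_indices"])
        ),
        calibration_datetime=str(data["calibration_datetime"]),
        fit_rms=float(data["fit_rms"]),
    )


def read_correction_factor(path, axis_unit: str = "raman_shift") -> CorrectionFactor:
    """Load a precomputed correction factor from two-column text/CSV or a
    spreadsheet (.xlsx) with axis and factor columns."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        import pandas as pd

        frame = pd.read_excel(path, header=None)
        if frame.shape[1] < 2 or frame.shape[0] < 2:
            raise FormatError(f"{path}: need two columns and at least 2 rows")
        try:
            axis = frame.iloc[:, 0].astype(float).to_numpy()
            factor = frame.iloc[:, 1].astype(float).to_numpy()
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: non-numeric cell ({exc})") from exc
    else:
        spec = read_spectrum(path)
        axis, factor = spec.axis, spec.intensity
    order = np.argsort(axis, kind="stable")
    return CorrectionFactor(axis[order], factor[order], axis_unit=axis_unit)


def write_correction_factor(path, cf: CorrectionFactor) -> None:
    """Write a correction factor as two-column tab-delimited text (the
    WL_CORR.txt-style artifact)."""
    path = Path(path)
    lines = [f"{float(a)!r}\t{float(f)!r}" for a, f in zip(cf.axis, cf.factor)]
    path.write_text("\n".join(lines) + "\n")
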
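"""System-level configuration, execution-path resolution and batch runs.

A *system configuration* (``config.json``) describes the instrument: its
type, excitation wavelength, detector geometry, and — crucially — whether
its exported spectra still need X-axis calibration and spectral response
correction. Instruments that export calibrated spectra (Renishaw-class)
bypass both automatically; intensity-only instruments require a
calibration record and, usually, a correction factor.

The *execution path* derived from the system + pipeline configurations
never reorders the P1–P8 pipeline; it only activates or bypasses stages.
Batch processing routes every file through the very same
``run_pipeline`` implementation as single-spectrum processing, so the
two are hash-identical on the same input, and per-file failures are
isolated in the batch report rather than aborting the run.

Both configuration schemas are strict: unknown keys are rejected so a
shared configuration file can never silently mean something different.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .calibration import CalibrationRecord, calibrate_spectrum
from .errors import ConfigurationError, RamanPrepError
from .pipeline import STAGE_IDS, PipelineConfig, run_pipeline
from .provenance import ProvenanceLog, record_provenance
from .response_correction import CorrectionFactor
from .spectral_io import read_spectrum, write_processed_spectrum
from .spectrum import DEFAULT_DIALECT, AxisKind, Spectrum, SpectrumDialect

SystemName = Literal["Cart", "Portable", "Renishaw", "MANTIS", "custom"]

# Instruments that export calibrated, response-corrected spectra.
_PRECALIBRATED_SYSTEMS = {"Renishaw"}


class SystemConfig(BaseModel):
    """Declarative instrument description (the config.json schema)."""

    model_config = ConfigDict(extra="forbid")

    system: SystemName
    excitation_wavelength_nm: float = Field(gt=0.0)
    detector: str = ""
    probe: str = ""
    spectral_range: tuple[float, float] = (100.0, 3400.0)  # cm-1
    ccd_x: int = Field(default=1340, ge=2)
    ccd_y: int = Field(default=100, ge=1)
    requires_calibration: Optional[bool] = None
    requires_src: Optional[bool] = None

    @model_validator(mode="after")
    def _resolve_requirements(self):
        default = self.system not in _PRECALIBRATED_SYSTEMS
        if self.requires_calibration is None:
            self.requires_calibration = default
        if self.requires_src is None:
            self.requires_src = default
        lo, hi = self.spectral_range
        if not lo < hi:
            raise ValueError("spectral_range must be an increasing interval")
        return self


@dataclass(frozen=True)
class ExecutionPath:
    """Which workflow stages run; the P1–P8 order itself is immutable."""

    run_calibration: bool
    run_src: bool
    stage_active: tuple[tuple[str, bool], ...]  # (stage_id, active) in fixed order

    @property
    def stage_ids(self) -> tuple[str, ...]:
        return tuple(sid for sid, _ in self.stage_active)


def resolve_execution_path(
    sys_cfg: SystemConfig, pipe_cfg: PipelineConfig
) -> ExecutionPath:
    """Derive the execution path from the two configurations alone.

    P2 is active iff the system requires SRC *and* the pipeline enables
    it; P6 is active iff a smoothing method is configured; P3 always runs
    as its documented no-op; everything else always runs.
    """
    run_src = bool(sys_cfg.requires_src and pipe_cfg.apply_src)
    active = {
        "P1": True,
        "P2": run_src,
        "P3": True,
        "P4": True,
        "P5": True,
        "P6": pipe_cfg.smoothing.method != "none",
        "P7": True,
        "P8": True,
    }
    return ExecutionPath(
        run_calibration=bool(sys_cfg.requires_calibration),
        run_src=run_src,
        stage_active=tuple((sid, active[sid]) for sid in STAGE_IDS),
    )


def _validation_message(exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        parts.append(f"{loc}: {err['msg']}")
    return "; ".join(parts)


def load_system_config(path) -> SystemConfig:
    """Load and strictly validate a config.json file."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ConfigurationError(f"{path}: invalid JSON ({exc})") from exc
    try:
        return SystemConfig.model_validate(payload)
    except ValidationError as exc:
        raise ConfigurationError(f"{path}: {_validation_message(exc)}") from exc


def load_pipeline_config(path) -> PipelineConfig:
    """Load and strictly validate a preprocessing.json file."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ConfigurationError(f"{path}: invalid JSON ({exc})") from exc
    try:
        return PipelineConfig.model_validate(payload)
    except ValidationError as exc:
        raise ConfigurationError(f"{path}: {_validation_message(exc)}") from exc


def save_system_config(cfg: SystemConfig, path) -> None:
    Path(path).write_text(cfg.model_dump_json(indent=1))


def save_pipeline_config(cfg: PipelineConfig, path) -> None:
    Path(path).write_text(cfg.model_dump_json(indent=1))


@dataclass(frozen=True)
class BatchEntry:
    input_path: str
    status: str  # "success" | "failed"
    output_filename: str = ""
    error: str = ""


@dataclass
class BatchReport:
    entries: list[BatchEntry] = field(default_factory=list)

    @property
    def n_success(self) -> int:
        return sum(1 for e in self.entries if e.status == "success")

    @property
    def n_fail(self) -> int:
        return sum(1 for e in self.entries if e.status == "failed")

    @property
    def failed_files(self) -> list[str]:
        return [e.input_path for e in self.entries if e.status == "failed"]


def output_filename(stem: str, pipe_cfg: PipelineConfig, timestamp: str) -> str:
    """Output naming scheme embedding the key parameters and a timestamp:
    ``<stem>__s<start>_e<stop>_b<width>_n<norm>__<timestamp>.txt``."""
    return (
        f"{stem}__s{pipe_cfg.truncate_start:g}_e{pipe_cfg.truncate_stop:g}"
        f"_b{pipe_cfg.bin_width:g}_n{pipe_cfg.normalization}__{timestamp}.txt"
    )


def process_one(
    spectrum: Spectrum,
    sys_cfg: SystemConfig,
    pipe_cfg: PipelineConfig,
    cal: Optional[CalibrationRecord] = None,
    cf: Optional[CorrectionFactor] = None,
) -> tuple[Spectrum, ProvenanceLog]:
    """Process a single spectrum along the resolved execution path.

    This is the one implementation shared by single-spectrum, preview and
    batch modes.
    """
    path = resolve_execution_path(sys_cfg, pipe_cfg)
    if path.run_calibration:
        if spectrum.axis_kind is AxisKind.PIXEL:
            if cal is None:
                raise ConfigurationError(
                    "system requires calibration but no calibration record was supplied"
                )
            spectrum = calibrate_spectrum(spectrum, cal)
        # spectra already on a shift axis are taken as externally calibrated
    if path.run_src and cf is None:
        raise ConfigurationError(
            "system requires spectral response correction but no factor was supplied"
        )
    out, log = run_pipeline(spectrum, pipe_cfg, cf if path.run_src else None)
    log.system_config = sys_cfg.model_dump(mode="json")
    return out, log


def run_batch(
    inputs,
    sys_cfg: SystemConfig,
    pipe_cfg: PipelineConfig,
    cal: Optional[CalibrationRecord] = None,
    cf: Optional[CorrectionFactor] = None,
    out_dir=None,
    dialect: SpectrumDialect = DEFAULT_DIALECT,
) -> BatchReport:
    """Process every input independently; per-file failures never abort
    the batch and are identified by name in the report."""
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    timestamp = _dt.datetime.now().strftime("%Y%m%dT%H%M%S")
    report = BatchReport()
    for input_path in inputs:
        input_path = Path(input_path)
        try:
            spectrum = read_spectrum(input_path, dialect)
            out, log = process_one(spectrum, sys_cfg, pipe_cfg, cal, cf)
            name = output_filename(input_path.stem, pipe_cfg, timestamp)
            if out_dir is not None:
                write_processed_spectrum(out_dir / name, out)
                record_provenance(log, (out_dir / name).with_suffix(".provenance.json"))
            report.entries.append(
                BatchEntry(input_path=str(input_path), status="success", output_filename=name)
            )
        except (RamanPrepError, OSError) as exc:
            report.entries.append(
                BatchEntry(input_path=str(input_path), status="failed", error=str(exc))
            )
    return report


def preview_first(
    inputs,
    sys_cfg: SystemConfig,
    pipe_cfg: PipelineConfig,
    cal: Optional[CalibrationRecord] = None,
    cf: Optional[CorrectionFactor] = None,
    dialect: SpectrumDialect = DEFAULT_DIALECT,
) -> tuple[Spectrum, ProvenanceLog]:
    """Validate settings by processing only the first file; writes nothing
    and produces exactly what that file's batch entry would."""
    inputs = list(inputs)
    if not inputs:
        raise ConfigurationError("preview requires at least one input file")
    spectrum = read_spectrum(Path(inputs[0]), dialect)
    return process_one(spectrum, sys_cfg, pipe_cfg, cal, cf)
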
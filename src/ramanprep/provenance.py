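"""Provenance recording: an ordered, replayable account of every operation.

Each pipeline stage appends an entry carrying its stage id, operation
name, the exact parameters used, content hashes of its input and output
spectra, and a timestamp. The log embeds the configuration snapshots
verbatim, so replaying the embedded configuration on the hashed input
must reproduce the hashed output — the operational definition of
reproducibility used throughout this package.

Hashes are SHA-256 digests of a canonical JSON serialization (sorted
keys, shortest round-trip float repr), making them stable across
platforms and sessions.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .spectrum import AxisKind, Spectrum


def _canonical(obj):
    """Canonicalize to JSON-safe structures with repr-formatted floats."""
    if isinstance(obj, dict):
        return {str(k): _canonical(obj[k]) for k in sorted(obj, key=str)}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_canonical(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        return repr(float(obj))
    if isinstance(obj, (np.integer, int)) and not isinstance(obj, bool):
        return int(obj)
    return obj


def canonical_hash(obj) -> str:
    payload = json.dumps(_canonical(obj), separators=(",", ":"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def spectrum_hash(spectrum: Spectrum) -> str:
    return canonical_hash(
        {
            "axis_kind": spectrum.axis_kind.value,
            "axis": spectrum.axis,
            "intensity": spectrum.intensity,
        }
    )


@dataclass(frozen=True)
class ProvenanceEntry:
    stage_id: str  # "P1".."P8" or a module id like "M1"
    operation: str
    params: dict
    input_hash: str
    output_hash: str
    timestamp: str
    skipped: bool = False  # stage bypassed by configuration
    noop: bool = False  # stage executed but defined as identity (P3)

    def to_dict(self) -> dict:
        return {
            "stage_id": self.stage_id,
            "operation": self.operation,
            "params": _canonical(self.params),
            "input_hash": self.input_hash,
            "output_hash": self.output_hash,
            "timestamp": self.timestamp,
            "skipped": self.skipped,
            "noop": self.noop,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProvenanceEntry":
        return cls(
            stage_id=d["stage_id"],
            operation=d["operation"],
            params=d["params"],
            input_hash=d["input_hash"],
            output_hash=d["output_hash"],
            timestamp=d["timestamp"],
            skipped=bool(d.get("skipped", False)),
            noop=bool(d.get("noop", False)),
        )


@dataclass
class ProvenanceLog:
    entries: list[ProvenanceEntry] = field(default_factory=list)
    pipeline_config: dict | None = None  # embedded verbatim snapshot
    system_config: dict | None = None
    input_hash: str = ""
    output_hash: str = ""

    def append(
        self,
        stage_id: str,
        operation: str,
        params: dict,
        input_spectrum: Spectrum,
        output_spectrum: Spectrum,
        skipped: bool = False,
        noop: bool = False,
    ) -> None:
        self.entries.append(
            ProvenanceEntry(
                stage_id=stage_id,
                operation=operation,
                params=dict(params),
                input_hash=spectrum_hash(input_spectrum),
                output_hash=spectrum_hash(output_spectrum),
                timestamp=_dt.datetime.now().isoformat(timespec="seconds"),
                skipped=skipped,
                noop=noop,
            )
        )

    @property
    def stage_ids(self) -> list[str]:
        return [e.stage_id for e in self.entries]

    def to_dict(self) -> dict:
        return {
            "entries": [e.to_dict() for e in self.entries],
            "pipeline_config": self.pipeline_config,
            "system_config": self.system_config,
            "input_hash": self.input_hash,
            "output_hash": self.output_hash,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProvenanceLog":
        return cls(
            entries=[ProvenanceEntry.from_dict(e) for e in d.get("entries", [])],
            pipeline_config=d.get("pipeline_config"),
            system_config=d.get("system_config"),
            input_hash=d.get("input_hash", ""),
            output_hash=d.get("output_hash", ""),
        )


def record_provenance(log: ProvenanceLog, path) -> None:
    """Serialize a provenance log as JSON alongside the processed output."""
    Path(path).write_text(json.dumps(log.to_dict(), indent=1, sort_keys=True))


def load_provenance(path) -> ProvenanceLog:
    return ProvenanceLog.from_dict(json.loads(Path(path).read_text()))


def replay(log: ProvenanceLog, input_spectrum: Spectrum, correction_factor=None):
    """Re-run the embedded pipeline configuration on ``input_spectrum`` and
    return (output_spectrum, hash_matches)."""
    from .pipeline import PipelineConfig, run_pipeline

    if log.pipeline_config is None:
        raise ValueError("log has no embedded pipeline configuration")
    cfg = PipelineConfig.model_validate(log.pipeline_config)
    out, new_log = run_pipeline(input_spectrum, cfg, correction_factor)
    return out, new_log.output_hash == log.output_hash
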
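"""Execution-path resolution, strict config schemas, batch engine and
provenance replay."""

import json

import numpy as np
import pytest

from ramanprep.errors import ConfigurationError
from ramanprep.pipeline import PipelineConfig, STAGE_IDS
from ramanprep.provenance import (
    load_provenance,
    record_provenance,
    replay,
    spectrum_hash,
)
from ramanprep.spectral_io import read_spectrum
from ramanprep.synthetic import write_corrupt_spectrum
from ramanprep.workflow import (
    SystemConfig,
    load_pipeline_config,
    load_system_config,
    output_filename,
    preview_first,
    process_one,
    resolve_execution_path,
    run_batch,
    save_pipeline_config,
    save_system_config,
)

from conftest import write_sample_files


class TestExecutionPath:
    def test_renishaw_bypasses_calibration_and_src(self, renishaw_system):
        path = resolve_execution_path(renishaw_system, PipelineConfig(apply_src=True))
        assert not path.run_calibration
        assert not path.run_src
        assert dict(path.stage_active)["P2"] is False

    def test_cart_with_src_activates_p2(self, cart_system):
        path = resolve_execution_path(cart_system, PipelineConfig(apply_src=True))
        assert path.run_calibration and path.run_src
        assert dict(path.stage_active)["P2"] is True

    def test_custom_with_flags_off_equals_renishaw_path(self, renishaw_system):
        custom = SystemConfig(
            system="custom", excitation_wavelength_nm=785.0,
            requires_calibration=False, requires_src=False,
        )
        cfg = PipelineConfig(apply_src=True)
        assert resolve_execution_path(custom, cfg).stage_active == resolve_execution_path(
            renishaw_system, cfg
        ).stage_active

    def test_stage_order_is_fixed(self, cart_system):
        path = resolve_execution_path(cart_system, PipelineConfig())
        assert path.stage_ids == STAGE_IDS


class TestConfigFiles:
    def test_pipeline_round_trip(self, tmp_path):
        cfg = PipelineConfig(truncate_start=850.0, bin_width=2.0, normalization="area")
        p = tmp_path / "preprocessing.json"
        save_pipeline_config(cfg, p)
        assert load_pipeline_config(p) == cfg

    def test_system_round_trip(self, tmp_path, cart_system):
        p = tmp_path / "config.json"
        save_system_config(cart_system, p)
        assert load_system_config(p) == cart_system

    def test_misspelled_key_rejected_by_name(self, tmp_path):
        p = tmp_path / "preprocessing.json"
        p.write_text(json.dumps({"binwdith": 3.5}))
        with pytest.raises(ConfigurationError, match="binwdith"):
            load_pipeline_config(p)

    def test_defaults_match_documented_values(self, tmp_path):
        p = tmp_path / "preprocessing.json"
        p.write_text("{}")
        cfg = load_pipeline_config(p)
        assert (cfg.truncate_start, cfg.truncate_stop, cfg.bin_width) == (900.0, 1700.0, 3.5)
        assert cfg.smoothing.method == "none"

    def test_invalid_json_reported(self, tmp_path):
        p = tmp_path / "config.json"
        p.write_text("{not json")
        with pytest.raises(ConfigurationError, match="JSON"):
            load_system_config(p)

    def test_renishaw_requirement_defaults(self):
        assert SystemConfig(system="Renishaw", excitation_wavelength_nm=785.0).requires_src is False
        assert SystemConfig(system="Cart", excitation_wavelength_nm=785.0).requires_src is True


class TestBatch:
    def test_seven_valid_spectra_all_succeed(self, tmp_path, renishaw_system, default_config):
        inputs = write_sample_files(tmp_path, 7)
        report = run_batch(inputs, renishaw_system, default_config, out_dir=tmp_path / "out")
        assert report.n_success == 7
        assert report.n_fail == 0

    def test_corrupted_file_isolated_and_named(self, tmp_path, renishaw_system, default_config):
        inputs = write_sample_files(tmp_path, 3)
        bad = tmp_path / "corrupt.txt"
        write_corrupt_spectrum(bad, "non_numeric")
        report = run_batch(inputs + [bad], renishaw_system, default_config, out_dir=tmp_path / "out")
        assert report.n_success == 3
        assert report.n_fail == 1
        assert report.failed_files == [str(bad)]
        assert report.n_success + report.n_fail == 4

    def test_batch_output_hash_equals_single_run(self, tmp_path, renishaw_system, default_config):
        inputs = write_sample_files(tmp_path, 2)
        out_dir = tmp_path / "out"
        report = run_batch(inputs, renishaw_system, default_config, out_dir=out_dir)
        for entry in report.entries:
            batch_out = read_spectrum(out_dir / entry.output_filename)
            single_out, _ = process_one(
                read_spectrum(entry.input_path), renishaw_system, default_config
            )
            assert spectrum_hash(batch_out) == spectrum_hash(single_out)

    def test_output_filename_embeds_parameters(self, default_config):
        name = output_filename("sample", default_config, "20260922T120000")
        assert name == "sample__s900_e1700_b3.5_nmean__20260922T120000.txt"

    def test_provenance_sidecar_written(self, tmp_path, renishaw_system, default_config):
        inputs = write_sample_files(tmp_path, 1)
        out_dir = tmp_path / "out"
        report = run_batch(inputs, renishaw_system, default_config, out_dir=out_dir)
        sidecar = (out_dir / report.entries[0].output_filename).with_suffix(".provenance.json")
        assert sidecar.exists()
        log = load_provenance(sidecar)
        assert log.stage_ids == list(STAGE_IDS)


class TestPreview:
    def test_preview_equals_batch_entry(self, tmp_path, renishaw_system, default_config):
        inputs = write_sample_files(tmp_path, 3)
        out_dir = tmp_path / "out"
        report = run_batch(inputs, renishaw_system, default_config, out_dir=out_dir)
        preview_out, _ = preview_first(inputs, renishaw_system, default_config)
        batch_first = read_spectrum(out_dir / report.entries[0].output_filename)
        assert spectrum_hash(preview_out) == spectrum_hash(batch_first)

    def test_preview_writes_nothing(self, tmp_path, renishaw_system, default_config):
        inputs = write_sample_files(tmp_path, 2)
        out_dir = tmp_path / "out"
        out_dir.mkdir()
        before = sorted(p.name for p in out_dir.iterdir())
        preview_first(inputs, renishaw_system, default_config)
        assert sorted(p.name for p in out_dir.iterdir()) == before

    def test_empty_input_list_rejected(self, renishaw_system, default_config):
        with pytest.raises(ConfigurationError):
            preview_first([], renishaw_system, default_config)


class TestProvenanceAndReproducibility:
    def test_replay_reproduces_output_hash(self, sample_spectrum, default_config):
        from ramanprep.pipeline import run_pipeline

        out, log = run_pipeline(sample_spectrum, default_config)
        replayed, matches = replay(log, sample_spectrum)
        assert matches
        assert replayed.equals(out)

    def test_recorded_log_round_trips_and_replays(self, tmp_path, sample_spectrum, default_config):
        from ramanprep.pipeline import run_pipeline

        _, log = run_pipeline(sample_spectrum, default_config)
        p = tmp_path / "prov.json"
        record_provenance(log, p)
        loaded = load_provenance(p)
        _, matches = replay(loaded, sample_spectrum)
        assert matches

    def test_log_lists_every_stage_including_skipped(self, sample_spectrum, default_config):
        from ramanprep.pipeline import run_pipeline

        _, log = run_pipeline(sample_spectrum, default_config)
        assert log.stage_ids == list(STAGE_IDS)
        assert any(e.skipped for e in log.entries)

    def test_embedded_config_byte_equals_source(self, tmp_path, sample_spectrum):
        from ramanprep.pipeline import run_pipeline

        p = tmp_path / "preprocessing.json"
        cfg = PipelineConfig(bin_width=4.0)
        save_pipeline_config(cfg, p)
        loaded = load_pipeline_config(p)
        _, log = run_pipeline(sample_spectrum, loaded)
        assert log.pipeline_config == json.loads(p.read_text())

    def test_two_working_directories_identical_outputs(
        self, tmp_path, renishaw_system, default_config
    ):
        # the operational reproducibility contract: same (input, configs)
        # triple, different directories, identical hashes
        inputs = write_sample_files(tmp_path / "a_in", 2)
        import shutil

        (tmp_path / "b_in").mkdir()
        copies = [shutil.copy(p, tmp_path / "b_in" / p.name) for p in inputs]
        rep_a = run_batch(inputs, renishaw_system, default_config, out_dir=tmp_path / "a_out")
        rep_b = run_batch(copies, renishaw_system, default_config, out_dir=tmp_path / "b_out")
        for ea, eb in zip(rep_a.entries, rep_b.entries):
            ha = spectrum_hash(read_spectrum(tmp_path / "a_out" / ea.output_filename))
            hb = spectrum_hash(read_spectrum(tmp_path / "b_out" / eb.output_filename))
            assert ha == hb

    def test_bypass_soundness(self, tmp_path, default_config):
        # with both requires_* flags off, supplying or omitting
        # calibration/SRC inputs must not change outputs
        from ramanprep.calibration import CalibrationRecord
        from ramanprep.response_correction import CorrectionFactor

        inputs = write_sample_files(tmp_path, 1)
        spectrum = read_spectrum(inputs[0])
        system = SystemConfig(
            system="custom", excitation_wavelength_nm=785.0,
            requires_calibration=False, requires_src=False,
        )
        cal = CalibrationRecord(
            coeffs=np.array([9390.0, 2.7, -1.5e-5, 1e-9]),
            laser_wavelength_nm=785.0,
            raman_shift_axis=np.linspace(3000, -100, len(spectrum)),
            selected_peak_indices=(0, 1, 2, 3),
            calibration_datetime="2026-01-01T00:00:00",
        )
        cf = CorrectionFactor(
            np.array([spectrum.axis[0], spectrum.axis[-1]]), np.array([1.7, 1.7])
        )
        out_bare, _ = process_one(spectrum, system, default_config)
        out_full, _ = process_one(spectrum, system, default_config, cal=cal, cf=cf)
        assert spectrum_hash(out_bare) == spectrum_hash(out_full)
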
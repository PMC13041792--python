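import numpy as np
import pytest

from ramanprep.calibration import acetaminophen_library, neon_argon_library
from ramanprep.pipeline import PipelineConfig
from ramanprep.synthetic import ForwardModel, gen_sample_spectrum
from ramanprep.workflow import SystemConfig


@pytest.fixture(scope="session")
def ne_ar_library():
    return neon_argon_library()


@pytest.fixture(scope="session")
def acet_library():
    return acetaminophen_library()


@pytest.fixture
def noiseless_model():
    return ForwardModel(noise_sigma=0.0, seed=7)


@pytest.fixture
def default_config():
    return PipelineConfig()


@pytest.fixture
def cart_system():
    return SystemConfig(system="Cart", excitation_wavelength_nm=785.0)


@pytest.fixture
def renishaw_system():
    return SystemConfig(system="Renishaw", excitation_wavelength_nm=785.0)


@pytest.fixture
def sample_spectrum():
    """A realistic synthetic sample spectrum (peaks + fluorescence + noise)."""
    return gen_sample_spectrum(ForwardModel(seed=11)).spectrum


def write_sample_files(tmp_path, n, seed0=100):
    """Write n valid two-column synthetic sample spectra; return paths."""
    from ramanprep.spectral_io import write_processed_spectrum

    tmp_path.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(n):
        fx = gen_sample_spectrum(ForwardModel(seed=seed0 + i))
        p = tmp_path / f"sample_{i:02d}.txt"
        write_processed_spectrum(p, fx.spectrum)
        paths.append(p)
    return paths
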
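import numpy as np
import pytest

from micropress import (
    CompressionRunSpec,
    SensorParams,
    VirtualCellParams,
    simulate_calibration_sweep,
)


@pytest.fixture
def sensor():
    return SensorParams(
        true_coefficient=2.0, phase_offset=30.0, adc_baseline=100.0, adc_noise_sd=0.0
    )


@pytest.fixture
def clean_sweep(sensor):
    """Noise-free 50-step rotation sweep with the standard steel ball."""
    return simulate_calibration_sweep(sensor, ball_mass=3.27e-5, n_steps=50, seed=0)


@pytest.fixture
def elastic_cell():
    """Purely elastic homogeneous cell: both compartments 5 kPa, beta = 0."""
    return VirtualCellParams(
        L0=15.0, nucleus_fraction=0.6, E0_cyto=5.0, E0_nuc=5.0,
        beta_cyto=0.0, beta_nuc=0.0,
    )


@pytest.fixture
def quiet_run():
    return CompressionRunSpec(
        speed=10.0, max_strain=0.5, sample_rate=100.0,
        include_unloading=True, force_noise_sd=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
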
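import warnings

import numpy as np
import pytest

from fdot.measurement import ProbeGeometry, default_probe_geometry
from fdot.optics import OpticalProperties
from fdot.phantom import (
    Inclusion,
    NoiseModel,
    make_calibration_exam,
    make_phantom,
    simulate_exam,
)

# diffusion-validity warnings are irrelevant noise in parameter sweeps
warnings.filterwarnings("ignore", message=".*diffusion approximation.*")

OMEGA_70MHZ = 2.0 * np.pi * 7.0e7
BACKGROUND = OpticalProperties(0.005, 1.0)


@pytest.fixture(scope="session")
def small_geometry() -> ProbeGeometry:
    """Reduced 5x5-source / 4x3-detector paddle on a 40 mm slab."""
    return default_probe_geometry(
        slab_thickness=40.0,
        wavelengths=(785.0,),
        source_grid=(5, 5),
        detector_grid=(4, 3),
        pitch=12.0,
    )


@pytest.fixture(scope="session")
def small_phantom():
    return make_phantom(
        lateral_extent=(70.0, 70.0),
        thickness=40.0,
        n_wavelengths=1,
        inclusions=[Inclusion((0.0, 0.0, 20.0), 7.5, 2.0)],
    )


@pytest.fixture(scope="session")
def exam_pair(small_geometry, small_phantom):
    """(inclusion exam, paired calibration exam) with shared channel gains,
    simulated once per session on a 2 mm mesh."""
    exam = simulate_exam(
        small_phantom,
        small_geometry,
        NoiseModel(seed=7, gain_seed=100),
        mesh_spacing=2.0,
    )
    cal = make_calibration_exam(
        BACKGROUND,
        small_geometry,
        NoiseModel(seed=8, gain_seed=100),
        mesh_spacing=2.0,
        lateral_extent=(70.0, 70.0),
    )
    return exam, cal


@pytest.fixture(scope="session")
def homogeneous_exam(small_geometry):
    """Noisy homogeneous exam sharing gains with the exam_pair calibration."""
    phantom = make_phantom(
        lateral_extent=(70.0, 70.0), thickness=40.0, n_wavelengths=1
    )
    return simulate_exam(
        phantom,
        small_geometry,
        NoiseModel(seed=9, gain_seed=100),
        mesh_spacing=2.0,
    )


@pytest.fixture(scope="session")
def clean_homogeneous_exam(small_geometry):
    """Noise-free, gain-free homogeneous exam (model-fidelity checks)."""
    phantom = make_phantom(
        lateral_extent=(70.0, 70.0), thickness=40.0, n_wavelengths=1
    )
    noise = NoiseModel(
        amplitude_noise=0.0,
        phase_noise=0.0,
        channel_gain_spread=0.0,
        channel_phase_offset_spread=0.0,
        seed=0,
    )
    return simulate_exam(phantom, small_geometry, noise, mesh_spacing=2.0)
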
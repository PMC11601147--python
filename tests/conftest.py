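import numpy as np
import pytest

import opusdmi as od


@pytest.fixture(scope="session")
def small_geometry():
    """8 sources over a 6 mm aperture, receiver central."""
    return od.make_default_probe(8, 6e-3, 0.0, 1)


@pytest.fixture(scope="session")
def small_acquisition():
    return od.AcquisitionSettings(n_time_samples=512, time_origin=0.0)


@pytest.fixture(scope="session")
def burst():
    """The study signature: four-cycle 11 MHz Hann-windowed tone burst."""
    return od.SourceSignature(kind="tone_burst", centre_frequency=11e6,
                              n_cycles=4, window="hann")


@pytest.fixture(scope="session")
def delta_signature():
    return od.SourceSignature(kind="delta")


@pytest.fixture(scope="session")
def small_grid():
    """A coarse 13×21 window around 3 mm depth."""
    return od.ImageGrid(x_extent=(-0.6e-3, 0.6e-3), z_extent=(2.5e-3, 3.5e-3),
                        dx=100e-6, dz=50e-6)


@pytest.fixture(scope="session")
def tiny_setup():
    """The smoke-scale end-to-end configuration (geometry + windows)."""
    return od.tiny_config(0)


@pytest.fixture(scope="session")
def tiny_system(tiny_setup):
    """System matrix + exact (LAPACK) factors of the smoke configuration."""
    cfg = tiny_setup
    matrix = od.build_system_matrix(cfg.geometry, cfg.grid_main,
                                    cfg.acquisition_main, cfg.signature)
    factors = od.decompose(matrix, cfg.inversion.sv_threshold)
    return matrix, factors


def relative_l2(a, b):
    return np.linalg.norm(np.ravel(a) - np.ravel(b)) / np.linalg.norm(
        np.ravel(b))
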
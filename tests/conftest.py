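import numpy as np
import pytest

from crcest import (
    AcquisitionProtocol,
    TissuePhantom,
    simulate_acquisition,
)
from crcest.kinetics import RoiTimeSeries
from crcest.phantom import cr_time_course


@pytest.fixture(scope="session")
def protocol() -> AcquisitionProtocol:
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def small_protocol() -> AcquisitionProtocol:
    """Full timing, reduced matrix, for fast image-domain tests."""
    return AcquisitionProtocol(matrix=(64, 64), fov_mm=(80.0, 80.0))


@pytest.fixture(scope="session")
def noiseless_session(small_protocol):
    """64² noiseless phantom session with realistic B0/B1 inhomogeneity."""
    phantom = TissuePhantom.default(
        matrix=small_protocol.matrix,
        seed=7,
        b0_amplitude_ppm=0.25,
        b1_range=(0.8, 1.2),
        noise_sd=0.0,
    )
    return simulate_acquisition(phantom, small_protocol, seed=7)


@pytest.fixture(scope="session")
def clean_session(small_protocol):
    """64² noiseless session with homogeneous fields (b0=0, b1=1)."""
    phantom = TissuePhantom.default(
        matrix=small_protocol.matrix,
        seed=7,
        b0_amplitude_ppm=0.0,
        b1_range=(1.0, 1.0),
        noise_sd=0.0,
    )
    return simulate_acquisition(phantom, small_protocol, seed=7)


def exact_series(rest, delta, tau, protocol=None, muscle="LG"):
    """Noiseless ROI series following the exponential recovery model."""
    protocol = protocol or AcquisitionProtocol()
    values = cr_time_course(rest, delta, tau, protocol)
    times = protocol.frame_times_s
    return RoiTimeSeries(
        muscle=muscle,
        times_s=times,
        values_pct=values,
        n_voxels=np.full(times.size, 100),
    )


@pytest.fixture
def series_factory():
    return exact_series
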
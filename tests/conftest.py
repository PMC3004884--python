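import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from mrsdss.simulate import AcquisitionSpec
from mrsdss.spectra_io import RawFID


@pytest.fixture(scope="session")
def acq() -> AcquisitionSpec:
    """Default 1.5 T acquisition: 2048 points, 2500 Hz sweep, 63.87 MHz."""
    return AcquisitionSpec()


def make_exponential_fid(
    acq: AcquisitionSpec,
    components: list[tuple[float, float, float, float]],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> RawFID:
    """Sum of damped complex exponentials: (amplitude, phase, f_hz, damping)."""
    t = np.arange(acq.n_points) * acq.dwell_time
    signal = np.zeros(acq.n_points, dtype=complex)
    for amplitude, phase, f_hz, damping in components:
        signal += amplitude * np.exp(1j * phase) * np.exp(
            (-damping + 2j * np.pi * f_hz) * t
        )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sd, size=(2, acq.n_points))
        signal = signal + noise[0] + 1j * noise[1]
    return RawFID(signal, acq.dwell_time, acq.transmitter_frequency, te=30.0)


@pytest.fixture()
def exponential_fid_factory(acq):
    def factory(components, noise_sd=0.0, seed=0):
        return make_exponential_fid(acq, components, noise_sd, seed)

    return factory
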
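import numpy as np
import pytest

from presynquant.calcium import FuraCalibration
from presynquant.trains import EvokedResponse


@pytest.fixture
def calib() -> FuraCalibration:
    """A realistic Fura-2 calibration (Kd 225 nM, typical Rmin/Rmax/beta)."""
    return FuraCalibration(Kd=225.0, Rmin=0.3, Rmax=6.0, beta=5.0)


def responses_from_amplitudes(amps, stim_times) -> list[EvokedResponse]:
    """Wrap bare amplitude/time arrays as evoked responses for the fitters."""
    return [
        EvokedResponse(
            stim_t=float(t),
            baseline=0.0,
            peak=-float(a),
            amplitude=float(a),
            index_in_train=k,
        )
        for k, (t, a) in enumerate(zip(stim_times, amps))
    ]


@pytest.fixture
def make_responses():
    return responses_from_amplitudes


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
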
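import logging

import numpy as np
import pytest

from ratiomet import synthgen as sg
from ratiomet.kinetics import RatioTrace
from ratiomet.quantify import IntensityTrace


@pytest.fixture(autouse=True)
def _quiet_generator_warnings(caplog):
    # amplitude-clip warnings are expected under the default full-activation
    # conditions; keep test output readable
    logging.getLogger("ratiomet.synthgen").setLevel(logging.ERROR)
    yield
    logging.getLogger("ratiomet.synthgen").setLevel(logging.NOTSET)


@pytest.fixture
def sensor():
    return sg.SensorParams()


@pytest.fixture
def kin():
    return sg.KineticParams()


def make_pair(i400, i480, roi=0, dt=0.5, stim_time=5.0):
    """Build an (I400, I480) IntensityTrace pair from plain arrays."""
    common = dict(roi=roi, dt=dt, stim_time=stim_time)
    return (
        IntensityTrace(values=np.asarray(i400, float), channel="ex400", **common),
        IntensityTrace(values=np.asarray(i480, float), channel="ex480", **common),
    )


def make_norm_trace(values, dt=0.5, stim_time=0.0, roi=0):
    """A RatioTrace pre-normalized to R0 = 1 (values are R/R0)."""
    values = np.asarray(values, float)
    tr = RatioTrace(r=values.copy(), dt=dt, stim_time=stim_time, roi=roi)
    tr.r0 = 1.0
    tr.r_norm = values
    return tr
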
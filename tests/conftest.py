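import numpy as np
import pytest

from frapquant import SimFrapConfig, SimJunctionConfig
from frapquant.config import POSTBLEACH, PREBLEACH
from frapquant.frap import FrapTrace


def make_trace(times, roi, cell=None, phase=None, trace_id="t0"):
    """Hand-built trace; phase defaults to prebleach for t<0, postbleach else."""
    times = np.asarray(times, dtype=float)
    if phase is None:
        phase = np.where(times < 0, PREBLEACH, POSTBLEACH)
    if cell is None:
        cell = np.full_like(times, 1000.0)
    return FrapTrace(trace_id=trace_id, times=times, roi_values=np.asarray(roi, float),
                     cell_values=np.asarray(cell, float), phase=np.asarray(phase, object))


@pytest.fixture
def noiseless_frap_config():
    return SimFrapConfig(
        prebleach_mean=1000.0, bleach_depth=0.2, mobile_fraction_true=0.5,
        tau_true=0.05, photofade_rate=0.002, noise_sd_frac=0.0, n_traces=3, seed=11,
    )


@pytest.fixture
def junction_config():
    return SimJunctionConfig(
        image_size=(512, 512), n_junctions_pos=15, n_junctions_neg=15,
        junction_intensity_pos=4.0, junction_intensity_neg=8.0,
        marker_intensity_pos=50.0, background=1.0, noise_sd=0.0, seed=4,
    )
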
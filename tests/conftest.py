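import numpy as np
import pytest

from rtquic.kinetics import CallingConfig
from rtquic.synthetic import gen_cohort, study_mimic_config
from rtquic.trace_io import annotate_traces


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Small noiseless cohort with annotated traces, plate map and truth."""
    cfg = study_mimic_config(n_an=8, n_mt=6, n_non=6, seed=42, noise_sd=0.0)
    traces, plate_map, truth = gen_cohort(cfg)
    return annotate_traces(traces, plate_map), plate_map, truth


@pytest.fixture(scope="session")
def noisy_cohort():
    cfg = study_mimic_config(n_an=8, n_mt=6, n_non=6, seed=43)
    traces, plate_map, truth = gen_cohort(cfg)
    return annotate_traces(traces, plate_map), plate_map, truth


@pytest.fixture
def percent_only_config():
    return CallingConfig(threshold_mode="percent_only")


def make_sigmoid_trace(times, baseline, plateau, lag, k=0.3, noise_sd=0.0, rng=None):
    """Raw-rfu logistic trace; lag is the 20%-of-own-plateau crossing time."""
    t50 = lag + np.log(4.0) / k
    y = baseline + plateau / (1.0 + np.exp(-k * (times - t50)))
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, size=times.shape)
    return np.maximum(y, 0.0)
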
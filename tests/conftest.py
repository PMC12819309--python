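import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import limbkine as lk

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def tt_noiseless_trial():
    """Noiseless default toe-tapping trial with its ground truth."""
    params = lk.TTGenParams().noiseless()
    return lk.generate_tt_trial(params, seed=7)


@pytest.fixture
def la_noiseless_trial():
    """Noiseless default leg-agility trial with its ground truth."""
    params = lk.LAGenParams().noiseless()
    return lk.generate_la_trial(params, seed=7)


@pytest.fixture
def tiny_cohort_params():
    """A small cohort configuration for fast end-to-end tests."""
    return lk.CohortGenParams(n_participants=3, trials_per_condition=2, seed=5)


def make_recording(pitch=None, acc_z=None, sample_rate=100.0, task="TT",
                   duration=None, **meta):
    """Build a recording from raw channel arrays for unit tests."""
    if pitch is not None:
        n = len(pitch)
    elif acc_z is not None:
        n = len(acc_z)
    else:
        n = int(round((duration or 20.0) * sample_rate))
    t = np.arange(n) / sample_rate
    if pitch is None:
        pitch = np.zeros(n)
    if acc_z is None:
        acc_z = np.full(n, 9.81)
    kwargs = dict(participant_id="T01", task=task, leg="right",
                  dominant=False, trial_index=1)
    kwargs.update(meta)
    return lk.TrialRecording(sample_rate=sample_rate, t=t,
                             pitch=np.asarray(pitch, dtype=float),
                             acc=np.asarray(acc_z, dtype=float), **kwargs)
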
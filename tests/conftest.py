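import numpy as np
import pytest

from oblfp import dataio, synthgen


@pytest.fixture(scope="session")
def short_config():
    """Canonical rates but half-second trials: full 32 x 15000 @ 30 kHz chain
    stays cheap while every downstream shape contract (129 PSD bins) holds."""
    return synthgen.SynthConfig(duration=0.5, seed=7)


@pytest.fixture(scope="session")
def tiny_trialset(short_config):
    """30 labeled trials: two odorants plus controls."""
    layout = synthgen.MainLayout(
        odor_counts={"hexanal": 10, "ethyl acetate": 10}, control_count=10)
    return dataio.assign_labels(synthgen.gen_trialset(short_config, layout))


def metadata_only_trialset(n_presence: int, n_absence: int) -> dataio.TrialSet:
    """Trial set with 1-sample signals: exercises pure metadata operations
    (labeling, balancing) at realistic trial counts without signal cost."""
    trials = []
    for i in range(n_presence):
        trials.append(dataio.TrialRecording(
            trial_id=f"odor-{i:04d}", signal=np.zeros((1, 1)), fs=1.0,
            odorant_name="hexanal", concentration=0.3, subject_id="m0"))
    for i in range(n_absence):
        trials.append(dataio.TrialRecording(
            trial_id=f"ctrl-{i:04d}", signal=np.zeros((1, 1)), fs=1.0,
            odorant_name=dataio.CONTROL_NAME, subject_id="m0"))
    return dataio.assign_labels(dataio.TrialSet(trials))
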
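import numpy as np
import pytest

from infant_erp.preprocessing import EpochSet
from infant_erp.study_design import build_montage, generate_schedule
from infant_erp.synthetic_eeg import ContinuousRecording, NoiseSpec, SimulationConfig


@pytest.fixture(scope="session")
def montage():
    return build_montage()


@pytest.fixture(scope="session")
def schedule():
    return generate_schedule(seed=1)


@pytest.fixture
def silent_recording(montage):
    """60 s of all-zero data with no events."""
    n = int(60 * montage.sampling_rate)
    data = np.zeros((len(montage.labels), n))
    return ContinuousRecording(montage=montage, data=data, events=())


@pytest.fixture
def noise_free_config():
    return SimulationConfig(seed=0, noise=NoiseSpec(rms_uv=0.0), subject_amp_sd=0.0)


def make_epochs(montage, data, conditions, t_min_ms=-200.0, modality="auditory"):
    return EpochSet(
        data=np.asarray(data, float),
        montage=montage,
        modality=modality,
        conditions=tuple(conditions),
        trial_indices=tuple(range(len(conditions))),
        t_min_ms=t_min_ms,
    )


@pytest.fixture
def flat_epochs(montage):
    """Four flat epochs, two per condition."""
    data = np.zeros((4, len(montage.labels), 425))
    return make_epochs(montage, data, ["own", "stranger", "own", "stranger"])
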
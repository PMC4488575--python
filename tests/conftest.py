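import numpy as np
import pytest

from tapentrain import (StimulusTrack, StudyDataset, TapTrial,
                        generate_stimulus_track)


@pytest.fixture
def rng():
    return np.random.default_rng(20150701)


@pytest.fixture
def isi400_track():
    return generate_stimulus_track("ISI400", 60)


@pytest.fixture
def tiny_dataset():
    """Three 3-tap test trials on an ISI400 track plus two training
    trials; small enough to verify counts by hand."""
    track = generate_stimulus_track("ISI400", 10)
    trials = [
        TapTrial(trial_id=f"t{i}", role="test",
                 onsets_ms=(0.0 + d, 400.0 + d, 800.0 + d))
        for i, d in enumerate((0.0, 30.0, 55.0))
    ]
    dataset = StudyDataset(participant_id="p1")
    dataset.sessions["ISI400"] = [(t, track) for t in trials]
    dataset.training_pool = [
        TapTrial(trial_id="tr0", role="training",
                 onsets_ms=(0.0, 410.0, 830.0)),
        TapTrial(trial_id="tr1", role="training",
                 onsets_ms=(5.0, 390.0, 900.0)),
    ]
    return dataset
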
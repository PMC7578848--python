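import numpy as np
import pytest

from eegwm.io import CHANNELS_64, build_adjacency, default_roi_map
from eegwm.segmentation import highpass, segment_acquisition
from eegwm.synthetic import generate_cohort, null_config


@pytest.fixture(scope="session")
def adjacency():
    return build_adjacency(CHANNELS_64)


@pytest.fixture(scope="session")
def roi_map():
    return default_roi_map()


@pytest.fixture(scope="session")
def tiny_cohort():
    """One participant, short segments, no planted effects."""
    cfg = null_config(
        n_participants=1,
        segment_duration_range=(8.0, 10.0),
        baseline_duration=20.0,
        seed=42,
    )
    pairs, truth = generate_cohort(cfg)
    return cfg, pairs, truth


@pytest.fixture(scope="session")
def tiny_runs(tiny_cohort):
    """Segmented, high-passed runs of the tiny cohort (visual, audiovisual)."""
    _, pairs, _ = tiny_cohort
    rec_v, rec_av = pairs[0]
    return (
        segment_acquisition(highpass(rec_v)),
        segment_acquisition(highpass(rec_av)),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
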
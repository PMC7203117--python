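import numpy as np
import pytest

from trajstyle.features import ConvFeatureExtractor
from trajstyle.simulate import ExperimentDesign, TrackLengthSpec, simulate_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_design():
    return ExperimentDesign(
        n_videos_per_condition=2,
        n_groups_per_video=2,
        n_tracks_per_group=6,
        observation_frames=60,
        track_length=TrackLengthSpec(mean=25, std=12),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_design):
    return simulate_experiment(small_design)


@pytest.fixture(scope="session")
def extractor():
    return ConvFeatureExtractor(weights="fixed_seed_random", weight_seed=0).fit()
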
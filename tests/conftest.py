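import numpy as np
import pandas as pd
import pytest

from foxcache.classification import ConfusionMatrix
from foxcache.config import SimConfig
from foxcache.synthetic import simulate_fox_season, write_fixture_files

#: pooled out-of-fold confusion matrix of the selected classifier on the
#: 660-sequence training set (rows = actual, cols = predicted, order
#: running/walking/digging/motionless)
REFERENCE_CONFUSION = np.array(
    [
        [141, 4, 1, 0],
        [5, 116, 2, 3],
        [3, 5, 37, 4],
        [3, 3, 0, 333],
    ]
)

#: training-set class counts (running, walking, digging, motionless)
TRAINING_COUNTS = {"running": 146, "walking": 126, "digging": 49, "motionless": 339}

CLOCK_OFFSET_S = 17.0


@pytest.fixture
def reference_cm() -> ConfusionMatrix:
    return ConfusionMatrix(REFERENCE_CONFUSION)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(seed=42, n_foxes=3, hours_per_fox=2.0)


@pytest.fixture(scope="session")
def small_season(small_config):
    return simulate_fox_season(small_config)


@pytest.fixture(scope="session")
def fixture_dir(small_season, tmp_path_factory):
    d = tmp_path_factory.mktemp("campaign")
    write_fixture_files(
        small_season,
        d,
        annotation_offset_s=CLOCK_OFFSET_S,
        annotated_bursts_per_fox_year=6,
    )
    return d
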
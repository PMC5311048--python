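import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import rqa_motion as rm


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two participants, two 60-s sessions each; fast but labelable."""
    config = rm.SyntheticConfig(seed=3, n_participants=2,
                                session_length_s=60.0)
    return rm.generate_cohort(config)


@pytest.fixture(scope="session")
def tiny_feature_table(tiny_cohort):
    """Feature table of the tiny cohort at a mid-grid epsilon."""
    return rm.build_feature_table(
        tiny_cohort, rm.SENSOR_POSITIONS, rm.SegmentationConfig(),
        rm.RQAConfig(0.232),
    )


def make_stream(n=120, rate=60.0, position="torso", seed=0, amplitude=0.2):
    rng = np.random.default_rng(seed)
    t = np.arange(n) / rate
    xyz = amplitude * rng.normal(size=(n, 3))
    return rm.AccelerometerStream(position, rate, t, xyz)


def make_session(duration_s=10.0, rate=60.0, intervals=(),
                 participant="p1", session="s1", seed=0):
    n = int(round(duration_s * rate))
    streams = {
        pos: make_stream(n, rate, pos, seed=seed + k)
        for k, pos in enumerate(rm.SENSOR_POSITIONS)
    }
    return rm.Session(participant, session, streams,
                      rm.AnnotationTrack(list(intervals)))
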
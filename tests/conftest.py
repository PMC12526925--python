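import numpy as np
import pytest

import physioclust as pc


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 subjects x 6 activities, 9 s, default separabilities."""
    cfg = pc.CohortConfig(n_subjects=3, duration_s=9.0, seed=7)
    return cfg, pc.generate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_preprocessed(tiny_cohort):
    _, trials = tiny_cohort
    return [pc.preprocess_trial(t) for t in trials]


@pytest.fixture()
def mean_subject():
    """Population-mean subject (zero separability draw)."""
    return pc.sample_subject_params("S_mean", 0.0, 0)


def make_channel(samples, kind=pc.ChannelKind.ACC_Y, rate=100.0, units="g"):
    return pc.SignalChannel(kind=kind, samples=np.asarray(samples, float), rate=rate, units=units)


@pytest.fixture(scope="session")
def channel_factory():
    return make_channel
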
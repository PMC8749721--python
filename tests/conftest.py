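import numpy as np
import pytest

from biopad import ppg_pipeline, synth_stream


@pytest.fixture(scope="session")
def vr_session():
    """The default 6-minute VR paradigm session (seed 1)."""
    cfg = synth_stream.default_session_config(seed=1)
    record, truth = synth_stream.gen_session(cfg)
    return cfg, record, truth


@pytest.fixture(scope="session")
def vr_session_cleaned(vr_session):
    """Same session with the red PPG channel RLS-cleaned."""
    _, record, _ = vr_session
    return ppg_pipeline.rls_cancel(record.ppg[:, 0], record.accel)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
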
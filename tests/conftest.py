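import warnings

import numpy as np
import pytest

from pupwake.pipeline import score_session
from pupwake.synthgen import GeneratorConfig, generate_session

warnings.filterwarnings("ignore", message="EMG band clamped")


@pytest.fixture(scope="session")
def p15_scored():
    """A mid-length P15 session without stimuli, with its scored hypnogram."""
    cfg = GeneratorConfig.for_age("P15", duration=6000.0, seed=3, stim_enabled=False)
    session, truth = generate_session(cfg)
    hyp, feats = score_session(session)
    return cfg, session, truth, hyp


@pytest.fixture(scope="session")
def p15_stim_scored():
    """A P15 session with the stimulation protocol enabled, scored."""
    cfg = GeneratorConfig.for_age("P15", duration=6000.0, seed=11)
    session, truth = generate_session(cfg)
    hyp, _ = score_session(session)
    return cfg, session, truth, hyp


@pytest.fixture(scope="session")
def adult_stim_scored():
    cfg = GeneratorConfig.for_age("adult", duration=4000.0, seed=7)
    session, truth = generate_session(cfg)
    hyp, _ = score_session(session)
    return cfg, session, truth, hyp


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
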
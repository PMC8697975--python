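import numpy as np
import pytest

import ftfa


@pytest.fixture(scope="session")
def tiny_session():
    """A small 2-run synthetic session shared by I/O and pipeline tests."""
    rec, events, effects = ftfa.demo_session(seed=5, n_runs=1, trials_per_condition_per_run=3)
    return rec, events, effects


@pytest.fixture(scope="session")
def tiny_tfr(tiny_session):
    rec, events, _ = tiny_session
    epochs = ftfa.epoch_extract(rec, events, -2.0, 4.0)
    tfr = ftfa.compute_tfr(epochs, np.arange(5.0, 31.0, 5.0))
    return ftfa.baseline_normalize(tfr, (-2.0, 0.0), "ratio"), ftfa.group_trials(epochs)
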
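import numpy as np
import pytest

from gart.simulate import simulate_session


@pytest.fixture(scope="session")
def small_session():
    """One simulated participant with short blocks (2 x 30 s phases).

    Session-scoped: several I/O and battery tests share it read-only.
    """
    sess, truths = simulate_session(
        participant_id="p00", group="ADHD", seed=11,
        n_phases=2, phase_seconds=30.0, include_eeg=False,
    )
    return sess, truths


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
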
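import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ground_truth():
    from statecode.synthetic import default_ground_truth

    return default_ground_truth()


@pytest.fixture(scope="session")
def decoded_session(ground_truth):
    """A short synthetic envelope session with a fitted 3-state HMM."""
    from statecode import states, synthetic

    labels, obs = synthetic.simulate_state_sequence(ground_truth, 8000, seed=11)
    fit = states.fit_hmm(obs, 3, seed=0, n_restarts=3)
    band_index = np.tile(np.arange(4), 3)
    seq = states.decode_and_label(fit, obs, band_index=band_index)
    return {"labels": labels, "obs": obs, "fit": fit, "seq": seq, "band_index": band_index}
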
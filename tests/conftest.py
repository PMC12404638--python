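import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_session():
    """A small but complete synthetic session shared across tests."""
    from spikereadout import simulate_session

    return simulate_session(
        n_single=12, n_repeat_stimuli=5, n_repeats=6,
        duration_mean=1.0, n_units=8, n_layers=3, seed=11,
    )


@pytest.fixture(scope="session")
def tiny_reliability(tiny_session):
    from spikereadout import ReliabilityAnalysis

    repeat = {
        u: tiny_session.responses.repeat_responses(u, tiny_session.schedule)
        for u in tiny_session.responses.unit_ids
    }
    return ReliabilityAnalysis(repeat).fit(R=1500, seed=5)
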
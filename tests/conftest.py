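import pytest
from hypothesis import HealthCheck, settings

from repstream import build_session, default_params, simulate_session
from repstream.detect import score_session, scores_frame

settings.register_profile(
    "repstream",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repstream")


@pytest.fixture(scope="session")
def session_design():
    """One full 12-block session, shared read-only across tests."""
    return build_session(participant_id=0, seed=20240915)


@pytest.fixture(scope="session")
def observer_params():
    return default_params()


@pytest.fixture(scope="session")
def simulated_session(session_design, observer_params):
    """Design + simulated presses/memory + scored detection table."""
    logs, responses = simulate_session(session_design, observer_params,
                                       seed=11)
    scores = score_session(session_design, logs)
    return {
        "design": session_design,
        "logs": logs,
        "responses": responses,
        "scores": scores,
        "scores_df": scores_frame(scores),
    }

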
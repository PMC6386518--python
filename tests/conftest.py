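"""Shared fixtures: small synthetic sessions reused across test modules."""

import numpy as np
import pytest

from ripplesift.synth import (
    control_spec,
    epileptic_spec,
    simulate_session,
)


@pytest.fixture(scope="session")
def default_session():
    """Default two-class epileptic session (rest / forage / rest), seed 1."""
    return simulate_session(epileptic_spec(seed=1))


@pytest.fixture(scope="session")
def control_session():
    """Ripple-only control session used as classification reference."""
    spec = control_spec(
        epochs=(("rest", 300.0), ("forage", 300.0)), seed=2
    )
    return simulate_session(spec)


@pytest.fixture(scope="session")
def detected_events(default_session):
    from ripplesift.detect import detect_events

    return detect_events(default_session.lfp_pyr, default_session.epochs)


@pytest.fixture(scope="session")
def control_features(control_session):
    from ripplesift.classify import extract_features_table
    from ripplesift.detect import detect_events

    ses = control_session
    events = detect_events(ses.lfp_pyr, ses.epochs)
    return extract_features_table(ses.lfp_pyr, events)


@pytest.fixture(scope="session")
def labeled_session(default_session, detected_events, control_features):
    """Default session with events classified against the control reference."""
    from ripplesift.classify import classify_events

    feats = classify_events(
        default_session.lfp_pyr, detected_events, control_features
    )
    return default_session, detected_events, feats


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
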
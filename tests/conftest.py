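"""Shared fixtures: small synthetic objects generated at test time."""

import numpy as np
import pytest

from voltkit.datamodel import Movie, StimulusEvent, StimulusProtocol, Trace


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def simple_protocol():
    """Two brief stimulation events, 1 s apart."""
    return StimulusProtocol([
        StimulusEvent(onset=1.0, duration=0.001, kind="efs_pulse"),
        StimulusEvent(onset=2.0, duration=0.001, kind="efs_pulse"),
    ])


@pytest.fixture
def flat_movie():
    """20-frame 8×8 movie at a constant background level of 100 counts."""
    return Movie(np.full((20, 8, 8), 100.0), rate=200.0)


def make_trace(values, rate=1000.0, **kw) -> Trace:
    return Trace(np.asarray(values, dtype=float), rate, **kw)
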
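"""Shared fixtures: tiny hand-written logs and a cached simulated dataset."""

import numpy as np
import pytest

from synchar import synth_home
from synchar.io_events import read_event_log
from synchar.windowing import EncodingSpec, build_dataset

THREE_LINE_LOG = """\
2010-01-01 00:00:00.000 M001 ON Kitchen_Activity begin
2010-01-01 00:00:01.500 M001 OFF
2010-01-01 00:00:02.250 T001 21.5 Kitchen_Activity end
"""

SENSOR_MAP = {"M001": "kitchen", "M002": "bath", "T001": "kitchen"}


@pytest.fixture
def three_line_log():
    return read_event_log(THREE_LINE_LOG, dialect="casas", sensor_map=SENSOR_MAP)


@pytest.fixture(scope="session")
def milan_sim():
    """Two simulated days of the milan-like home, full ground truth."""
    cfg = synth_home.SimulationConfig(preset="milan_like", days=2, seed=7)
    log, segments = synth_home.generate(cfg)
    return log, segments


@pytest.fixture(scope="session")
def milan_dataset(milan_sim):
    """Encoded train/val/test splits at the scaled experiment resolution
    (8 slots per window, 60 s hop)."""
    log, segments = milan_sim
    spec = EncodingSpec.from_log(log, T=8)
    return build_dataset(log, spec, seed=7, step_ms=60_000, segments=segments)


@pytest.fixture
def tiny_net_rng():
    return np.random.default_rng(42)
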
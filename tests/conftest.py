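"""Shared fixtures: surrogate recordings, templates and event series.

Everything is generated programmatically with fixed seeds; the expensive
objects are session-scoped so the suite builds them once.
"""

import numpy as np
import pytest

from ratefab.io_fixtures import (
    SurrogateSpec,
    generate_respiration_events,
    generate_surrogate_recording,
)
from ratefab.rate_template import RateTemplate, build_template, rescale_to_rate


@pytest.fixture(scope="session")
def pc_train_115s():
    """A 115-s Purkinje-cell-like surrogate recording (~65 Hz, LV 0.31)."""
    return generate_surrogate_recording(
        SurrogateSpec(64.9, 0.31, 0.10, 1.0, duration=115.0, seed=11)
    )


@pytest.fixture(scope="session")
def master_115s(pc_train_115s):
    return build_template(pc_train_115s)


@pytest.fixture(scope="session")
def pc_train_20s():
    return generate_surrogate_recording(
        SurrogateSpec(64.9, 0.31, 0.10, 1.0, duration=20.0, seed=11)
    )


@pytest.fixture(scope="session")
def master_20s(pc_train_20s):
    return build_template(pc_train_20s)


@pytest.fixture(scope="session")
def master_mf_20s(master_20s):
    return rescale_to_rate(master_20s, 20.4)


@pytest.fixture(scope="session")
def events_20s():
    return generate_respiration_events(duration=20.0, seed=7)


@pytest.fixture(scope="session")
def events_115s():
    return generate_respiration_events(duration=115.0, seed=7)


@pytest.fixture()
def constant_template():
    """Constant 64.9 Hz template over 115 s."""
    return RateTemplate(dt=1e-3, values=np.full(115000, 64.9), duration=115.0)
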
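"""Shared fixtures: expensive steady states are computed once per session.

The stored reference fixture (package data) provides a cheap starting
state for unit tests; the acceptance tests pace from the documented
initial conditions from scratch.
"""

from __future__ import annotations

import numpy as np
import pytest

from ordsim import constants as C
from ordsim.integrator import steady_state_pace
from ordsim.io import load_fixtures
from ordsim.model import State, make_params


@pytest.fixture(scope="session")
def ref_state_1000() -> State:
    """Stored endo steady state at CL 1000 ms (reference fixture)."""
    fx = load_fixtures()
    return State(np.array(fx["endo_ss_cl1000"]["state"]))


@pytest.fixture(scope="session")
def endo_params():
    return make_params("endo")


@pytest.fixture(scope="session")
def accept_ss1000():
    """Endo cell paced from the documented initial conditions at CL=1000 ms
    for up to 1000 beats (the published beat count for steady state)."""
    return steady_state_pace(make_params("endo"), 1000.0, max_beats=1000)


@pytest.fixture(scope="session")
def accept_ss2000(accept_ss1000):
    return steady_state_pace(make_params("endo"), 2000.0,
                             start_state=accept_ss1000.state, max_beats=600)
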
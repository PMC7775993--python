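"""Shared fixtures: short schedules and a reduced dictionary.

Physics tests run on a 200-pulse schedule and an every-3rd-point relaxation
grid; both keep the full piecewise structure of the defaults while staying
desk-scale.  Session-scoped fixtures are built once per run.
"""

import numpy as np
import pytest

from mrfmorph.dictionary import build_dictionary, build_grid, compress, decimate_grid
from mrfmorph.schedule import build_schedule


@pytest.fixture(scope="session")
def short_schedule():
    """200-pulse triangular schedule, paper timing (TR 12 ms, TE 0.5 ms)."""
    return build_schedule(
        n_pulses=200, ramp_up_len=100, ramp_down_len=50, n_segments=8
    )


@pytest.fixture(scope="session")
def full_schedule():
    """The default 880-pulse / 56-segment acquisition."""
    return build_schedule()


@pytest.fixture(scope="session")
def reduced_grid():
    return decimate_grid(build_grid(), 3)


@pytest.fixture(scope="session")
def reduced_dictionary(reduced_grid, short_schedule):
    return build_dictionary(reduced_grid, short_schedule)


@pytest.fixture(scope="session")
def compressed_dictionary(reduced_dictionary):
    return compress(reduced_dictionary, rank=10)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)
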
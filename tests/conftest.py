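"""Shared fixtures: session-scoped synthetic ensembles and trajectories."""

import numpy as np
import pytest

from zipperjunction.synthetic_data import gen_bj_ensemble, gen_sequence, preset_trace
from zipperjunction.trace_analysis import set_displacement_origin
from zipperjunction.zipper_sim import Duplex, Protocol, ZipperParams, kmc_run


@pytest.fixture(scope="session")
def ens90_noisy():
    """500 originated 90-mer-preset traces with default noise."""
    ens = gen_bj_ensemble(preset_trace("90mer"), 500, seed=1)
    return [set_displacement_origin(tr) for tr in ens]


@pytest.fixture(scope="session")
def duplex90():
    return Duplex.from_sequence(gen_sequence(90, 0.5, seed=1))


@pytest.fixture(scope="session")
def traj90(duplex90):
    """One default pull-hold-return trajectory of the 90-bp duplex."""
    return kmc_run(duplex90, ZipperParams(), Protocol(), seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
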
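"""Shared fixtures; the heavy chain / X-network runs are session-scoped.

All simulations use the study's standard numerical protocol (adaptive
RK 4/5 at tolerance 1e-10, zero initial state, transient 300, output step
0.01) at full window length T = 5e4 unless a test needs a variant.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from antisync import SolverConfig, run_basic_chain, run_x_network

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from antisync.fixtures import AnticipationProfile, BurstModel, make_burst_train


@pytest.fixture(scope="session")
def chain_n0():
    """Direct master-slave coupling, full-length run."""
    return run_basic_chain(0)


@pytest.fixture(scope="session")
def chain_n3():
    """Three-intermediary chain, full-length run."""
    return run_basic_chain(3)


@pytest.fixture(scope="session")
def chain_n3_loose_tol():
    """Three-intermediary chain at tolerance 1e-6 over a 5e3 window."""
    return run_basic_chain(
        3, SolverConfig(rel_tolerance=1e-6, abs_tolerance=1e-6, T_total=5e3)
    )


@pytest.fixture(scope="session")
def fig3_runs():
    """The anticipation / no-anticipation X-network pair."""
    return (
        run_x_network("fig3_anticipation"),
        run_x_network("fig3_no_anticipation"),
    )


@pytest.fixture()
def burst_fixture_pair():
    """Synthetic bursting master train + slave with a two-level
    anticipation profile (low ISIs -> 0.7, high ISIs -> 0.4)."""
    master, seg = make_burst_train(
        BurstModel(n_bursts=8, intra_isis=(2.0, 1.6, 1.6, 2.0), inter_burst_gap=40.0),
        neuron_id="master",
    )
    profile = AnticipationProfile(
        steps=((0.0, 10.0, 0.7), (10.0, 1e9, 0.4)), first_spike=0.4
    )
    return master, seg, profile
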
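"""Shared fixtures: the HeLa wild-type table and the selected network."""

from __future__ import annotations

import numpy as np
import pytest

import burstex as bx


@pytest.fixture(scope="session")
def hela():
    return bx.hela_wildtype()


@pytest.fixture(scope="session")
def selected(hela):
    """(topology, rates) of the unique pruning survivor."""
    survivor, _results = bx.select_network(hela)
    return survivor.topology, survivor.rates


@pytest.fixture(scope="session")
def wt_steady(hela, selected):
    topo, rates = selected
    return bx.steady_state(topo, rates, hela)


@pytest.fixture(scope="session")
def all_cycle_results(hela):
    """Inference results for all 24 cycles, with stage-2 flags filled in."""
    results = [bx.infer_rates(t, hela) for t in bx.enumerate_cycles()]
    bx.prune(results, hela)
    return results


def assert_exclusion(traj):
    """No two legs on one site; left < right for every loaded extruder."""
    for t in range(traj.legs.shape[0]):
        legs = traj.legs[t]
        loaded = legs[:, 0] >= 0
        assert (legs[loaded, 0] < legs[loaded, 1]).all(), f"leg inversion at frame {t}"
        sites = np.concatenate([legs[loaded, 0], legs[loaded, 1]])
        assert len(sites) == len(np.unique(sites)), f"site shared by two legs at frame {t}"
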
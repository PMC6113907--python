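"""Shared fixtures.

The expensive coupled-islet simulations are computed once per session and
shared across tests: a bimodal hub/non-hub inhibition series, a unimodal
hub series, a SERCA-reduced series and a small species panel.  Scales
(islet size, epoch lengths, fraction grids) are chosen so the whole suite
runs on one CPU in well under half an hour while preserving the
directional physiology being tested.
"""

from __future__ import annotations

import numpy as np
import pytest

from islethub.architecture import generate_human_like, generate_mouse_like
from islethub.assembly import assemble_network
from islethub.engine import (SimulationProtocol, nested_inhibition_sets,
                             run_protocol)

# desk-scale study conditions shared by the heavy fixtures
N_CELLS = 120
FRACTIONS = (0.0, 2.5, 5.0, 7.5)
PROTOCOL = SimulationProtocol(equilibration_s=40.0, baseline_s=30.0,
                              inhibition_s=30.0, recovery_s=0.0, rtol=1e-5)
SPECIES_N_CELLS = 240
SPECIES_FRACTIONS = (0.0, 2.0, 4.0)
SPECIES_PROTOCOL = SimulationProtocol(equilibration_s=30.0, baseline_s=25.0,
                                      inhibition_s=25.0, recovery_s=0.0,
                                      rtol=1e-5)


def run_series(network, fractions, target, protocol, rng_seed=0):
    """Inhibition series that reuses the shared 0% baseline run."""
    sets = nested_inhibition_sets(network, fractions, target, rng_seed)
    results = []
    for cells in sets:
        results.append(run_protocol(
            network, protocol.with_(inhibited=tuple(int(c) for c in cells))))
    return results


@pytest.fixture(scope="session")
def mouse_arch():
    return generate_mouse_like(N_CELLS, rng_seed=0)


@pytest.fixture(scope="session")
def bimodal_runs(mouse_arch):
    """Hub and non-hub inhibition series on one bimodal mouse-like islet."""
    net = assemble_network(mouse_arch, master_seed=0, gj_mode="bimodal")
    baseline = run_protocol(net, PROTOCOL)
    out = {"network": net, "fractions": FRACTIONS, "protocol": PROTOCOL,
           "results": {}}
    for target in ("hub", "nonhub"):
        sets = nested_inhibition_sets(net, FRACTIONS[1:], target, 0)
        series = [baseline] + [
            run_protocol(net, PROTOCOL.with_(
                inhibited=tuple(int(c) for c in cells)))
            for cells in sets]
        out["results"][target] = series
    return out


@pytest.fixture(scope="session")
def unimodal_hub_runs(mouse_arch):
    """Hub inhibition series with unimodal gap junctions (same islet)."""
    net = assemble_network(mouse_arch, master_seed=0, gj_mode="unimodal")
    sets = nested_inhibition_sets(net, FRACTIONS[1:], "hub", 0)
    series = [run_protocol(net, PROTOCOL)] + [
        run_protocol(net, PROTOCOL.with_(
            inhibited=tuple(int(c) for c in cells)))
        for cells in sets]
    return {"network": net, "fractions": FRACTIONS, "results": series}


@pytest.fixture(scope="session")
def serca_reduced_runs(mouse_arch):
    """Hub and non-hub series with the maximal SERCA flux reduced by 40%."""
    net = assemble_network(mouse_arch, master_seed=0, gj_mode="bimodal",
                           p_serca_scale=0.6)
    baseline = run_protocol(net, PROTOCOL)
    out = {"network": net, "fractions": FRACTIONS, "results": {}}
    for target in ("hub", "nonhub"):
        sets = nested_inhibition_sets(net, FRACTIONS[1:], target, 0)
        out["results"][target] = [baseline] + [
            run_protocol(net, PROTOCOL.with_(
                inhibited=tuple(int(c) for c in cells)))
            for cells in sets]
    return out


@pytest.fixture(scope="session")
def species_runs():
    """Hub-inhibition series for size-matched mouse- and human-like islets.

    Clustered architectures need enough cells for several sub-clusters, so
    the species panel uses larger islets than the other fixtures.
    """
    out = {"fractions": SPECIES_FRACTIONS, "mouse": [], "human": []}
    seed = 1000
    for species, gen in (("mouse", generate_mouse_like),
                         ("human", generate_human_like)):
        arch = gen(SPECIES_N_CELLS, rng_seed=seed)
        net = assemble_network(arch, master_seed=seed, gj_mode="bimodal")
        series = run_series(net, SPECIES_FRACTIONS, "hub",
                            SPECIES_PROTOCOL, rng_seed=seed)
        out[species].append(series)
    return out


@pytest.fixture(scope="session")
def recovery_run(bimodal_runs):
    """One run with a recovery epoch after clamping 6% of the islet (hubs)."""
    net = bimodal_runs["network"]
    sets = nested_inhibition_sets(net, [6.0], "hub", 0)
    proto = PROTOCOL.with_(recovery_s=30.0,
                           inhibited=tuple(int(c) for c in sets[0]))
    return run_protocol(net, proto)
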
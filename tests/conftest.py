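"""Shared fixtures: synthetic structures and their derived networks.

Everything is generated programmatically at session scope; no coordinate
files ship with the tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from tcrflex.constraint_network import apply_energy_cutoff, build_network
from tcrflex.geomsim import SimParams, build_templates, run_geometric_simulation
from tcrflex.rigidity import pebble_game
from tcrflex.structure_model import LoopDefinition
from tcrflex.synthetic_data import (
    ToySpec,
    add_obstacle_wall,
    make_conformer_pair,
    make_hairpin_scaffold,
    make_lattice_fixture,
    make_two_domain_chain,
)


@pytest.fixture(scope="session")
def hairpin():
    return make_hairpin_scaffold(ToySpec())


@pytest.fixture(scope="session")
def hairpin_loop(hairpin):
    _, truth = hairpin
    lo, hi = truth["loop_range"]
    return LoopDefinition("loop", "A", lo, hi)


@pytest.fixture(scope="session")
def hairpin_network(hairpin):
    st, _ = hairpin
    return apply_energy_cutoff(build_network(st), -3.0)


@pytest.fixture(scope="session")
def hairpin_decomposition(hairpin_network):
    return pebble_game(hairpin_network)


@pytest.fixture(scope="session")
def hairpin_templates(hairpin, hairpin_decomposition, hairpin_network):
    st, _ = hairpin
    return build_templates(st, hairpin_decomposition, hairpin_network)


@pytest.fixture(scope="session")
def two_domain():
    return make_two_domain_chain(ToySpec(two_domain=True))


@pytest.fixture(scope="session")
def lattice_fixture():
    return make_lattice_fixture(ToySpec(cell=(0.0, 0.0, 0.0, 90.0, 90.0, 90.0)))


@pytest.fixture(scope="session")
def flap_field(hairpin, hairpin_loop):
    """Unit displacement field along the hairpin loop's hinge flap."""
    st, _ = hairpin
    base, flapped = make_conformer_pair(st, hairpin_loop, 2.0)
    field = flapped.coords_array() - base.coords_array()
    return field / np.linalg.norm(field)


@pytest.fixture(scope="session")
def paired_obstacle_runs(hairpin, hairpin_loop, hairpin_network, hairpin_templates, flap_field):
    """Obstacle-free and wall-obstructed runs of the same loop-flap motion.

    The rigid core is pinned in both runs (as a lattice would hold it), so
    the loop is the only mover and the paired comparison isolates the
    obstacle's effect.
    """
    st, truth = hairpin
    net, tmpl = hairpin_network, hairpin_templates
    lo, hi = truth["loop_range"]
    res = np.array([a.res_seq for a in net.atoms])
    core_pin = np.flatnonzero(~((res >= lo) & (res <= hi)))
    params = SimParams(max_frames=250)
    free = run_geometric_simulation(st, tmpl, net, flap_field, 1, params, pinned=core_pin)

    disp = np.linalg.norm(free.final_frame - st.coords_array(), axis=1)
    k = int(np.argmax(disp))
    start, end = st.coords_array()[k], free.final_frame[k]
    normal = (end - start) / np.linalg.norm(end - start)
    obs_st, wall_idx = add_obstacle_wall(
        st, 0.5 * (start + end), normal, half_extent=8.0, spacing=1.5
    )
    obs_net = apply_energy_cutoff(build_network(obs_st), -3.0)
    obs_tmpl = build_templates(obs_st, pebble_game(obs_net), obs_net)
    obs_field = np.vstack([flap_field, np.zeros((len(wall_idx), 3))])
    pinned = np.concatenate([core_pin, wall_idx])
    obstructed = run_geometric_simulation(
        obs_st, obs_tmpl, obs_net, obs_field, 1, params, pinned=pinned
    )
    return {
        "free": free,
        "obstructed": obstructed,
        "obstructed_network": obs_net,
        "obstructed_templates": obs_tmpl,
        "pinned": pinned,
        "core_pin": core_pin,
    }
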
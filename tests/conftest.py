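"""Shared fixtures.

The heavy session fixtures (three-ratio deployment and the four pulsatile
flow solutions) drive the deployment- and flow-level tests as well as the
acceptance checks; they are computed once per session at the default
desk-scale settings.
"""

from __future__ import annotations

import numpy as np
import pytest

from archstent.anatomy import (AnatomyConfig, build_dissected_aorta,
                               largest_inscribed_sphere_diameter)
from archstent.deployment import crimp_radial, release_and_expand
from archstent.lbm import LatticeConfig, run_pulsatile_lbm, voxelize
from archstent.materials import AORTIC_WALL, scale_flap_stiffness
from archstent.stent import DEFAULT_DESIGN, build_stent
from archstent.waveforms import inlet_velocity_spec, pressure_outlet_spec

STIFFNESS_RATIOS = (1.0, 0.1, 0.01)
TEST_LATTICE = LatticeConfig(dx=2.0e-3, tau=0.75, u_lat_peak=0.05,
                             n_cycles=3, samples_per_cycle=12)


@pytest.fixture(scope="session")
def aorta():
    return build_dissected_aorta(AnatomyConfig())


@pytest.fixture(scope="session")
def straight_tube():
    return build_dissected_aorta(AnatomyConfig(
        arch_radius=float("inf"), ascending_length=60.0, descending_length=60.0,
        branch_positions=(), branch_diameters=()))


@pytest.fixture(scope="session")
def stent_pair():
    return build_stent(DEFAULT_DESIGN)


@pytest.fixture(scope="session")
def crimped_state(aorta, stent_pair):
    mesh, sutures = stent_pair
    target = largest_inscribed_sphere_diameter(aorta)
    state, record = crimp_radial(mesh, target_diameter=target, sutures=sutures)
    return state, record


@pytest.fixture(scope="session")
def deployed_states(aorta, crimped_state):
    state, _ = crimped_state
    out = {}
    for ratio in STIFFNESS_RATIOS:
        out[ratio] = release_and_expand(
            state, aorta, scale_flap_stiffness(AORTIC_WALL, ratio))
    return out


@pytest.fixture(scope="session")
def flow_fields(aorta, deployed_states):
    inlet = inlet_velocity_spec()
    outlet = pressure_outlet_spec("constant")
    fields = {}
    models = {"non-stented": aorta}
    for r, st in deployed_states.items():
        models[f"1:{r:g}"] = st.aorta
    for name, model in models.items():
        lat = voxelize(model, TEST_LATTICE.dx)
        fields[name] = run_pulsatile_lbm(lat, inlet, outlet,
                                         config=TEST_LATTICE)
    return fields


@pytest.fixture(scope="session")
def inlet_waveform():
    return inlet_velocity_spec()
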
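"""Shared fixtures: geometries, field solutions and neurons reused across tests.

Expensive artifacts (field solves, the standoff batch) are session-scoped so
each is computed once for the whole run.
"""

import numpy as np
import pytest

import retfield as rf
from retfield.geometry import SyntheticRetinaConfig, make_synthetic_retina
from retfield.layout import make_argus2_layout
from retfield.pipeline import RunConfig, _solve_electrode
from retfield.population import NeuronBuildParams, build_neuron


@pytest.fixture(scope="session")
def layout():
    return make_argus2_layout()


@pytest.fixture(scope="session")
def flat_geometry():
    """Flat retina: 200 µm thickness, 100 µm standoff, no noise or tilt."""
    return make_synthetic_retina(SyntheticRetinaConfig(
        standoff_um=100.0, thickness_sd_um=0.0, surface_relief_um=0.0, seed=0))


@pytest.fixture(scope="session")
def homogeneous_quarter_solutions(layout):
    """Quarter-domain homogeneous solves at 50 and 25 µm for the disc oracle.

    The electrode center sits on a box corner, so the two insulating box
    faces through it are symmetry planes: the solve covers one quarter of an
    effectively 4× larger domain, and the unit-current potential of the full
    problem is the quarter-domain value divided by 4.
    """
    geom = make_synthetic_retina(SyntheticRetinaConfig(
        standoff_um=200.0, thickness_sd_um=0.0, surface_relief_um=0.0,
        choroid_thickness_mm=4.0, seed=0))
    cx, cy = layout["C6"].center_xy
    from retfield.conductivity import voxelize
    sols = {}
    for res, size in [(50.0, (4.8, 4.8, 5.0)), (25.0, (3.2, 3.2, 4.9))]:
        center = (cx + size[0] / 2, cy + size[1] / 2)
        grid = voxelize(geom, layout, resolution_um=res, center_xy=center,
                        size_mm=size, rpe_conductance=1e12)
        grid.sigma[(grid.labels != 4) & (grid.labels != 5)] = 0.1
        sols[res] = rf.solve_unit_field(grid, rf.SolverConfig(
            active_electrode="C6", tolerance=1e-6))
    return geom, (cx, cy), sols


@pytest.fixture(scope="session")
def solved_electrode(layout, flat_geometry):
    """Layered-geometry unit-field solution for electrode C6 at 50 µm."""
    cfg = RunConfig(geometry=flat_geometry.config, electrodes=["C6"],
                    resolution_um=50.0, seed=0)
    return cfg, _solve_electrode(cfg, flat_geometry, layout, "C6", None)


@pytest.fixture(scope="session")
def reference_neuron(layout, flat_geometry, solved_electrode):
    """One RGC under electrode C6 with its unit extracellular potentials."""
    _, sol = solved_electrode
    neuron = build_neuron(layout["C6"].center_xy, flat_geometry,
                          NeuronBuildParams(axon_max_length_mm=1.2))
    unit = rf.interpolate_potential(sol, neuron.centers_mm)
    return neuron, rf.CableModel(neuron), unit


@pytest.fixture(scope="session")
def standoff_batch():
    """Phosphene study under the standard conditions: 50–300 µm standoffs,
    100 neurons per electrode."""
    return rf.run_standoff_batch(n_neurons=100, resolution_um=50.0, seed=0)
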
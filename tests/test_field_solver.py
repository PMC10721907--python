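"""Voxel conductivity maps and the finite-volume Laplace solver."""

import numpy as np
import pytest

import retfield as rf
from retfield.conductivity import voxelize, LABELS
from retfield.field import (SolverConfig, analytic_disc_potential,
                            interpolate_potential, solve_unit_field,
                            FieldSolverError)
from retfield.geometry import SyntheticRetinaConfig, make_synthetic_retina


class TestVoxelize:
    def test_default_conductivities(self, layout, flat_geometry):
        grid = voxelize(flat_geometry, layout, resolution_um=50.0,
                        center_xy=layout["C6"].center_xy, size_mm=(2.0, 2.0, 1.6))
        assert np.all(grid.sigma[grid.labels == LABELS["retina"]] == 0.100)
        assert np.all(grid.sigma[grid.labels == LABELS["vitreous"]] == 1.5)
        assert np.all(grid.sigma[grid.labels == LABELS["choroid"]] == 0.503)
        assert np.all(grid.sigma[grid.labels == LABELS["substrate"]] == 0.0)
        # RPE thin-layer conductance sigma/t = 0.001 / 10e-6
        assert np.isclose(grid.rpe_conductance, 100.0)

    def test_too_coarse_resolution_rejected(self, layout, flat_geometry):
        with pytest.raises(ValueError, match="too coarse"):
            voxelize(flat_geometry, layout, resolution_um=60.0,
                     center_xy=layout["C6"].center_xy, size_mm=(2.4, 2.4, 1.8))

    def test_platinum_under_electrodes_only(self, layout, flat_geometry):
        grid = voxelize(flat_geometry, layout, resolution_um=50.0,
                        center_xy=layout["C6"].center_xy, size_mm=(2.0, 2.0, 1.6))
        idx = grid.electrode_voxels["C6"]
        assert len(idx) > 0
        r = layout["C6"].diameter_um / 2000.0
        cx, cy = layout["C6"].center_xy
        for ix, iy, iz in idx:
            assert np.hypot(grid.x[ix] - cx, grid.y[iy] - cy) <= r + 1e-12
        assert np.all(grid.labels[tuple(idx.T)] == LABELS["platinum"])


class TestAnalyticDisc:
    def test_surface_value(self):
        # arctan(inf) = pi/2 gives the classic I/(4*sigma*a) surface value
        v0 = analytic_disc_potential(100.0, 0.1, 1.0, 0.0)
        assert np.isclose(v0, 1.0 / (4 * 0.1 * 100e-6))

    def test_half_value_at_z_equals_a(self):
        assert np.isclose(analytic_disc_potential(100.0, 0.1, 1.0, 100.0),
                          0.5 * analytic_disc_potential(100.0, 0.1, 1.0, 0.0))

    def test_point_source_asymptote(self):
        z = np.array([2000.0, 5000.0, 10000.0])   # > 20 a
        v = analytic_disc_potential(100.0, 0.1, 1.0, z)
        point = 1.0 / (2 * np.pi * 0.1 * z * 1e-6)
        assert np.all(np.abs(v / point - 1) < 0.01)


class TestSolver:
    def test_oracle_agreement_beyond_two_voxels(self, homogeneous_quarter_solutions):
        geom, (cx, cy), sols = homogeneous_quarter_solutions
        sol = sols[25.0]
        z_face = geom.plane_z(cx, cy)
        zs = np.arange(0.075, 0.45, 0.025)
        h = 0.0125 + 1e-9   # nearest voxel-center column to the axis
        pts = np.array([[cx + h, cy + h, z_face - z] for z in zs])
        v_num = interpolate_potential(sol, pts) / 4.0   # quarter symmetry
        r_um = np.sqrt(2 * h ** 2 + zs ** 2) * 1000.0
        v_ana = analytic_disc_potential(100.0, 0.1, 1.0, r_um)
        assert np.max(np.abs(v_num / v_ana - 1)) < 0.05

    def test_refinement_reduces_error(self, homogeneous_quarter_solutions):
        geom, (cx, cy), sols = homogeneous_quarter_solutions
        z_face = geom.plane_z(cx, cy)
        zs = np.arange(0.1, 0.4, 0.05)
        errs = {}
        for res, sol in sols.items():
            h = res / 2000.0 + 1e-9
            pts = np.array([[cx + h, cy + h, z_face - z] for z in zs])
            v_num = interpolate_potential(sol, pts) / 4.0
            r_um = np.sqrt(2 * h ** 2 + zs ** 2) * 1000.0
            v_ana = analytic_disc_potential(100.0, 0.1, 1.0, r_um)
            errs[res] = np.sqrt(np.mean((v_num / v_ana - 1) ** 2))
        assert errs[25.0] < errs[50.0]

    def test_current_conservation(self, homogeneous_quarter_solutions, solved_electrode):
        _, _, sols = homogeneous_quarter_solutions
        for sol in sols.values():
            assert abs(sol.ground_current - 1.0) < 0.005
        _, layered = solved_electrode
        assert abs(layered.ground_current - 1.0) < 0.005

    def test_linearity(self, solved_electrode):
        _, sol = solved_electrode
        assert np.allclose(sol.scaled(2.0), 2.0 * sol.potential)

    def test_monotone_onaxis_attenuation(self, layout, flat_geometry, solved_electrode):
        _, sol = solved_electrode
        cx, cy = layout["C6"].center_xy
        z_face = flat_geometry.plane_z(cx, cy)
        zs = np.arange(0.075, 0.5, 0.025)
        v = interpolate_potential(sol, np.array([[cx, cy, z_face - z] for z in zs]))
        assert np.all(np.diff(v) < 1e-9)

    def test_retina_conductivity_direction(self, layout, flat_geometry):
        """Raising retinal conductivity lowers intraretinal potentials."""
        vals = {}
        for sigma_ret in (0.05, 0.2):
            grid = voxelize(flat_geometry, layout, resolution_um=50.0,
                            center_xy=layout["C6"].center_xy,
                            size_mm=(2.4, 2.4, 1.6),
                            conductivity_table={"retina": sigma_ret})
            sol = solve_unit_field(grid, SolverConfig(active_electrode="C6",
                                                      tolerance=1e-6))
            cx, cy = layout["C6"].center_xy
            z = flat_geometry.sample("inner_surface_z", cx, cy) - 0.050
            vals[sigma_ret] = interpolate_potential(sol, [[cx, cy, z]])[0]
        assert vals[0.2] < vals[0.05]

    def test_disconnected_path_errors(self, layout, flat_geometry):
        grid = voxelize(flat_geometry, layout, resolution_um=50.0,
                        center_xy=layout["C6"].center_xy, size_mm=(2.0, 2.0, 1.6))
        # sever the domain with an insulating slab below the electrode
        grid.sigma[:, :, 10:12] = 0.0
        with pytest.raises(FieldSolverError, match="no conductive path"):
            solve_unit_field(grid, SolverConfig(active_electrode="C6",
                                                tolerance=1e-6))

    def test_tolerance_validation(self):
        with pytest.raises(ValueError):
            SolverConfig(tolerance=1e-2)
        with pytest.raises(ValueError):
            SolverConfig(tolerance=0.0)


class TestInterpolation:
    def test_voxel_center_identity(self, solved_electrode):
        _, sol = solved_electrode
        ix, iy, iz = 10, 12, 20
        v = interpolate_potential(sol, [[sol.x[ix], sol.y[iy], sol.z[iz]]])
        assert np.isclose(v[0], sol.potential[ix, iy, iz])

    def test_midpoint_mean(self, solved_electrode):
        _, sol = solved_electrode
        ix, iy, iz = 10, 12, 20
        v = interpolate_potential(
            sol, [[0.5 * (sol.x[ix] + sol.x[ix + 1]), sol.y[iy], sol.z[iz]]])
        assert np.isclose(v[0], 0.5 * (sol.potential[ix, iy, iz]
                                       + sol.potential[ix + 1, iy, iz]))

    def test_outside_point_named(self, solved_electrode):
        _, sol = solved_electrode
        with pytest.raises(ValueError, match="outside solved domain"):
            interpolate_potential(sol, [[99.0, 0.0, 0.0]])
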
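"""Quasi-static volume-conductor solver.

The electric potential in the tissue obeys Laplace's equation
∇·(σ∇V) = 0 with a unit current injected at the active electrode and the
outer choroid boundary grounded.  The heterogeneous conductivity map is
discretized by a cell-centered finite-volume scheme on the voxel grid:
each face between two voxels carries the series (harmonic-mean)
conductance of the two half-cells, RPE interface faces add the thin-layer
contact conductance in series, and all outer boundaries except the ground
face are insulating.  The resulting symmetric positive-definite system is
solved by preconditioned conjugate gradients.

Because the medium is linear, one unit-current solve per electrode
suffices: the potential at any stimulus amplitude is the unit solution
scaled by the current, which is what makes amplitude bisection cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.interpolate import RegularGridInterpolator
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import cg

from .conductivity import ConductivityGrid, CONDUCTIVITY_TABLE, LABELS

__all__ = ["SolverConfig", "FieldSolution", "FieldSolverError",
           "solve_unit_field", "analytic_disc_potential",
           "interpolate_potential", "ground_flux"]


class FieldSolverError(RuntimeError):
    pass


@dataclass
class SolverConfig:
    """Linear-solve controls for one active electrode.

    ``tolerance`` is the relative residual of the conjugate-gradient solve
    (must lie in (0, 1e-3]).  Inactive electrodes keep their platinum
    voxels by default, which makes each disc near-equipotential and passive
    — a cheap stand-in for a true floating-potential constraint.
    """

    active_electrode: str = "C6"
    tolerance: float = 1e-8
    max_iterations: int = 20000
    keep_inactive_platinum: bool = True

    def __post_init__(self):
        if not (0 < self.tolerance <= 1e-3):
            # tolerances above 1e-3 defeat the conservation audit
            raise ValueError("tolerance must lie in (0, 1e-3]")


@dataclass
class FieldSolution:
    """Potential (V per ampere injected) on the voxel grid.

    Substrate voxels carry no physical potential; for interpolation near
    the array face they are filled with the value of the nearest conductive
    voxel below.  ``ground_current`` is the discrete current leaving
    through the grounded face (≈ 1 A by conservation).
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    potential: np.ndarray              # [ix, iy, iz], V/A
    active_electrode: str
    injected_current: float = 1.0
    residual: float = np.nan
    ground_current: float = np.nan
    resolution_mm: float = np.nan

    def scaled(self, current_A: float) -> np.ndarray:
        return self.potential * current_A


def analytic_disc_potential(radius_um: float, sigma: float, current_A: float,
                            z_um) -> np.ndarray | float:
    """On-axis potential of an equipotential disc on an insulating plane.

    For a disc of radius ``a`` carrying current ``I`` into a homogeneous
    half-space of conductivity ``σ``, the on-axis potential at height ``z``
    is V(z) = I/(2πσa)·arctan(a/z), with the surface value V(0) = I/(4σa).
    Used as the closed-form oracle for the voxel solver.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    a = radius_um * 1e-6
    z = np.asarray(z_um, dtype=float) * 1e-6
    if np.any(z < 0):
        raise ValueError("z must be >= 0")
    with np.errstate(divide="ignore"):
        v = current_A / (2 * np.pi * sigma * a) * np.arctan2(a, z)
    return v if v.ndim else float(v)


def _assemble(grid: ConductivityGrid, config: SolverConfig):
    """Build the finite-volume system restricted to conductive voxels."""
    h = grid.resolution_mm * 1e-3          # m
    sigma = grid.sigma.copy()
    if not config.keep_inactive_platinum:
        for lbl, idx in grid.electrode_voxels.items():
            if lbl != config.active_electrode:
                sigma[tuple(idx.T)] = 0.0
    if config.active_electrode not in grid.electrode_voxels:
        raise FieldSolverError(
            f"active electrode {config.active_electrode!r} has no voxels in the grid")
    act = grid.electrode_voxels[config.active_electrode]
    sigma[tuple(act.T)] = np.maximum(sigma[tuple(act.T)],
                                     CONDUCTIVITY_TABLE["platinum"])

    nx, ny, nz = sigma.shape
    n = nx * ny * nz
    conductive = sigma.ravel() > 0
    # face conductance between voxel pairs: harmonic mean * area / spacing
    rows, cols, vals = [], [], []
    diag = np.zeros(n)

    def add_faces(axis):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(0, -1)
        sl_hi[axis] = slice(1, None)
        s1 = sigma[tuple(sl_lo)]
        s2 = sigma[tuple(sl_hi)]
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.where((s1 > 0) & (s2 > 0), 2 * s1 * s2 / (s1 + s2), 0.0) * h
        if axis == 2:
            # RPE contact layer in series on its interface faces
            k = grid.rpe_face_k
            valid = k >= 1
            ii, jj = np.nonzero(valid)
            kk = k[valid] - 1                      # face between voxels kk and kk+1
            g_face = g[ii, jj, kk]
            g_rpe = grid.rpe_conductance * h * h   # S
            nzm = g_face > 0
            g[ii[nzm], jj[nzm], kk[nzm]] = 1.0 / (1.0 / g_face[nzm] + 1.0 / g_rpe)
        idx = np.arange(n).reshape(nx, ny, nz)
        i_lo = idx[tuple(sl_lo)].ravel()
        i_hi = idx[tuple(sl_hi)].ravel()
        gf = g.ravel()
        m = gf > 0
        rows.append(i_lo[m]); cols.append(i_hi[m]); vals.append(-gf[m])
        rows.append(i_hi[m]); cols.append(i_lo[m]); vals.append(-gf[m])
        np.add.at(diag, i_lo[m], gf[m])
        np.add.at(diag, i_hi[m], gf[m])

    for axis in range(3):
        add_faces(axis)

    # Dirichlet ground on the outer choroid (bottom z) face: half-cell conductance
    g_ground = 2.0 * sigma[:, :, 0].ravel() * h    # sigma*A/(h/2)
    flat_bottom = np.arange(n).reshape(nx, ny, nz)[:, :, 0].ravel()
    gmask = g_ground > 0
    diag[flat_bottom[gmask]] += g_ground[gmask]

    A = sp.csr_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))), shape=(n, n))
    A = A + sp.diags(diag)

    b = np.zeros(n)
    flat_act = np.ravel_multi_index(tuple(act.T), (nx, ny, nz))
    b[flat_act] = 1.0 / len(flat_act)

    # each electrode's platinum voxels collapse to one equipotential
    # super-node: the active disc becomes a true current terminal, inactive
    # discs exact floating potentials (no net current), and the 10^7:1
    # conductivity contrast leaves the linear system
    groups = []
    for lbl, idx in grid.electrode_voxels.items():
        flat = np.ravel_multi_index(tuple(idx.T), (nx, ny, nz))
        if lbl == config.active_electrode or \
                (config.keep_inactive_platinum and sigma.ravel()[flat[0]] > 0):
            groups.append(flat)

    keep = np.flatnonzero(conductive)
    return A, b, keep, sigma, (flat_bottom[gmask], g_ground[gmask]), flat_act, groups


def solve_unit_field(grid: ConductivityGrid,
                     config: SolverConfig | None = None) -> FieldSolution:
    """Solve for the potential of a 1 A injection at the active electrode.

    Raises
    ------
    FieldSolverError
        If the conjugate-gradient iteration fails to reach the configured
        relative residual, or if no conductive path connects the active
        electrode to the grounded boundary.
    """
    config = config or SolverConfig()
    A, b, keep, sigma, (ground_idx, ground_g), flat_act, groups = \
        _assemble(grid, config)
    n = A.shape[0]
    sub = np.full(n, -1, dtype=np.int64)
    sub[keep] = np.arange(len(keep))
    Ak = A[keep][:, keep].tocsr()
    bk = b[keep]

    # Galerkin reduction: map each electrode's voxels onto one unknown
    col_of = np.arange(len(keep))
    merged = np.zeros(len(keep), bool)
    for flat in groups:
        g = sub[flat]
        col_of[g] = g[0]
        merged[g[1:]] = True
    remap = np.cumsum(~merged) - 1
    col_of = remap[col_of]
    m = int(remap[-1]) + 1
    P = sp.csr_matrix((np.ones(len(keep)), (np.arange(len(keep)), col_of)),
                      shape=(len(keep), m))
    Ar = (P.T @ Ak @ P).tocsr()
    br = P.T @ bk

    # connectivity audit: electrode must reach a grounded voxel
    ncomp, comp = connected_components(sp.csr_matrix(
        (np.ones_like(Ar.data), Ar.indices, Ar.indptr), shape=Ar.shape),
        directed=False)
    el_comp = comp[col_of[sub[flat_act[0]]]]
    grounded = ground_idx[np.isin(ground_idx, keep)]
    if len(grounded) == 0 or not np.any(comp[col_of[sub[grounded]]] == el_comp):
        raise FieldSolverError("no conductive path from the active electrode "
                               "to the grounded boundary")

    M = sp.diags(1.0 / Ar.diagonal())
    vr, info = cg(Ar, br, rtol=config.tolerance, atol=0.0,
                  maxiter=config.max_iterations, M=M)
    res = float(np.linalg.norm(Ar @ vr - br) / np.linalg.norm(br))
    if info != 0 or res > 10 * config.tolerance:
        raise FieldSolverError(
            f"linear solve did not converge (info={info}, relative residual {res:.2e})")
    v = P @ vr

    V = np.full(n, np.nan)
    V[keep] = v
    nx, ny, nz = grid.shape
    V = V.reshape(nx, ny, nz)
    # fill insulating (substrate) voxels from below for safe interpolation
    for k in range(1, nz):
        layer = V[:, :, k]
        mask = np.isnan(layer)
        layer[mask] = V[:, :, k - 1][mask]
    # ground current audit
    vg = V.reshape(-1)[ground_idx]
    i_ground = float(np.sum(ground_g * vg))

    return FieldSolution(x=grid.x, y=grid.y, z=grid.z, potential=V,
                         active_electrode=config.active_electrode,
                         injected_current=1.0, residual=res,
                         ground_current=i_ground,
                         resolution_mm=grid.resolution_mm)


def interpolate_potential(solution: FieldSolution, points_mm: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of the unit-field potential at xyz points (mm).

    Raises ``ValueError`` naming the first offending point if any point
    lies outside the solved voxel domain.
    """
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    interp = RegularGridInterpolator((solution.x, solution.y, solution.z),
                                     solution.potential, bounds_error=False,
                                     fill_value=np.nan)
    out = interp(pts)
    if np.any(np.isnan(out)):
        bad = pts[np.isnan(out)][0]
        raise ValueError(f"point outside solved domain: {tuple(bad)}")
    return out


def ground_flux(solution: FieldSolution) -> float:
    """Current (A) leaving through the grounded boundary (conservation audit)."""
    return solution.ground_current
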
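"""Voxel conductivity maps of the layered implant–retina geometry.

The stacked anatomy (choroid / retina / optional fibrosis / vitreous, with
the platinum discs and insulating substrate of the array suspended in the
vitreous) is rasterized column-by-column onto a regular isotropic voxel
grid.  The thin, resistive retinal pigment epithelium at the retina–choroid
boundary is not resolved as voxels; it is carried as a per-face contact
conductance (S/m²) applied to the vertical faces on that interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely

from .geometry import RetinaGeometry
from .layout import ArrayLayout

__all__ = ["CONDUCTIVITY_TABLE", "RPE_THICKNESS_UM", "RPE_SIGMA",
           "LABELS", "ConductivityGrid", "voxelize"]

# tissue conductivities, S/m
CONDUCTIVITY_TABLE = {
    "vitreous": 1.5,
    "retina": 0.100,
    "fibrosis": 0.15,
    "choroid": 0.503,
    "platinum": 9.43e6,
    "substrate": 0.0,       # perfect insulator
}

# retinal pigment epithelium contact layer: sigma / thickness = 100 S/m^2
RPE_SIGMA = 0.001           # S/m
RPE_THICKNESS_UM = 10.0

LABELS = {"vitreous": 0, "retina": 1, "fibrosis": 2, "choroid": 3,
          "platinum": 4, "substrate": 5}
LABEL_NAMES = {v: k for k, v in LABELS.items()}


@dataclass
class ConductivityGrid:
    """Isotropic voxel grid of conductivities over a solver subdomain.

    ``x``, ``y``, ``z`` are voxel-center coordinates (mm); ``sigma`` and
    ``labels`` are indexed ``[ix, iy, iz]`` with z increasing choroid →
    vitreous.  ``rpe_face_k[ix, iy]`` gives the z-face index of the RPE
    interface in that column (face k separates voxels k-1 and k; -1 where
    the interface is outside the box) and ``rpe_conductance`` its thin-layer
    conductance in S/m².  ``electrode_voxels`` maps electrode labels to the
    (n, 3) integer indices of their platinum voxels.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    resolution_mm: float
    sigma: np.ndarray
    labels: np.ndarray
    rpe_face_k: np.ndarray
    rpe_conductance: float
    electrode_voxels: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.sigma.shape


def voxelize(geometry: RetinaGeometry, layout: ArrayLayout,
             resolution_um: float = 25.0,
             conductivity_table: dict[str, float] | None = None,
             center_xy: tuple[float, float] | None = None,
             size_mm: tuple[float, float, float] = (5.0, 5.0, 2.5),
             substrate_thickness_um: float = 100.0,
             rpe_conductance: float | None = None,
             include_inactive_platinum: bool = True) -> ConductivityGrid:
    """Rasterize a subdomain of the geometry onto a voxel grid.

    The box is ``size_mm`` wide laterally, centered on ``center_xy``
    (default: the array center), and extends vertically from the outer
    choroid boundary upward.  Current practice is a 25 µm grid, which puts
    8 voxels across a 200 µm electrode; a resolution coarser than 1/4 of
    the electrode diameter is rejected.
    """
    table = dict(CONDUCTIVITY_TABLE, **(conductivity_table or {}))
    missing = set(LABELS) - set(table)
    if missing:
        raise ValueError(f"conductivity table incomplete, missing {sorted(missing)}")
    h = resolution_um / 1000.0
    d_el = layout.electrodes[0].diameter_um
    if d_el / resolution_um < 4:
        raise ValueError(
            f"resolution {resolution_um} µm too coarse: fewer than 4 voxels "
            f"across the {d_el:.0f} µm electrode diameter")
    if rpe_conductance is None:
        rpe_conductance = RPE_SIGMA / (RPE_THICKNESS_UM * 1e-6)   # S/m^2

    if center_xy is None:
        c = layout.centers().mean(axis=0)
        center_xy = (float(c[0]), float(c[1]))
    nx = int(round(size_mm[0] / h))
    ny = int(round(size_mm[1] / h))
    nz = int(round(size_mm[2] / h))
    x = center_xy[0] - size_mm[0] / 2 + (np.arange(nx) + 0.5) * h
    y = center_xy[1] - size_mm[1] / 2 + (np.arange(ny) + 0.5) * h
    if not (geometry.contains(x[0], y[0]) and geometry.contains(x[-1], y[-1])):
        raise ValueError("voxel box extends outside the geometry's lateral grid")

    xx, yy = np.meshgrid(x, y, indexing="ij")
    inner = geometry.sample("inner_surface_z", xx.ravel(), yy.ravel()).reshape(nx, ny)
    thick = geometry.sample("thickness_um", xx.ravel(), yy.ravel()).reshape(nx, ny) / 1000.0
    fibro = geometry.sample("fibrosis_um", xx.ravel(), yy.ravel()).reshape(nx, ny) / 1000.0
    plane = geometry.plane_z(xx, yy)
    outer = inner - thick                                  # retina/choroid boundary

    z_bottom = float(outer.min() - geometry.choroid_thickness_mm)
    z = z_bottom + (np.arange(nz) + 0.5) * h
    if z[-1] < plane.max() + substrate_thickness_um / 1000.0 + 2 * h:
        raise ValueError("voxel box too short: no vitreous above the array substrate")

    labels = np.full((nx, ny, nz), LABELS["vitreous"], dtype=np.uint8)
    zc = z[None, None, :]
    labels[zc < outer[:, :, None]] = LABELS["choroid"]
    in_retina = (zc >= outer[:, :, None]) & (zc < inner[:, :, None])
    labels[in_retina] = LABELS["retina"]
    # fibrosis hangs below the array face
    in_fibrosis = (zc >= inner[:, :, None]) & (zc < plane[:, :, None]) & \
                  (zc >= (plane - fibro)[:, :, None])
    labels[in_fibrosis] = LABELS["fibrosis"]

    # array: one voxel layer of platinum at the electrode discs, insulating
    # substrate elsewhere on the array plane and above it
    sub_lo = plane[:, :, None]
    sub_hi = (plane + substrate_thickness_um / 1000.0)[:, :, None]
    on_substrate = shapely.contains_xy(layout.substrate_outline, xx.ravel(),
                                       yy.ravel()).reshape(nx, ny)
    in_substrate = (zc >= sub_lo) & (zc < sub_hi) & on_substrate[:, :, None]
    labels[in_substrate] = LABELS["substrate"]

    electrode_voxels: dict[str, np.ndarray] = {}
    r_el = d_el / 2000.0                                   # mm
    for e in layout.electrodes:
        lateral = (xx - e.center_xy[0]) ** 2 + (yy - e.center_xy[1]) ** 2 <= r_el ** 2
        if not lateral.any():
            continue
        in_disc = in_substrate & lateral[:, :, None] & \
                  (zc < sub_lo + h)                        # first layer above the face
        idx = np.argwhere(in_disc)
        if len(idx) == 0:
            continue
        if include_inactive_platinum:
            labels[in_disc] = LABELS["platinum"]
        electrode_voxels[e.label] = idx

    sigma = np.empty((nx, ny, nz))
    for name, code in LABELS.items():
        sigma[labels == code] = table[name]

    # z-face index of the RPE interface per column (face k sits at z_bottom + k*h)
    rpe_k = np.clip(np.round((outer - z_bottom) / h).astype(int), -1, nz)
    rpe_k[(rpe_k <= 0) | (rpe_k >= nz)] = -1

    return ConductivityGrid(x=x, y=y, z=z, resolution_mm=h, sigma=sigma,
                            labels=labels, rpe_face_k=rpe_k,
                            rpe_conductance=float(rpe_conductance),
                            electrode_voxels=electrode_voxels)
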
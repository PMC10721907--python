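"""Target RGC populations beneath each electrode.

For every stimulating electrode, somata are spread quasi-uniformly over a
disc beneath it by Lloyd's algorithm (centroidal Voronoi relaxation,
discrete flavour), each soma is given a multi-compartment morphology —
equivalent-cylinder dendrite, soma, axon hillock, high-density sodium-channel
band, and an axon that follows the nerve-fiber trajectory toward the optic
disc — and neurons over severely degenerated retina (thickness below a
floor) are removed.  Depths follow the anatomy of the ganglion-cell layer:
somata 55 µm and axons 15 µm below the inner retinal surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .axon import TrajectoryParams, soma_to_path
from .geometry import RetinaGeometry

__all__ = ["SECTION_CODES", "SomaPopulation", "NeuronGeometry",
           "NeuronBuildParams", "lloyd_disc", "place_somas", "build_neuron",
           "apply_thickness_exclusion"]

SECTION_CODES = {"dendrite": 0, "soma": 1, "hillock": 2, "sodium_band": 3,
                 "axon": 4}


@dataclass
class SomaPopulation:
    """Soma positions (mm) for one electrode's target population."""

    electrode_label: str
    soma_xyz: np.ndarray            # (n, 3) mm
    placement_radius_um: float = 700.0
    seed: int = 0

    @property
    def n(self) -> int:
        return len(self.soma_xyz)


@dataclass
class NeuronGeometry:
    """Ordered compartment chain of one RGC (dendrite tip → distal axon)."""

    centers_mm: np.ndarray          # (n, 3)
    length_um: np.ndarray           # (n,)
    diameter_um: np.ndarray         # (n,)
    section: np.ndarray             # (n,) codes per SECTION_CODES

    def mask(self, name: str) -> np.ndarray:
        return self.section == SECTION_CODES[name]

    @property
    def n_compartments(self) -> int:
        return len(self.centers_mm)


@dataclass
class NeuronBuildParams:
    """Morphology defaults.

    The dendritic tree is collapsed to a single equivalent cylinder (a
    documented stand-in for a full reconstructed arbor); the sodium band is
    the short high-channel-density segment just distal to the hillock where
    spikes initiate.  ``axon_max_length_mm`` truncates the distal axon —
    compartments several space constants from the electrode no longer
    influence threshold.
    """

    soma_depth_um: float = 55.0
    axon_depth_um: float = 15.0
    soma_diameter_um: float = 20.0
    dendrite_length_um: float = 200.0
    dendrite_diameter_um: float = 2.0
    dendrite_compartment_um: float = 20.0
    hillock_length_um: float = 40.0
    hillock_diameter_um: float = 1.5
    band_length_um: float = 40.0
    band_diameter_um: float = 1.0
    axon_diameter_um: float = 1.0
    proximal_compartment_um: float = 10.0
    axon_compartment_um: float = 25.0
    axon_max_length_mm: float = 2.0
    trajectory: TrajectoryParams = field(default_factory=TrajectoryParams)


def lloyd_disc(n: int, radius: float, iterations: int = 50,
               seed: int = 0, n_samples: int | None = None) -> np.ndarray:
    """Quasi-uniform points in a disc by discrete Lloyd relaxation.

    A fixed dense set of uniform sample points in the disc is generated
    from ``seed``; each iteration assigns samples to their nearest seed
    point and moves every seed to the centroid of its assigned samples
    (its discrete Voronoi cell clipped to the disc).  Deterministic for a
    fixed seed; the returned (n, 2) points are in the units of ``radius``
    and centered on the origin.
    """
    if n < 1 or radius <= 0:
        raise ValueError("need n >= 1 and radius > 0")
    rng = np.random.default_rng(seed)
    m = n_samples or max(256 * n, 20000)
    rr = radius * np.sqrt(rng.uniform(size=m))
    th = rng.uniform(0, 2 * np.pi, size=m)
    samples = np.column_stack([rr * np.cos(th), rr * np.sin(th)])
    rp = radius * np.sqrt(rng.uniform(size=n))
    tp = rng.uniform(0, 2 * np.pi, size=n)
    pts = np.column_stack([rp * np.cos(tp), rp * np.sin(tp)])
    for _ in range(iterations):
        _, owner = cKDTree(pts).query(samples)
        for i in range(n):
            cell = samples[owner == i]
            if len(cell):
                pts[i] = cell.mean(axis=0)
    return pts


def place_somas(electrode_center_xy, geometry: RetinaGeometry,
                n: int = 250, radius_um: float = 700.0,
                soma_depth_um: float = 55.0, iterations: int = 50,
                seed: int = 0, electrode_label: str = "") -> SomaPopulation:
    """Distribute ``n`` somata beneath an electrode and assign their depths."""
    xy = lloyd_disc(n, radius_um / 1000.0, iterations=iterations, seed=seed)
    xy = xy + np.asarray(electrode_center_xy, float)
    inner = geometry.sample("inner_surface_z", xy[:, 0], xy[:, 1])
    z = np.asarray(inner) - soma_depth_um / 1000.0
    return SomaPopulation(electrode_label=electrode_label,
                          soma_xyz=np.column_stack([xy, z]),
                          placement_radius_um=radius_um, seed=seed)


def _polyline_z(points_xy: np.ndarray, geometry: RetinaGeometry,
                depth_um: float) -> np.ndarray:
    inner = geometry.sample("inner_surface_z", points_xy[:, 0], points_xy[:, 1])
    return np.asarray(inner) - depth_um / 1000.0


def build_neuron(soma_xy, geometry: RetinaGeometry,
                 params: NeuronBuildParams | None = None) -> NeuronGeometry:
    """Assemble the compartment chain of one RGC at a soma position (mm).

    The axon follows the nerve-fiber trajectory toward the optic disc at
    ``axon_depth_um`` below the inner surface; the hillock and sodium band
    occupy its first stretch, with z ramping from soma depth to axon depth.
    The dendrite is a single equivalent cylinder extending opposite the
    axon's initial direction at soma depth.  Trajectories that leave the
    geometry grid are truncated at the boundary with a warning.
    """
    p = params or NeuronBuildParams()
    soma_xy = np.asarray(soma_xy, dtype=float)
    traj = soma_to_path(soma_xy, p.trajectory,
                        compartment_length_um=p.proximal_compartment_um)
    path = traj.points
    inside = np.array([geometry.contains(x, y) for x, y in path])
    if not inside.all():
        first_out = int(np.argmin(inside))
        warnings.warn("axon trajectory leaves the geometry grid; truncating "
                      f"after {first_out} points", stacklevel=2)
        path = path[:max(first_out, 2)]
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)]) * 1000.0    # µm along path

    s_hillock = p.hillock_length_um
    s_band = s_hillock + p.band_length_um
    s_max = min(s[-1], s_band + p.axon_max_length_mm * 1000.0)

    def sample_path(s_um):
        return np.column_stack([np.interp(s_um, s, path[:, 0]),
                                np.interp(s_um, s, path[:, 1])])

    centers, lengths, diams, sect = [], [], [], []

    # dendrite: equivalent cylinder opposite the axon's initial direction
    d0 = path[min(2, len(path) - 1)] - path[0]
    nrm = np.linalg.norm(d0)
    d_hat = -d0 / nrm if nrm > 0 else np.array([1.0, 0.0])
    nden = max(int(round(p.dendrite_length_um / p.dendrite_compartment_um)), 1)
    den_s = (np.arange(nden)[::-1] + 0.5) * p.dendrite_compartment_um / 1000.0
    soma_inner = geometry.sample("inner_surface_z", soma_xy[0], soma_xy[1])
    z_soma = soma_inner - p.soma_depth_um / 1000.0
    for ds in den_s:
        xy = soma_xy + d_hat * (ds + p.soma_diameter_um / 2000.0)
        centers.append([xy[0], xy[1], z_soma])
        lengths.append(p.dendrite_compartment_um)
        diams.append(p.dendrite_diameter_um)
        sect.append(SECTION_CODES["dendrite"])

    centers.append([soma_xy[0], soma_xy[1], z_soma])
    lengths.append(p.soma_diameter_um)
    diams.append(p.soma_diameter_um)
    sect.append(SECTION_CODES["soma"])

    # hillock + sodium band + axon along the trajectory
    def add_section(s_from, s_to, comp_um, diameter, code, depth_ramp):
        n_comp = max(int(np.ceil((s_to - s_from) / comp_um)), 1)
        edges = np.linspace(s_from, s_to, n_comp + 1)
        mids = 0.5 * (edges[:-1] + edges[1:])
        xy = sample_path(mids)
        if depth_ramp:
            frac = (mids - 0.0) / max(s_band, 1e-9)
            depth = p.soma_depth_um + (p.axon_depth_um - p.soma_depth_um) * \
                np.clip(frac, 0.0, 1.0)
        else:
            depth = np.full(len(mids), p.axon_depth_um)
        inner = geometry.sample("inner_surface_z", xy[:, 0], xy[:, 1])
        zz = np.asarray(inner) - depth / 1000.0
        for k in range(len(mids)):
            centers.append([xy[k, 0], xy[k, 1], zz[k]])
            lengths.append(edges[k + 1] - edges[k])
            diams.append(diameter)
            sect.append(code)

    add_section(0.0, min(s_hillock, s_max), p.proximal_compartment_um,
                p.hillock_diameter_um, SECTION_CODES["hillock"], True)
    if s_max > s_hillock:
        add_section(s_hillock, min(s_band, s_max), p.proximal_compartment_um,
                    p.band_diameter_um, SECTION_CODES["sodium_band"], True)
    if s_max > s_band:
        add_section(s_band, s_max, p.axon_compartment_um,
                    p.axon_diameter_um, SECTION_CODES["axon"], False)

    return NeuronGeometry(centers_mm=np.asarray(centers),
                          length_um=np.asarray(lengths),
                          diameter_um=np.asarray(diams),
                          section=np.asarray(sect, dtype=np.int8))


def apply_thickness_exclusion(population: SomaPopulation,
                              geometry: RetinaGeometry,
                              floor_um: float = 100.0
                              ) -> tuple[SomaPopulation, np.ndarray]:
    """Remove neurons whose soma sits over retina thinner than ``floor_um``.

    Returns the filtered population and the boolean *removal* mask
    (True = removed), so per-neuron thresholds computed before filtering
    can be re-aggregated afterwards.
    """
    xy = population.soma_xyz[:, :2]
    thick = np.asarray(geometry.sample("thickness_um", xy[:, 0], xy[:, 1]))
    removed = thick < floor_um
    kept = replace(population, soma_xyz=population.soma_xyz[~removed])
    return kept, removed
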
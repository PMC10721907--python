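"""Retinal nerve-fiber-layer axon trajectories.

Retinal ganglion cell axons run from the soma to the optic disc along
arcuate paths that never cross the horizontal raphe.  This module
implements the Jansonius et al. (2009) mathematical description of those
nerve-fiber bundle trajectories: in modified polar coordinates (r, φ)
centered on the optic disc, a fiber entering the disc at angle φ0 follows

    φ(r) = φ0 + b(φ0) · (r − r0)^c(φ0),      r ≥ r0,

with hemisphere-specific coefficient functions b and c.  Coordinates are
degrees of visual angle in a right-eye retinal frame: fovea at the origin,
x positive toward the nasal side, y positive superior, optic disc at
(15°, 2°); φ0 = 0 points along the nasal horizontal and |φ0| → 180°
toward the temporal raphe.  The coefficient defaults below are the model
variant used by common phosphene-modelling software (β_sup = −1.9,
β_inf = 0.5); all constants are overridable through TrajectoryParams.

Retinal millimetres and visual degrees are interconverted with a single
scale factor of 288 µm per degree (no eccentricity-dependent
magnification).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = ["MM_PER_DEG", "TrajectoryParams", "AxonTrajectory",
           "jansonius_path", "soma_to_path", "degrees_to_mm", "mm_to_degrees"]

MM_PER_DEG = 0.288   # retinal mm per degree of visual angle


@dataclass
class TrajectoryParams:
    """Constants of the nerve-fiber trajectory model (angles in degrees)."""

    optic_disc_deg: tuple[float, float] = (15.0, 2.0)
    r0: float = 4.0                  # start radius of the spiral at the disc
    beta_sup: float = -1.9
    beta_inf: float = 0.5
    max_r: float = 45.0              # outermost modelled eccentricity from the disc
    mm_per_degree: float = MM_PER_DEG
    step_deg: float = 0.05           # radial sampling of the generated polyline

    def coefficients(self, phi0: float) -> tuple[float, float]:
        """(b, c) for a fiber entering the disc at angle phi0."""
        if phi0 > 0:       # superior hemisphere
            b = np.exp(self.beta_sup + 3.9 * np.tanh(-(phi0 - 121.0) / 14.0))
            c = 1.9 + 1.4 * np.tanh((phi0 - 121.0) / 14.0)
        else:              # inferior hemisphere (raphe ties resolve here)
            b = -np.exp(self.beta_inf + 1.5 * np.tanh(-(-phi0 - 90.0) / 25.0))
            c = 1.0 + 0.5 * np.tanh((-phi0 - 90.0) / 25.0)
        return float(b), float(c)


@dataclass
class AxonTrajectory:
    """Ordered polyline of one axon, soma end first, disc end last.

    ``points`` is (n, 2) in the units given by ``unit`` ("deg" or "mm");
    a z column is attached downstream once the retinal surface is known.
    """

    points: np.ndarray
    phi0: float
    unit: str = "deg"

    @property
    def arc_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


def degrees_to_mm(points_deg, mm_per_degree: float = MM_PER_DEG) -> np.ndarray:
    """Visual degrees → retinal mm (scalar scaling about the foveal origin)."""
    return np.asarray(points_deg, dtype=float) * mm_per_degree


def mm_to_degrees(points_mm, mm_per_degree: float = MM_PER_DEG) -> np.ndarray:
    return np.asarray(points_mm, dtype=float) / mm_per_degree


def _phi_of_r(r, phi0: float, params: TrajectoryParams):
    b, c = params.coefficients(phi0)
    r = np.asarray(r, dtype=float)
    return phi0 + b * np.clip(r - params.r0, 0.0, None) ** c


def jansonius_path(phi0: float, params: TrajectoryParams | None = None) -> AxonTrajectory:
    """Trajectory entering the optic disc at angle ``phi0`` (2-D, degrees).

    The polyline runs from the outermost modelled eccentricity inward and
    terminates at the disc center (a straight radial stub covers r < r0).
    φ is confined to the launch hemisphere: superior paths are truncated
    where φ would reach 180°, inferior where it would reach −180°, so no
    path wraps across the temporal raphe.
    """
    params = params or TrajectoryParams()
    if not (-180.0 < phi0 <= 180.0) or phi0 == 0.0:
        raise ValueError("phi0 must lie in (-180, 180] and be nonzero "
                         "(raphe somata are assigned phi0 < 0)")
    r = np.arange(params.max_r, 0.0, -params.step_deg)
    r = np.append(r, 0.0)
    phi = _phi_of_r(r, phi0, params)
    keep = np.abs(phi) < 180.0
    r, phi = r[keep], phi[keep]
    xod, yod = params.optic_disc_deg
    pts = np.column_stack([xod + r * np.cos(np.deg2rad(phi)),
                           yod + r * np.sin(np.deg2rad(phi))])
    return AxonTrajectory(points=pts, phi0=phi0, unit="deg")


def _resample(points: np.ndarray, spacing: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        return points[:1]
    si = np.arange(0.0, s[-1], spacing)
    si = np.append(si, s[-1])
    return np.column_stack([np.interp(si, s, points[:, 0]),
                            np.interp(si, s, points[:, 1])])


def soma_to_path(soma_xy_mm, params: TrajectoryParams | None = None,
                 compartment_length_um: float = 25.0) -> AxonTrajectory:
    """Axon polyline (mm) from a soma position to the optic disc.

    Finds the entry angle φ0 whose trajectory passes through the soma
    (scalar root-find, bracketing scan over the soma's hemisphere) and
    returns the distal portion soma → disc, resampled at the compartment
    length.  Somata exactly on the raphe go to the inferior hemisphere.

    Raises ``ValueError`` when no trajectory of the model reaches the soma
    (soma outside the modelled region).
    """
    params = params or TrajectoryParams()
    soma_deg = mm_to_degrees(np.asarray(soma_xy_mm, float), params.mm_per_degree)
    xod, yod = params.optic_disc_deg
    dx, dy = soma_deg[0] - xod, soma_deg[1] - yod
    r_s = float(np.hypot(dx, dy))
    if r_s < 1e-9:
        raise ValueError("soma coincides with the optic disc")
    phi_s = float(np.degrees(np.arctan2(dy, dx)))
    if r_s <= params.r0:
        # inside the spiral start radius: straight radial stub to the disc
        phi0 = phi_s if phi_s != 0.0 else -1e-6
        pts_deg = np.array([[soma_deg[0], soma_deg[1]], [xod, yod]])
    else:
        superior = dy > 0
        def f(phi0):
            return _phi_of_r(r_s, phi0, params) - phi_s
        lo, hi = (1e-6, 180.0 - 1e-6) if superior else (-180.0 + 1e-6, -1e-6)
        grid = np.linspace(lo, hi, 721)
        vals = np.array([f(g) for g in grid])
        sign = np.sign(vals)
        flips = np.nonzero(np.diff(sign) != 0)[0]
        if len(flips) == 0:
            raise ValueError(
                f"soma at {tuple(np.round(soma_deg, 2))} deg is outside the "
                "modelled nerve-fiber region (no trajectory reaches it)")
        i = flips[0]
        phi0 = float(brentq(f, grid[i], grid[i + 1], xtol=1e-8))
        # distal portion: from the soma radius inward to the disc
        r = np.arange(r_s, params.r0, -params.step_deg)
        r = np.concatenate([r, [params.r0, 0.0]])
        phi = _phi_of_r(r, phi0, params)
        pts_deg = np.column_stack([xod + r * np.cos(np.deg2rad(phi)),
                                   yod + r * np.sin(np.deg2rad(phi))])
    pts_mm = degrees_to_mm(pts_deg, params.mm_per_degree)
    pts_mm = _resample(pts_mm, compartment_length_um / 1000.0)
    pts_mm[0] = degrees_to_mm(soma_deg, params.mm_per_degree)  # exact soma anchor
    return AxonTrajectory(points=pts_mm, phi0=phi0, unit="mm")
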
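"""Virtual-patient retinal geometry.

Real inputs to the modelling pipeline are per-electrode measurements taken
from OCT B-scans of an implanted eye: the gap between each electrode face
and the inner retinal surface, the local retinal thickness, and the
thickness of any fibrotic tissue on the array surface.  Because such scans
cannot be shared, this module generates *virtual patients*: a 2.5-D
height-field geometry (lateral grid with stacked layers — choroid, retina,
optional fibrosis, vitreous — and a tilted electrode-array plane) whose
per-electrode measurements have the same structure and ranges as the
clinical ones.

Coordinate convention: x–y in the retinal plane in mm, z in mm increasing
from the choroid toward the vitreous.  Electrode faces lie on the array
plane at ``z = inner surface + gap``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter

from .layout import ArrayLayout

__all__ = [
    "SyntheticRetinaConfig", "RetinaGeometry", "ElectrodeMeasurement",
    "make_synthetic_retina", "measure_electrodes", "synth_thresholds",
    "synth_impedances", "measurements_to_frame", "frame_to_measurements",
    "save_geometry", "load_geometry",
]

MEASUREMENT_COLUMNS = ["label", "distance_mm", "thickness_mm", "fibrosis_mm",
                       "impedance_kohm", "threshold_uA", "visible"]


@dataclass
class SyntheticRetinaConfig:
    """Parameters of the virtual-patient generator.

    Lengths are µm unless the name says mm.  The array plane is
    ``z = standoff + tilt_x·x + tilt_y·y`` above the mean inner surface, so a
    tilt produces a spread of electrode–retina distances across the grid, as
    seen clinically.
    """

    extent_mm: tuple[float, float] = (25.0, 17.0)   # lateral domain
    grid_spacing_mm: float = 0.05
    vitreous_height_mm: float = 18.0
    choroid_thickness_mm: float = 0.25

    mean_thickness_um: float = 200.0
    thickness_sd_um: float = 20.0
    smoothness_mm: float = 0.5                      # Gaussian length-scale of the random fields
    surface_relief_um: float = 20.0                 # inner-surface height variation

    # degeneration patches: thin regions (thickness clipped to patch floor)
    n_degeneration_patches: int = 0
    degeneration_radius_mm: float = 1.0
    degeneration_floor_um: float = 50.0

    standoff_um: float = 100.0                      # gap at the domain center
    tilt_um_per_mm: tuple[float, float] = (0.0, 0.0)

    # fibrosis patches on the array surface
    n_fibrosis_patches: int = 0
    fibrosis_radius_mm: float = 1.0
    fibrosis_thickness_um: float = 80.0

    seed: int = 0


@dataclass
class RetinaGeometry:
    """Gridded layered geometry of one virtual patient.

    Fields are sampled on the regular lateral grid (``x``, ``y``), indexed
    ``[ix, iy]``.  ``inner_surface_z`` is the vitreo-retinal boundary height
    (mm); ``thickness_um`` the inner-to-outer retinal thickness; and
    ``fibrosis_um`` the fibrotic-tissue thickness hanging below the array
    plane (0 where absent).  ``array_plane`` holds ``(z0, gx, gy)`` of the
    electrode-face plane ``z = z0 + gx·x + gy·y`` (mm).
    """

    x: np.ndarray
    y: np.ndarray
    inner_surface_z: np.ndarray
    thickness_um: np.ndarray
    fibrosis_um: np.ndarray
    array_plane: tuple[float, float, float]
    vitreous_height_mm: float = 18.0
    choroid_thickness_mm: float = 0.25
    # lateral extent over which the array plane must clear the retina
    # (the array footprint region; the extrapolated plane far outside it
    # is never used)
    plane_check_extent_mm: tuple[float, float] = (5.0, 3.0)
    config: SyntheticRetinaConfig | None = None

    def __post_init__(self):
        if np.any(self.thickness_um < 0) or np.any(self.fibrosis_um < 0):
            raise ValueError("thickness and fibrosis fields must be non-negative")
        if np.any(self.gap_mm()[self._plane_mask()] < -1e-9):
            raise ValueError("array plane intersects the retina")

    def _plane_mask(self) -> np.ndarray:
        xx, yy = np.meshgrid(self.x, self.y, indexing="ij")
        ex, ey = self.plane_check_extent_mm
        return (np.abs(xx) <= ex / 2) & (np.abs(yy) <= ey / 2)

    def plane_z(self, x, y):
        z0, gx, gy = self.array_plane
        return z0 + gx * np.asarray(x, float) + gy * np.asarray(y, float)

    def gap_mm(self) -> np.ndarray:
        """Electrode-plane-to-inner-surface distance field (mm, ≥ 0)."""
        xx, yy = np.meshgrid(self.x, self.y, indexing="ij")
        return self.plane_z(xx, yy) - self.inner_surface_z

    def _interp(self, values):
        return RegularGridInterpolator((self.x, self.y), values,
                                       bounds_error=True)

    def contains(self, x: float, y: float) -> bool:
        return (self.x[0] <= x <= self.x[-1]) and (self.y[0] <= y <= self.y[-1])

    def sample(self, what: str, x, y):
        """Bilinear sample of a named field at lateral point(s) (mm)."""
        fields = {"inner_surface_z": self.inner_surface_z,
                  "thickness_um": self.thickness_um,
                  "fibrosis_um": self.fibrosis_um}
        pts = np.column_stack([np.atleast_1d(x), np.atleast_1d(y)])
        out = self._interp(fields[what])(pts)
        return out if np.ndim(x) else float(out[0])


@dataclass
class ElectrodeMeasurement:
    """Per-electrode OCT-analogue measurements (lengths in mm)."""

    label: str
    distance_mm: float
    thickness_mm: float
    fibrosis_mm: float
    impedance_kohm: float = np.nan
    threshold_uA: float = np.nan
    visible: bool = True


def _smooth_field(rng, shape, spacing_mm, length_scale_mm, sd):
    """Zero-mean Gaussian random field with ~unit sd, rescaled to ``sd``."""
    noise = rng.standard_normal(shape)
    f = gaussian_filter(noise, sigma=length_scale_mm / spacing_mm, mode="reflect")
    s = f.std()
    return f * (sd / s) if s > 0 else f


def make_synthetic_retina(config: SyntheticRetinaConfig | None = None,
                          seed: int | None = None, **overrides) -> RetinaGeometry:
    """Generate a virtual-patient geometry (deterministic for a fixed seed).

    Keyword overrides update a copy of ``config``.  Raises ``ValueError`` if
    the requested standoff/tilt would push the array plane into the retina.
    """
    cfg = SyntheticRetinaConfig(**{**(asdict(config) if config else {}), **overrides})
    if seed is not None:
        cfg.seed = seed
    rng = np.random.default_rng(cfg.seed)

    nx = int(round(cfg.extent_mm[0] / cfg.grid_spacing_mm)) + 1
    ny = int(round(cfg.extent_mm[1] / cfg.grid_spacing_mm)) + 1
    x = np.linspace(-cfg.extent_mm[0] / 2, cfg.extent_mm[0] / 2, nx)
    y = np.linspace(-cfg.extent_mm[1] / 2, cfg.extent_mm[1] / 2, ny)
    xx, yy = np.meshgrid(x, y, indexing="ij")

    inner_z = _smooth_field(rng, (nx, ny), cfg.grid_spacing_mm,
                            cfg.smoothness_mm, cfg.surface_relief_um / 1000.0)
    thickness = cfg.mean_thickness_um + _smooth_field(
        rng, (nx, ny), cfg.grid_spacing_mm, cfg.smoothness_mm, cfg.thickness_sd_um)
    thickness = np.clip(thickness, 1.0, None)

    for _ in range(cfg.n_degeneration_patches):
        cx = rng.uniform(x[0], x[-1])
        cy = rng.uniform(y[0], y[-1])
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 < cfg.degeneration_radius_mm ** 2
        thickness[mask] = np.minimum(thickness[mask], cfg.degeneration_floor_um)

    gx, gy = (t / 1000.0 for t in cfg.tilt_um_per_mm)   # µm/mm -> mm/mm
    z0 = cfg.standoff_um / 1000.0
    plane = z0 + gx * xx + gy * yy
    gap = plane - inner_z
    footprint = (np.abs(xx) <= 2.5) & (np.abs(yy) <= 1.5)
    if gap[footprint].min() < 0:
        raise ValueError(
            f"array plane intersects the retina (min gap over the array "
            f"footprint {gap[footprint].min()*1e3:.1f} µm); increase "
            "standoff_um or reduce tilt")

    fibrosis = np.zeros_like(thickness)
    for _ in range(cfg.n_fibrosis_patches):
        cx = rng.uniform(x[0], x[-1])
        cy = rng.uniform(y[0], y[-1])
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 < cfg.fibrosis_radius_mm ** 2
        fibrosis[mask] = cfg.fibrosis_thickness_um
    # fibrosis hangs from the array face; it cannot exceed the gap
    fibrosis = np.minimum(fibrosis, np.clip(gap, 0.0, None) * 1000.0)

    return RetinaGeometry(x=x, y=y, inner_surface_z=inner_z,
                          thickness_um=thickness, fibrosis_um=fibrosis,
                          array_plane=(z0, gx, gy),
                          vitreous_height_mm=cfg.vitreous_height_mm,
                          choroid_thickness_mm=cfg.choroid_thickness_mm,
                          config=cfg)


def measure_electrodes(geometry: RetinaGeometry, layout: ArrayLayout) -> list[ElectrodeMeasurement]:
    """OCT-analogue measurements at each electrode center.

    The electrode–retina distance is the vertical gap from the electrode
    face to the inner retinal surface at the electrode center; for an
    apposed electrode with fibrosis underneath, the gap is filled by the
    fibrotic tissue so distance equals fibrosis thickness.  Electrodes whose
    centers fall outside the lateral grid are flagged not visible (the
    analogue of an electrode not captured by any B-scan).
    """
    out = []
    for e in layout.electrodes:
        cx, cy = e.center_xy
        if not geometry.contains(cx, cy):
            out.append(ElectrodeMeasurement(e.label, np.nan, np.nan, np.nan,
                                            visible=False))
            continue
        inner = geometry.sample("inner_surface_z", cx, cy)
        dist = float(geometry.plane_z(cx, cy) - inner)
        out.append(ElectrodeMeasurement(
            label=e.label,
            distance_mm=max(dist, 0.0),
            thickness_mm=geometry.sample("thickness_um", cx, cy) / 1000.0,
            fibrosis_mm=geometry.sample("fibrosis_um", cx, cy) / 1000.0,
        ))
    return out


def synth_thresholds(measurements: list[ElectrodeMeasurement],
                     coefficients: dict[str, float],
                     noise_sd: float = 0.0, seed: int = 0,
                     floor_uA: float = 1.0) -> list[ElectrodeMeasurement]:
    """Fill perceptual thresholds with a linear model plus Gaussian noise.

    ``coefficients`` maps covariate names (``intercept``, ``distance_mm``,
    ``thickness_mm``, ``fibrosis_mm``, ``impedance_kohm``) to slopes in
    µA per covariate unit.  Thresholds are clipped below at ``floor_uA``.
    A typical virtual patient uses a positive slope on distance and a
    negative slope on thickness, the directions the clinical regressions
    consistently find.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for m in measurements:
        y = coefficients.get("intercept", 0.0)
        for name, slope in coefficients.items():
            if name == "intercept":
                continue
            y += slope * getattr(m, name)
        y += rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        out.append(ElectrodeMeasurement(**{**asdict(m),
                                           "threshold_uA": max(y, floor_uA)}))
    return out


def synth_impedances(measurements: list[ElectrodeMeasurement],
                     coefficients: dict[str, float] | None = None,
                     noise_sd: float = 0.5, seed: int = 0,
                     floor_kohm: float = 1.0) -> list[ElectrodeMeasurement]:
    """Fill electrode impedances (kΩ), linear in geometry covariates + noise."""
    coefficients = coefficients or {"intercept": 20.0, "distance_mm": -10.0}
    rng = np.random.default_rng(seed)
    out = []
    for m in measurements:
        z = coefficients.get("intercept", 0.0)
        for name, slope in coefficients.items():
            if name == "intercept":
                continue
            z += slope * getattr(m, name)
        z += rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        out.append(ElectrodeMeasurement(**{**asdict(m),
                                           "impedance_kohm": max(z, floor_kohm)}))
    return out


def measurements_to_frame(measurements: list[ElectrodeMeasurement]) -> pd.DataFrame:
    return pd.DataFrame([asdict(m) for m in measurements])[MEASUREMENT_COLUMNS]


def frame_to_measurements(df: pd.DataFrame) -> list[ElectrodeMeasurement]:
    return [ElectrodeMeasurement(**{k: row[k] for k in MEASUREMENT_COLUMNS})
            for _, row in df.iterrows()]


def save_geometry(geometry: RetinaGeometry, path: str | Path) -> None:
    """Persist to an .npz array container with a JSON metadata entry."""
    meta = {"array_plane": list(geometry.array_plane),
            "vitreous_height_mm": geometry.vitreous_height_mm,
            "choroid_thickness_mm": geometry.choroid_thickness_mm,
            "config": asdict(geometry.config) if geometry.config else None}
    np.savez(path, x=geometry.x, y=geometry.y,
             inner_surface_z=geometry.inner_surface_z,
             thickness_um=geometry.thickness_um,
             fibrosis_um=geometry.fibrosis_um,
             meta_json=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8))


def load_geometry(path: str | Path) -> RetinaGeometry:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"geometry file not found: {path}")
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta_json"].tobytes()).decode())
        cfg = SyntheticRetinaConfig(**meta["config"]) if meta["config"] else None
        return RetinaGeometry(
            x=z["x"], y=z["y"], inner_surface_z=z["inner_surface_z"],
            thickness_um=z["thickness_um"], fibrosis_um=z["fibrosis_um"],
            array_plane=tuple(meta["array_plane"]),
            vitreous_height_mm=meta["vitreous_height_mm"],
            choroid_thickness_mm=meta["choroid_thickness_mm"], config=cfg)
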
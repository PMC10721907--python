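"""Microelectrode array layouts.

The Argus II epiretinal implant carries 60 platinum disc electrodes
(200 µm diameter) in a 6 × 10 rectangular grid at 525 µm pitch, labelled
A1–F10 (rows A–F, columns 1–10).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

__all__ = ["Electrode", "ArrayLayout", "make_argus2_layout"]


@dataclass(frozen=True)
class Electrode:
    """A single disc electrode site.

    Coordinates are in mm in the retinal plane; the diameter is in µm.
    """

    label: str
    center_xy: tuple[float, float]
    diameter_um: float
    row: int
    col: int


@dataclass(frozen=True)
class ArrayLayout:
    """Rectangular grid of disc electrodes plus the insulating substrate outline."""

    electrodes: tuple[Electrode, ...]
    pitch_um: float
    substrate_outline: Polygon = field(compare=False, default=None)

    def __post_init__(self):
        labels = [e.label for e in self.electrodes]
        if len(set(labels)) != len(labels):
            raise ValueError("electrode labels must be unique")

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.electrodes]

    def __getitem__(self, label: str) -> Electrode:
        for e in self.electrodes:
            if e.label == label:
                return e
        raise KeyError(f"no electrode labelled {label!r}")

    def centers(self) -> np.ndarray:
        """(n, 2) electrode centers in mm."""
        return np.array([e.center_xy for e in self.electrodes], dtype=float)


def make_argus2_layout(pitch_um: float = 525.0, diameter_um: float = 200.0,
                       center_xy: tuple[float, float] = (0.0, 0.0)) -> ArrayLayout:
    """Build the 6 × 10 Argus II grid, labels A1–F10, centered at ``center_xy``.

    Parameters
    ----------
    pitch_um : float
        Nearest-neighbour center spacing, µm (default 525).
    diameter_um : float
        Disc electrode diameter, µm (default 200).

    Returns
    -------
    ArrayLayout
        60 electrodes; row letters A–F run along y, column numbers 1–10 along x.
    """
    if not pitch_um > diameter_um > 0:
        raise ValueError("require pitch > diameter > 0")
    n_rows, n_cols = 6, 10
    pitch_mm = pitch_um / 1000.0
    x0 = center_xy[0] - (n_cols - 1) / 2.0 * pitch_mm
    y0 = center_xy[1] - (n_rows - 1) / 2.0 * pitch_mm
    electrodes = []
    for r in range(n_rows):
        for c in range(n_cols):
            electrodes.append(Electrode(
                label=f"{string.ascii_uppercase[r]}{c + 1}",
                center_xy=(x0 + c * pitch_mm, y0 + r * pitch_mm),
                diameter_um=diameter_um,
                row=r, col=c,
            ))
    margin = pitch_mm / 2.0
    outline = Polygon([
        (x0 - margin, y0 - margin),
        (x0 + (n_cols - 1) * pitch_mm + margin, y0 - margin),
        (x0 + (n_cols - 1) * pitch_mm + margin, y0 + (n_rows - 1) * pitch_mm + margin),
        (x0 - margin, y0 + (n_rows - 1) * pitch_mm + margin),
    ])
    return ArrayLayout(electrodes=tuple(electrodes), pitch_um=pitch_um,
                       substrate_outline=outline)
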
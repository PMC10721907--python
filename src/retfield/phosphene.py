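"""Per-electrode threshold maps and phosphene-size predictions.

Per-neuron activation thresholds are aggregated into an electrode-level
map (the minimum over the retained target population), activation
patterns at multiples of that minimum, and the slope of activated area
versus amplitude.  A neuron counts as activated at amplitude A when its
own threshold is ≤ A — valid because each neuron's response is monotone
in amplitude, so the 1.2×–6× sweep costs nothing beyond the threshold
computation.  Activated-area is the convex hull of activated cell bodies,
in mm² and in squared degrees of visual angle at 288 µm/degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import MultiPoint

from .axon import MM_PER_DEG

__all__ = ["DEFAULT_AMPLITUDE_MULTIPLES", "ElectrodeThresholds", "ThresholdMap",
           "ActivationPattern", "electrode_threshold_map", "activation_pattern",
           "size_amplitude_slope"]

DEFAULT_AMPLITUDE_MULTIPLES = (1.2, 2.0, 3.0, 4.0, 5.0, 6.0)


@dataclass
class ElectrodeThresholds:
    """Per-neuron thresholds for one electrode's target population.

    ``excluded`` marks neurons removed from aggregation (thin retina, or
    inexcitable/NaN thresholds).  ``flagged`` electrodes have no retained
    neuron and carry no minimum.
    """

    label: str
    soma_xy_mm: np.ndarray          # (n, 2)
    thresholds_uA: np.ndarray       # (n,), NaN = inexcitable
    excluded: np.ndarray            # (n,) bool

    def __post_init__(self):
        self.excluded = np.asarray(self.excluded, bool) | \
            ~np.isfinite(self.thresholds_uA)

    @property
    def retained(self) -> np.ndarray:
        return ~self.excluded

    @property
    def flagged(self) -> bool:
        return not self.retained.any()

    @property
    def min_threshold_uA(self) -> float:
        if self.flagged:
            return np.nan
        return float(np.min(self.thresholds_uA[self.retained]))


@dataclass
class ThresholdMap:
    entries: dict[str, ElectrodeThresholds]
    provenance: dict = field(default_factory=dict)

    def minima(self) -> dict[str, float]:
        return {lbl: e.min_threshold_uA for lbl, e in self.entries.items()}


@dataclass
class ActivationPattern:
    amplitude_multiple: float
    activated_xy_mm: np.ndarray
    hull_area_mm2: float

    @property
    def hull_area_deg2(self) -> float:
        return self.hull_area_mm2 / MM_PER_DEG ** 2

    @property
    def n_activated(self) -> int:
        return len(self.activated_xy_mm)


def electrode_threshold_map(populations: dict[str, np.ndarray],
                            thresholds: dict[str, np.ndarray],
                            excluded: dict[str, np.ndarray] | None = None,
                            provenance: dict | None = None) -> ThresholdMap:
    """Aggregate per-neuron thresholds into a per-electrode map.

    ``populations`` maps electrode labels to (n, 2+) soma coordinates,
    ``thresholds`` to matching per-neuron thresholds, and ``excluded``
    (optional) to removal masks from the thin-retina rule.  Minima can be
    re-computed after exclusion simply by rebuilding the map with an
    updated mask; the per-neuron thresholds themselves never change.
    """
    entries = {}
    for lbl, somas in populations.items():
        th = np.asarray(thresholds[lbl], dtype=float)
        somas = np.asarray(somas, dtype=float)[:, :2]
        if len(th) != len(somas):
            raise ValueError(f"electrode {lbl!r}: {len(somas)} somata but "
                             f"{len(th)} thresholds")
        excl = (np.asarray(excluded[lbl], bool) if excluded and lbl in excluded
                else np.zeros(len(th), bool))
        entries[lbl] = ElectrodeThresholds(lbl, somas, th, excl)
    return ThresholdMap(entries=entries, provenance=provenance or {})


def activation_pattern(entry: ElectrodeThresholds,
                       k: float) -> ActivationPattern:
    """Activated somata and convex-hull area at ``k`` × the electrode minimum.

    Degenerate activated sets (< 3 non-collinear somata) have zero area.
    """
    if k < 1.0:
        raise ValueError("amplitude multiple k must be >= 1")
    if entry.flagged:
        return ActivationPattern(k, np.empty((0, 2)), 0.0)
    amp = k * entry.min_threshold_uA
    act = entry.retained & (entry.thresholds_uA <= amp + 1e-12)
    xy = entry.soma_xy_mm[act]
    area = MultiPoint(xy).convex_hull.area if len(xy) >= 3 else 0.0
    return ActivationPattern(k, xy, float(area))


def size_amplitude_slope(patterns: list[ActivationPattern]
                         ) -> tuple[float, float, float]:
    """Least-squares line of hull area (deg²) against amplitude multiple.

    Returns ``(slope, intercept, r_squared)`` with slope in
    deg²/(× threshold); all-zero areas yield NaN slope (undefined).
    """
    if len(patterns) < 3:
        raise ValueError("need at least 3 amplitude multiples")
    k = np.array([p.amplitude_multiple for p in patterns])
    area = np.array([p.hull_area_deg2 for p in patterns])
    if np.all(area == 0):
        return np.nan, np.nan, np.nan
    A = np.column_stack([k, np.ones_like(k)])
    (slope, intercept), res, *_ = np.linalg.lstsq(A, area, rcond=None)
    ss_tot = float(np.sum((area - area.mean()) ** 2))
    ss_res = float(np.sum((area - A @ np.array([slope, intercept])) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), float(r2)
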
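"""Compound graft metrics: integrated fiber density, D/V ratio, survival."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GraftMetrics",
    "integrated_fiber_density",
    "dorsoventral_ratio",
    "survival_percent",
    "expected_dopaminergic_cells",
]


@dataclass
class GraftMetrics:
    """Per-animal quantification summary.

    ``integrated_fiber_density`` is the total thresholded TH-ir fiber
    area (mm², summed over analysed sections) multiplied by the relative
    fiber density expressed as a fraction of the intact striatum; only
    relative comparisons of this compound score are meaningful.
    """

    animal_id: str
    group: str
    core_volume_mm3: float
    fiber_volume_mm3: float
    relative_density_percent: float
    integrated_fiber_density: float
    dv_ratio: float
    th_cell_count: float
    cells_per_mm3: float
    survival_percent: float
    flags: dict = field(default_factory=dict)


def integrated_fiber_density(total_fiber_area: float, rel_density_percent: float) -> float:
    """Compound reinnervation score: fiber area x relative density.

    ``total_fiber_area`` is the summed per-section thresholded fiber
    area (any fixed unit); ``rel_density_percent`` is the lesioned-side
    fiber OD as a percentage of the intact striatum.  The score is
    bilinear in the two inputs.
    """
    if total_fiber_area < 0:
        raise ValueError("fiber area must be >= 0")
    if rel_density_percent < 0:
        raise ValueError("relative density must be >= 0 percent")
    return total_fiber_area * rel_density_percent / 100.0


def dorsoventral_ratio(
    fiber_masks: Sequence[np.ndarray],
    core_masks: Sequence[np.ndarray],
    per_section: bool = False,
) -> float:
    """Dorsal/ventral split of fiber-positive pixels about the core centre.

    The centre row is the area-weighted centroid row of the graft-core
    masks pooled over all sections ("dorsal" = smaller row indices); the
    ratio is fiber pixels strictly dorsal of that row over pixels
    strictly ventral, with pixels on the centre row split evenly.  With
    ``per_section`` the centre is recomputed per section before pooling
    the dorsal and ventral counts.

    Returns ``inf`` (flagged by the caller) when no ventral pixels exist.
    """
    if len(fiber_masks) != len(core_masks):
        raise ValueError("fiber and core mask sequences must align per section")
    core_rows = []
    core_weights = []
    for cmask in core_masks:
        cmask = np.asarray(cmask, dtype=bool)
        if cmask.any():
            rows = np.nonzero(cmask)[0]
            core_rows.append(rows.mean())
            core_weights.append(rows.size)
    if not core_rows:
        raise ValueError("no section has a nonempty graft-core mask")
    pooled_center = float(np.average(core_rows, weights=core_weights))

    dorsal = ventral = 0.0
    for fmask, cmask in zip(fiber_masks, core_masks):
        fmask = np.asarray(fmask, dtype=bool)
        if not fmask.any():
            continue
        if per_section:
            cmask = np.asarray(cmask, dtype=bool)
            if cmask.any():
                center = float(np.nonzero(cmask)[0].mean())
            else:
                center = pooled_center
        else:
            center = pooled_center
        rows = np.nonzero(fmask)[0].astype(float)
        dorsal += float(np.sum(rows < center))
        ventral += float(np.sum(rows > center))
        on_line = float(np.sum(rows == center))
        dorsal += on_line / 2.0
        ventral += on_line / 2.0
    if ventral == 0:
        warnings.warn("no ventral fiber pixels; dorsoventral ratio is infinite", stacklevel=2)
        return float("inf")
    return dorsal / ventral


def expected_dopaminergic_cells(cells_transplanted: float, da_fraction: float) -> float:
    """Expected dopaminergic cells in the graft (e.g. 10% of 130,000)."""
    if cells_transplanted <= 0:
        raise ValueError("cells_transplanted must be > 0")
    if not 0 < da_fraction <= 1:
        raise ValueError("da_fraction must be in (0, 1]")
    return cells_transplanted * da_fraction


def survival_percent(
    th_count: float, cells_transplanted: float, da_fraction: float
) -> float:
    """TH-ir cell survival as % of the expected dopaminergic cells."""
    if th_count < 0:
        raise ValueError("TH-ir cell count must be >= 0")
    expected = expected_dopaminergic_cells(cells_transplanted, da_fraction)
    return 100.0 * th_count / expected
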
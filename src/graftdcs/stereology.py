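"""Volume reconstruction from serial sections and corrected cell counts.

Two classical estimators:

* **Truncated-cone (frustum) interpolation.**  Consecutive section
  profiles are treated as circles of area A_n and A_{n+1}; the tissue
  between them (spacing h) is a frustum,

      V_n = (h/3) * (A_n + sqrt(A_n * A_{n+1}) + A_{n+1}),

  which is the radius form V = h*pi/3*(R^2 + R r + r^2) after
  substituting r = sqrt(A/pi).  Summing over consecutive pairs gives the
  per-animal volume; no end caps are added beyond the first and last
  section.

* **Abercrombie profile-count correction.**  Counting every profile a
  sphere of mean height D leaves on sections of thickness T overcounts
  objects by the factor (T + D)/T; the corrected count is
  N = n * T / (T + D).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import SectionGeometry

__all__ = [
    "AreaSeries",
    "CellCountEstimate",
    "frustum_volume",
    "series_volume",
    "abercrombie_estimate",
    "series_cell_estimate",
    "cells_per_volume",
]

_UNIT_TO_MM2 = {"mm2": 1.0, "um2": 1e-6}


@dataclass(frozen=True)
class AreaSeries:
    """Ordered per-section profile areas with their sampling interval."""

    areas: tuple[float, ...]
    spacing_um: float
    unit: str = "um2"
    label: str = "graft core"

    def __post_init__(self) -> None:
        if len(self.areas) < 1:
            raise ValueError("an area series needs at least one section")
        if any(a < 0 for a in self.areas):
            raise ValueError("section areas must be >= 0")
        if self.spacing_um <= 0:
            raise ValueError("section spacing must be > 0 µm")
        if self.unit not in _UNIT_TO_MM2:
            raise ValueError(f"unit must be one of {sorted(_UNIT_TO_MM2)}")

    @property
    def areas_mm2(self) -> np.ndarray:
        return np.asarray(self.areas, dtype=float) * _UNIT_TO_MM2[self.unit]


@dataclass(frozen=True)
class CellCountEstimate:
    """Raw profile count and its Abercrombie-corrected object count."""

    raw_profiles: float
    section_thickness_um: float
    object_height_um: float
    corrected_count: float


def frustum_volume(area_n: float, area_n1: float, spacing: float) -> float:
    """Volume of the truncated cone between two consecutive sections.

    Areas and spacing must share a length unit (e.g. mm² and mm -> mm³).
    Symmetric in the two areas and linear in the spacing; degenerates to
    a cylinder (equal areas) or a cone (one zero area).
    """
    if area_n < 0 or area_n1 < 0:
        raise ValueError("section areas must be >= 0")
    if spacing <= 0:
        raise ValueError("section spacing must be > 0")
    return spacing / 3.0 * (area_n + np.sqrt(area_n * area_n1) + area_n1)


def series_volume(series: AreaSeries) -> float:
    """Total frustum-interpolated volume of an area series, in mm³.

    Sums the truncated-cone volumes over the N-1 consecutive section
    pairs.  A single-section series has no pairs and returns 0 with a
    warning.
    """
    areas = series.areas_mm2
    if len(areas) == 1:
        warnings.warn(
            "area series has a single section; frustum interpolation needs at "
            "least two, returning 0 mm³",
            stacklevel=2,
        )
        return 0.0
    h_mm = series.spacing_um * 1e-3
    pairs = zip(areas[:-1], areas[1:])
    return float(sum(frustum_volume(a, b, h_mm) for a, b in pairs))


def abercrombie_estimate(
    n_profiles: float, thickness_um: float, object_height_um: float
) -> CellCountEstimate:
    """Correct a profile count for objects spanning multiple sections.

    N = n * T / (T + D).  The result is kept as a float; rounding is left
    to the reporting layer.
    """
    if n_profiles < 0:
        raise ValueError("profile count must be >= 0")
    if thickness_um <= 0:
        raise ValueError("section thickness must be > 0 µm")
    if object_height_um < 0:
        raise ValueError("object height must be >= 0 µm")
    corrected = n_profiles * thickness_um / (thickness_um + object_height_um)
    return CellCountEstimate(
        raw_profiles=float(n_profiles),
        section_thickness_um=float(thickness_um),
        object_height_um=float(object_height_um),
        corrected_count=float(corrected),
    )


def series_cell_estimate(
    profile_counts: Sequence[float],
    geometry: SectionGeometry,
    object_height_um: float,
) -> float:
    """Total object count from profile counts on a 1-in-k sampled series.

    Applies the Abercrombie correction to the summed profile count and
    scales by the inverse sampling fraction h/T:

        N_total = sum(n_s) * T/(T+D) * h/T = sum(n_s) * h / (T + D).

    With contiguous sections (gap 0, h = T) this reduces to the plain
    Abercrombie estimate.
    """
    total = float(np.sum(np.asarray(profile_counts, dtype=float)))
    est = abercrombie_estimate(total, geometry.thickness_um, object_height_um)
    return est.corrected_count * geometry.spacing_um / geometry.thickness_um


def cells_per_volume(corrected_count: float, core_volume_mm3: float) -> float:
    """Cell density in cells/mm³ of graft core."""
    if core_volume_mm3 <= 0:
        raise ValueError("core volume must be > 0 mm³")
    return corrected_count / core_volume_mm3
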
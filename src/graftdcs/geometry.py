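"""Section geometry and simple 3-D region primitives.

Coordinate convention
---------------------
The tissue block lives in a right-handed micrometre coordinate system
``(x, y, z)``:

* ``z`` is the cutting axis; sections are planes of constant ``z``.
* ``y`` maps to image rows; *dorsal* means smaller ``y`` (smaller row index).
* ``x`` maps to image columns (mediolateral axis); the lesioned/grafted
  hemisphere sits at small ``x``, the intact hemisphere at large ``x``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np

__all__ = ["SectionGeometry", "Ellipsoid", "AxisSlab"]


@dataclass(frozen=True)
class SectionGeometry:
    """Physical sampling geometry of a serial-section series.

    Parameters
    ----------
    thickness_um : float
        Section thickness ``T`` in µm (must be > 0).
    gap_um : float
        Unsampled tissue between consecutive analysed sections, in µm
        (>= 0).  The centre-to-centre spacing used by all volume
        reconstruction is ``spacing_um = thickness_um + gap_um``.
    pixel_size_um : float
        In-plane sampling, µm per pixel.
    width_px, height_px : int
        Image width (columns) and height (rows) in pixels.
    """

    thickness_um: float = 40.0
    gap_um: float = 120.0
    pixel_size_um: float = 5.16
    width_px: int = 892
    height_px: int = 582

    def __post_init__(self) -> None:
        if self.thickness_um <= 0:
            raise ValueError("section thickness must be > 0 µm")
        if self.gap_um < 0:
            raise ValueError("inter-section gap must be >= 0 µm")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be > 0 µm")
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")

    @property
    def spacing_um(self) -> float:
        """Centre-to-centre section spacing h = T + gap, µm."""
        return self.thickness_um + self.gap_um

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SectionGeometry":
        return cls(**d)


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: centre and semi-axes in µm."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("ellipsoid semi-axes must be positive")

    @property
    def volume_um3(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c

    @property
    def volume_mm3(self) -> float:
        return self.volume_um3 * 1e-9

    def normalized_radius(self, x, y, z):
        """Ellipsoidal coordinate m: m < 1 inside, m = 1 on the surface.

        Accepts scalars or broadcastable arrays (µm).
        """
        cx, cy, cz = self.center
        ax, ay, az = self.semi_axes
        return np.sqrt(
            ((np.asarray(x) - cx) / ax) ** 2
            + ((np.asarray(y) - cy) / ay) ** 2
            + ((np.asarray(z) - cz) / az) ** 2
        )

    def contains(self, x, y, z):
        return self.normalized_radius(x, y, z) <= 1.0

    def section_mask(self, xx, yy, z: float):
        """Boolean mask of the ellipsoid on the plane at height ``z``."""
        return self.normalized_radius(xx, yy, z) <= 1.0

    def to_dict(self) -> dict:
        return {"center": list(self.center), "semi_axes": list(self.semi_axes)}

    @classmethod
    def from_dict(cls, d: dict) -> "Ellipsoid":
        return cls(center=tuple(d["center"]), semi_axes=tuple(d["semi_axes"]))


@dataclass(frozen=True)
class AxisSlab:
    """Axis-aligned box; ``None`` bounds extend to the full block."""

    y_range: tuple[float, float]
    x_range: tuple[float, float] | None = None
    z_range: tuple[float, float] | None = None

    def contains(self, x, y, z):
        x = np.asarray(x)
        y = np.asarray(y)
        z = np.asarray(z)
        inside = (y >= self.y_range[0]) & (y <= self.y_range[1])
        if self.x_range is not None:
            inside = inside & (x >= self.x_range[0]) & (x <= self.x_range[1])
        if self.z_range is not None:
            inside = inside & (z >= self.z_range[0]) & (z <= self.z_range[1])
        return inside

    def section_mask(self, xx, yy, z: float):
        return self.contains(xx, yy, np.full_like(np.asarray(xx, dtype=float), z))

    def to_dict(self) -> dict:
        return {
            "y_range": list(self.y_range),
            "x_range": None if self.x_range is None else list(self.x_range),
            "z_range": None if self.z_range is None else list(self.z_range),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AxisSlab":
        return cls(
            y_range=tuple(d["y_range"]),
            x_range=None if d.get("x_range") is None else tuple(d["x_range"]),
            z_range=None if d.get("z_range") is None else tuple(d["z_range"]),
        )
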
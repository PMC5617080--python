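"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .geometry import SectionGeometry

__all__ = ["ROI_LABELS", "SectionStack", "ROISet", "GroundTruthRecord", "Dataset"]

#: Integer labels used in ROI label-mask images. 0 = outside any ROI.
#: Graft-core pixels are anatomically part of the lesioned striatum; the
#: label image gives them the dedicated graft_core label and
#: :meth:`ROISet.mask` re-adds them to ``striatum_ipsi``.
ROI_LABELS = {
    "striatum_ipsi": 1,
    "striatum_contra": 2,
    "corpus_callosum": 3,
    "graft_core": 4,
    "artifact": 5,
}


@dataclass
class SectionStack:
    """Ordered grayscale serial sections plus their physical geometry.

    ``images`` has shape (n_sections, height, width); darker pixels carry
    more stain (brightfield DAB convention).  ``z_positions_um`` are the
    z coordinates of each slab's proximal face along the cutting axis.
    """

    images: np.ndarray
    geometry: SectionGeometry
    z_positions_um: np.ndarray

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        self.z_positions_um = np.asarray(self.z_positions_um, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must be a (sections, rows, cols) array")
        if len(self.z_positions_um) != self.n_sections:
            raise ValueError("one z position is required per section")
        if np.any(np.diff(self.z_positions_um) <= 0):
            raise ValueError("sections must be ordered by position along the cutting axis")

    @property
    def n_sections(self) -> int:
        return self.images.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1:]


@dataclass
class ROISet:
    """Per-section integer label masks (see :data:`ROI_LABELS`)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a (sections, rows, cols) array")
        unknown = set(np.unique(self.labels)) - ({0} | set(ROI_LABELS.values()))
        if unknown:
            raise ValueError(f"unknown ROI labels in mask: {sorted(unknown)}")

    def mask(self, name: str, section: Optional[int] = None) -> np.ndarray:
        """Boolean mask for a named ROI (one section, or the full stack)."""
        if name not in ROI_LABELS:
            raise KeyError(f"unknown ROI name {name!r}; known: {sorted(ROI_LABELS)}")
        lab = self.labels if section is None else self.labels[section]
        m = lab == ROI_LABELS[name]
        if name == "striatum_ipsi":
            # graft core lies inside the lesioned striatum
            m = m | (lab == ROI_LABELS["graft_core"])
        return m

    @property
    def n_sections(self) -> int:
        return self.labels.shape[0]


@dataclass
class GroundTruthRecord:
    """Analytic/numeric ground truth attached to a synthetic dataset."""

    core_volume_mm3: float
    fiber_volume_mm3: float
    cell_count: int
    dv_ratio: float
    dv_mass_ratio: float
    seed: Optional[int] = None
    coupling: Optional[dict] = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthRecord":
        return cls(**d)


@dataclass
class Dataset:
    """A section stack, its ROI masks, geometry, and (optionally) truth."""

    stack: SectionStack
    rois: ROISet
    truth: Optional[GroundTruthRecord] = None

    def __post_init__(self) -> None:
        if self.rois.labels.shape != self.stack.images.shape:
            raise ValueError(
                "ROI label stack shape "
                f"{self.rois.labels.shape} does not match image stack shape "
                f"{self.stack.images.shape}"
            )

    @property
    def geometry(self) -> SectionGeometry:
        return self.stack.geometry

    @property
    def n_sections(self) -> int:
        return self.stack.n_sections
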
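"""Per-section optical-density and fiber-segmentation operations.

Brightfield DAB sections are normalized per section against a
stain-negative reference region (the corpus callosum): the optical
density of a pixel with raw intensity I is

    OD(p) = max(0, log10(I_ref / I(p)))

with I_ref the mean raw intensity inside the reference mask.  Pixels at
least as bright as the reference get OD 0; zero-intensity pixels are
clamped to 1 before the log.  The definition is ratiometric, so fiber
areas are invariant under intensity rescalings that preserve the ratio
to the reference mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "ODImage",
    "FiberSegmentation",
    "ThresholdRule",
    "section_od",
    "resolve_threshold",
    "segment_fibers",
    "mirror_mask",
    "relative_fiber_density",
    "count_cell_profiles",
]


@dataclass
class ODImage:
    """Per-pixel optical density of one section."""

    od: np.ndarray
    reference_mean: float
    section_index: int = 0

    def __post_init__(self) -> None:
        self.od = np.asarray(self.od, dtype=float)


@dataclass(frozen=True)
class ThresholdRule:
    """How the fiber-positive OD threshold θ is chosen.

    ``kind="reference_sd"`` sets θ = mean + k·SD of the OD inside a
    reference region (the same rule transfers to the contralateral
    hemisphere); ``kind="fixed"`` uses ``value`` directly.
    """

    kind: str = "reference_sd"
    k: float = 3.0
    value: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("reference_sd", "fixed"):
            raise ValueError("threshold rule kind must be 'reference_sd' or 'fixed'")

    def describe(self) -> str:
        if self.kind == "fixed":
            return f"fixed(theta={self.value:g})"
        return f"reference_mean+{self.k:g}*SD"


@dataclass
class FiberSegmentation:
    """Binary fiber mask and its bookkeeping for one section."""

    mask: np.ndarray
    positive_pixels: int
    area_um2: float
    threshold: float
    threshold_rule: str
    mean_od_positive: float
    empty_analysis_mask: bool = False


def section_od(image: np.ndarray, reference_mask: np.ndarray, section_index: int = 0) -> ODImage:
    """Normalize one section to its stain-negative reference region."""
    image = np.asarray(image, dtype=float)
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if reference_mask.shape != image.shape:
        raise ValueError("reference mask shape does not match the image")
    if not reference_mask.any():
        raise ValueError("reference mask is empty; cannot normalize the section")
    ref = float(image[reference_mask].mean())
    od = np.log10(ref / np.maximum(image, 1.0))
    np.clip(od, 0.0, None, out=od)
    return ODImage(od=od, reference_mean=ref, section_index=section_index)


def resolve_threshold(
    od_image: ODImage, rule: ThresholdRule, reference_mask: Optional[np.ndarray] = None
) -> float:
    """Materialize a threshold rule into a numeric θ for one section."""
    if rule.kind == "fixed":
        return float(rule.value)
    if reference_mask is None or not np.any(reference_mask):
        raise ValueError("reference_sd threshold rule needs a nonempty reference mask")
    vals = od_image.od[np.asarray(reference_mask, dtype=bool)]
    return float(vals.mean() + rule.k * vals.std())


def segment_fibers(
    od_image: ODImage,
    analysis_mask: np.ndarray,
    threshold_rule: ThresholdRule,
    reference_mask: Optional[np.ndarray] = None,
    pixel_size_um: float = 5.16,
) -> FiberSegmentation:
    """Count pixels strictly above θ inside the analysis mask.

    ``analysis_mask`` is expected to already exclude the graft core and
    artifact labels.  An empty analysis mask yields area 0 with a warning
    flag rather than an error.
    """
    analysis_mask = np.asarray(analysis_mask, dtype=bool)
    theta = resolve_threshold(od_image, threshold_rule, reference_mask)
    if not analysis_mask.any():
        return FiberSegmentation(
            mask=np.zeros_like(analysis_mask),
            positive_pixels=0,
            area_um2=0.0,
            threshold=theta,
            threshold_rule=threshold_rule.describe(),
            mean_od_positive=float("nan"),
            empty_analysis_mask=True,
        )
    mask = analysis_mask & (od_image.od > theta)
    count = int(mask.sum())
    mean_od = float(od_image.od[mask].mean()) if count else float("nan")
    return FiberSegmentation(
        mask=mask,
        positive_pixels=count,
        area_um2=count * pixel_size_um**2,
        threshold=theta,
        threshold_rule=threshold_rule.describe(),
        mean_od_positive=mean_od,
    )


def mirror_mask(mask: np.ndarray) -> np.ndarray:
    """Flip a 2-D mask horizontally (column c -> width-1-c)."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mirror_mask expects a single 2-D mask")
    return mask[:, ::-1].copy()


@dataclass
class RelativeDensityResult:
    percent: float
    lesioned_mean_od: float
    contra_mean_od: float
    lesioned_pixels: int
    contra_pixels: int
    undefined: bool = False
    warning: Optional[str] = None
    aggregation: str = "pooled-across-sections"


def relative_fiber_density(
    od_images: Sequence[ODImage],
    fiber_masks: Sequence[np.ndarray],
    contra_masks: Sequence[np.ndarray],
    threshold_rule: ThresholdRule,
    contra_reference_masks: Optional[Sequence[np.ndarray]] = None,
) -> RelativeDensityResult:
    """Fiber density of the lesioned side as % of the intact striatum.

    For each section the lesioned-side fiber mask is mirrored about the
    vertical midline, restricted to the contralateral striatum, and
    thresholded with a θ derived from the unlesioned hemisphere (same
    rule, mirrored reference region).  Mean OD over positive pixels is
    pooled across sections on each side and the ratio reported in
    percent.
    """
    if not (len(od_images) == len(fiber_masks) == len(contra_masks)):
        raise ValueError("od_images, fiber_masks and contra_masks must align per section")
    les_sum = les_n = 0.0
    con_sum = con_n = 0.0
    for i, (odi, fmask, cmask) in enumerate(zip(od_images, fiber_masks, contra_masks)):
        fmask = np.asarray(fmask, dtype=bool)
        if fmask.any():
            les_sum += float(odi.od[fmask].sum())
            les_n += int(fmask.sum())
        region = mirror_mask(fmask) & np.asarray(cmask, dtype=bool)
        if not region.any():
            continue
        ref = None
        if threshold_rule.kind == "reference_sd":
            if contra_reference_masks is not None:
                ref = contra_reference_masks[i]
            else:
                raise ValueError(
                    "reference_sd rule needs contra_reference_masks to derive the "
                    "contralateral threshold"
                )
        theta_c = resolve_threshold(odi, threshold_rule, ref)
        pos = region & (odi.od > theta_c)
        con_sum += float(odi.od[pos].sum())
        con_n += int(pos.sum())
    if les_n == 0:
        return RelativeDensityResult(
            percent=0.0,
            lesioned_mean_od=float("nan"),
            contra_mean_od=con_sum / con_n if con_n else float("nan"),
            lesioned_pixels=0,
            contra_pixels=int(con_n),
            warning="lesioned-side fiber mask is empty",
        )
    if con_n == 0:
        return RelativeDensityResult(
            percent=float("nan"),
            lesioned_mean_od=les_sum / les_n,
            contra_mean_od=float("nan"),
            lesioned_pixels=int(les_n),
            contra_pixels=0,
            undefined=True,
            warning="no fiber-positive pixels on the contralateral side",
        )
    contra_mean = con_sum / con_n
    les_mean = les_sum / les_n
    return RelativeDensityResult(
        percent=100.0 * les_mean / contra_mean,
        lesioned_mean_od=les_mean,
        contra_mean_od=contra_mean,
        lesioned_pixels=int(les_n),
        contra_pixels=int(con_n),
    )


def count_cell_profiles(
    image: np.ndarray,
    core_mask: np.ndarray,
    intensity_threshold: float,
    dilate_px: int = 10,
    min_area_px: int = 1,
) -> int:
    """Count TH-ir soma profiles in and around the graft core.

    Somata are rendered/stained far darker than fibers or the core
    neuropil, so a profile is a connected component of pixels strictly
    darker than ``intensity_threshold`` within the core mask dilated by
    ``dilate_px`` (cells sit at the core border).
    """
    image = np.asarray(image, dtype=float)
    core_mask = np.asarray(core_mask, dtype=bool)
    if not core_mask.any():
        return 0
    # separable square dilation: cheap and close enough to a disk here
    size = 2 * dilate_px + 1
    search = ndimage.maximum_filter(core_mask.astype(np.uint8), size=size).astype(bool)
    candidates = search & (image < intensity_threshold)
    if not candidates.any():
        return 0
    labeled = measure.label(candidates, connectivity=2)
    count = 0
    for region in measure.regionprops(labeled):
        if region.area >= min_area_px:
            count += 1
    return count
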
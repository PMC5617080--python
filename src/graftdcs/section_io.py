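"""Disk layout for serial-section datasets.

A dataset directory contains::

    sections/section_000.tif ...   grayscale sections (8- or 16-bit TIFF)
    masks/mask_000.tif ...         integer ROI label masks, one per section
    metadata.json                  geometry (µm units), label table, z positions
    ground_truth.json              optional synthetic ground truth

TIFF keeps pixel data bit-exact across round trips and label images make
area computation a pixel count.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .containers import ROI_LABELS, Dataset, GroundTruthRecord, ROISet, SectionStack
from .geometry import SectionGeometry

__all__ = ["save_dataset", "load_dataset", "DatasetIOError"]

_METADATA = "metadata.json"
_TRUTH = "ground_truth.json"


class DatasetIOError(RuntimeError):
    """Raised for malformed or incomplete dataset directories."""


def save_dataset(dataset: Dataset, path: str | Path, overwrite: bool = False) -> None:
    """Write a dataset to ``path`` in the TIFF/JSON layout.

    Refuses to overwrite an existing dataset unless ``overwrite`` is set.
    """
    if dataset.n_sections == 0:
        raise DatasetIOError("refusing to save an empty dataset (0 sections)")
    path = Path(path)
    if (path / _METADATA).exists() and not overwrite:
        raise DatasetIOError(
            f"{path} already contains a dataset; pass overwrite=True to replace it"
        )
    (path / "sections").mkdir(parents=True, exist_ok=True)
    (path / "masks").mkdir(parents=True, exist_ok=True)
    for i in range(dataset.n_sections):
        tifffile.imwrite(path / "sections" / f"section_{i:03d}.tif", dataset.stack.images[i])
        tifffile.imwrite(path / "masks" / f"mask_{i:03d}.tif", dataset.rois.labels[i])
    meta = {
        "geometry": dataset.geometry.to_dict(),
        "z_positions_um": dataset.stack.z_positions_um.tolist(),
        "roi_labels": ROI_LABELS,
        "units": {"distance": "um", "volume": "mm3"},
        "stain_convention": "brightfield DAB: darker pixels carry more stain",
        "note": "graft_core pixels are part of striatum_ipsi anatomically",
    }
    (path / _METADATA).write_text(json.dumps(meta, indent=2))
    if dataset.truth is not None:
        (path / _TRUTH).write_text(json.dumps(dataset.truth.to_dict(), indent=2))


def load_dataset(path: str | Path) -> Dataset:
    """Load a dataset written by :func:`save_dataset`.

    Sections are ordered by filename index; errors name the offending
    section or file.
    """
    path = Path(path)
    meta_path = path / _METADATA
    if not meta_path.exists():
        raise DatasetIOError(f"missing metadata sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    geometry = SectionGeometry.from_dict(meta["geometry"])

    section_files = sorted((path / "sections").glob("section_*.tif"))
    if not section_files:
        raise DatasetIOError(f"no section images found under {path / 'sections'}")
    images, labels = [], []
    for i, f in enumerate(section_files):
        img = tifffile.imread(f)
        mask_path = path / "masks" / f.name.replace("section_", "mask_")
        if not mask_path.exists():
            raise DatasetIOError(f"missing ROI mask for section index {i} ({mask_path.name})")
        lab = tifffile.imread(mask_path)
        if lab.shape != img.shape:
            raise DatasetIOError(
                f"section index {i}: mask shape {lab.shape} != image shape {img.shape}"
            )
        images.append(img)
        labels.append(lab)

    file_labels = meta.get("roi_labels", ROI_LABELS)
    if file_labels != ROI_LABELS:
        raise DatasetIOError(f"unknown ROI label table in sidecar: {file_labels}")
    known = {0} | set(ROI_LABELS.values())
    label_stack = np.stack(labels)
    unknown = set(np.unique(label_stack)) - known
    if unknown:
        raise DatasetIOError(f"unknown labels {sorted(unknown)} in mask files")

    z = np.asarray(meta["z_positions_um"], dtype=float)
    if len(z) != len(images):
        raise DatasetIOError(
            f"sidecar lists {len(z)} z positions but {len(images)} sections were found"
        )
    truth = None
    if (path / _TRUTH).exists():
        truth = GroundTruthRecord.from_dict(json.loads((path / _TRUTH).read_text()))
    return Dataset(
        stack=SectionStack(images=np.stack(images), geometry=geometry, z_positions_um=z),
        rois=ROISet(labels=label_stack),
        truth=truth,
    )
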
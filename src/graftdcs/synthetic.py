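"""Synthetic phantoms with known ground truth.

This module emulates the data a unilateral 6-OHDA graft study produces:

* a 3-D *phantom* of the grafted brain block — an ellipsoidal graft core
  inside the lesioned striatum, a TH-fiber stain field decaying radially
  from the core with a configurable dorsal bias, TH-ir somata as spheres
  concentrated at the core border, a TH-negative corpus-callosum band,
  and a uniformly TH-positive contralateral striatum;
* serial brightfield sections of that phantom (darker = more stain) with
  per-section ROI label masks, sampled with a microtome-like geometry
  (thickness T, inter-section gap g, spacing h = T + g);
* drug-induced rotation tables whose improvement is linearly coupled to
  each animal's reinnervation score;
* per-hemisphere BDNF concentration tables.

All quantities that the downstream pipeline estimates (core volume,
thresholded fiber volume, cell count, dorsal/ventral ratio) are recorded
as ground truth, analytically where a closed form exists and otherwise
by fine-grid numeric integration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import ROI_LABELS, Dataset, GroundTruthRecord, ROISet, SectionStack
from .geometry import AxisSlab, Ellipsoid, SectionGeometry

__all__ = [
    "PhantomConfig",
    "Phantom",
    "PhantomValidationError",
    "CohortConfig",
    "generate_phantom",
    "section_phantom",
    "generate_rotation_data",
    "generate_bdnf_data",
    "DEFAULT_IMAGING",
]


class PhantomValidationError(ValueError):
    """Raised when a phantom configuration is geometrically inconsistent."""


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and staining parameters of a synthetic grafted block.

    Distances are µm; stain levels are fractions in [0, 1] of the maximal
    attenuation the imaging model applies.  Defaults draw a sham-like
    animal: a graft core of ~0.87 mm³ inside a ~7.5 mm³ striatum, ~640
    TH-ir cells of 12 µm diameter at the core border, and a fiber halo
    reaching ~600 µm from the core surface.
    """

    # block extent along (x, y, z), µm; z is the cutting axis
    extent_um: tuple[float, float, float] = (4600.0, 3000.0, 3200.0)
    striatum_ipsi: Ellipsoid = Ellipsoid((1200.0, 1700.0, 1600.0), (1000.0, 1200.0, 1500.0))
    striatum_contra: Ellipsoid = Ellipsoid((3400.0, 1700.0, 1600.0), (1000.0, 1200.0, 1500.0))
    corpus_callosum: AxisSlab = AxisSlab(y_range=(150.0, 400.0))
    graft_core: Ellipsoid = Ellipsoid((1200.0, 1700.0, 1600.0), (550.0, 550.0, 690.0))

    # fiber field: amplitude * (exp(-d/lambda_eff) - cutoff) / (1 - cutoff),
    # d = ellipsoidal distance from the core surface, truncated at max reach;
    # dorsal bias beta multiplies the decay length dorsally:
    # lambda_eff = (1 + beta) * lambda for y < core centre, lambda otherwise.
    fiber_amplitude: float = 0.75
    fiber_decay_um: float = 350.0
    fiber_max_reach_um: float = 300.0
    dorsal_bias: float = 0.2
    contra_level: float = 0.45
    core_level: float = 0.7
    cell_level: float = 1.0

    n_cells: int = 641
    cell_diameter_um: float = 12.0
    cell_shell_width_um: float = 50.0
    cell_border_depth: float = 0.3  # cells sit at ellipsoidal radius >= 1 - depth

    n_artifacts: int = 0
    artifact_radius_um: float = 60.0

    # ground-truth integration
    truth_stain_threshold: float = 0.0
    truth_grid_um: float = 20.0
    compute_truths: bool = True

    def replace(self, **kw) -> "PhantomConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for name in ("striatum_ipsi", "striatum_contra", "graft_core"):
            d[name] = getattr(self, name).to_dict()
        d["corpus_callosum"] = self.corpus_callosum.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        for name in ("striatum_ipsi", "striatum_contra", "graft_core"):
            if isinstance(d.get(name), dict):
                d[name] = Ellipsoid.from_dict(d[name])
        if isinstance(d.get("corpus_callosum"), dict):
            d["corpus_callosum"] = AxisSlab.from_dict(d["corpus_callosum"])
        for tup in ("extent_um",):
            if tup in d:
                d[tup] = tuple(d[tup])
        return cls(**d)


@dataclass
class PhantomTruths:
    core_volume_mm3: float
    fiber_volume_mm3: float
    cell_count: int
    dv_ratio: float  # ratio of thresholded fiber volume dorsal/ventral of core centre
    dv_mass_ratio: float  # ratio of integrated stain mass dorsal/ventral


@dataclass
class Phantom:
    """A realized synthetic block: regions, stain field, cells, truths."""

    config: PhantomConfig
    cells: np.ndarray  # (n, 3) centres, µm
    truths: PhantomTruths
    seed: int

    def fiber_stain(self, x, y, z):
        """Fiber stain fraction at (x, y, z) µm (cells/core not included).

        Zero inside the corpus callosum and the graft core; uniform
        ``contra_level`` in the contralateral striatum; radially decaying
        (dorsally biased) halo in the lesioned striatum outside the core.
        """
        cfg = self.config
        x, y, z = np.broadcast_arrays(
            np.asarray(x, dtype=float), np.asarray(y, dtype=float), np.asarray(z, dtype=float)
        )
        out = np.zeros(x.shape, dtype=float)

        contra = cfg.striatum_contra.contains(x, y, z)
        out[contra] = cfg.contra_level

        ipsi = cfg.striatum_ipsi.contains(x, y, z)
        m = cfg.graft_core.normalized_radius(x, y, z)
        halo = ipsi & (m > 1.0)
        if np.any(halo):
            a, b, c = cfg.graft_core.semi_axes
            r_geo = (a * b * c) ** (1.0 / 3.0)
            d = (m[halo] - 1.0) * r_geo
            lam = np.where(
                y[halo] < cfg.graft_core.center[1],
                cfg.fiber_decay_um * (1.0 + cfg.dorsal_bias),
                cfg.fiber_decay_um,
            )
            cut = np.exp(-cfg.fiber_max_reach_um / cfg.fiber_decay_um)
            f = cfg.fiber_amplitude * (np.exp(-d / lam) - cut) / (1.0 - cut)
            out[halo] = np.clip(f, 0.0, None)

        out[cfg.corpus_callosum.contains(x, y, z)] = 0.0
        out[m <= 1.0] = 0.0
        return out


def _validate_config(cfg: PhantomConfig) -> None:
    ex, ey, ez = cfg.extent_um
    for ell in (cfg.striatum_ipsi, cfg.striatum_contra, cfg.graft_core):
        cx, cy, cz = ell.center
        ax, ay, az = ell.semi_axes
        if not (0 <= cx - ax and cx + ax <= ex and 0 <= cy - ay and cy + ay <= ey):
            raise PhantomValidationError("region extends beyond the block in x/y")
    # graft core must lie inside the lesioned striatum: sample its surface
    rng = np.random.default_rng(202406)
    u = rng.normal(size=(512, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    pts = np.asarray(cfg.graft_core.center) + u * np.asarray(cfg.graft_core.semi_axes)
    if np.any(cfg.striatum_ipsi.normalized_radius(*pts.T) > 1.0):
        raise PhantomValidationError("graft core is not contained in the lesioned striatum")
    if cfg.n_cells < 0:
        raise PhantomValidationError("n_cells must be >= 0")
    if cfg.cell_diameter_um <= 0:
        raise PhantomValidationError("cell diameter must be > 0")
    if not 0 <= cfg.cell_border_depth < 1:
        raise PhantomValidationError("cell_border_depth must be in [0, 1)")


def _place_cells(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Sample soma centres concentrated at the graft-core border.

    Cells sit at ellipsoidal radius m in [1 - depth, 1], skewed toward
    m = 1 (the border), with an optional outward excursion bounded so
    every cell stays inside the core dilated by the shell width.
    """
    if cfg.n_cells == 0:
        return np.zeros((0, 3), dtype=float)
    u = rng.normal(size=(cfg.n_cells, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    m = 1.0 - cfg.cell_border_depth * rng.uniform(size=cfg.n_cells) ** 2
    outward = rng.uniform(size=cfg.n_cells) < 0.25
    max_dm = cfg.cell_shell_width_um / max(cfg.graft_core.semi_axes)
    m = m + outward * rng.uniform(0.0, max_dm, size=cfg.n_cells)
    centers = np.asarray(cfg.graft_core.center) + (
        u * np.asarray(cfg.graft_core.semi_axes) * m[:, None]
    )
    return centers


def _integrate_truths(phantom: Phantom) -> None:
    """Fill grid-integrated truths (fiber volume, D/V ratios) in place."""
    cfg = phantom.config
    ell = cfg.striatum_ipsi
    step = cfg.truth_grid_um
    lo = np.asarray(ell.center) - np.asarray(ell.semi_axes)
    hi = np.asarray(ell.center) + np.asarray(ell.semi_axes)
    xs = np.arange(lo[0] + step / 2, hi[0], step)
    ys = np.arange(lo[1] + step / 2, hi[1], step)
    zs = np.arange(lo[2] + step / 2, hi[2], step)
    xx = xs[:, None, None]
    yy = ys[None, :, None]
    zz = zs[None, None, :]
    f = phantom.fiber_stain(xx, yy, zz)
    # restrict to the lesioned-striatum halo (fiber_stain is already zero
    # in the core and CC, but the bbox also brushes the contra striatum)
    ipsi = ell.contains(xx, yy, zz)
    f = np.where(ipsi, f, 0.0)
    voxel_mm3 = (step**3) * 1e-9
    pos = f > cfg.truth_stain_threshold
    phantom.truths.fiber_volume_mm3 = float(pos.sum() * voxel_mm3)
    dorsal = np.broadcast_to(yy < cfg.graft_core.center[1], f.shape)
    vol_d = float((pos & dorsal).sum())
    vol_v = float((pos & ~dorsal).sum())
    mass_d = float(f[dorsal].sum())
    mass_v = float(f[~dorsal].sum())
    phantom.truths.dv_ratio = vol_d / vol_v if vol_v > 0 else float("inf")
    phantom.truths.dv_mass_ratio = mass_d / mass_v if mass_v > 0 else float("inf")


def generate_phantom(config: PhantomConfig | None = None, seed: int = 0) -> Phantom:
    """Build a deterministic phantom from (config, seed).

    Raises :class:`PhantomValidationError` for inconsistent geometry
    (e.g. a graft core not contained in the striatum).
    """
    cfg = config if config is not None else PhantomConfig()
    _validate_config(cfg)
    rng = np.random.default_rng(seed)
    cells = _place_cells(cfg, rng)
    truths = PhantomTruths(
        core_volume_mm3=cfg.graft_core.volume_mm3,
        fiber_volume_mm3=float("nan"),
        cell_count=int(cfg.n_cells),
        dv_ratio=float("nan"),
        dv_mass_ratio=float("nan"),
    )
    phantom = Phantom(config=cfg, cells=cells, truths=truths, seed=seed)
    if cfg.compute_truths:
        _integrate_truths(phantom)
    return phantom


@dataclass(frozen=True)
class ImagingConfig:
    """Brightfield rendering model: intensity = background - scale * stain."""

    background: float = 220.0
    stain_scale: float = 200.0
    noise_sd: float = 3.0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit depth must be 8 or 16")


DEFAULT_IMAGING = ImagingConfig()


def _render_cells(
    stain: np.ndarray,
    cells: np.ndarray,
    diameter: float,
    level: float,
    z0: float,
    z1: float,
    pixel_size: float,
) -> None:
    """Paint disc profiles of spheres intersecting the slab [z0, z1].

    A sphere of diameter D intersects the slab iff its centre lies within
    D/2 of the slab; the painted disc uses the largest chord radius the
    slab cuts from the sphere.  This over-projection within a section is
    exactly the sampling bias the Abercrombie correction removes.
    """
    if len(cells) == 0:
        return
    radius = diameter / 2.0
    zc = cells[:, 2]
    dz = np.clip(np.maximum(z0 - zc, zc - z1), 0.0, None)
    hit = dz < radius
    h_img, w_img = stain.shape
    for xc, yc, _z, d in zip(cells[hit, 0], cells[hit, 1], cells[hit, 2], dz[hit]):
        r = float(np.sqrt(radius**2 - d**2))
        c0 = int(np.floor((xc - r) / pixel_size))
        c1 = int(np.ceil((xc + r) / pixel_size)) + 1
        r0 = int(np.floor((yc - r) / pixel_size))
        r1 = int(np.ceil((yc + r) / pixel_size)) + 1
        c0, c1 = max(c0, 0), min(c1, w_img)
        r0, r1 = max(r0, 0), min(r1, h_img)
        if c0 >= c1 or r0 >= r1:
            continue
        cols = (np.arange(c0, c1) + 0.5) * pixel_size
        rows = (np.arange(r0, r1) + 0.5) * pixel_size
        disc = (cols[None, :] - xc) ** 2 + (rows[:, None] - yc) ** 2 <= r**2
        if not disc.any():
            # sub-pixel profile: mark the nearest pixel so the profile count
            # stays faithful to the slab-intersection sampling rule
            rr = min(max(int(yc / pixel_size), r0), r1 - 1)
            cc = min(max(int(xc / pixel_size), c0), c1 - 1)
            stain[rr, cc] = max(stain[rr, cc], level)
            continue
        region = stain[r0:r1, c0:c1]
        region[disc] = np.maximum(region[disc], level)


def section_phantom(
    phantom: Phantom,
    geometry: SectionGeometry,
    imaging: ImagingConfig = DEFAULT_IMAGING,
    seed: int = 0,
) -> Dataset:
    """Cut the phantom into a serial-section dataset.

    One section is produced for every slab of thickness T starting at
    multiples of h = T + gap across the block's z extent; pixel intensity
    is background minus the stain contribution (darker = more stain) plus
    Gaussian noise, quantized to the configured bit depth.  ROI label
    masks are rendered from the region geometries at the slab mid-plane.
    """
    cfg = phantom.config
    h = geometry.spacing_um
    n_sections = int(cfg.extent_um[2] // h)
    if n_sections < 1:
        raise ValueError(
            f"block extent {cfg.extent_um[2]} µm is shorter than the section spacing {h} µm"
        )
    rng = np.random.default_rng(seed)
    px = geometry.pixel_size_um
    H, W = geometry.height_px, geometry.width_px
    cols = (np.arange(W) + 0.5) * px
    rows = (np.arange(H) + 0.5) * px
    xx = cols[None, :]
    yy = rows[:, None]

    maxval = 2**imaging.bit_depth - 1
    dtype = np.uint8 if imaging.bit_depth == 8 else np.uint16
    images = np.empty((n_sections, H, W), dtype=dtype)
    labels = np.zeros((n_sections, H, W), dtype=np.uint8)
    z_positions = np.arange(n_sections) * h

    artifact_specs = [
        (
            rng.uniform(cfg.striatum_ipsi.center[0] - 0.5 * cfg.striatum_ipsi.semi_axes[0],
                        cfg.striatum_ipsi.center[0] + 0.5 * cfg.striatum_ipsi.semi_axes[0]),
            rng.uniform(cfg.striatum_ipsi.center[1] - 0.5 * cfg.striatum_ipsi.semi_axes[1],
                        cfg.striatum_ipsi.center[1] + 0.5 * cfg.striatum_ipsi.semi_axes[1]),
            rng.uniform(0, cfg.extent_um[2]),
            cfg.artifact_radius_um,
        )
        for _ in range(cfg.n_artifacts)
    ]

    for i, z0 in enumerate(z_positions):
        z_mid = z0 + geometry.thickness_um / 2.0
        stain = phantom.fiber_stain(xx, yy, z_mid)

        core = cfg.graft_core.section_mask(xx, yy, z_mid)
        stain[core] = cfg.core_level
        _render_cells(
            stain, phantom.cells, cfg.cell_diameter_um, cfg.cell_level,
            z0, z0 + geometry.thickness_um, px,
        )

        img = imaging.background - imaging.stain_scale * stain
        if imaging.noise_sd > 0:
            img = img + rng.normal(0.0, imaging.noise_sd, size=img.shape)
        images[i] = np.clip(np.rint(img), 0, maxval).astype(dtype)

        ipsi = cfg.striatum_ipsi.section_mask(xx, yy, z_mid)
        contra = cfg.striatum_contra.section_mask(xx, yy, z_mid)
        cc = cfg.corpus_callosum.section_mask(xx, yy, z_mid) & ~ipsi & ~contra
        lab = labels[i]
        lab[ipsi] = ROI_LABELS["striatum_ipsi"]
        lab[contra] = ROI_LABELS["striatum_contra"]
        lab[cc] = ROI_LABELS["corpus_callosum"]
        lab[core & ipsi] = ROI_LABELS["graft_core"]
        for ax_, ay_, az_, ar in artifact_specs:
            if abs(az_ - z_mid) < 2 * ar:
                blob = ((xx - ax_) ** 2 + (yy - ay_) ** 2) <= ar**2
                blob = blob & ipsi & ~core
                lab[blob] = ROI_LABELS["artifact"]
                images[i][blob] = 0  # opaque debris

    stack = SectionStack(images=images, geometry=geometry, z_positions_um=z_positions)
    truth = GroundTruthRecord(
        core_volume_mm3=phantom.truths.core_volume_mm3,
        fiber_volume_mm3=phantom.truths.fiber_volume_mm3,
        cell_count=phantom.truths.cell_count,
        dv_ratio=phantom.truths.dv_ratio,
        dv_mass_ratio=phantom.truths.dv_mass_ratio,
        seed=phantom.seed,
        extra={"imaging": dataclasses.asdict(imaging)},
    )
    return Dataset(stack=stack, rois=ROISet(labels=labels), truth=truth)


# ---------------------------------------------------------------------------
# behavioral / BDNF generators
# ---------------------------------------------------------------------------

TIMEPOINTS = ("baseline", "week2", "week5")


@dataclass(frozen=True)
class CohortConfig:
    """Rotometry cohort: baselines and reinnervation-behavior coupling.

    ``coupling_slope``/``coupling_intercept``/``coupling_sd`` parameterize
    improvement_i = a + b * IFD_i + eps, eps ~ N(0, sigma); week-5 rate is
    baseline minus improvement, week 2 realizes ``week2_fraction`` of it.
    With ``standardize_ifd`` the coupling uses the cohort z-score of the
    reinnervation score instead of its raw value, making the behavioral
    effect independent of the score's (arbitrary) unit scale.  Baselines
    are drawn from N(mean, sd) and, when ``enforce_inclusion`` is set,
    resampled until they exceed the inclusion threshold (> 4 net
    ipsilateral turns/min).
    """

    baseline_mean: float = 12.0
    baseline_sd: float = 3.0
    enforce_inclusion: bool = True
    inclusion_threshold: float = 4.0
    coupling_intercept: float = 2.0
    coupling_slope: float = 1.0
    coupling_sd: float = 1.5
    standardize_ifd: bool = False
    week2_fraction: float = 0.5
    week2_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.coupling_sd < 0:
            raise ValueError("coupling noise SD must be >= 0")
        if self.week2_sd < 0:
            raise ValueError("week-2 noise SD must be >= 0")

    def replace(self, **kw) -> "CohortConfig":
        return dataclasses.replace(self, **kw)


def generate_rotation_data(
    cohort_config: CohortConfig,
    ground_truths: pd.DataFrame,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate net full-body turns/min at baseline, week 2 and week 5.

    Parameters
    ----------
    ground_truths : DataFrame
        One row per animal with columns ``animal_id``, ``group`` and
        ``integrated_fiber_density`` (the per-animal reinnervation score
        driving the behavioral coupling).

    Returns
    -------
    DataFrame with columns ``animal_id, group, timepoint, net_turns_per_min``
    (positive = ipsilateral to the lesion), one row per animal x timepoint.
    """
    cfg = cohort_config
    required = {"animal_id", "group", "integrated_fiber_density"}
    missing = required - set(ground_truths.columns)
    if missing:
        raise ValueError(f"ground_truths is missing columns: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    n = len(ground_truths)
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n)
    if cfg.enforce_inclusion:
        for _ in range(1000):
            bad = baseline <= cfg.inclusion_threshold
            if not bad.any():
                break
            baseline[bad] = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=int(bad.sum()))
        else:  # pragma: no cover - pathological config
            raise RuntimeError("could not sample baselines above the inclusion threshold")
    ifd = ground_truths["integrated_fiber_density"].to_numpy(dtype=float)
    if cfg.standardize_ifd:
        sd_ifd = ifd.std(ddof=1) if n > 1 else 0.0
        ifd = (ifd - ifd.mean()) / sd_ifd if sd_ifd > 0 else np.zeros_like(ifd)
    improvement = (
        cfg.coupling_intercept
        + cfg.coupling_slope * ifd
        + (rng.normal(0.0, cfg.coupling_sd, size=n) if cfg.coupling_sd > 0 else 0.0)
    )
    week5 = baseline - improvement
    week2 = baseline - cfg.week2_fraction * improvement + (
        rng.normal(0.0, cfg.week2_sd, size=n) if cfg.week2_sd > 0 else 0.0
    )
    rows = []
    for i, (_, animal) in enumerate(ground_truths.iterrows()):
        for tp, val in zip(TIMEPOINTS, (baseline[i], week2[i], week5[i])):
            rows.append(
                {
                    "animal_id": animal["animal_id"],
                    "group": animal["group"],
                    "timepoint": tp,
                    "net_turns_per_min": float(val),
                }
            )
    return pd.DataFrame(rows)


def generate_bdnf_data(
    group_ratio_means: dict[str, float] | None = None,
    group_ratio_sds: dict[str, float] | None = None,
    n_per_group: dict[str, int] | None = None,
    contra_mean_pg_per_mg: float = 100.0,
    contra_sd_pg_per_mg: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-hemisphere BDNF concentrations for a naive-stimulation cohort.

    Each animal gets a contralateral (unstimulated) concentration and a
    stimulated-hemisphere concentration whose ratio (in percent) is drawn
    from the group's ratio distribution.  Defaults emulate a sham group
    near 100% and an anodal group elevated by ~20%.
    """
    means = group_ratio_means or {"sham": 99.0, "anodal": 120.0}
    sds = group_ratio_sds or {"sham": 12.0, "anodal": 28.0}
    ns = n_per_group or {"sham": 7, "anodal": 9}
    rng = np.random.default_rng(seed)
    rows = []
    idx = 0
    for group, n in ns.items():
        ratios = rng.normal(means[group], sds[group], size=n)
        contra = np.abs(rng.normal(contra_mean_pg_per_mg, contra_sd_pg_per_mg, size=n))
        for r, c in zip(ratios, contra):
            rows.append(
                {
                    "animal_id": f"bdnf_{idx:02d}",
                    "group": group,
                    "stim_pg_per_mg": float(c * r / 100.0),
                    "contra_pg_per_mg": float(c),
                }
            )
            idx += 1
    return pd.DataFrame(rows)
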
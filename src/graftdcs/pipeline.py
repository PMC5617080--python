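"""End-to-end orchestration: simulate, quantify, analyze, report.

The pipeline chains the other modules into the study workflow:

1. *simulate* — generate per-animal phantoms with group-specific injected
   effects, section them, and (optionally) write TIFF/JSON datasets;
2. *quantify* — run densitometry + stereology + morphometry on each
   animal's sections to produce :class:`~graftdcs.morphometry.GraftMetrics`;
3. *behave* — generate rotometry tables coupled to the measured
   reinnervation and compute improvement/recovery;
4. *stats* — the group comparison battery, mixed RM-ANOVA on rotation,
   and the improvement ~ reinnervation regression;
5. *report* — one JSON document embedding the resolved configuration,
   the seed, and a content hash of the inputs.

Also houses stimulation-protocol bookkeeping (charge per session).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import behavior as beh
from . import densitometry as dens
from . import morphometry as morph
from . import stats as st
from . import stereology as ster
from .containers import Dataset
from .geometry import SectionGeometry
from .synthetic import (
    CohortConfig,
    ImagingConfig,
    PhantomConfig,
    generate_bdnf_data,
    generate_phantom,
    generate_rotation_data,
    section_phantom,
)

__all__ = [
    "StimulationProtocol",
    "session_charge",
    "QuantConfig",
    "GroupSpec",
    "RunConfig",
    "geometry_for_config",
    "scaled_phantom_config",
    "quantify_dataset",
    "simulate_cohort",
    "run_pipeline",
]

log = logging.getLogger("graftdcs")

GROUP_CODING = {"sham": 0, "anodal": 1, "cathodal": 2}


# ---------------------------------------------------------------------------
# stimulation bookkeeping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulationProtocol:
    """Transcranial DCS dosing: 8 A/m² for 20 min, once daily x 14."""

    current_density_A_per_m2: float = 8.0
    session_duration_s: float = 1200.0
    sessions: int = 14

    def __post_init__(self) -> None:
        if self.current_density_A_per_m2 < 0 or self.session_duration_s < 0 or self.sessions < 0:
            raise ValueError("stimulation protocol fields must be non-negative")

    @property
    def charge_per_session_C_per_cm2(self) -> float:
        return session_charge(self.current_density_A_per_m2, self.session_duration_s)

    @property
    def total_charge_C_per_cm2(self) -> float:
        return self.sessions * self.charge_per_session_C_per_cm2


def session_charge(current_density_A_per_m2: float, duration_s: float) -> float:
    """Charge delivered per session in C/cm².

    current density [A/m²] x duration [s] = charge [C/m²]; dividing by
    10⁴ cm²/m² gives C/cm² (8 A/m² x 1200 s -> 0.96 C/cm²).
    """
    if current_density_A_per_m2 < 0 or duration_s < 0:
        raise ValueError("current density and duration must be >= 0")
    return current_density_A_per_m2 * duration_s / 1e4


# ---------------------------------------------------------------------------
# quantification of one animal's dataset
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuantConfig:
    """Knobs of the per-animal quantification.

    ``abercrombie_d_um`` is the mean TH-ir soma height used by the
    profile-count correction; ``cell_intensity_threshold`` separates the
    near-opaque soma profiles from the lighter core neuropil in raw
    intensity units.
    """

    threshold_rule: dens.ThresholdRule = dens.ThresholdRule("reference_sd", k=3.0)
    abercrombie_d_um: float = 12.0
    cell_intensity_threshold: float = 50.0
    profile_dilation_px: int = 10
    cells_transplanted: float = 130_000.0
    da_fraction: float = 0.10
    per_section_dv: bool = False

    def replace(self, **kw) -> "QuantConfig":
        return dataclasses.replace(self, **kw)


def quantify_dataset(
    dataset: Dataset,
    quant: QuantConfig = QuantConfig(),
    animal_id: str = "animal",
    group: str = "unassigned",
) -> morph.GraftMetrics:
    """Full histological quantification of one animal.

    Per section: OD normalization to the corpus callosum, fiber
    segmentation over the lesioned striatum (graft core and artifacts
    excluded), graft-core profile areas, and soma-profile counts.  The
    per-section measurements are then reduced to frustum volumes, the
    relative fiber density, the integrated fiber density, the D/V ratio,
    and the Abercrombie-corrected cell count.
    """
    geom = dataset.geometry
    px2 = geom.pixel_area_um2
    flags: dict = {}

    od_images: list[dens.ODImage] = []
    fiber_masks: list[np.ndarray] = []
    core_masks: list[np.ndarray] = []
    contra_masks: list[np.ndarray] = []
    contra_refs: list[np.ndarray] = []
    core_areas: list[float] = []
    fiber_areas: list[float] = []
    profile_counts: list[int] = []

    for s in range(dataset.n_sections):
        image = dataset.stack.images[s]
        cc = dataset.rois.mask("corpus_callosum", s)
        if not cc.any():
            raise ValueError(f"section {s}: empty corpus-callosum reference mask")
        odi = dens.section_od(image, cc, section_index=s)
        od_images.append(odi)

        ipsi = dataset.rois.mask("striatum_ipsi", s)
        core = dataset.rois.mask("graft_core", s)
        artifact = dataset.rois.mask("artifact", s)
        analysis = ipsi & ~core & ~artifact
        seg = dens.segment_fibers(
            odi, analysis, quant.threshold_rule, reference_mask=cc, pixel_size_um=geom.pixel_size_um
        )
        fiber_masks.append(seg.mask)
        fiber_areas.append(seg.area_um2)
        core_masks.append(core)
        core_areas.append(float(core.sum()) * px2)
        contra_masks.append(dataset.rois.mask("striatum_contra", s))
        contra_refs.append(dens.mirror_mask(cc))

        if core.any():
            clean = np.asarray(image, dtype=float).copy()
            clean[artifact] = np.iinfo(image.dtype).max if image.dtype.kind == "u" else 255
            profile_counts.append(
                dens.count_cell_profiles(
                    clean,
                    core,
                    quant.cell_intensity_threshold,
                    dilate_px=quant.profile_dilation_px,
                )
            )
        else:
            profile_counts.append(0)

    h = geom.spacing_um
    core_volume = ster.series_volume(ster.AreaSeries(tuple(core_areas), h, "um2", "graft core"))
    fiber_volume = ster.series_volume(
        ster.AreaSeries(tuple(fiber_areas), h, "um2", "TH-ir fibers")
    )

    rel = dens.relative_fiber_density(
        od_images, fiber_masks, contra_masks, quant.threshold_rule, contra_refs
    )
    if rel.undefined:
        flags["relative_density"] = rel.warning
    if rel.warning and not rel.undefined:
        flags.setdefault("relative_density", rel.warning)

    total_fiber_area_mm2 = float(np.sum(fiber_areas)) * 1e-6
    rel_pct = rel.percent if np.isfinite(rel.percent) else 0.0
    ifd = morph.integrated_fiber_density(total_fiber_area_mm2, rel_pct)
    if rel.undefined:
        flags["integrated_fiber_density"] = "relative density undefined; score uses 0%"

    try:
        dv = morph.dorsoventral_ratio(fiber_masks, core_masks, per_section=quant.per_section_dv)
        if not np.isfinite(dv):
            flags["dv_ratio"] = "no ventral fiber pixels; ratio infinite"
    except ValueError as exc:
        dv = float("nan")
        flags["dv_ratio"] = str(exc)

    n_cells = ster.series_cell_estimate(profile_counts, geom, quant.abercrombie_d_um)
    if core_volume > 0:
        density = ster.cells_per_volume(n_cells, core_volume)
    else:
        density = float("nan")
        flags["cells_per_mm3"] = "zero graft-core volume"
    surv = morph.survival_percent(n_cells, quant.cells_transplanted, quant.da_fraction)

    return morph.GraftMetrics(
        animal_id=animal_id,
        group=group,
        core_volume_mm3=core_volume,
        fiber_volume_mm3=fiber_volume,
        relative_density_percent=rel.percent,
        integrated_fiber_density=ifd,
        dv_ratio=dv,
        th_cell_count=n_cells,
        cells_per_mm3=density,
        survival_percent=surv,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """Injected group-level effect, relative to the base phantom.

    ``core_scale`` multiplies the graft-core semi-axes (so volume scales
    with its cube); ``fiber_reach_um`` and ``dorsal_bias`` replace the
    base fiber-halo reach and bias; cell counts are drawn per animal.
    Defaults for the three stimulation groups mirror the anodal-larger /
    cathodal-intermediate pattern of the modelled study.
    """

    n: int = 7
    core_scale: float = 1.0
    n_cells_mean: float = 641.0
    n_cells_sd: float = 120.0
    dorsal_bias: float = 0.2
    fiber_reach_um: Optional[float] = None
    fiber_amplitude: Optional[float] = None
    animal_cv: float = 0.06  # per-animal jitter on the core scale


DEFAULT_GROUPS: dict[str, GroupSpec] = {
    "sham": GroupSpec(n=7, core_scale=1.0, n_cells_mean=641, dorsal_bias=0.2),
    "anodal": GroupSpec(
        n=9, core_scale=1.164, n_cells_mean=965, dorsal_bias=0.9, fiber_reach_um=420.0
    ),
    "cathodal": GroupSpec(
        n=8, core_scale=1.117, n_cells_mean=505, dorsal_bias=0.7, fiber_reach_um=330.0
    ),
}


def geometry_for_config(
    config: PhantomConfig,
    thickness_um: float = 40.0,
    gap_um: float = 120.0,
    pixel_size_um: float = 5.16,
) -> SectionGeometry:
    """Section geometry whose image frame covers the phantom block."""
    ex, ey, _ = config.extent_um
    return SectionGeometry(
        thickness_um=thickness_um,
        gap_um=gap_um,
        pixel_size_um=pixel_size_um,
        width_px=int(np.ceil(ex / pixel_size_um)),
        height_px=int(np.ceil(ey / pixel_size_um)),
    )


def scaled_phantom_config(base: PhantomConfig | None = None, scale: float = 0.5) -> PhantomConfig:
    """Spatially scaled copy of a phantom configuration.

    All region geometries, the fiber decay/reach, and the cell shell are
    multiplied by ``scale``; stain levels and cell count/diameter are
    kept.  Used to run many cohorts at reduced raster sizes.
    """
    cfg = base if base is not None else PhantomConfig()

    def s_ell(e):
        return dataclasses.replace(
            e,
            center=tuple(c * scale for c in e.center),
            semi_axes=tuple(a * scale for a in e.semi_axes),
        )

    cc = cfg.corpus_callosum
    cc = dataclasses.replace(
        cc,
        y_range=tuple(v * scale for v in cc.y_range),
        x_range=None if cc.x_range is None else tuple(v * scale for v in cc.x_range),
        z_range=None if cc.z_range is None else tuple(v * scale for v in cc.z_range),
    )
    return cfg.replace(
        extent_um=tuple(v * scale for v in cfg.extent_um),
        striatum_ipsi=s_ell(cfg.striatum_ipsi),
        striatum_contra=s_ell(cfg.striatum_contra),
        graft_core=s_ell(cfg.graft_core),
        corpus_callosum=cc,
        fiber_decay_um=cfg.fiber_decay_um * scale,
        fiber_max_reach_um=cfg.fiber_max_reach_um * scale,
        cell_shell_width_um=cfg.cell_shell_width_um * scale,
    )


def simulate_cohort(
    groups: dict[str, GroupSpec] | None = None,
    base_config: PhantomConfig | None = None,
    geometry: SectionGeometry | None = None,
    imaging: ImagingConfig = ImagingConfig(),
    seed: int = 0,
    compute_truths: bool = False,
) -> list[tuple[str, str, Dataset]]:
    """Generate one sectioned dataset per animal with injected effects.

    Returns ``(animal_id, group, dataset)`` triples; all randomness
    derives from ``seed``.
    """
    groups = groups if groups is not None else DEFAULT_GROUPS
    base = base_config if base_config is not None else PhantomConfig()
    geom = geometry if geometry is not None else geometry_for_config(base)
    rng = np.random.default_rng(seed)
    out = []
    idx = 0
    for gname, spec in groups.items():
        for _ in range(spec.n):
            scale = spec.core_scale * max(rng.normal(1.0, spec.animal_cv), 0.5)
            core = dataclasses.replace(
                base.graft_core,
                semi_axes=tuple(a * scale for a in base.graft_core.semi_axes),
            )
            n_cells = max(int(round(rng.normal(spec.n_cells_mean, spec.n_cells_sd))), 0)
            bias = max(rng.normal(spec.dorsal_bias, 0.08), 0.0)
            cfg = base.replace(
                graft_core=core,
                n_cells=n_cells,
                dorsal_bias=bias,
                fiber_max_reach_um=(
                    spec.fiber_reach_um if spec.fiber_reach_um is not None else base.fiber_max_reach_um
                ),
                fiber_amplitude=(
                    spec.fiber_amplitude if spec.fiber_amplitude is not None else base.fiber_amplitude
                ),
                compute_truths=compute_truths,
            )
            sub = int(rng.integers(0, 2**31 - 1))
            phantom = generate_phantom(cfg, seed=sub)
            ds = section_phantom(phantom, geom, imaging=imaging, seed=sub + 1)
            out.append((f"{gname}_{idx:02d}", gname, ds))
            idx += 1
    return out


# ---------------------------------------------------------------------------
# run configuration and full pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    seed: int = 0
    outdir: Optional[str] = None
    spatial_scale: float = 1.0
    pixel_size_um: float = 5.16
    thickness_um: float = 40.0
    gap_um: float = 120.0
    phantom_overrides: dict = field(default_factory=dict)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    groups: dict[str, GroupSpec] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    quant: QuantConfig = field(default_factory=QuantConfig)
    cohort: CohortConfig = field(
        default_factory=lambda: CohortConfig(
            coupling_intercept=10.0, coupling_slope=2.5, coupling_sd=1.5, standardize_ifd=True
        )
    )
    inclusion_threshold: float = 4.0
    t_variant: str = "student"
    bdnf_tails: str = "upper"
    stimulation: StimulationProtocol = field(default_factory=StimulationProtocol)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["quant"]["threshold_rule"] = dataclasses.asdict(self.quant.threshold_rule)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "imaging" in d and isinstance(d["imaging"], dict):
            d["imaging"] = ImagingConfig(**d["imaging"])
        if "groups" in d:
            d["groups"] = {
                k: (GroupSpec(**v) if isinstance(v, dict) else v) for k, v in d["groups"].items()
            }
        if "quant" in d and isinstance(d["quant"], dict):
            q = dict(d["quant"])
            if isinstance(q.get("threshold_rule"), dict):
                q["threshold_rule"] = dens.ThresholdRule(**q["threshold_rule"])
            d["quant"] = QuantConfig(**q)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortConfig(**d["cohort"])
        if "stimulation" in d and isinstance(d["stimulation"], dict):
            d["stimulation"] = StimulationProtocol(**d["stimulation"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _content_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _summary(values: pd.Series) -> dict:
    vals = values.to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        return {"n": 0, "mean": None, "sd": None}
    return {
        "n": int(len(vals)),
        "mean": float(np.mean(vals)),
        "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
    }


_COMPARED_METRICS = [
    "core_volume_mm3",
    "th_cell_count",
    "cells_per_mm3",
    "fiber_volume_mm3",
    "relative_density_percent",
    "integrated_fiber_density",
    "dv_ratio",
]


def run_pipeline(config: RunConfig | None = None) -> dict:
    """Execute the full synthetic study and return the report dict.

    Simulation, quantification, behavior and statistics all derive their
    randomness from ``config.seed``; running twice with the same config
    yields an identical report.
    """
    cfg = config if config is not None else RunConfig()
    rng = np.random.default_rng(cfg.seed)

    base = scaled_phantom_config(scale=cfg.spatial_scale) if cfg.spatial_scale != 1.0 else PhantomConfig()
    if cfg.phantom_overrides:
        base = base.replace(**cfg.phantom_overrides)
    geom = geometry_for_config(
        base, thickness_um=cfg.thickness_um, gap_um=cfg.gap_um, pixel_size_um=cfg.pixel_size_um
    )
    log.info("simulating cohort (seed=%d, %d groups)", cfg.seed, len(cfg.groups))
    cohort = simulate_cohort(
        cfg.groups, base, geom, imaging=cfg.imaging, seed=int(rng.integers(0, 2**31 - 1))
    )

    log.info("quantifying %d animals", len(cohort))
    metrics = [
        quantify_dataset(ds, cfg.quant, animal_id=aid, group=grp) for aid, grp, ds in cohort
    ]
    mtab = pd.DataFrame([dataclasses.asdict(m) for m in metrics])

    truths = mtab[["animal_id", "group", "integrated_fiber_density"]].copy()
    rotation = generate_rotation_data(
        cfg.cohort, truths, seed=int(rng.integers(0, 2**31 - 1))
    )
    imp = beh.improvement_table(rotation)
    included = beh.apply_inclusion(
        dict(
            zip(
                imp["animal_id"],
                imp["baseline"],
            )
        ),
        threshold=cfg.inclusion_threshold,
    )
    imp["included"] = imp["animal_id"].isin(included)

    # --- group statistics -------------------------------------------------
    comparisons = {}
    for other in [g for g in cfg.groups if g != "sham"]:
        pair = {}
        for metric in _COMPARED_METRICS:
            x = mtab.loc[mtab.group == "sham", metric].dropna()
            y = mtab.loc[mtab.group == other, metric].dropna()
            x = x[np.isfinite(x)]
            y = y[np.isfinite(y)]
            if len(x) < 2 or len(y) < 2:
                pair[metric] = {"error": "not enough finite observations"}
                continue
            res = st.auto_compare(x, y, variant=cfg.t_variant, tails="two")
            pair[metric] = res.to_dict()
        rot_pair = rotation[rotation.group.isin(["sham", other])]
        try:
            aov = st.rm_anova_mixed(rot_pair)
            pair["rotation_rm_anova"] = aov.to_dict()
        except ValueError as exc:
            pair["rotation_rm_anova"] = {"error": str(exc)}
        comparisons[f"sham_vs_{other}"] = pair

    # --- regression: improvement ~ integrated fiber density + GROUP -------
    reg_tab = imp.merge(
        mtab[["animal_id", "integrated_fiber_density"]], on="animal_id", how="inner"
    )
    reg_tab["group_code"] = reg_tab["group"].map(GROUP_CODING)
    regression: dict
    try:
        reg = st.ols_fit(
            reg_tab["improvement"],
            reg_tab[["integrated_fiber_density", "group_code"]],
        )
        regression = reg.to_dict()
        regression["group_coding"] = GROUP_CODING
    except ValueError as exc:
        regression = {"degenerate": True, "error": str(exc), "group_coding": GROUP_CODING}

    # --- BDNF -------------------------------------------------------------
    bdnf = generate_bdnf_data(seed=int(rng.integers(0, 2**31 - 1)))
    bdnf["ratio_percent"] = [
        st.interhemispheric_ratio(s, c)
        for s, c in zip(bdnf["stim_pg_per_mg"], bdnf["contra_pg_per_mg"])
    ]
    bdnf_res = st.two_sample_t(
        bdnf.loc[bdnf.group == "anodal", "ratio_percent"],
        bdnf.loc[bdnf.group == "sham", "ratio_percent"],
        variant="welch",
        tails=cfg.bdnf_tails,
    )

    report = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "input_hash": _content_hash({"config": cfg.to_dict(), "seed": cfg.seed}),
        "stimulation": {
            "charge_per_session_C_per_cm2": cfg.stimulation.charge_per_session_C_per_cm2,
            "total_charge_C_per_cm2": cfg.stimulation.total_charge_C_per_cm2,
            "sessions": cfg.stimulation.sessions,
        },
        "animals": mtab.to_dict(orient="records"),
        "group_summaries": {
            g: {m: _summary(mtab.loc[mtab.group == g, m]) for m in _COMPARED_METRICS}
            for g in cfg.groups
        },
        "rotation": rotation.to_dict(orient="records"),
        "improvement": imp.to_dict(orient="records"),
        "recovery_fraction_full": {
            g: float(
                (imp.loc[imp.group == g, "recovery"] == beh.FULL_RECOVERY).mean()
            )
            for g in cfg.groups
        },
        "comparisons": comparisons,
        "regression_improvement": regression,
        "bdnf": {
            "table": bdnf.to_dict(orient="records"),
            "anodal_vs_sham": bdnf_res.to_dict(),
        },
        "decisions": {
            "relative_density_aggregation": "pooled across sections",
            "improvement_definition": "baseline - week5 (signed turns/min)",
            "dv_center": "pooled core centroid row",
            "group_coding": GROUP_CODING,
        },
    }
    if cfg.outdir is not None:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
        mtab.to_csv(out / "graft_metrics.csv", index=False)
        rotation.to_csv(out / "rotation.csv", index=False)
        bdnf.to_csv(out / "bdnf.csv", index=False)
    return report
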
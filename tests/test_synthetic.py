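"""Phantom generator: determinism, geometry truths, sectioning, behavior tables."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import graftdcs as g
from graftdcs.containers import ROI_LABELS
from graftdcs.geometry import Ellipsoid, SectionGeometry
from graftdcs.synthetic import (
    CohortConfig,
    ImagingConfig,
    PhantomConfig,
    PhantomValidationError,
    generate_phantom,
    generate_rotation_data,
    section_phantom,
)


def test_phantom_is_deterministic_per_seed(half_config):
    a = generate_phantom(half_config, seed=3)
    b = generate_phantom(half_config, seed=3)
    assert np.array_equal(a.cells, b.cells)
    assert dataclasses.asdict(a.truths) == dataclasses.asdict(b.truths)
    c = generate_phantom(half_config, seed=4)
    assert not np.array_equal(a.cells, c.cells)


def test_sectioning_is_deterministic_per_seed(half_phantom, half_geometry):
    a = section_phantom(half_phantom, half_geometry, seed=5)
    b = section_phantom(half_phantom, half_geometry, seed=5)
    assert np.array_equal(a.stack.images, b.stack.images)
    assert np.array_equal(a.rois.labels, b.rois.labels)


def test_core_volume_truth_is_analytic():
    cfg = PhantomConfig().replace(
        graft_core=Ellipsoid((1200.0, 1700.0, 1600.0), (500.0, 500.0, 500.0)),
        compute_truths=False,
    )
    phantom = generate_phantom(cfg, seed=0)
    assert phantom.truths.core_volume_mm3 == pytest.approx(0.5236, abs=1e-4)


def test_zero_cell_config_yields_empty_cells():
    cfg = PhantomConfig().replace(n_cells=0, compute_truths=False)
    phantom = generate_phantom(cfg, seed=0)
    assert phantom.cells.shape == (0, 3)
    assert phantom.truths.cell_count == 0


def test_core_outside_striatum_is_rejected():
    cfg = PhantomConfig().replace(
        graft_core=Ellipsoid((2100.0, 1700.0, 1600.0), (550.0, 550.0, 690.0))
    )
    with pytest.raises(PhantomValidationError):
        generate_phantom(cfg, seed=0)


def test_cells_stay_inside_dilated_core(half_phantom):
    cfg = half_phantom.config
    dilated = Ellipsoid(
        cfg.graft_core.center,
        tuple(a + cfg.cell_shell_width_um for a in cfg.graft_core.semi_axes),
    )
    x, y, z = half_phantom.cells.T
    assert np.all(dilated.normalized_radius(x, y, z) <= 1.0 + 1e-9)


def test_section_count_is_extent_over_spacing(half_phantom, half_geometry):
    # half-scale block is 1600 µm deep; h = 160 µm -> 10 sections
    ds = section_phantom(half_phantom, half_geometry, seed=1)
    assert ds.n_sections == 10
    assert np.allclose(np.diff(ds.stack.z_positions_um), half_geometry.spacing_um)


def test_too_coarse_spacing_raises(half_phantom):
    geom = SectionGeometry(thickness_um=40, gap_um=2000, width_px=10, height_px=10)
    with pytest.raises(ValueError, match="spacing"):
        section_phantom(half_phantom, geom, seed=1)


def test_unstained_noise_free_sections_are_flat(half_geometry, half_config):
    cfg = half_config.replace(
        fiber_amplitude=0.0, contra_level=0.0, core_level=0.0, n_cells=0, compute_truths=False
    )
    phantom = generate_phantom(cfg, seed=0)
    ds = section_phantom(phantom, half_geometry, imaging=ImagingConfig(noise_sd=0.0), seed=0)
    assert np.all(ds.stack.images == int(ImagingConfig().background))


def test_roi_masks_are_disjoint_and_core_nested(half_dataset):
    labels = half_dataset.rois.labels
    # label images are single-valued, so raw ROIs are disjoint by construction;
    # check the semantic masks: core subset of ipsi, striata/CC pairwise disjoint
    for s in range(half_dataset.n_sections):
        ipsi = half_dataset.rois.mask("striatum_ipsi", s)
        contra = half_dataset.rois.mask("striatum_contra", s)
        cc = half_dataset.rois.mask("corpus_callosum", s)
        core = half_dataset.rois.mask("graft_core", s)
        assert not (ipsi & contra).any()
        assert not (ipsi & cc).any()
        assert not (contra & cc).any()
        assert (core & ~ipsi).sum() == 0
    assert set(np.unique(labels)) <= {0} | set(ROI_LABELS.values())


def test_cavalieri_sum_of_core_masks_matches_truth(half_config):
    # h = 50 µm <= core radius / 5 (half-scale core semi-axis 275 µm)
    cfg = half_config.replace(n_cells=0, compute_truths=False)
    phantom = generate_phantom(cfg, seed=0)
    geom = SectionGeometry(
        thickness_um=40.0,
        gap_um=10.0,
        pixel_size_um=10.32,
        width_px=int(np.ceil(cfg.extent_um[0] / 10.32)),
        height_px=int(np.ceil(cfg.extent_um[1] / 10.32)),
    )
    ds = section_phantom(phantom, geom, imaging=ImagingConfig(noise_sd=0.0), seed=0)
    areas_um2 = np.array(
        [ds.rois.mask("graft_core", s).sum() * geom.pixel_area_um2 for s in range(ds.n_sections)]
    )
    cavalieri_mm3 = areas_um2.sum() * geom.spacing_um * 1e-9
    assert cavalieri_mm3 == pytest.approx(phantom.truths.core_volume_mm3, rel=0.05)


def test_dorsal_mass_ratio_increases_with_bias(half_config):
    ratios = []
    for beta in (0.0, 0.4, 0.8):
        cfg = half_config.replace(dorsal_bias=beta, n_cells=0)
        ratios.append(generate_phantom(cfg, seed=0).truths.dv_mass_ratio)
    assert ratios[0] == pytest.approx(1.0, abs=0.05)
    assert ratios[0] < ratios[1] < ratios[2]


# ---------------------------------------------------------------------------
# rotation / BDNF generators
# ---------------------------------------------------------------------------


def _truths(n=6, ifd=2.0):
    return pd.DataFrame(
        {
            "animal_id": [f"a{i}" for i in range(n)],
            "group": ["sham"] * n,
            "integrated_fiber_density": [ifd] * n,
        }
    )


def test_noise_free_uncoupled_rotation_improves_by_intercept():
    cfg = CohortConfig(coupling_slope=0.0, coupling_sd=0.0, week2_sd=0.0, coupling_intercept=3.0)
    rot = generate_rotation_data(cfg, _truths(), seed=0)
    wide = rot.pivot_table(index="animal_id", columns="timepoint", values="net_turns_per_min")
    assert np.allclose(wide["baseline"] - wide["week5"], 3.0)
    assert np.allclose(wide["baseline"] - wide["week2"], 1.5)  # half realized at week 2


def test_rotation_generator_is_deterministic():
    cfg = CohortConfig()
    a = generate_rotation_data(cfg, _truths(), seed=9)
    b = generate_rotation_data(cfg, _truths(), seed=9)
    pd.testing.assert_frame_equal(a, b)


def test_rotation_baselines_respect_inclusion_threshold():
    cfg = CohortConfig(baseline_mean=6.0, baseline_sd=3.0, enforce_inclusion=True)
    rot = generate_rotation_data(cfg, _truths(n=40), seed=1)
    base = rot[rot.timepoint == "baseline"]["net_turns_per_min"]
    assert (base > 4.0).all()


def test_negative_noise_sd_is_rejected():
    with pytest.raises(ValueError):
        CohortConfig(coupling_sd=-1.0)


def test_bdnf_table_has_elevated_anodal_ratio():
    tab = g.generate_bdnf_data(seed=0)
    ratios = 100 * tab["stim_pg_per_mg"] / tab["contra_pg_per_mg"]
    assert ratios[tab.group == "anodal"].mean() > ratios[tab.group == "sham"].mean()
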
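"""Optical density, thresholding, mirroring, relative fiber density."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from graftdcs.densitometry import (
    ODImage,
    ThresholdRule,
    count_cell_profiles,
    mirror_mask,
    relative_fiber_density,
    section_od,
    segment_fibers,
)

PX = 5.16


def _flat(value, shape=(40, 40)):
    return np.full(shape, float(value))


def test_od_zero_when_image_equals_reference():
    img = _flat(200.0)
    ref = np.ones_like(img, dtype=bool)
    odi = section_od(img, ref)
    assert odi.reference_mean == 200.0
    assert np.all(odi.od == 0.0)


def test_od_one_decade_below_reference():
    img = _flat(200.0)
    img[10, 10] = 20.0
    ref = np.zeros_like(img, dtype=bool)
    ref[:5] = True
    odi = section_od(img, ref)
    assert odi.od[10, 10] == pytest.approx(1.0)


def test_od_clips_pixels_brighter_than_reference():
    img = _flat(100.0)
    img[0, 0] = 250.0
    ref = np.zeros_like(img, dtype=bool)
    ref[5:, :] = True
    odi = section_od(img, ref)
    assert odi.od[0, 0] == 0.0


def test_od_requires_nonempty_reference():
    with pytest.raises(ValueError, match="reference"):
        section_od(_flat(100.0), np.zeros((40, 40), dtype=bool))


def test_od_is_ratiometric_under_global_rescaling():
    rng = np.random.default_rng(0)
    img = rng.uniform(50, 250, size=(60, 60))
    ref = np.zeros_like(img, dtype=bool)
    ref[:10] = True
    a = section_od(img, ref)
    b = section_od(img * 0.5, ref)  # float path: no clamp in play
    assert np.allclose(a.od, b.od)


def test_segment_fibers_counts_strictly_above_threshold():
    od = ODImage(od=np.zeros((20, 20)), reference_mean=200.0)
    od.od[5, 5] = 0.30  # exactly theta -> excluded
    od.od[6, 6] = 0.31
    mask = np.ones((20, 20), dtype=bool)
    seg = segment_fibers(od, mask, ThresholdRule("fixed", value=0.30), pixel_size_um=PX)
    assert seg.positive_pixels == 1
    assert seg.area_um2 == pytest.approx(PX**2)


def test_segmented_disc_area_matches_rasterization_oracle():
    h = w = 101
    rr, cc = np.mgrid[0:h, 0:w]
    disc = (rr - 50) ** 2 + (cc - 50) ** 2 <= 20**2
    od = ODImage(od=np.where(disc, 1.0, 0.0), reference_mean=200.0)
    seg = segment_fibers(
        od, np.ones((h, w), dtype=bool), ThresholdRule("fixed", value=0.5), pixel_size_um=PX
    )
    assert seg.positive_pixels == int(disc.sum())  # oracle: rasterized pixel count
    analytic = np.pi * 20**2 * PX**2
    ring = (2 * np.pi * 20 + 4) * PX**2  # one-pixel boundary ring
    assert abs(seg.area_um2 - analytic) <= ring


def test_empty_analysis_mask_is_flagged_not_fatal():
    od = ODImage(od=np.ones((10, 10)), reference_mean=200.0)
    seg = segment_fibers(od, np.zeros((10, 10), dtype=bool), ThresholdRule("fixed", value=0.1))
    assert seg.area_um2 == 0.0
    assert seg.empty_analysis_mask


def test_fiber_area_monotonically_nonincreasing_in_threshold():
    rng = np.random.default_rng(1)
    od = ODImage(od=rng.uniform(0, 1, size=(50, 50)), reference_mean=200.0)
    mask = np.ones((50, 50), dtype=bool)
    areas = [
        segment_fibers(od, mask, ThresholdRule("fixed", value=t)).area_um2
        for t in np.linspace(0, 1, 11)
    ]
    assert all(a >= b for a, b in zip(areas, areas[1:]))


def test_reference_sd_rule_matches_manual_computation():
    rng = np.random.default_rng(2)
    od = ODImage(od=np.abs(rng.normal(0, 0.01, size=(30, 30))), reference_mean=200.0)
    ref = np.zeros((30, 30), dtype=bool)
    ref[:8] = True
    seg = segment_fibers(od, np.ones_like(ref), ThresholdRule("reference_sd", k=3.0), ref)
    vals = od.od[ref]
    assert seg.threshold == pytest.approx(vals.mean() + 3 * vals.std())


@settings(derandomize=True, max_examples=25)
@given(hst.integers(min_value=1, max_value=40), hst.integers(min_value=1, max_value=40))
def test_mirror_is_an_involution_and_preserves_count(h, w):
    rng = np.random.default_rng(h * 41 + w)
    m = rng.uniform(size=(h, w)) > 0.5
    assert np.array_equal(mirror_mask(mirror_mask(m)), m)
    assert mirror_mask(m).sum() == m.sum()


def test_mirror_maps_column_three_to_six_in_width_ten():
    m = np.zeros((1, 10), dtype=bool)
    m[0, 3] = True
    assert np.nonzero(mirror_mask(m))[1][0] == 6


def test_symmetric_mask_is_a_mirror_fixed_point():
    m = np.zeros((5, 9), dtype=bool)
    m[:, 2] = m[:, 6] = True
    assert np.array_equal(mirror_mask(m), m)


def _od_pair(les_value, con_value, shape=(20, 40)):
    """One section: lesioned fibers on the left, contra striatum on the right."""
    od = np.zeros(shape)
    fiber = np.zeros(shape, dtype=bool)
    fiber[5:15, 5:15] = True
    contra = np.zeros(shape, dtype=bool)
    contra[:, shape[1] // 2:] = True
    od[fiber] = les_value
    od[mirror_mask(fiber) & contra] = con_value
    return ODImage(od=od, reference_mean=200.0), fiber, contra


def test_relative_density_is_hundred_for_symmetric_staining():
    odi, fiber, contra = _od_pair(0.4, 0.4)
    res = relative_fiber_density([odi], [fiber], [contra], ThresholdRule("fixed", value=0.1))
    assert res.percent == pytest.approx(100.0)


def test_relative_density_halves_when_lesioned_od_halves():
    odi, fiber, contra = _od_pair(0.3, 0.6)
    res = relative_fiber_density([odi], [fiber], [contra], ThresholdRule("fixed", value=0.1))
    assert res.percent == pytest.approx(50.0)


def test_relative_density_empty_lesioned_mask_is_zero_with_warning():
    odi, fiber, contra = _od_pair(0.0, 0.6)
    # fiber mask empty: nothing segmented on the lesioned side
    res = relative_fiber_density(
        [odi], [np.zeros_like(fiber)], [contra], ThresholdRule("fixed", value=0.1)
    )
    assert res.percent == 0.0
    assert res.warning is not None


def test_relative_density_no_contra_positives_is_flagged_undefined():
    odi, fiber, contra = _od_pair(0.4, 0.0)
    res = relative_fiber_density([odi], [fiber], [contra], ThresholdRule("fixed", value=0.1))
    assert res.undefined
    assert np.isnan(res.percent)


def test_cell_profiles_are_counted_as_connected_components():
    img = np.full((60, 60), 220.0)
    core = np.zeros((60, 60), dtype=bool)
    core[20:40, 20:40] = True
    for r, c in [(22, 22), (30, 30), (38, 25), (41, 41)]:  # last is just outside core
        img[r - 1:r + 2, c - 1:c + 2] = 20.0
    assert count_cell_profiles(img, core, intensity_threshold=50.0, dilate_px=5) == 4
    assert count_cell_profiles(img, core, intensity_threshold=50.0, dilate_px=0) == 3
    assert count_cell_profiles(img, np.zeros_like(core), 50.0) == 0
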
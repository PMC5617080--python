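"""Statistical battery: hand oracles, enumeration oracles, calibration smoke."""

import itertools

import numpy as np
import pandas as pd
import pytest

from graftdcs.stats import (
    _mixed_anova_sums_of_squares,
    auto_compare,
    interhemispheric_ratio,
    ks_normality,
    mann_whitney_u,
    ols_fit,
    rm_anova_mixed,
    two_sample_t,
)


# --- KS normality gate ------------------------------------------------------


def test_ks_rejects_uniform_and_passes_normal():
    rng = np.random.default_rng(0)
    assert ks_normality(rng.uniform(0, 1, size=500)).p < 0.01
    passes = sum(
        ks_normality(np.random.default_rng(s).normal(size=500)).p > 0.05 for s in range(20)
    )
    assert passes >= 18


def test_ks_flags_constant_sample():
    res = ks_normality([2.0, 2.0, 2.0, 2.0])
    assert res.extra.get("degenerate")


def test_ks_needs_three_observations():
    with pytest.raises(ValueError):
        ks_normality([1.0, 2.0])


# --- two-sample t -----------------------------------------------------------


def test_t_is_zero_for_identical_samples():
    x = [1.0, 2.0, 3.0, 4.0]
    res = two_sample_t(x, x)
    assert res.statistic == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)


def test_student_t_matches_pooled_variance_hand_formula():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([2.0, 3.0, 4.0, 5.0])
    res = two_sample_t(x, y, variant="student")
    sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / (len(x) + len(y) - 2)
    t_hand = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / len(x) + 1 / len(y)))
    assert res.statistic == pytest.approx(t_hand)
    assert res.statistic == pytest.approx(-1.095, abs=5e-4)
    assert res.df == 6


def test_welch_df_never_exceeds_student_df():
    rng = np.random.default_rng(4)
    for _ in range(20):
        x = rng.normal(0, 1, size=rng.integers(3, 12))
        y = rng.normal(0, rng.uniform(0.5, 3), size=rng.integers(3, 12))
        student = two_sample_t(x, y, variant="student")
        welch = two_sample_t(x, y, variant="welch")
        assert welch.df <= student.df + 1e-9


def test_t_antisymmetric_in_sample_order():
    rng = np.random.default_rng(5)
    x, y = rng.normal(size=8), rng.normal(1, 1, size=6)
    a = two_sample_t(x, y)
    b = two_sample_t(y, x)
    assert a.statistic == pytest.approx(-b.statistic)
    assert a.p == pytest.approx(b.p)


def test_degenerate_equal_constant_samples_are_flagged():
    res = two_sample_t([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
    assert res.extra.get("degenerate")


def test_upper_tailed_variant_is_directional():
    x = [5.0, 6.0, 7.0, 8.0]
    y = [1.0, 2.0, 3.0, 4.0]
    up = two_sample_t(x, y, variant="welch", tails="upper")
    two = two_sample_t(x, y, variant="welch", tails="two")
    assert up.p == pytest.approx(two.p / 2)


# --- Mann-Whitney -----------------------------------------------------------


def _mw_exact_oracle(x, y):
    """Two-sided exact p by enumerating all label arrangements."""
    nx, ny = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(combined)) + 1.0
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    us = []
    for idx in itertools.combinations(range(nx + ny), nx):
        u = ranks[list(idx)].sum() - nx * (nx + 1) / 2
        us.append(u)
    us = np.asarray(us)
    u_star = max(u_obs, nx * ny - u_obs)
    return min(1.0, 2 * np.mean(us >= u_star))


def test_u_is_zero_when_x_below_y():
    assert mann_whitney_u([1, 2, 3], [4, 5, 6]).statistic == 0.0


def test_u_is_half_product_for_identical_samples():
    res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.statistic == pytest.approx(4.5)


def test_exact_p_for_two_versus_two():
    res = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
    assert res.extra["exact"]
    assert res.p == pytest.approx(1 / 3, abs=1e-9)


@pytest.mark.parametrize("nx,ny", [(2, 3), (3, 3), (4, 3), (5, 4)])
def test_exact_p_matches_enumeration_oracle(nx, ny):
    rng = np.random.default_rng(nx * 10 + ny)
    for _ in range(5):
        x = rng.permutation(np.arange(1.0, nx + ny + 1))[:nx]
        y = np.setdiff1d(np.arange(1.0, nx + ny + 1), x)
        res = mann_whitney_u(x, y)
        assert res.extra["exact"]
        assert res.p == pytest.approx(_mw_exact_oracle(x, y), abs=1e-9)


def test_large_samples_fall_back_to_normal_approximation():
    rng = np.random.default_rng(8)
    res = mann_whitney_u(rng.normal(size=25), rng.normal(size=25))
    assert not res.extra["exact"]
    assert "z" in res.extra


def test_auto_compare_routes_nonnormal_data_to_mann_whitney():
    rng = np.random.default_rng(9)
    x = rng.lognormal(0, 2, size=300)  # heavy-tailed: KS should reject
    y = rng.lognormal(0, 2, size=300)
    res = auto_compare(x, y)
    assert res.extra["normality_gate"] == "mann-whitney"
    res2 = auto_compare(rng.normal(size=30), rng.normal(size=30))
    assert res2.extra["normality_gate"] == "t"


# --- mixed RM-ANOVA ---------------------------------------------------------


def _rotation_frame(rng, n=8, time_effect=0.0, const=False):
    rows = []
    for grp in ("sham", "anodal"):
        for i in range(n):
            base = 10.0 if const else rng.normal(10, 3)
            for j, tp in enumerate(("baseline", "week2", "week5")):
                val = base if const else base + time_effect * j + rng.normal(0, 2)
                rows.append(
                    dict(animal_id=f"{grp}{i}", group=grp, timepoint=tp, net_turns_per_min=val)
                )
    return pd.DataFrame(rows)


def test_constant_data_reports_zero_time_effect():
    res = rm_anova_mixed(_rotation_frame(np.random.default_rng(0), const=True))
    assert res.time.statistic == 0.0
    assert res.time.p == 1.0
    assert res.group.statistic == 0.0


def test_anova_matches_first_principles_sums_of_squares():
    rng = np.random.default_rng(1)
    data = _rotation_frame(rng)
    res = rm_anova_mixed(data)
    wide = data.pivot_table(index="animal_id", columns="timepoint", values="net_turns_per_min")
    manual = _mixed_anova_sums_of_squares(wide, data.groupby("animal_id")["group"].first())
    assert res.time.statistic == pytest.approx(manual["time"]["F"], rel=1e-6)
    assert res.group.statistic == pytest.approx(manual["group"]["F"], rel=1e-6)
    assert res.interaction.statistic == pytest.approx(manual["interaction"]["F"], rel=1e-6)
    assert res.time.p == pytest.approx(manual["time"]["p-unc"], rel=1e-6)


def test_anova_detects_injected_time_effect_with_posthocs():
    rng = np.random.default_rng(2)
    res = rm_anova_mixed(_rotation_frame(rng, time_effect=-4.0))
    assert res.time.p < 0.001
    assert len(res.posthoc) == 4  # 2 groups x (week2, week5)
    week5 = res.posthoc[res.posthoc.timepoint == "week5"]
    assert (week5.p < 0.01).all()


def test_incomplete_design_is_an_error():
    data = _rotation_frame(np.random.default_rng(3))
    data = data[~((data.animal_id == "sham0") & (data.timepoint == "week5"))]
    with pytest.raises(ValueError, match="incomplete"):
        rm_anova_mixed(data)


# --- OLS --------------------------------------------------------------------


def test_perfect_line_recovers_slope_and_r2():
    x = np.arange(10.0)
    res = ols_fit(2 * x, pd.DataFrame({"x": x}))
    assert res.params["x"] == pytest.approx(2.0)
    assert res.rsquared == pytest.approx(1.0)


def test_constant_response_has_zero_slope_and_r2():
    x = np.arange(10.0)
    res = ols_fit(np.full(10, 3.0), pd.DataFrame({"x": x}))
    assert res.params["x"] == pytest.approx(0.0, abs=1e-12)
    assert res.rsquared == pytest.approx(0.0, abs=1e-12)


def test_collinear_design_raises_with_column_names():
    x = np.arange(10.0)
    with pytest.raises(ValueError, match="x2"):
        ols_fit(x, pd.DataFrame({"x1": x, "x2": 2 * x}))


def test_standardized_coefficients_invariant_to_rescaling():
    rng = np.random.default_rng(6)
    x1 = rng.normal(size=50)
    x2 = rng.normal(size=50)
    y = 1.5 * x1 - 0.7 * x2 + rng.normal(0, 0.5, size=50)
    a = ols_fit(y, pd.DataFrame({"x1": x1, "x2": x2}))
    b = ols_fit(y, pd.DataFrame({"x1": 1000 * x1, "x2": 0.01 * x2}))
    for k in ("x1", "x2"):
        assert a.params_standardized[k] == pytest.approx(b.params_standardized[k], rel=1e-9)


# --- interhemispheric ratio -------------------------------------------------


def test_interhemispheric_ratio_examples():
    assert interhemispheric_ratio(5.0, 5.0) == pytest.approx(100.0)
    assert interhemispheric_ratio(6.0, 5.0) == pytest.approx(120.0)
    with pytest.raises(ValueError):
        interhemispheric_ratio(5.0, 0.0)
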
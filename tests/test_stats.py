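"""Crosslink densities, plateau fits, regression, and group comparisons."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from tenmech.stats import (CrosslinkSample, compare_groups, crosslink_density,
                           fit_exponential_plateau,
                           regress_modulus_on_crosslinks)
from tenmech.synthetic import DoseResponseDataset, gen_dose_response


# ---------------------------------------------------------------------------
# crosslink density


@pytest.mark.parametrize("hp, lp, mass, expected", [
    (100.0, 0.0, 2.0, (50.0, 0.0, 50.0)),
    (80.0, 20.0, 1.0, (80.0, 20.0, 100.0)),
])
def test_density_arithmetic(hp, lp, mass, expected):
    assert crosslink_density(hp, lp, mass) == pytest.approx(expected)


def test_density_rejects_zero_mass():
    with pytest.raises(ValueError):
        crosslink_density(10, 5, 0.0)
    with pytest.raises(ValueError):
        CrosslinkSample("s1", 10, 5, 0.0)


def test_sample_carries_derived_densities():
    s = CrosslinkSample("s1", 80, 20, 2.0)
    assert s.total_density == pytest.approx(50.0)


# ---------------------------------------------------------------------------
# plateau fit


def test_noiseless_plateau_recovered_to_machine_precision():
    data, truth = gen_dose_response(10, 50, 1, noise_sd=0.0)
    fit = fit_exponential_plateau(data)
    assert fit.converged
    assert fit.y0 == pytest.approx(10.0, rel=1e-6)
    assert fit.ym == pytest.approx(50.0, rel=1e-6)
    assert fit.k == pytest.approx(1.0, rel=1e-6)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-9)


def test_noisy_plateau_ym_within_five_percent():
    data, truth = gen_dose_response(10, 50, 1, noise_sd=1.0, seed=2, reps=5)
    fit = fit_exponential_plateau(data)
    assert fit.ym == pytest.approx(truth.ym, rel=0.05)


def test_constant_response_flags_unidentifiable_k():
    fit = fit_exponential_plateau((np.array([0, 1, 2, 5.0]),
                                   np.array([7.0, 7, 7, 7])))
    assert fit.y0 == fit.ym == 7.0
    assert not fit.k_identifiable


def test_plateau_preconditions():
    with pytest.raises(ValueError):
        fit_exponential_plateau((np.array([0, 0, 1, 1.0]),
                                 np.array([1, 2, 3, 4.0])))


def test_plateau_invariant_to_row_order_and_y_rescaling():
    data, _ = gen_dose_response(10, 50, 1, noise_sd=1.0, seed=4)
    fit = fit_exponential_plateau(data)
    perm = np.random.default_rng(0).permutation(data.x.size)
    fit_perm = fit_exponential_plateau((data.x[perm], data.y[perm]))
    assert fit_perm.ym == pytest.approx(fit.ym, rel=1e-6)
    assert fit_perm.k == pytest.approx(fit.k, rel=1e-6)
    # affine rescale y -> a*y + b maps (y0, ym) affinely and keeps k
    a, b = 3.0, 20.0
    fit_aff = fit_exponential_plateau((data.x, a * data.y + b))
    assert fit_aff.y0 == pytest.approx(a * fit.y0 + b, rel=1e-5)
    assert fit_aff.ym == pytest.approx(a * fit.ym + b, rel=1e-5)
    assert fit_aff.k == pytest.approx(fit.k, rel=1e-5)


# ---------------------------------------------------------------------------
# regression


def test_perfect_line_r2_one():
    res = regress_modulus_on_crosslinks([1, 2, 3, 4], [3, 5, 7, 9])
    assert res.r_squared == pytest.approx(1.0, abs=1e-12)
    assert res.p_value < 1e-10


def test_regression_matches_closed_form_oracle():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([2.1, 3.9, 6.2, 7.8])
    res = regress_modulus_on_crosslinks(x, y)
    # explicit textbook formulas
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    sxx = np.sum((x - x.mean()) ** 2)
    syy = np.sum((y - y.mean()) ** 2)
    slope = sxy / sxx
    r = sxy / math.sqrt(sxx * syy)
    t = r * math.sqrt(2 / (1 - r * r))
    p = 2 * sps.t.sf(abs(t), 2)
    assert res.slope == pytest.approx(slope, rel=1e-12)
    assert res.pearson_r == pytest.approx(r, rel=1e-12)
    assert res.p_value == pytest.approx(p, rel=1e-9)
    assert res.r_squared == pytest.approx(res.pearson_r ** 2, abs=1e-12)


def test_regression_preconditions():
    with pytest.raises(ValueError):
        regress_modulus_on_crosslinks([1, 2], [1, 2])
    with pytest.raises(ValueError):
        regress_modulus_on_crosslinks([2, 2, 2], [1, 2, 3])


# ---------------------------------------------------------------------------
# group comparisons


def test_identical_groups_give_null_t():
    res = compare_groups({"a": [1.0, 2, 3], "b": [1.0, 2, 3]})
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0, abs=1e-12)


def test_two_group_anova_f_equals_t_squared(rng):
    a = rng.normal(0, 1, 8)
    b = rng.normal(0.7, 1, 8)
    t_res = compare_groups({"a": a, "b": b})
    f, _ = sps.f_oneway(a, b)
    assert t_res.statistic ** 2 == pytest.approx(f, abs=1e-9)


def test_paired_mode_matches_scipy(rng):
    a = rng.normal(0, 1, 10)
    b = a + rng.normal(0.3, 0.2, 10)
    res = compare_groups({"a": a, "b": b}, paired=True)
    t, p = sps.ttest_rel(a, b)
    assert res.statistic == pytest.approx(t)
    assert res.p_value == pytest.approx(p)


def test_group_size_precondition():
    with pytest.raises(ValueError):
        compare_groups({"a": [1.0], "b": [1.0, 2.0]})


def test_anova_p_matches_permutation_oracle():
    """One-way ANOVA p agrees with a label-permutation null distribution."""
    rng = np.random.default_rng(42)
    groups = {k: rng.normal(loc, 1.0, 6)
              for k, loc in zip("abcd", (0.0, 0.4, 0.8, 0.2))}
    res = compare_groups(groups, "multi_group")
    values = np.concatenate(list(groups.values()))
    n, k, per = values.size, 4, 6
    n_perm = 40000
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    perm_vals = values[idx].reshape(n_perm, k, per)
    gm = perm_vals.mean(axis=2)
    ssb = per * np.sum((gm - values.mean()) ** 2, axis=1)
    ssw = np.sum((perm_vals - gm[:, :, None]) ** 2, axis=(1, 2))
    f_perm = (ssb / (k - 1)) / (ssw / (n - k))
    p_perm = np.mean(f_perm >= res.statistic)
    mc_sd = math.sqrt(res.p_value * (1 - res.p_value) / n_perm)
    assert abs(p_perm - res.p_value) <= max(5 * mc_sd, 0.01)


def test_tukey_adjusted_p_not_below_unadjusted(rng):
    """Tukey HSD p >= pooled-MSE pairwise t-test p for every pair."""
    groups = {k: rng.normal(i * 0.5, 1.0, 6) for i, k in enumerate("abcd")}
    res = compare_groups(groups, "multi_group")
    arrays = [np.asarray(v) for v in groups.values()]
    n_tot = sum(a.size for a in arrays)
    df_err = n_tot - len(arrays)
    mse = sum(np.sum((a - a.mean()) ** 2) for a in arrays) / df_err
    names = list(groups)
    for _, row in res.post_hoc.iterrows():
        a = np.asarray(groups[row["group1"]])
        b = np.asarray(groups[row["group2"]])
        se = math.sqrt(mse * (1 / a.size + 1 / b.size))
        t = (a.mean() - b.mean()) / se
        p_unadj = 2 * sps.t.sf(abs(t), df_err)
        assert row["p_adj"] >= p_unadj - 1e-12


def test_type_i_error_calibrated(rng):
    """Null t-test rejects at the nominal 5% rate (quick 2,000-run check)."""
    n_sim = 2000
    a = rng.normal(0, 1, (8, n_sim))
    b = rng.normal(0, 1, (8, n_sim))
    _, p = sps.ttest_ind(a, b, axis=0)
    rate = np.mean(p < 0.05)
    assert 0.03 <= rate <= 0.07
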
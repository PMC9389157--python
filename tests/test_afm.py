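"""Force-volume AFM: contact detection, Hertz fitting, map summaries."""

import math

import numpy as np
import pytest

from tenmech.afm import (PYRAMID_COEFF, ForceCurve, ProbeSpec,
                         analyze_force_map, detect_contact_point, fit_hertz,
                         read_force_map_csv, summarize_map,
                         write_force_map_csv, _modulus_prefactor_nn_nm)
from tenmech.synthetic import gen_force_curve, gen_force_map


def test_probe_invariants():
    with pytest.raises(ValueError):
        ProbeSpec(spring_constant=0)
    with pytest.raises(ValueError):
        ProbeSpec(tip_half_angle_deg=95)
    with pytest.raises(ValueError):
        ProbeSpec(poisson_ratio=0.7)


def test_force_curve_validation(probe):
    z = np.linspace(0, 100, 50)
    with pytest.raises(ValueError):
        ForceCurve(z, np.zeros(49), probe)
    with pytest.raises(ValueError):
        ForceCurve(np.zeros(50), np.zeros(50), probe)  # not monotone


def test_noiseless_contact_at_exact_z(probe):
    curve = gen_force_curve(10.0, probe, noise_sd_nm=0.0, contact_z_nm=500.0)
    j, d0, ok, _ = detect_contact_point(curve)
    assert ok
    assert curve.z_nm[j] == pytest.approx(500.0, abs=1e-9)
    assert d0 == pytest.approx(0.0, abs=1e-12)


def test_trigger_defines_final_deflection(probe):
    curve = gen_force_curve(25.0, probe, noise_sd_nm=0.0)
    assert curve.deflection_nm[-1] == pytest.approx(
        probe.trigger_deflection_nm, abs=1e-9)


def test_contact_recovery_under_noise(probe):
    """Contact index within 3 samples of truth in >= 95% of noisy curves."""
    rng = np.random.default_rng(7)
    hits = 0
    n = 300
    for _ in range(n):
        e = rng.uniform(5, 200)
        curve = gen_force_curve(e, probe, noise_sd_nm=0.5, rng=rng,
                                n_baseline=64)
        j, _, ok, _ = detect_contact_point(curve)
        hits += ok and abs(j - 64) <= 3
    assert hits / n >= 0.95


def test_rising_curve_flagged_invalid(probe):
    z = np.linspace(0, 600, 120)
    d = 0.07 * z        # deflection climbs from the very first sample
    j, _, ok, reason = detect_contact_point(ForceCurve(z, d, probe))
    assert not ok and "baseline" in reason
    res = fit_hertz(ForceCurve(z, d, probe))
    assert not res.valid


def test_constant_deflection_invalid(probe):
    z = np.linspace(0, 600, 64)
    res = fit_hertz(ForceCurve(z, np.full(64, 3.0), probe))
    assert not res.valid


def test_noiseless_fit_exact(probe):
    curve = gen_force_curve(10.0, probe, noise_sd_nm=0.0)
    res = fit_hertz(curve, "pyramid")
    assert res.valid
    assert res.modulus_kpa == pytest.approx(10.0, rel=1e-6)
    assert res.r_squared == pytest.approx(1.0, abs=1e-9)


def test_sphere_model_roundtrip(probe):
    curve = gen_force_curve(30.0, probe, noise_sd_nm=0.0, model="sphere")
    res = fit_hertz(curve, "sphere")
    assert res.valid
    assert res.modulus_kpa == pytest.approx(30.0, rel=1e-6)


def test_fit_matches_grid_search_oracle(probe):
    """LS fit agrees with an explicit 0.01 kPa grid search on E."""
    rng = np.random.default_rng(3)
    pref = _modulus_prefactor_nn_nm(probe, "pyramid", PYRAMID_COEFF)
    grid = np.arange(1.0, 250.0, 0.01)
    for _ in range(5):
        e = rng.uniform(5, 200)
        curve = gen_force_curve(e, probe, noise_sd_nm=0.5, rng=rng)
        res = fit_hertz(curve, "pyramid")
        j, d0 = res.contact_index, res.baseline_offset_nm
        dd = curve.deflection_nm[j:] - d0
        delta = (curve.z_nm[j:] - curve.z_nm[j]) - dd
        sel = (delta > 0) & (dd > 0) & (dd <= probe.trigger_deflection_nm + 1e-9)
        force = probe.spring_constant * dd[sel]
        dp = delta[sel] ** 2
        # SSE(E) evaluated on the full grid
        sse = (np.sum(force ** 2) - 2 * grid * pref * np.sum(force * dp)
               + (grid * pref) ** 2 * np.sum(dp * dp))
        e_grid = grid[int(np.argmin(sse))]
        assert abs(e_grid - res.modulus_kpa) <= 0.01 + 1e-9


def test_unit_invariance(probe):
    """Scaling z and deflection by c scales the fitted modulus by 1/c."""
    curve = gen_force_curve(40.0, probe, noise_sd_nm=0.0)
    c = 1000.0
    scaled = ForceCurve(curve.z_nm * c, curve.deflection_nm * c,
                        ProbeSpec(trigger_deflection_nm=probe.trigger_deflection_nm * c))
    r1 = fit_hertz(curve)
    r2 = fit_hertz(scaled)
    assert r2.modulus_kpa == pytest.approx(r1.modulus_kpa / c, rel=1e-9)


def test_two_phase_map_median_matches_sorted_oracle():
    field = np.full((8, 8), 10.0)
    field[:, 4:] = 50.0
    fmap, truth = gen_force_map(field, noise_sd_nm=0.0, seed=7)
    mm = analyze_force_map(fmap)
    oracle = sorted(truth.modulus_kpa.ravel())
    med = (oracle[31] + oracle[32]) / 2
    assert mm.n_valid == 64
    assert mm.median_kpa == pytest.approx(med, rel=2e-2)
    # per-phase medians recover the generating values
    grid = mm.modulus_grid()
    assert np.median(grid[:, :4]) == pytest.approx(10.0, rel=2e-2)
    assert np.median(grid[:, 4:]) == pytest.approx(50.0, rel=2e-2)


def test_uniform_map_closed_loop():
    fmap, _ = gen_force_map(np.full((4, 4), 20.0), noise_sd_nm=0.0, seed=0)
    mm = analyze_force_map(fmap)
    vals = mm.valid_values()
    assert np.allclose(vals, 20.0, rtol=1e-6)
    assert mm.median_kpa == pytest.approx(20.0, rel=1e-6)


def test_map_rejects_nonpositive_modulus():
    with pytest.raises(ValueError):
        gen_force_map(np.array([[10.0, -1.0]]), seed=0)


def test_median_not_mean_for_skewed_values():
    fmap, _ = gen_force_map(np.array([[1.0, 1.0], [1.0, 10.0]]),
                            noise_sd_nm=0.0, seed=0)
    mm = analyze_force_map(fmap)
    assert mm.median_kpa == pytest.approx(1.0, rel=1e-6)    # mean would be 3.25


def test_summarize_histogram_and_permutation_invariance():
    rng = np.random.default_rng(11)
    field = rng.lognormal(3.0, 0.4, size=(8, 8))
    fmap, _ = gen_force_map(field, noise_sd_nm=0.0, seed=5)
    mm = analyze_force_map(fmap, bin_width_kpa=5.0)
    assert mm.hist_rel_freq.sum() == pytest.approx(1.0, abs=1e-9)
    med, edges, rel = summarize_map(mm, 5.0)
    # median equals the sort-based oracle and ignores pixel ordering
    vals = np.sort(mm.valid_values())
    assert med == pytest.approx((vals[31] + vals[32]) / 2, abs=1e-12)
    perm = np.random.default_rng(1).permutation(64)
    shuffled = mm.valid_values()[perm]
    assert np.median(shuffled) == pytest.approx(med, abs=1e-12)


def test_summarize_errors_when_all_invalid():
    from tenmech.afm import HertzFitResult, ModulusMap
    bad = ModulusMap([[HertzFitResult(float("nan"), 0, 0, 0, 0, "pyramid",
                                      False, "x")]],
                     float("nan"), np.array([]), np.array([]), 0, 1)
    with pytest.raises(ValueError):
        summarize_map(bad)


def test_force_map_csv_roundtrip(tmp_path, probe):
    fmap, _ = gen_force_map(np.full((2, 2), 15.0), noise_sd_nm=0.0, seed=1)
    csv = tmp_path / "map.csv"
    pj = tmp_path / "probe.json"
    write_force_map_csv(fmap, csv, pj)
    back = read_force_map_csv(csv, pj)
    assert back.shape == (2, 2)
    mm = analyze_force_map(back)
    assert mm.median_kpa == pytest.approx(15.0, rel=1e-6)
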
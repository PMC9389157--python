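"""PSR content/maturity, nuclei counting, TUNEL viability, cell density."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tenmech.histology import (MaturityThresholds, RegionSample,
                               calibrate_maturity_report, cell_density,
                               classify_maturity, count_nuclei, psr_content,
                               viability)
from tenmech.synthetic import gen_nuclei_image, gen_psr_image


def _rgb(r, g, b=0, shape=(4, 4)):
    img = np.zeros(shape + (3,), dtype=np.uint8)
    img[..., 0], img[..., 1], img[..., 2] = r, g, b
    return img


# ---------------------------------------------------------------------------
# PSR content


def test_content_degenerate_images():
    full = _rgb(200, 150, 100, shape=(16, 16))
    assert psr_content(full, "fixed", fixed_threshold=10) == 100.0
    blank = np.zeros((16, 16, 3), np.uint8)
    assert psr_content(blank, "fixed", fixed_threshold=10) == 0.0
    with pytest.warns(UserWarning):
        assert psr_content(blank, "otsu") == 0.0


def test_content_known_coverage():
    img = np.zeros((10, 10, 3), np.uint8)
    img[:4, :, :] = 200                       # 40 rows of 100 -> 40%
    assert psr_content(img, "fixed", fixed_threshold=50) == pytest.approx(40.0)


# ---------------------------------------------------------------------------
# maturity classification


def test_boundary_ratios_follow_printed_rule():
    # ratio exactly 1.8 -> red (inclusive); exactly 1.1 -> green (inclusive)
    red = classify_maturity(_rgb(180, 100))
    assert red.pct_red == 100.0
    green = classify_maturity(_rgb(110, 100))
    assert green.pct_green == 100.0
    yellow = classify_maturity(_rgb(150, 100))
    assert yellow.pct_yellow == 100.0


def test_zero_green_with_bright_red_is_red():
    res = classify_maturity(_rgb(50, 0))
    assert res.pct_red == 100.0


def test_all_background_errors():
    with pytest.raises(ValueError, match="no tissue"):
        classify_maturity(np.zeros((8, 8, 3), np.uint8))


def test_generated_fractions_recovered_exactly():
    img, _ = gen_psr_image(0.3, 0.3, 0.4, width=100, height=100, seed=1)
    res = classify_maturity(img)
    assert res.pct_red == pytest.approx(30.0, abs=1e-9)
    assert res.pct_yellow == pytest.approx(30.0, abs=1e-9)
    assert res.pct_green == pytest.approx(40.0, abs=1e-9)
    assert res.n_background == 0


def test_pure_red_image():
    img, _ = gen_psr_image(1.0, 0.0, 0.0, width=32, height=32, seed=0)
    assert classify_maturity(img).pct_red == 100.0


def test_partition_over_full_rg_lattice():
    """Every (R, G) pair maps to exactly one of the four classes."""
    r, g = np.meshgrid(np.arange(256), np.arange(256), indexing="ij")
    img = np.zeros((256, 256, 3), np.uint8)
    img[..., 0], img[..., 1] = r, g
    thr = MaturityThresholds()
    floor = thr.background_floor
    tissue = np.maximum(r, g) > floor
    res = classify_maturity(img, thr)
    assert res.n_classified == int(tissue.sum())
    assert res.n_background == 256 * 256 - res.n_classified
    assert res.pct_red + res.pct_yellow + res.pct_green == pytest.approx(
        100.0, abs=1e-9)
    # independent per-pixel oracle
    with np.errstate(divide="ignore"):
        ratio = np.where(g > 0, r / np.maximum(g, 1e-300), np.inf)
    n_red = int(np.sum(tissue & (ratio >= 1.8)))
    assert res.pct_red == pytest.approx(n_red / tissue.sum() * 100, abs=1e-9)


@settings(max_examples=25, deadline=None)
@given(scale=st.floats(min_value=0.3, max_value=1.0),
       r=st.integers(min_value=40, max_value=255),
       g=st.integers(min_value=40, max_value=255))
def test_classification_invariant_to_common_channel_scaling(scale, r, g):
    """Scaling R and G together leaves the ratio class unchanged."""
    a = classify_maturity(_rgb(r, g))
    b = classify_maturity(_rgb(r * scale, g * scale))
    assert (a.pct_red, a.pct_yellow, a.pct_green) == \
        (b.pct_red, b.pct_yellow, b.pct_green)


# ---------------------------------------------------------------------------
# calibration report


def _region(color, ratio):
    return RegionSample(color, np.full(10, 100.0 * ratio), np.full(10, 100.0))


def test_calibration_reports_constant_ratios():
    samples = [_region("red", 2.0)] * 12 + [_region("green", 0.9)] * 12
    rep = calibrate_maturity_report(samples)
    assert rep["red"]["median"] == pytest.approx(2.0)
    assert rep["green"]["median"] == pytest.approx(0.9)


def test_calibration_median_matches_oracle(rng):
    ratios_r = rng.uniform(1.9, 2.5, 13)
    ratios_g = rng.uniform(0.7, 1.0, 12)
    samples = ([_region("red", x) for x in ratios_r]
               + [_region("green", x) for x in ratios_g])
    rep = calibrate_maturity_report(samples)
    assert rep["red"]["median"] == pytest.approx(np.median(ratios_r))
    assert rep["green"]["median"] == pytest.approx(np.median(ratios_g))


def test_calibration_requires_twenty_regions():
    samples = [_region("red", 2.0)] * 5 + [_region("green", 0.9)] * 5
    with pytest.raises(ValueError, match="20"):
        calibrate_maturity_report(samples)


# ---------------------------------------------------------------------------
# nuclei counting / viability


def test_blank_image_counts_zero():
    assert count_nuclei(np.zeros((32, 32), np.uint8)) == 0


def test_synthetic_disks_counted_exactly():
    total, _, truth = gen_nuclei_image(50, 0.0, seed=5)
    assert count_nuclei(total) == truth.n_total == 50


def test_touching_disks_merge():
    from skimage.draw import disk
    img = np.zeros((40, 40), np.uint8)
    for c in ((15, 15), (15, 21)):            # overlapping disks
        rr, cc = disk(c, 5, shape=img.shape)
        img[rr, cc] = 255
    assert count_nuclei(img) == 1


def test_count_matches_flood_fill_oracle():
    """8-connected counting agrees with a hand-rolled BFS flood fill."""
    rng = np.random.default_rng(0)
    for _ in range(10):
        binary = rng.random((24, 24)) > 0.7
        img = (binary * 255).astype(np.uint8)
        seen = np.zeros_like(binary)
        n = 0
        for i in range(24):
            for j in range(24):
                if binary[i, j] and not seen[i, j]:
                    n += 1
                    stack = [(i, j)]
                    seen[i, j] = True
                    while stack:
                        a, b = stack.pop()
                        for da in (-1, 0, 1):
                            for db in (-1, 0, 1):
                                x, y = a + da, b + db
                                if 0 <= x < 24 and 0 <= y < 24 and \
                                        binary[x, y] and not seen[x, y]:
                                    seen[x, y] = True
                                    stack.append((x, y))
        assert count_nuclei(img, min_area_px=1) == n


def test_viability_formula_and_closed_loop():
    total, apo, truth = gen_nuclei_image(120, 0.25, seed=9)
    res = viability(total, apo)
    assert res.n_total == 120
    assert res.n_apoptotic == 30
    assert res.pct_viable == pytest.approx(75.0)


def test_viability_no_apoptosis_is_100():
    total, apo, _ = gen_nuclei_image(40, 0.0, seed=2)
    assert viability(total, apo).pct_viable == 100.0


def test_viability_requires_cells():
    blank = np.zeros((32, 32), np.uint8)
    with pytest.raises(ValueError):
        viability(blank, blank)


# ---------------------------------------------------------------------------
# cell density


@pytest.mark.parametrize("n, side, expected", [
    (36, 120.0, 2500.0),
    (0, 120.0, 0.0),
    (17, 100.0, 1700.0),
])
def test_cell_density_arithmetic(n, side, expected):
    assert cell_density(n, side).density_cells_mm2 == pytest.approx(expected)


def test_cell_density_rejects_bad_tile():
    with pytest.raises(ValueError):
        cell_density(10, 0.0)
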
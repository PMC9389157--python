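"""Tensile metrics from uniaxial load-displacement traces.

Engineering stress/strain convention: ``strain = displacement / gauge_length``
and ``stress = load / cross-sectional area`` (mN/mm^2 = kPa, reported in MPa).
Elastic modulus is the slope of the linear region of the stress-strain curve,
peak stress the maximum stress, and peak strain the strain at that sample
(first attainment on ties).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import TensileTrace

__all__ = ["StressStrainCurve", "TensileResult", "to_stress_strain",
           "find_linear_region", "tensile_metrics"]


@dataclass
class StressStrainCurve:
    strain: np.ndarray          # dimensionless
    stress_mpa: np.ndarray


@dataclass
class TensileResult:
    elastic_modulus_mpa: float
    peak_stress_mpa: float
    peak_strain: float
    linear_region: tuple[int, int]      # [start, stop) indices
    linear_r_squared: float


def to_stress_strain(trace: TensileTrace) -> StressStrainCurve:
    """Convert a load-displacement trace to engineering stress/strain."""
    if trace.cross_sectional_area_mm2 <= 0:
        raise ValueError("cross-sectional area must be > 0")
    if trace.gauge_length_mm <= 0:
        raise ValueError("gauge length must be > 0")
    disp = np.asarray(trace.displacement_um, dtype=float)
    load = np.asarray(trace.load_mn, dtype=float)
    if disp.shape != load.shape or disp.size < 20:
        raise ValueError("trace needs >= 20 samples of equal length")
    strain = disp / (trace.gauge_length_mm * 1000.0)
    stress_kpa = load / trace.cross_sectional_area_mm2    # mN/mm^2 = kPa
    return StressStrainCurve(strain, stress_kpa / 1000.0)


def _linfit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope, intercept and r^2 (r^2 = 1 for an exact line)."""
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    sxy = float(np.sum((x - xm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - ym) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 0.0
    return slope, intercept, r2


def find_linear_region(curve: StressStrainCurve, window_fraction: float = 0.2,
                       r2_floor: float = 0.99,
                       expand: bool = True) -> tuple[int, int]:
    """Locate the linear region of a stress-strain curve.

    A sliding window of ``window_fraction`` of the pre-peak samples is scanned
    exhaustively; among windows whose linear fit reaches ``r2_floor`` the one
    with the maximum slope wins (ties broken toward the later window).  The
    winning window is then extended sample-by-sample on both sides for as
    long as each candidate sample's residual against the current fit stays
    within 3x the window residual RMS and the fit stays at or above the
    floor — so a globally linear curve returns the whole pre-peak range while
    a curved toe is excluded.  Deterministic throughout.
    """
    strain, stress = curve.strain, curve.stress_mpa
    if strain.size < 20:
        raise ValueError("need >= 20 samples")
    peak = int(np.argmax(stress))
    n_pre = peak + 1
    w = max(5, int(round(window_fraction * n_pre)))
    if n_pre < w:
        raise ValueError("too few pre-peak samples for the requested window")
    best: tuple[int, int] | None = None
    best_slope = -np.inf
    best_r2_seen = -np.inf
    for start in range(0, n_pre - w + 1):
        sl, _, r2 = _linfit(strain[start:start + w], stress[start:start + w])
        best_r2_seen = max(best_r2_seen, r2)
        if r2 >= r2_floor and sl >= best_slope:
            best_slope = sl
            best = (start, start + w)
    if best is None:
        raise ValueError(
            f"no window of {w} samples reaches r^2 >= {r2_floor}; "
            f"best achieved r^2 = {best_r2_seen:.6f}")
    lo, hi = best
    if not expand:
        return lo, hi

    def _accepts(candidate: int, a: int, b: int) -> bool:
        sl, ic, _ = _linfit(strain[a:b], stress[a:b])
        resid = stress[a:b] - (sl * strain[a:b] + ic)
        rms = float(np.sqrt(np.mean(resid ** 2)))
        tol = max(3.0 * rms, 1e-9 * float(np.max(np.abs(stress)) or 1.0))
        if abs(stress[candidate] - (sl * strain[candidate] + ic)) > tol:
            return False
        new_a, new_b = min(a, candidate), max(b, candidate + 1)
        return _linfit(strain[new_a:new_b], stress[new_a:new_b])[2] >= r2_floor

    while lo > 0 and _accepts(lo - 1, lo, hi):
        lo -= 1
    while hi < n_pre and _accepts(hi, lo, hi):
        hi += 1
    return lo, hi


def tensile_metrics(curve: StressStrainCurve, window_fraction: float = 0.2,
                    r2_floor: float = 0.99) -> TensileResult:
    """Elastic modulus, peak stress and peak strain for one specimen."""
    lo, hi = find_linear_region(curve, window_fraction, r2_floor)
    slope, _, r2 = _linfit(curve.strain[lo:hi], curve.stress_mpa[lo:hi])
    peak = int(np.argmax(curve.stress_mpa))      # argmax -> earliest on ties
    return TensileResult(
        elastic_modulus_mpa=float(slope),
        peak_stress_mpa=float(curve.stress_mpa[peak]),
        peak_strain=float(curve.strain[peak]),
        linear_region=(lo, hi),
        linear_r_squared=float(r2),
    )
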
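"""Force-volume AFM analysis: contact-point detection, Hertzian fitting, modulus maps.

A force-volume acquisition rasters a cantilever over the sample and records one
force-displacement curve per pixel (piezo extension ``z`` vs. cantilever
deflection ``d``, both in nm).  Each curve is reduced to a Young's modulus by
(1) estimating the contact point, where the tip first touches the sample, and
(2) least-squares fitting the post-contact segment to a Hertz/Sneddon contact
law.  Maps are summarized by their median (modulus distributions in soft tissue
are right-skewed) and by a relative-frequency histogram on shared bin edges so
that treatment groups remain comparable.

Contact laws (E = Young's modulus, nu = Poisson ratio, delta = indentation):

* four-sided pyramid: ``F = C * tan(alpha) * E / (1 - nu^2) * delta^2`` with
  geometry coefficient ``C`` (default 0.7453, the Bilodeau convention) and tip
  half-angle ``alpha``;
* sphere: ``F = (4/3) * E / (1 - nu^2) * sqrt(R) * delta^(3/2)`` with tip
  radius ``R``.

Forces are reconstructed from deflection via Hooke's law, ``F = k * (d - d0)``,
and indentation is ``delta = (z - z0) - (d - d0)`` where ``(z0, d0)`` are the
contact position and baseline deflection offset.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProbeSpec",
    "ForceCurve",
    "HertzFitResult",
    "ForceMap",
    "ModulusMap",
    "detect_contact_point",
    "fit_hertz",
    "analyze_force_map",
    "summarize_map",
    "read_force_map_csv",
    "write_force_map_csv",
]

#: Bilodeau coefficient for a four-sided pyramidal indenter.
PYRAMID_COEFF = 0.7453

Model = Literal["pyramid", "sphere"]


@dataclass(frozen=True)
class ProbeSpec:
    """Cantilever/tip constants for one acquisition.

    Defaults reflect a soft-tissue mapping setup: a soft 0.06 N/m pyramidal
    silicon-nitride probe with ~20 nm nominal tip radius, driven until a 40 nm
    deflection trigger at 6 um/s approach speed.  ``approach_speed_um_s`` is
    metadata only; fitting is rate-independent.
    """

    spring_constant: float = 0.06          # N/m
    tip_half_angle_deg: float = 18.0       # degrees, pyramid face half-angle
    tip_radius_nm: float = 20.0            # nm, used by the sphere model
    poisson_ratio: float = 0.5             # incompressible soft tissue
    trigger_deflection_nm: float = 40.0    # nm
    approach_speed_um_s: float = 6.0       # metadata

    def __post_init__(self) -> None:
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be > 0")
        if not 0.0 < self.tip_half_angle_deg < 90.0:
            raise ValueError("tip_half_angle_deg must be in (0, 90)")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must be in [0, 0.5]")
        if self.trigger_deflection_nm <= 0:
            raise ValueError("trigger_deflection_nm must be > 0")


@dataclass
class ForceCurve:
    """One approach curve: piezo extension vs. cantilever deflection, both nm."""

    z_nm: np.ndarray
    deflection_nm: np.ndarray
    probe: ProbeSpec

    def __post_init__(self) -> None:
        self.z_nm = np.asarray(self.z_nm, dtype=float)
        self.deflection_nm = np.asarray(self.deflection_nm, dtype=float)
        if self.z_nm.shape != self.deflection_nm.shape or self.z_nm.ndim != 1:
            raise ValueError("z and deflection must be 1-D arrays of equal length")
        if self.z_nm.size < 16:
            raise ValueError("force curve needs at least 16 samples")
        dz = np.diff(self.z_nm)
        if not (np.all(dz > 0) or np.all(dz < 0)):
            raise ValueError("z must be strictly monotone")

    def __len__(self) -> int:
        return self.z_nm.size


@dataclass
class HertzFitResult:
    """Outcome of fitting a single curve; ``valid=False`` carries a reason."""

    modulus_kpa: float
    contact_index: int
    contact_z_nm: float
    baseline_offset_nm: float
    r_squared: float
    model: str
    valid: bool
    reason: str = ""


@dataclass
class ForceMap:
    """Rectangular grid of force curves over a scanned area (default 10x10 um)."""

    curves: list[list[ForceCurve]]
    scan_size_um: tuple[float, float] = (10.0, 10.0)

    def __post_init__(self) -> None:
        ncols = {len(row) for row in self.curves}
        if len(ncols) != 1:
            raise ValueError("force map must be rectangular")

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.curves), len(self.curves[0])


@dataclass
class ModulusMap:
    """Per-pixel fit results plus median and relative-frequency histogram."""

    fits: list[list[HertzFitResult]]
    median_kpa: float
    hist_edges_kpa: np.ndarray
    hist_rel_freq: np.ndarray
    n_valid: int
    n_invalid: int
    quality_warning: bool = False

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.fits), len(self.fits[0])

    def modulus_grid(self) -> np.ndarray:
        """kPa grid with NaN at invalid pixels."""
        rows, cols = self.shape
        out = np.full((rows, cols), np.nan)
        for i in range(rows):
            for j in range(cols):
                f = self.fits[i][j]
                if f.valid:
                    out[i, j] = f.modulus_kpa
        return out

    def valid_values(self) -> np.ndarray:
        g = self.modulus_grid().ravel()
        return g[np.isfinite(g)]

    def to_json(self) -> str:
        return json.dumps(
            {
                "median_kpa": self.median_kpa,
                "n_valid": self.n_valid,
                "n_invalid": self.n_invalid,
                "quality_warning": self.quality_warning,
                "hist_edges_kpa": list(map(float, self.hist_edges_kpa)),
                "hist_rel_freq": list(map(float, self.hist_rel_freq)),
            },
            sort_keys=True,
            indent=2,
        )


# ---------------------------------------------------------------------------
# geometry helpers

def _law_exponent(model: Model) -> float:
    return 2.0 if model == "pyramid" else 1.5


def _modulus_prefactor_nn_nm(probe: ProbeSpec, model: Model,
                             geometry_coefficient: float) -> float:
    """Force-law prefactor per kPa of modulus, in nN/nm^p units.

    pyramid: F = [C tan(alpha) / (1-nu^2)] * E * delta^2
    sphere:  F = [(4/3) sqrt(R) / (1-nu^2)] * E * delta^1.5
    Returned so that F[nN] = prefactor * E[kPa] * delta[nm]^p.
    """
    one_minus = 1.0 - probe.poisson_ratio ** 2
    if model == "pyramid":
        geo = geometry_coefficient * math.tan(math.radians(probe.tip_half_angle_deg))
        # E kPa -> Pa (1e3); delta^2 nm^2 -> m^2 (1e-18); F N -> nN (1e9)
        return geo / one_minus * 1e3 * 1e-18 * 1e9
    if model == "sphere":
        geo = (4.0 / 3.0) * math.sqrt(probe.tip_radius_nm * 1e-9)
        # delta^1.5 nm^1.5 -> m^1.5 (1e-13.5)
        return geo / one_minus * 1e3 * 10 ** (-13.5) * 1e9
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# contact-point detection

def detect_contact_point(curve: ForceCurve, model: Model = "pyramid",
                         min_baseline: int = 8, min_contact: int = 8,
                         baseline_rms_fraction: float = 0.05,
                         coarse_stride: int = 2) -> tuple[int, float, bool, str]:
    """Estimate the contact point of an approach curve.

    For each candidate contact index ``j`` the curve is modelled piecewise: a
    flat baseline (mean deflection of samples before ``j``) followed by the
    power-law contact branch with its amplitude fitted in closed form.  The
    index minimizing the total squared residual (in deflection units) is the
    contact point; the search is coarse-then-refined and fully deterministic.

    Returns ``(contact_index, baseline_offset_nm, ok, reason)``.  ``ok`` is
    False when no flat baseline exists (deflection rising from the first
    sample, judged by baseline RMS > ``baseline_rms_fraction`` x trigger) or
    when the post-contact branch carries no signal.
    """
    z = curve.z_nm
    d = curve.deflection_nm
    n = z.size
    if n < min_baseline + min_contact:
        return 0, 0.0, False, "too few samples"
    if np.ptp(d) == 0:
        return 0, float(d[0]), False, "constant deflection"

    p = _law_exponent(model)

    csum = np.cumsum(d)
    csum2 = np.cumsum(d * d)

    def _sse(cands: np.ndarray) -> np.ndarray:
        m = csum[cands - 1] / cands                       # baseline means
        sse_pre = csum2[cands - 1] - cands * m * m
        idx = np.arange(n)
        mask = idx[None, :] >= cands[:, None]
        dd = d[None, :] - m[:, None]                      # force/k, nm
        delta = (z[None, :] - z[cands][:, None]) - dd
        delta = np.where(mask & (delta > 0), delta, 0.0)
        dp = delta ** p
        denom = np.sum(dp * dp, axis=1)
        num = np.sum(np.where(mask, dd, 0.0) * dp, axis=1)
        amp = np.where(denom > 0, np.clip(num / np.maximum(denom, 1e-300), 0, None), 0.0)
        resid = np.where(mask, dd, 0.0) - amp[:, None] * dp
        sse_post = np.sum(resid * resid, axis=1)
        return sse_pre + sse_post

    cands = np.arange(min_baseline, n - min_contact, coarse_stride)
    sse = _sse(cands)
    best = cands[int(np.argmin(sse))]
    lo = max(min_baseline, best - coarse_stride)
    hi = min(n - min_contact, best + coarse_stride + 1)
    fine = np.arange(lo, hi)
    j = int(fine[int(np.argmin(_sse(fine)))])

    m = float(csum[j - 1] / j)
    rms_pre = math.sqrt(max(float(csum2[j - 1] / j - m * m), 0.0))
    # flat-baseline checks: bounded scatter and no systematic drift across
    # the pre-contact span (a deflection rising from the first sample fails)
    tol = baseline_rms_fraction * curve.probe.trigger_deflection_nm
    slope = np.polyfit(z[:j], d[:j], 1)[0]
    drift = abs(slope) * (z[j - 1] - z[0])
    if rms_pre > tol or abs(drift) > tol:
        return j, m, False, "no detectable baseline"
    return j, m, True, ""


# ---------------------------------------------------------------------------
# Hertz fitting

def fit_hertz(curve: ForceCurve, model: Model = "pyramid",
              geometry_coefficient: float = PYRAMID_COEFF,
              contact: tuple[int, float] | None = None) -> HertzFitResult:
    """Fit one curve to the selected contact law and return the modulus in kPa.

    The amplitude of ``F = A * delta^p`` is linear in E, so the least-squares
    solution is closed-form:  ``A = sum(F * delta^p) / sum(delta^(2p))`` over
    the window from the contact sample to the trigger deflection.  The fit is
    scale-invariant: rescaling z and d by a common factor rescales E by the
    inverse factor exactly.
    """
    if contact is None:
        j, d0, ok, reason = detect_contact_point(curve, model)
        if not ok:
            return HertzFitResult(float("nan"), j, float(curve.z_nm[j]), d0,
                                  0.0, model, False, reason)
    else:
        j, d0 = contact
    z, d, probe = curve.z_nm, curve.deflection_nm, curve.probe
    p = _law_exponent(model)

    dd = d[j:] - d0                                  # deflection above baseline, nm
    delta = (z[j:] - z[j]) - dd                      # indentation, nm
    sel = (delta > 0) & (dd > 0) & (dd <= probe.trigger_deflection_nm + 1e-9)
    if np.count_nonzero(sel) < 8:
        return HertzFitResult(float("nan"), j, float(z[j]), d0, 0.0, model,
                              False, "no contact")
    force = probe.spring_constant * dd[sel]          # nN
    dp = delta[sel] ** p
    denom = float(np.sum(dp * dp))
    amp = float(np.sum(force * dp)) / denom          # nN / nm^p
    pref = _modulus_prefactor_nn_nm(probe, model, geometry_coefficient)
    modulus = amp / pref                             # kPa
    if modulus <= 0:
        return HertzFitResult(float("nan"), j, float(z[j]), d0, 0.0, model,
                              False, "negative modulus")
    resid = force - amp * dp
    ss_tot = float(np.sum((force - force.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 0.0
    return HertzFitResult(modulus, j, float(z[j]), d0,
                          float(np.clip(r2, 0.0, 1.0)), model, True)


def analyze_force_map(fmap: ForceMap, model: Model = "pyramid",
                      geometry_coefficient: float = PYRAMID_COEFF,
                      bin_width_kpa: float = 5.0,
                      hist_edges_kpa: np.ndarray | None = None) -> ModulusMap:
    """Fit every pixel of a force map and attach the median + histogram summary.

    Invalid pixels (no baseline, no contact, pathological fit) are kept with
    their reason but excluded from the median and the histogram; a quality
    warning is raised when more than half the pixels fail.
    """
    rows, cols = fmap.shape
    fits: list[list[HertzFitResult]] = []
    for i in range(rows):
        fits.append([fit_hertz(fmap.curves[i][j], model, geometry_coefficient)
                     for j in range(cols)])
    mm = ModulusMap(fits, float("nan"), np.array([]), np.array([]), 0, 0)
    vals = mm.valid_values()
    mm.n_valid = vals.size
    mm.n_invalid = rows * cols - vals.size
    mm.quality_warning = mm.n_invalid > rows * cols / 2
    if vals.size:
        med, edges, freq = summarize_map(mm, bin_width_kpa, hist_edges_kpa)
        mm.median_kpa, mm.hist_edges_kpa, mm.hist_rel_freq = med, edges, freq
    return mm


def summarize_map(mmap: ModulusMap, bin_width_kpa: float = 5.0,
                  edges_kpa: np.ndarray | None = None
                  ) -> tuple[float, np.ndarray, np.ndarray]:
    """Median modulus over valid pixels + relative-frequency histogram.

    The median (not the mean) is the per-sample summary because modulus
    distributions shift asymmetrically under treatment.  Fixed bin edges can
    be shared across treatment groups for comparable histograms.
    """
    vals = mmap.valid_values()
    if vals.size == 0:
        raise ValueError("all pixels invalid; no modulus values to summarize")
    if edges_kpa is None:
        top = max(bin_width_kpa, float(np.max(vals)))
        nbins = int(math.ceil(top / bin_width_kpa + 1e-12))
        edges_kpa = np.arange(nbins + 1, dtype=float) * bin_width_kpa
    edges_kpa = np.asarray(edges_kpa, dtype=float)
    counts, _ = np.histogram(vals, bins=edges_kpa)
    inside = counts.sum()
    rel = counts / inside if inside else counts.astype(float)
    return float(np.median(vals)), edges_kpa, rel


# ---------------------------------------------------------------------------
# IO: long-format CSV + JSON probe metadata

def write_force_map_csv(fmap: ForceMap, csv_path: str | Path,
                        probe_json_path: str | Path | None = None) -> None:
    """Write a force map as long CSV (pixel_row, pixel_col, z_nm, deflection_nm)."""
    rows = []
    nr, nc = fmap.shape
    for i in range(nr):
        for j in range(nc):
            c = fmap.curves[i][j]
            rows.append(pd.DataFrame({
                "pixel_row": i, "pixel_col": j,
                "z_nm": c.z_nm, "deflection_nm": c.deflection_nm,
            }))
    pd.concat(rows, ignore_index=True).to_csv(csv_path, index=False,
                                              float_format="%.10g")
    if probe_json_path is not None:
        probe = fmap.curves[0][0].probe
        Path(probe_json_path).write_text(
            json.dumps(asdict(probe), sort_keys=True, indent=2) + "\n")


def read_force_map_csv(csv_path: str | Path,
                       probe: ProbeSpec | str | Path,
                       scan_size_um: tuple[float, float] = (10.0, 10.0)) -> ForceMap:
    """Read a long-format force-map CSV; probe may be a ProbeSpec or JSON path."""
    if not isinstance(probe, ProbeSpec):
        probe = ProbeSpec(**json.loads(Path(probe).read_text()))
    df = pd.read_csv(csv_path)
    nr = int(df["pixel_row"].max()) + 1
    nc = int(df["pixel_col"].max()) + 1
    grid: list[list[ForceCurve]] = [[None] * nc for _ in range(nr)]  # type: ignore
    for (i, j), g in df.groupby(["pixel_row", "pixel_col"], sort=True):
        grid[int(i)][int(j)] = ForceCurve(g["z_nm"].to_numpy(),
                                          g["deflection_nm"].to_numpy(), probe)
    return ForceMap(grid, scan_size_um)
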
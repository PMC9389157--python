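"""Synthetic inputs with known ground truth for every assay in the pipeline.

The study's raw data are not deposited, so each analysis stage is validated by
parameter recovery on generated data: force-volume maps following the
pyramidal contact law, toe-then-linear tensile traces, tri-color birefringence
images with prescribed red/yellow/green fractions, oriented fiber fields,
non-overlapping nuclei point patterns with a prescribed apoptotic fraction,
and dose-response tables drawn from the exponential-plateau law
``Y = YM - (YM - Y0) * exp(-k * x)``.

Every generator is deterministic given (parameters, seed) and returns its
output together with a ground-truth record of the parameters that produced
it.  Noise is additive Gaussian throughout; images are 8-bit with a stated
um/px scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.draw import disk as _disk_coords
from skimage.draw import line as _line_coords

from .afm import ForceCurve, ForceMap, ProbeSpec, _law_exponent, _modulus_prefactor_nn_nm

__all__ = [
    "ForceMapTruth", "TensileTruth", "PsrTruth", "ShgTruth", "NucleiTruth",
    "DoseResponseTruth", "TensileTrace", "DoseResponseDataset",
    "gen_force_map", "gen_force_curve", "gen_tensile_trace", "gen_psr_image",
    "gen_shg_image", "gen_nuclei_image", "gen_dose_response",
]


# ---------------------------------------------------------------------------
# ground-truth records


@dataclass(frozen=True)
class ForceMapTruth:
    modulus_kpa: np.ndarray          # true modulus field, kPa
    contact_z_nm: float
    noise_sd_nm: float
    model: str = "pyramid"


@dataclass(frozen=True)
class TensileTruth:
    modulus_mpa: float
    peak_stress_mpa: float
    peak_strain: float
    toe_fraction: float
    noise_sd_mpa: float


@dataclass(frozen=True)
class PsrTruth:
    fraction_red: float
    fraction_yellow: float
    fraction_green: float
    n_red: int
    n_yellow: int
    n_green: int
    n_background: int


@dataclass(frozen=True)
class ShgTruth:
    mean_angle_deg: float
    angular_sd_deg: float
    angles_deg: np.ndarray           # realized per-fiber orientations
    fiber_count: int

    @property
    def sample_sd_deg(self) -> float:
        """Sample sd of realized orientations about the mean (wrapped)."""
        dev = (self.angles_deg - self.mean_angle_deg + 90.0) % 180.0 - 90.0
        return float(np.std(dev, ddof=1)) if dev.size > 1 else 0.0


@dataclass(frozen=True)
class NucleiTruth:
    n_total: int
    n_apoptotic: int
    apoptotic_fraction: float
    centers: np.ndarray              # (n, 2) row/col


@dataclass(frozen=True)
class DoseResponseTruth:
    y0: float
    ym: float
    k: float
    noise_sd: float


@dataclass
class TensileTrace:
    """Load-displacement record plus specimen geometry."""
    displacement_um: np.ndarray
    load_mn: np.ndarray
    gauge_length_mm: float
    cross_sectional_area_mm2: float
    strain_rate_pct_s: float = 1.0


@dataclass
class DoseResponseDataset:
    """Long-format (x, y) dose-response records with a group label per row."""
    x: np.ndarray
    y: np.ndarray
    group: list[str]


# ---------------------------------------------------------------------------
# force-volume maps


def _solve_deflection(u_nm: np.ndarray, coeff: float, k: float,
                      p: float) -> np.ndarray:
    """Deflection d solving k*d = coeff*(u - d)^p for u >= 0 (nm, nN units).

    For the pyramid law (p=2) the solution is closed-form via the stable
    quadratic root; for other exponents bisection is used.
    """
    u = np.asarray(u_nm, dtype=float)
    if p == 2.0:
        # coeff*d^2 - (2*coeff*u + k)*d + coeff*u^2 = 0; take the root < u
        b = 2.0 * coeff * u + k
        disc = np.sqrt(b * b - 4.0 * coeff ** 2 * u * u)
        d_plus = (b + disc) / (2.0 * coeff)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(d_plus > 0, u * u / d_plus, 0.0)
        return d
    lo = np.zeros_like(u)
    hi = u.copy()
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        too_low = k * mid < coeff * np.maximum(u - mid, 0.0) ** p
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return 0.5 * (lo + hi)


def gen_force_curve(modulus_kpa: float, probe: ProbeSpec, *,
                    noise_sd_nm: float = 0.0,
                    contact_z_nm: float = 500.0,
                    n_baseline: int = 64, n_contact: int = 128,
                    model: str = "pyramid",
                    geometry_coefficient: float = 0.7453,
                    rng: np.random.Generator | None = None) -> ForceCurve:
    """One synthetic approach curve: flat baseline then the contact branch.

    The z ramp places the contact point exactly on a sample and ends exactly
    at the deflection trigger, so the noiseless curve's final deflection
    equals ``probe.trigger_deflection_nm``.
    """
    if modulus_kpa <= 0:
        raise ValueError("modulus must be strictly positive")
    if noise_sd_nm < 0:
        raise ValueError("noise_sd must be >= 0")
    p = _law_exponent(model)  # type: ignore[arg-type]
    coeff = _modulus_prefactor_nn_nm(probe, model, geometry_coefficient) * modulus_kpa
    k = probe.spring_constant
    d_t = probe.trigger_deflection_nm
    u_trig = d_t + (k * d_t / coeff) ** (1.0 / p)
    z_pre = np.linspace(0.0, contact_z_nm, n_baseline, endpoint=False)
    z_post = contact_z_nm + np.linspace(0.0, u_trig, n_contact)
    z = np.concatenate([z_pre, z_post])
    d = np.zeros_like(z)
    d[n_baseline:] = _solve_deflection(z_post - contact_z_nm, coeff, k, p)
    if noise_sd_nm > 0:
        if rng is None:
            rng = np.random.default_rng()
        d = d + rng.normal(0.0, noise_sd_nm, size=d.shape)
    return ForceCurve(z, d, probe)


def gen_force_map(modulus_field_kpa: np.ndarray,
                  probe: ProbeSpec | None = None, *,
                  noise_sd_nm: float = 0.5, seed: int = 0,
                  contact_z_nm: float = 500.0,
                  n_baseline: int = 64, n_contact: int = 128,
                  model: str = "pyramid",
                  geometry_coefficient: float = 0.7453,
                  scan_size_um: tuple[float, float] = (10.0, 10.0),
                  ) -> tuple[ForceMap, ForceMapTruth]:
    """Force-volume map: one synthetic curve per pixel of the modulus field."""
    field_arr = np.atleast_2d(np.asarray(modulus_field_kpa, dtype=float))
    if np.any(field_arr <= 0):
        raise ValueError("modulus field must be strictly positive everywhere")
    if noise_sd_nm < 0:
        raise ValueError("noise_sd must be >= 0")
    probe = probe or ProbeSpec()
    rng = np.random.default_rng(seed)
    rows, cols = field_arr.shape
    grid: list[list[ForceCurve]] = []
    for i in range(rows):
        row = [gen_force_curve(field_arr[i, j], probe, noise_sd_nm=noise_sd_nm,
                               contact_z_nm=contact_z_nm, n_baseline=n_baseline,
                               n_contact=n_contact, model=model,
                               geometry_coefficient=geometry_coefficient,
                               rng=rng)
               for j in range(cols)]
        grid.append(row)
    truth = ForceMapTruth(field_arr.copy(), contact_z_nm, noise_sd_nm, model)
    return ForceMap(grid, scan_size_um), truth


# ---------------------------------------------------------------------------
# tensile traces


def gen_tensile_trace(modulus_mpa: float, gauge_length_mm: float,
                      csa_mm2: float, *, toe_fraction: float = 0.05,
                      failure_strain: float = 0.25, noise_sd_mpa: float = 0.0,
                      seed: int = 0, n_points: int = 400,
                      strain_rate_pct_s: float = 1.0,
                      ) -> tuple[TensileTrace, TensileTruth]:
    """Uniaxial pull-to-failure trace: exponential toe, linear region, post-peak drop.

    The toe follows ``sigma = E*ec*(exp((eps-eps_t)/ec) - exp(-eps_t/ec))``
    with ``ec = toe_fraction/3``, which joins the linear branch with matching
    value and slope at ``eps_t = toe_fraction``.  Noise (MPa) is added to the
    stress and carried into the load channel.
    """
    if modulus_mpa <= 0 or gauge_length_mm <= 0 or csa_mm2 <= 0:
        raise ValueError("modulus and geometry must be positive")
    if not 0 <= toe_fraction < failure_strain:
        raise ValueError("require 0 <= toe_fraction < failure_strain")
    if noise_sd_mpa < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n_drop = max(4, n_points // 20)
    strain = np.linspace(0.0, failure_strain, n_points)
    if toe_fraction > 0:
        ec = toe_fraction / 3.0
        toe = strain <= toe_fraction
        stress = np.where(
            toe,
            modulus_mpa * ec * (np.exp((strain - toe_fraction) / ec)
                                - math.exp(-toe_fraction / ec)),
            0.0)
        sigma_t = modulus_mpa * ec * (1.0 - math.exp(-toe_fraction / ec))
        stress = np.where(toe, stress,
                          sigma_t + modulus_mpa * (strain - toe_fraction))
    else:
        stress = modulus_mpa * strain
    peak_stress = float(stress[-1])
    peak_strain = float(strain[-1])
    # post-peak drop to 40% of peak over a short strain interval
    drop_strain = failure_strain + np.linspace(0.0, 0.02, n_drop + 1)[1:]
    drop_stress = peak_stress * np.linspace(1.0, 0.4, n_drop + 1)[1:]
    strain = np.concatenate([strain, drop_strain])
    stress = np.concatenate([stress, drop_stress])
    if noise_sd_mpa > 0:
        stress = stress + rng.normal(0.0, noise_sd_mpa, size=stress.shape)
    load_mn = stress * csa_mm2 * 1000.0          # MPa * mm^2 = N -> mN
    displacement_um = strain * gauge_length_mm * 1000.0
    trace = TensileTrace(displacement_um, load_mn, gauge_length_mm, csa_mm2,
                         strain_rate_pct_s)
    return trace, TensileTruth(modulus_mpa, peak_stress, peak_strain,
                               toe_fraction, noise_sd_mpa)


# ---------------------------------------------------------------------------
# picrosirius-red birefringence images

# class colors chosen well inside the I_R/I_G decision regions:
# red 200/100 = 2.0 (>1.8), yellow 150/100 = 1.5, green 90/100 = 0.9 (<1.1)
_PSR_COLORS = {"red": (200, 100, 30), "yellow": (150, 100, 40),
               "green": (90, 100, 50)}


def _largest_remainder(fractions: Sequence[float], total: int) -> list[int]:
    raw = [f * total for f in fractions]
    base = [int(math.floor(r)) for r in raw]
    short = total - sum(base)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - base[i], reverse=True)
    for i in order[:short]:
        base[i] += 1
    return base


def _grow_regions(shape: tuple[int, int], quotas: dict[str, int],
                  rng: np.random.Generator) -> np.ndarray:
    """Multi-seed region growing with exact per-class pixel quotas.

    Produces spatially contiguous blobs (not salt-and-pepper) whose pixel
    counts match the quotas exactly; the leftover class is background.
    """
    h, w = shape
    label = np.full((h, w), -1, dtype=np.int16)
    names = [n for n, q in quotas.items() if q > 0]
    remaining = {n: quotas[n] for n in names}
    frontiers: dict[str, list[tuple[int, int]]] = {n: [] for n in names}

    def _seed(name: str) -> None:
        free = np.argwhere(label < 0)
        r, c = free[rng.integers(len(free))]
        label[r, c] = names.index(name)
        remaining[name] -= 1
        frontiers[name].append((int(r), int(c)))

    for name in names:
        n_seeds = max(1, remaining[name] // 600)
        for _ in range(min(n_seeds, remaining[name] + 1)):
            if remaining[name] > 0:
                _seed(name)
    nbrs = ((-1, 0), (1, 0), (0, -1), (0, 1))
    active = [n for n in names if remaining[n] > 0]
    while active:
        for name in list(active):
            if remaining[name] <= 0:
                active.remove(name)
                continue
            grew = False
            front = frontiers[name]
            while front and not grew:
                idx = int(rng.integers(len(front)))
                r, c = front[idx]
                options = [(r + dr, c + dc) for dr, dc in nbrs
                           if 0 <= r + dr < h and 0 <= c + dc < w
                           and label[r + dr, c + dc] < 0]
                if not options:
                    front[idx] = front[-1]
                    front.pop()
                    continue
                rr, cc = options[int(rng.integers(len(options)))]
                label[rr, cc] = names.index(name)
                remaining[name] -= 1
                front.append((rr, cc))
                grew = True
            if not grew and remaining[name] > 0:
                _seed(name)
    return label


def gen_psr_image(fraction_red: float, fraction_yellow: float,
                  fraction_green: float, *, width: int = 128,
                  height: int = 128, seed: int = 0,
                  pixel_size_um: float = 0.5,
                  ) -> tuple[np.ndarray, PsrTruth]:
    """Tri-color polarized-light image with exact class pixel fractions.

    Returns an (H, W, 3) uint8 array whose red/yellow/green blob pixel counts
    follow the requested fractions exactly (largest-remainder rounding); the
    remainder is background at intensity 0.  Per-blob brightness varies by a
    common scale on all channels, which leaves the I_R/I_G ratio untouched.
    """
    fracs = (fraction_red, fraction_yellow, fraction_green)
    if any(f < 0 for f in fracs):
        raise ValueError("fractions must be >= 0")
    if sum(fracs) > 1.0 + 1e-12:
        raise ValueError("fractions must sum to <= 1")
    rng = np.random.default_rng(seed)
    total = width * height
    # background participates in the rounding so class counts stay exact
    n_red, n_yellow, n_green, _ = _largest_remainder(
        (*fracs, max(0.0, 1.0 - sum(fracs))), total)
    quotas = {"red": n_red, "yellow": n_yellow, "green": n_green}
    label = _grow_regions((height, width), quotas, rng)
    img = np.zeros((height, width, 3), dtype=np.uint8)
    names = [n for n, q in quotas.items() if q > 0]
    scale = rng.uniform(0.85, 1.15, size=(height, width))
    for li, name in enumerate(names):
        mask = label == li
        base = np.array(_PSR_COLORS[name], dtype=float)
        pix = np.clip(np.round(base[None, :] * scale[mask, None]), 0, 255)
        img[mask] = pix.astype(np.uint8)
    n_bg = total - n_red - n_yellow - n_green
    truth = PsrTruth(fraction_red, fraction_yellow, fraction_green,
                     n_red, n_yellow, n_green, n_bg)
    return img, truth


# ---------------------------------------------------------------------------
# SHG fiber images


def gen_shg_image(mean_angle_deg: float, angular_sd_deg: float, *,
                  fiber_count: int = 200, width: int = 256, height: int = 256,
                  seed: int = 0, fiber_length_px: int = 100,
                  pixel_size_um: float = 0.3,
                  ) -> tuple[np.ndarray, ShgTruth]:
    """Bright line segments on dark background with wrapped-normal orientations.

    Orientation convention: degrees counter-clockwise from the image x-axis
    (as displayed), in [-90, 90).  Fibers are placed entirely inside the
    frame and drawn at a common amplitude, so every fiber contributes equal
    weight to the Fourier orientation histogram and the power-weighted
    dispersion estimate is comparable to the plain sample sd of the drawn
    angles (stored in the truth record).  ``angular_sd_deg=0`` gives
    identical orientations.
    """
    if fiber_count < 1:
        raise ValueError("fiber_count must be >= 1")
    if angular_sd_deg < 0:
        raise ValueError("angular_sd must be >= 0")
    rng = np.random.default_rng(seed)
    angles = mean_angle_deg + rng.normal(0.0, angular_sd_deg, size=fiber_count)
    angles = (angles + 90.0) % 180.0 - 90.0              # wrap to [-90, 90)
    img = np.zeros((height, width), dtype=float)
    half = fiber_length_px / 2.0
    mr = min(half, (height - 1) / 2.0)
    mc = min(half, (width - 1) / 2.0)
    for ang in angles:
        r0 = rng.uniform(mr, height - mr)
        c0 = rng.uniform(mc, width - mc)
        dr = -math.sin(math.radians(ang))                # row axis points down
        dc = math.cos(math.radians(ang))
        r1, c1 = r0 - half * dr, c0 - half * dc
        r2, c2 = r0 + half * dr, c0 + half * dc
        rr, cc = _line_coords(int(round(r1)), int(round(c1)),
                              int(round(r2)), int(round(c2)))
        keep = (rr >= 0) & (rr < height) & (cc >= 0) & (cc < width)
        img[rr[keep], cc[keep]] += 200.0
    img = np.clip(img, 0, 255).astype(np.uint8)
    return img, ShgTruth(mean_angle_deg, angular_sd_deg, angles, fiber_count)


# ---------------------------------------------------------------------------
# nuclei / apoptosis two-channel images


def gen_nuclei_image(total: int, apoptotic_fraction: float, *,
                     width: int = 256, height: int = 256,
                     min_separation_px: float = 12.0, radius_px: int = 4,
                     seed: int = 0, pixel_size_um: float = 0.5,
                     max_tries_per_cell: int = 200,
                     ) -> tuple[np.ndarray, np.ndarray, NucleiTruth]:
    """Two-channel nuclei point pattern with a prescribed apoptotic fraction.

    Channel 1 holds ``total`` non-overlapping bright disks (all nuclei);
    channel 2 marks ``round(total * apoptotic_fraction)`` of the same centers
    (apoptotic nuclei).  Placement is rejection-sampled at the requested
    minimum center separation and errors out if packing is infeasible.
    """
    if not 0.0 <= apoptotic_fraction <= 1.0:
        raise ValueError("apoptotic_fraction must be in [0, 1]")
    if total < 1:
        raise ValueError("total must be >= 1")
    rng = np.random.default_rng(seed)
    centers: list[tuple[float, float]] = []
    margin = radius_px + 1
    for _ in range(total):
        for attempt in range(max_tries_per_cell):
            r = rng.uniform(margin, height - margin)
            c = rng.uniform(margin, width - margin)
            if all((r - r0) ** 2 + (c - c0) ** 2 >= min_separation_px ** 2
                   for r0, c0 in centers):
                centers.append((r, c))
                break
        else:
            raise ValueError(
                f"could not place {total} nuclei at min separation "
                f"{min_separation_px}px in a {width}x{height} image")
    n_apo = round(total * apoptotic_fraction)
    order = rng.permutation(total)
    apo_idx = set(order[:n_apo].tolist())
    chan_total = np.zeros((height, width), dtype=np.uint8)
    chan_apo = np.zeros((height, width), dtype=np.uint8)
    for i, (r, c) in enumerate(centers):
        rr, cc = _disk_coords((r, c), radius_px, shape=(height, width))
        chan_total[rr, cc] = 255
        if i in apo_idx:
            chan_apo[rr, cc] = 255
    truth = NucleiTruth(total, n_apo, apoptotic_fraction,
                        np.array(centers))
    return chan_total, chan_apo, truth


# ---------------------------------------------------------------------------
# dose-response tables


def gen_dose_response(y0: float, ym: float, k: float, *,
                      levels: Sequence[float] = (0.0, 1.0, 2.0, 5.0),
                      reps: int = 5, noise_sd: float = 0.0, seed: int = 0,
                      ) -> tuple[DoseResponseDataset, DoseResponseTruth]:
    """Replicated observations of the exponential-plateau law at each dose level."""
    if ym < y0:
        raise ValueError("require ym >= y0 (saturating response)")
    if k <= 0:
        raise ValueError("k must be > 0")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    xs, ys, groups = [], [], []
    for lv in levels:
        mean = ym - (ym - y0) * math.exp(-k * lv)
        for _ in range(reps):
            xs.append(lv)
            ys.append(mean + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0))
            groups.append(f"{lv:g}X")
    data = DoseResponseDataset(np.array(xs), np.array(ys), groups)
    return data, DoseResponseTruth(y0, ym, k, noise_sd)
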
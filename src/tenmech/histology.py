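"""Histological quantification: PSR collagen content and maturity, nuclei
counting for TUNEL viability, and H&E cell density.

Collagen maturity follows the polarized-light picrosirius-red convention:
birefringence hue shifts green -> yellow -> red as fibers thicken and pack,
so each above-background pixel is classed by its red:green intensity ratio
I_R/I_G — red (mature) when the ratio is >= 1.8, green (immature) when
<= 1.1, yellow (intermediate) strictly between.  Both boundary values are
inclusive toward their color class.  Viability from TUNEL staining is
``(N_total - N_apoptotic) / N_total * 100`` with both counts obtained by
thresholding plus connected-component analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label

__all__ = [
    "MaturityThresholds", "MaturityResult", "ViabilityResult",
    "CellDensityResult", "RegionSample", "psr_content", "classify_maturity",
    "calibrate_maturity_report", "count_nuclei", "viability", "cell_density",
]


@dataclass(frozen=True)
class MaturityThresholds:
    """I_R/I_G cutoffs for the red/yellow/green maturity classes."""
    t_green: float = 1.1      # ratio <= t_green -> green (immature)
    t_red: float = 1.8        # ratio >= t_red -> red (mature)
    background_floor: int = 10  # 8-bit max-channel at or below -> background

    def __post_init__(self) -> None:
        if not 0 < self.t_green < self.t_red:
            raise ValueError("require 0 < t_green < t_red")


@dataclass
class MaturityResult:
    pct_red: float
    pct_yellow: float
    pct_green: float
    n_classified: int
    n_background: int


@dataclass
class ViabilityResult:
    n_total: int
    n_apoptotic: int
    pct_viable: float


@dataclass
class CellDensityResult:
    n_cells: int
    tile_area_um2: float
    density_cells_mm2: float


@dataclass
class RegionSample:
    """A reviewer-labeled region used for ratio-threshold calibration."""
    color: Literal["red", "green"]
    red_intensities: np.ndarray
    green_intensities: np.ndarray

    def mean_ratio(self) -> float:
        g = float(np.mean(self.green_intensities))
        if g == 0:
            return float("inf")
        return float(np.mean(self.red_intensities)) / g


def psr_content(image: np.ndarray, method: Literal["otsu", "fixed"] = "otsu",
                fixed_threshold: float | None = None) -> float:
    """Stained-area fraction (%) of a brightfield PSR image.

    The RGB image is collapsed to 8-bit grayscale and thresholded; pixels
    above the threshold count as PSR-positive.  With ``method='otsu'`` on a
    blank (constant) image the function returns 0% with a warning.
    """
    img = np.asarray(image)
    if img.ndim == 3:
        gray = np.round(rgb2gray(img) * 255.0)
    else:
        gray = img.astype(float)
    if method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed method requires fixed_threshold")
        thr = float(fixed_threshold)
    elif method == "otsu":
        if np.ptp(gray) == 0:
            warnings.warn("blank image: Otsu threshold undefined, returning 0%")
            return 0.0
        thr = float(threshold_otsu(gray.astype(np.uint8)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(np.count_nonzero(gray > thr)) / gray.size * 100.0


def classify_maturity(image: np.ndarray,
                      thresholds: MaturityThresholds = MaturityThresholds(),
                      ) -> MaturityResult:
    """Red/yellow/green percentages of classified (above-background) pixels.

    Background = pixels whose maximum channel is at or below the floor.
    Classification is ratio-based and therefore invariant to a common scaling
    of the R and G channels; I_G = 0 with I_R above the floor counts as red
    (the ratio's limit).
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] < 2:
        raise ValueError("expected an RGB image")
    r = img[..., 0].astype(float)
    g = img[..., 1].astype(float)
    tissue = img.max(axis=2).astype(float) > thresholds.background_floor
    n_classified = int(np.count_nonzero(tissue))
    if n_classified == 0:
        raise ValueError("no tissue pixels: the whole image is background")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(g > 0, r / np.where(g > 0, g, 1.0), np.inf)
    red = tissue & (ratio >= thresholds.t_red)
    green = tissue & (ratio <= thresholds.t_green)
    yellow = tissue & ~red & ~green
    n = float(n_classified)
    return MaturityResult(
        pct_red=np.count_nonzero(red) / n * 100.0,
        pct_yellow=np.count_nonzero(yellow) / n * 100.0,
        pct_green=np.count_nonzero(green) / n * 100.0,
        n_classified=n_classified,
        n_background=int(img.shape[0] * img.shape[1] - n_classified),
    )


def calibrate_maturity_report(samples: Sequence[RegionSample],
                              min_regions: int = 20) -> dict[str, dict[str, float]]:
    """Summarize region-mean I_R/I_G ratios of reviewer-labeled regions.

    This reports per-color min/median/max of the region means so an analyst
    can choose classification cutoffs; it deliberately does not set the
    thresholds itself.  At least ``min_regions`` regions spanning both colors
    are required, mirroring the >= 20-region inspection protocol.
    """
    if len(samples) < min_regions:
        raise ValueError(
            f"calibration needs at least {min_regions} labeled regions; "
            f"got {len(samples)}")
    colors = {s.color for s in samples}
    if not {"red", "green"} <= colors:
        raise ValueError("calibration regions must span both red and green")
    report: dict[str, dict[str, float]] = {}
    for color in ("red", "green"):
        ratios = np.array([s.mean_ratio() for s in samples if s.color == color])
        report[color] = {
            "n": int(ratios.size),
            "min": float(np.min(ratios)),
            "median": float(np.median(ratios)),
            "max": float(np.max(ratios)),
        }
    return report


def count_nuclei(image: np.ndarray, threshold: float = 127,
                 min_area_px: int = 5) -> int:
    """Count bright particles: global threshold -> 8-connected components
    with area >= ``min_area_px``.  Touching nuclei merge (no declumping)."""
    img = np.asarray(image, dtype=float)
    binary = img > threshold
    if not binary.any():
        return 0
    labels, n = _cc_label(binary, connectivity=2, return_num=True)
    if min_area_px <= 1:
        return int(n)
    areas = np.bincount(labels.ravel())[1:]
    return int(np.count_nonzero(areas >= min_area_px))


def viability(total_channel: np.ndarray, apoptotic_channel: np.ndarray,
              threshold: float = 127, min_area_px: int = 5) -> ViabilityResult:
    """Percent viable cells from nuclear-stain and TUNEL channels.

    One shared threshold is applied to both channels (and should be shared
    across a batch); viability = (N_total - N_apoptotic) / N_total * 100.
    """
    if np.asarray(total_channel).shape != np.asarray(apoptotic_channel).shape:
        raise ValueError("channels must have the same shape")
    n_total = count_nuclei(total_channel, threshold, min_area_px)
    n_apo = count_nuclei(apoptotic_channel, threshold, min_area_px)
    if n_total == 0:
        raise ValueError("no cells detected in the total channel")
    n_apo = min(n_apo, n_total)
    return ViabilityResult(n_total, n_apo,
                           (n_total - n_apo) / n_total * 100.0)


def cell_density(n_cells: int, tile_side_um: float = 120.0) -> CellDensityResult:
    """Cells per mm^2 from a manual count over a square tile (default 120 um)."""
    if tile_side_um <= 0:
        raise ValueError("tile side must be > 0")
    area_um2 = tile_side_um ** 2
    density = n_cells / (area_um2 * 1e-6)        # um^2 -> mm^2
    return CellDensityResult(int(n_cells), area_um2, float(density))
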
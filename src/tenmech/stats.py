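"""Crosslink densities and the study's statistics: group comparisons,
exponential-plateau dose-response fits, and modulus-crosslink regression.

Crosslink density normalizes pyridinoline content (HP = hydroxylysyl
pyridinoline, LP = lysyl pyridinoline, in pmol) by tissue dry mass (mg).  The
dose-response ceiling is modelled by the exponential-plateau law
``Y = YM - (YM - Y0) * exp(-k * x)`` where Y0 is the response at zero dose,
YM the plateau and k the rate per dose unit.  Group comparisons use the
two-sided Student t-test (pooled variance; paired mode for contralateral-limb
designs) or one-way ANOVA with Tukey's HSD post-hoc over all pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .synthetic import DoseResponseDataset

__all__ = [
    "CrosslinkSample", "PlateauFit", "RegressionResult", "GroupComparison",
    "crosslink_density", "fit_exponential_plateau",
    "regress_modulus_on_crosslinks", "compare_groups",
]


@dataclass
class CrosslinkSample:
    """HPLC pyridinoline content for one specimen, with derived densities."""
    sample_id: str
    hp_content_pmol: float
    lp_content_pmol: float
    dry_mass_mg: float
    hp_density: float = field(init=False)
    lp_density: float = field(init=False)
    total_density: float = field(init=False)

    def __post_init__(self) -> None:
        if self.dry_mass_mg <= 0:
            raise ValueError("dry mass must be > 0")
        if self.hp_content_pmol < 0 or self.lp_content_pmol < 0:
            raise ValueError("contents must be >= 0")
        self.hp_density, self.lp_density, self.total_density = \
            crosslink_density(self.hp_content_pmol, self.lp_content_pmol,
                              self.dry_mass_mg)


def crosslink_density(hp_content_pmol: float, lp_content_pmol: float,
                      dry_mass_mg: float) -> tuple[float, float, float]:
    """(HP, LP, HP+LP) densities in pmol/mg: content over dry mass."""
    if dry_mass_mg <= 0:
        raise ValueError("dry mass must be > 0")
    hp = hp_content_pmol / dry_mass_mg
    lp = lp_content_pmol / dry_mass_mg
    return hp, lp, hp + lp


@dataclass
class PlateauFit:
    y0: float
    ym: float
    k: float
    r_squared: float
    converged: bool
    k_identifiable: bool = True


def _plateau(x: np.ndarray, y0: float, ym: float, k: float) -> np.ndarray:
    return ym - (ym - y0) * np.exp(-k * x)


def fit_exponential_plateau(data: DoseResponseDataset | tuple[np.ndarray, np.ndarray],
                            k_grid: np.ndarray | None = None) -> PlateauFit:
    """Nonlinear least-squares fit of the exponential-plateau law.

    The rate constant is awkward to initialize, so the fit is multi-started
    from a log-spaced grid of k values over [0.01, 10] per dose unit and the
    lowest-SSE solution is kept — deterministic with no user tuning.  r^2 is
    reported against the mean-only model.  Constant responses return
    ``y0 = ym = const`` with the rate flagged unidentifiable.
    """
    if isinstance(data, DoseResponseDataset):
        x, y = data.x, data.y
    else:
        x, y = data
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("plateau fit needs >= 3 distinct dose levels")
    if x.size < 4:
        raise ValueError("plateau fit needs >= 4 observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return PlateauFit(float(y[0]), float(y[0]), float("nan"), float("nan"),
                          True, k_identifiable=False)
    if k_grid is None:
        k_grid = np.logspace(-2, 1, 10)
    y0_init = float(np.mean(y[x == x.min()]))
    ym_init = float(np.mean(y[x == x.max()]))
    best: tuple[float, np.ndarray] | None = None
    for k0 in k_grid:
        try:
            popt, _ = optimize.curve_fit(
                _plateau, x, y, p0=[y0_init, ym_init, float(k0)],
                bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
                maxfev=20000)
        except RuntimeError:
            continue
        sse = float(np.sum((y - _plateau(x, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        return PlateauFit(float("nan"), float("nan"), float("nan"),
                          float("nan"), False)
    sse, (y0, ym, k) = best
    return PlateauFit(float(y0), float(ym), float(k), 1.0 - sse / ss_tot, True)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    pearson_r: float
    p_value: float
    n: int


def regress_modulus_on_crosslinks(x: Sequence[float], y: Sequence[float]
                                  ) -> RegressionResult:
    """OLS of modulus on crosslink density plus Pearson correlation.

    The two-sided p-value comes from the exact t distribution with n-2
    degrees of freedom; ``r_squared`` is exactly ``pearson_r ** 2``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("regression needs n >= 3 paired observations")
    if np.var(x) == 0:
        raise ValueError("zero variance in x")
    res = sps.linregress(x, y)
    return RegressionResult(float(res.slope), float(res.intercept),
                            float(res.rvalue) ** 2, float(res.rvalue),
                            float(res.pvalue), int(x.size))


@dataclass
class GroupComparison:
    test: Literal["t", "anova"]
    statistic: float
    p_value: float
    post_hoc: pd.DataFrame | None = None    # Tukey pairwise table for ANOVA


def compare_groups(groups: dict[str, Sequence[float]],
                   design: Literal["two_group", "multi_group"] | None = None,
                   paired: bool = False) -> GroupComparison:
    """Student t-test (two groups) or one-way ANOVA + Tukey HSD (more groups).

    The t-test is two-sided with pooled variance; ``paired=True`` switches to
    a paired t-test for contralateral-limb designs.  For the multi-group
    design, Tukey's HSD p-values come from the studentized-range
    distribution, one row per group pair.
    """
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 values")
    if design is None:
        design = "two_group" if len(arrays) == 2 else "multi_group"
    if design == "two_group":
        if len(arrays) != 2:
            raise ValueError("two_group design requires exactly 2 groups")
        if paired:
            if arrays[0].size != arrays[1].size:
                raise ValueError("paired design requires equal group sizes")
            t, p = sps.ttest_rel(arrays[0], arrays[1])
        else:
            t, p = sps.ttest_ind(arrays[0], arrays[1], equal_var=True)
        return GroupComparison("t", float(t), float(p))
    if len(arrays) < 3:
        raise ValueError("multi_group design requires >= 3 groups")
    f, p = sps.f_oneway(*arrays)
    hsd = sps.tukey_hsd(*arrays)
    ci = hsd.confidence_interval()
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            rows.append({
                "group1": names[i], "group2": names[j],
                "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                "p_adj": float(hsd.pvalue[i, j]),
                "ci_low": float(ci.low[i, j]),
                "ci_high": float(ci.high[i, j]),
            })
    return GroupComparison("anova", float(f), float(p), pd.DataFrame(rows))
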
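"""End-to-end orchestration: simulate -> analyze -> statistics -> tidy outputs.

A run is driven by a single YAML/dict config (validated with itemized errors)
and a root seed.  Each stage draws its randomness from a named substream of
the root seed, so stages are independent yet the whole run is reproducible:
the same config + seed reproduces every output file byte-identically.

Outputs per run: ``results.csv`` (tidy long table: sample_id, stage,
treatment, assay, metric, value, units), per-assay JSON reports, generated
images as TIFF with ground-truth JSON sidecars, and ``manifest.json``
recording the effective configuration and stage status.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import afm, histology, shg, stats, synthetic, tensile
from ._version import __version__

__all__ = ["DEFAULT_CONFIG", "load_config", "validate_config", "run_pipeline"]


DEFAULT_CONFIG: dict[str, Any] = {
    "experiment": "demo",
    "output_dir": "tenmech_out",
    "seed": 0,
    "stages": ["afm", "tensile", "histology", "shg", "dose_response"],
    "stage_labels": ["HH40", "HH43"],
    "treatments": ["Ctrl", "1X", "2X", "5X"],
    "afm": {
        "grid": [16, 16],
        "base_modulus_kpa": 20.0,
        # multiplicative modulus effect per treatment (saturating with dose)
        "treatment_effect": {"Ctrl": 1.0, "1X": 1.8, "2X": 2.6, "5X": 2.8},
        "noise_sd_nm": 0.5,
        "bin_width_kpa": 5.0,
        "model": "pyramid",
        "geometry_coefficient": 0.7453,
        "input_csv": None,           # analyze real data instead of simulating
        "probe_json": None,
    },
    "tensile": {
        "modulus_mpa": 40.0,
        "gauge_length_mm": 2.0,
        "csa_mm2": 0.08,
        "toe_fraction": 0.05,
        "failure_strain": 0.25,
        "noise_sd_mpa": 0.1,
        "window_fraction": 0.2,
        "r2_floor": 0.95,
    },
    "histology": {
        "image_size": [128, 128],
        "psr_fractions": [0.3, 0.3, 0.3],    # red, yellow, green
        "t_green": 1.1,
        "t_red": 1.8,
        "background_floor": 10,
        "nuclei_image_size": [256, 256],
        "n_nuclei": 120,
        "apoptotic_fraction": 0.1,
        "nuclei_threshold": 127,
        "min_area_px": 5,
        "tile_side_um": 120.0,
    },
    "shg": {
        "image_size": [256, 256],
        "mean_angle_deg": 30.0,
        "angular_sd_deg": 15.0,
        "fiber_count": 200,
        "n_bins": 60,
    },
    "dose_response": {
        "levels": [0.0, 1.0, 2.0, 5.0],
        "reps": 5,
        "y0": 10.0,
        "ym": 50.0,
        "k": 1.0,
        "noise_sd": 1.0,
    },
}

_STAGES = ("afm", "tensile", "histology", "shg", "dose_response")


def load_config(path: str | Path) -> dict[str, Any]:
    """Read a YAML config file into a plain dict (empty file -> {})."""
    text = Path(path).read_text()
    return yaml.safe_load(text) or {}


def _merge(defaults: dict[str, Any], user: dict[str, Any],
           errors: list[str], prefix: str = "") -> dict[str, Any]:
    out = copy.deepcopy(defaults)
    for key, val in user.items():
        if key not in defaults:
            errors.append(f"unknown key: {prefix}{key}")
            continue
        if isinstance(defaults[key], dict) and isinstance(val, dict) \
                and key != "treatment_effect":
            out[key] = _merge(defaults[key], val, errors, f"{prefix}{key}.")
        else:
            out[key] = copy.deepcopy(val)
    return out


def validate_config(config: dict[str, Any] | None,
                    ) -> tuple[dict[str, Any], list[str]]:
    """Fill defaults and range-check a run config.

    Returns ``(effective_config, errors)``; an empty config is valid and
    echoes all defaults.  Unknown keys, out-of-range thresholds and missing
    input files are reported as an itemized error list.
    """
    errors: list[str] = []
    cfg = _merge(DEFAULT_CONFIG, config or {}, errors)
    for st in cfg["stages"]:
        if st not in _STAGES:
            errors.append(f"unknown stage: {st}")
    if not isinstance(cfg["seed"], int):
        errors.append("seed must be an integer")
    a = cfg["afm"]
    if a["base_modulus_kpa"] <= 0:
        errors.append("afm.base_modulus_kpa must be > 0")
    if a["noise_sd_nm"] < 0:
        errors.append("afm.noise_sd_nm must be >= 0")
    for key in ("input_csv", "probe_json"):
        if a[key] is not None and not Path(a[key]).exists():
            errors.append(f"afm.{key}: file not found: {a[key]}")
    t = cfg["tensile"]
    if t["modulus_mpa"] <= 0 or t["gauge_length_mm"] <= 0 or t["csa_mm2"] <= 0:
        errors.append("tensile geometry and modulus must be > 0")
    if not 0 <= t["toe_fraction"] < t["failure_strain"]:
        errors.append("tensile.toe_fraction must be in [0, failure_strain)")
    h = cfg["histology"]
    if not 0 < h["t_green"] < h["t_red"]:
        errors.append("histology thresholds must satisfy 0 < t_green < t_red")
    if sum(h["psr_fractions"]) > 1.0 + 1e-12 or min(h["psr_fractions"]) < 0:
        errors.append("histology.psr_fractions must be >= 0 and sum to <= 1")
    if not 0 <= h["apoptotic_fraction"] <= 1:
        errors.append("histology.apoptotic_fraction must be in [0, 1]")
    s = cfg["shg"]
    if s["angular_sd_deg"] < 0:
        errors.append("shg.angular_sd_deg must be >= 0")
    if s["fiber_count"] < 1:
        errors.append("shg.fiber_count must be >= 1")
    d = cfg["dose_response"]
    if d["k"] <= 0:
        errors.append("dose_response.k must be > 0")
    if d["ym"] < d["y0"]:
        errors.append("dose_response.ym must be >= y0")
    if d["noise_sd"] < 0:
        errors.append("dose_response.noise_sd must be >= 0")
    return cfg, errors


def _stage_seed(root_seed: int, stage: str, index: int = 0) -> np.random.SeedSequence:
    key = sum(ord(ch) for ch in stage)       # stable, order-independent name hash
    return np.random.SeedSequence(entropy=root_seed, spawn_key=(key, index))


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def _write_json(path: Path, obj: Any) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=2,
                               default=_jsonable) + "\n")


def _jsonable(o: Any) -> Any:
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: dict[str, Any] | None = None,
                 seed: int | None = None,
                 output_dir: str | Path | None = None) -> pd.DataFrame:
    """Execute the configured stages and write tidy outputs.

    Independent stages continue past a failed one; failures are recorded in
    the manifest.  Returns the tidy results table (also written as
    ``results.csv`` in the output directory).
    """
    cfg, errors = validate_config(config)
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    if seed is not None:
        cfg["seed"] = int(seed)
    if output_dir is not None:
        cfg["output_dir"] = str(output_dir)
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    rows: list[dict[str, Any]] = []
    status: dict[str, str] = {}
    reports: dict[str, Any] = {}

    for stage in cfg["stages"]:
        try:
            runner = globals()[f"_run_{stage}"]
            runner(cfg, rows, reports, out)
            status[stage] = "ok"
        except Exception as exc:       # independent stages continue
            status[stage] = f"failed: {exc}"

    table = pd.DataFrame(rows, columns=["sample_id", "stage", "treatment",
                                        "assay", "metric", "value", "units"])
    table.to_csv(out / "results.csv", index=False, float_format="%.10g")
    for name, rep in reports.items():
        _write_json(out / f"{name}_report.json", rep)
    manifest = {
        "tenmech_version": __version__,
        "seed": cfg["seed"],
        "effective_config": cfg,
        "stage_status": status,
    }
    _write_json(out / "manifest.json", manifest)
    return table


# ---------------------------------------------------------------------------
# stage runners


def _add(rows: list, sample_id: str, stage: str, treatment: str, assay: str,
         metric: str, value: float, units: str) -> None:
    rows.append({"sample_id": sample_id, "stage": stage,
                 "treatment": treatment, "assay": assay, "metric": metric,
                 "value": float(value), "units": units})


def _run_afm(cfg: dict, rows: list, reports: dict, out: Path) -> None:
    a = cfg["afm"]
    stage_label = cfg["stage_labels"][-1]
    medians: dict[str, float] = {}
    if a["input_csv"] is not None:
        probe = a["probe_json"] or afm.ProbeSpec()
        fmap = afm.read_force_map_csv(a["input_csv"], probe)
        mm = afm.analyze_force_map(fmap, a["model"], a["geometry_coefficient"],
                                   a["bin_width_kpa"])
        medians["input"] = mm.median_kpa
        _add(rows, "input", stage_label, "NA", "afm", "median_modulus",
             mm.median_kpa, "kPa")
    else:
        for i, treat in enumerate(cfg["treatments"]):
            eff = a["treatment_effect"].get(treat, 1.0)
            ss = _stage_seed(cfg["seed"], "afm", i)
            rng = np.random.default_rng(ss)
            grid = np.asarray(a["grid"], dtype=int)
            field = a["base_modulus_kpa"] * eff * rng.lognormal(
                0.0, 0.25, size=(grid[0], grid[1]))
            fmap, truth = synthetic.gen_force_map(
                field, noise_sd_nm=a["noise_sd_nm"], seed=_seed_int(ss))
            mm = afm.analyze_force_map(fmap, a["model"],
                                       a["geometry_coefficient"],
                                       a["bin_width_kpa"])
            medians[treat] = mm.median_kpa
            _add(rows, f"afm_{treat}", stage_label, treat, "afm",
                 "median_modulus", mm.median_kpa, "kPa")
            _add(rows, f"afm_{treat}", stage_label, treat, "afm",
                 "n_valid_pixels", mm.n_valid, "count")
    reports["afm"] = {"median_modulus_kpa": medians}


def _run_tensile(cfg: dict, rows: list, reports: dict, out: Path) -> None:
    t = cfg["tensile"]
    rep: dict[str, Any] = {}
    for si, stage_label in enumerate(cfg["stage_labels"]):
        for ti, treat in enumerate(("Ctrl", cfg["treatments"][1]
                                    if len(cfg["treatments"]) > 1 else "rLOX")):
            # saturating treatment effect on the linear-region modulus
            eff = 1.0 if treat == "Ctrl" else 1.5
            ss = _stage_seed(cfg["seed"], "tensile", si * 10 + ti)
            trace, truth = synthetic.gen_tensile_trace(
                t["modulus_mpa"] * eff, t["gauge_length_mm"], t["csa_mm2"],
                toe_fraction=t["toe_fraction"],
                failure_strain=t["failure_strain"],
                noise_sd_mpa=t["noise_sd_mpa"], seed=_seed_int(ss))
            curve = tensile.to_stress_strain(trace)
            res = tensile.tensile_metrics(curve, t["window_fraction"],
                                          t["r2_floor"])
            sid = f"tensile_{stage_label}_{treat}"
            _add(rows, sid, stage_label, treat, "tensile", "elastic_modulus",
                 res.elastic_modulus_mpa, "MPa")
            _add(rows, sid, stage_label, treat, "tensile", "peak_stress",
                 res.peak_stress_mpa, "MPa")
            _add(rows, sid, stage_label, treat, "tensile", "peak_strain",
                 res.peak_strain, "")
            rep[sid] = {"modulus_mpa": res.elastic_modulus_mpa,
                        "true_modulus_mpa": truth.modulus_mpa,
                        "linear_r2": res.linear_r_squared}
    reports["tensile"] = rep


def _run_histology(cfg: dict, rows: list, reports: dict, out: Path) -> None:
    h = cfg["histology"]
    stage_label = cfg["stage_labels"][-1]
    hh, ww = h["image_size"]
    ss = _stage_seed(cfg["seed"], "histology", 0)
    fr, fy, fg = h["psr_fractions"]
    img, psr_truth = synthetic.gen_psr_image(fr, fy, fg, width=ww, height=hh,
                                             seed=_seed_int(ss))
    tifffile.imwrite(out / "psr_demo.tif", img)
    _write_json(out / "psr_demo_truth.json", {
        "fraction_red": fr, "fraction_yellow": fy, "fraction_green": fg})
    thr = histology.MaturityThresholds(h["t_green"], h["t_red"],
                                       h["background_floor"])
    mat = histology.classify_maturity(img, thr)
    content = histology.psr_content(img, "fixed",
                                    fixed_threshold=h["background_floor"])
    sid = "psr_demo"
    _add(rows, sid, stage_label, "Ctrl", "psr", "content_area_fraction",
         content, "%")
    _add(rows, sid, stage_label, "Ctrl", "psr", "pct_red", mat.pct_red, "%")
    _add(rows, sid, stage_label, "Ctrl", "psr", "pct_yellow", mat.pct_yellow, "%")
    _add(rows, sid, stage_label, "Ctrl", "psr", "pct_green", mat.pct_green, "%")

    ss2 = _stage_seed(cfg["seed"], "histology", 1)
    nh, nw = h["nuclei_image_size"]
    chan_total, chan_apo, nuc_truth = synthetic.gen_nuclei_image(
        h["n_nuclei"], h["apoptotic_fraction"], width=nw, height=nh,
        seed=_seed_int(ss2))
    tifffile.imwrite(out / "tunel_total_demo.tif", chan_total)
    tifffile.imwrite(out / "tunel_apoptotic_demo.tif", chan_apo)
    via = histology.viability(chan_total, chan_apo, h["nuclei_threshold"],
                              h["min_area_px"])
    _add(rows, "tunel_demo", stage_label, "Ctrl", "tunel", "pct_viable",
         via.pct_viable, "%")
    _add(rows, "tunel_demo", stage_label, "Ctrl", "tunel", "n_total",
         via.n_total, "count")
    dens = histology.cell_density(via.n_total, h["tile_side_um"])
    _add(rows, "he_demo", stage_label, "Ctrl", "he", "cell_density",
         dens.density_cells_mm2, "cells/mm^2")
    reports["histology"] = {
        "maturity": {"pct_red": mat.pct_red, "pct_yellow": mat.pct_yellow,
                     "pct_green": mat.pct_green},
        "viability_pct": via.pct_viable,
        "true_viability_pct": 100.0 * (1 - nuc_truth.n_apoptotic
                                       / nuc_truth.n_total),
    }


def _run_shg(cfg: dict, rows: list, reports: dict, out: Path) -> None:
    s = cfg["shg"]
    stage_label = cfg["stage_labels"][-1]
    hh, ww = s["image_size"]
    ss = _stage_seed(cfg["seed"], "shg", 0)
    img, truth = synthetic.gen_shg_image(s["mean_angle_deg"],
                                         s["angular_sd_deg"],
                                         fiber_count=s["fiber_count"],
                                         width=ww, height=hh,
                                         seed=_seed_int(ss))
    tifffile.imwrite(out / "shg_demo.tif", img)
    mask = shg.segment_shg(img)
    hist = shg.directionality(img, s["n_bins"])
    sid = "shg_demo"
    _add(rows, sid, stage_label, "Ctrl", "shg", "content",
         shg.shg_content(img), "a.u.")
    _add(rows, sid, stage_label, "Ctrl", "shg", "density",
         shg.shg_density(img, mask), "fraction")
    _add(rows, sid, stage_label, "Ctrl", "shg", "peak_angle",
         hist.peak_angle_deg, "deg")
    _add(rows, sid, stage_label, "Ctrl", "shg", "dispersion",
         hist.dispersion_deg, "deg")
    reports["shg"] = {
        "peak_angle_deg": hist.peak_angle_deg,
        "dispersion_deg": hist.dispersion_deg,
        "true_mean_angle_deg": truth.mean_angle_deg,
        "true_angular_sd_deg": truth.angular_sd_deg,
        "goodness": hist.goodness,
    }


def _run_dose_response(cfg: dict, rows: list, reports: dict, out: Path) -> None:
    d = cfg["dose_response"]
    stage_label = cfg["stage_labels"][-1]
    ss = _stage_seed(cfg["seed"], "dose_response", 0)
    data, truth = synthetic.gen_dose_response(
        d["y0"], d["ym"], d["k"], levels=tuple(d["levels"]), reps=d["reps"],
        noise_sd=d["noise_sd"], seed=_seed_int(ss))
    fit = stats.fit_exponential_plateau(data)
    levels = np.asarray(d["levels"], dtype=float)
    level_means = np.array([data.y[data.x == lv].mean() for lv in levels])
    # per-level means of a correlated second response stand in for crosslink
    # densities in the demo regression
    ss2 = _stage_seed(cfg["seed"], "dose_response", 1)
    data2, _ = synthetic.gen_dose_response(
        d["y0"] / 5, d["ym"] / 5, d["k"], levels=tuple(d["levels"]),
        reps=d["reps"], noise_sd=d["noise_sd"] / 5, seed=_seed_int(ss2))
    xl_means = np.array([data2.y[data2.x == lv].mean() for lv in levels])
    reg = stats.regress_modulus_on_crosslinks(xl_means, level_means)
    groups = {g: data.y[data.x == lv]
              for g, lv in zip(("Ctrl", "1X", "2X", "5X"), levels)}
    comp = stats.compare_groups(groups, "multi_group")
    sid = "dose_demo"
    _add(rows, sid, stage_label, "all", "dose_response", "plateau_ym",
         fit.ym, "kPa")
    _add(rows, sid, stage_label, "all", "dose_response", "plateau_y0",
         fit.y0, "kPa")
    _add(rows, sid, stage_label, "all", "dose_response", "plateau_k",
         fit.k, "1/x")
    _add(rows, sid, stage_label, "all", "dose_response", "plateau_r2",
         fit.r_squared, "")
    _add(rows, sid, stage_label, "all", "dose_response", "regression_r2",
         reg.r_squared, "")
    _add(rows, sid, stage_label, "all", "dose_response", "anova_p",
         comp.p_value, "")
    reports["dose_response"] = {
        "plateau": {"y0": fit.y0, "ym": fit.ym, "k": fit.k,
                    "r_squared": fit.r_squared},
        "truth": {"y0": truth.y0, "ym": truth.ym, "k": truth.k},
        "regression": {"slope": reg.slope, "r_squared": reg.r_squared,
                       "p_value": reg.p_value},
        "anova": {"F": comp.statistic, "p": comp.p_value},
    }
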
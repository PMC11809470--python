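"""End-to-end pipeline: simulate (or load) scenes, run the plate and chamber
analyses, and emit tables plus a JSON report with full provenance.

Stages, in the order the method runs:

1. plate      — render an asynchronous population, segment, measure per-cell
                RI and dry-mass density.
2. calibrate  — hydraulically pressurised medium-filled chambers → linear
                chamber-height calibration d_chamber(P).
3. chamber    — pressurised packed-chamber series → per-pressure signed OPD,
                RI and density (GIP = 0 points flagged as underestimated).
4. fit        — OLS of RI vs GIP with the plate anchor; extrapolate to the
                water RI for the nominal intracellular osmotic pressure Π_c0.
5. gfp        — fluorescence z-stacks per chamber → corrected totals and the
                density–fluorescence proportionality test.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, baseline_ri, config_hash
from .densitometry import (
    ChamberObservation,
    density_from_ri,
    fit_height_calibration,
    ri_chamber,
    ri_plate,
)
from .fluorescence import (
    correct_fluorescence,
    estimate_autofluorescence,
    estimate_background,
    sum_zstack,
)
from .inference import fit_ri_vs_gip, nominal_pressure, proportionality_check
from .io import write_table
from .morphometry import measure_plate_image
from .synthetic import (
    SyntheticCell,
    SyntheticChamberTruth,
    generate_gfp_stack,
    generate_pressure_series,
    render_chamber_scene,
    render_plate_scene,
    sample_plate_population,
)

__all__ = ["PipelineError", "run_pipeline", "analyze_plate_scene", "analyze_chamber_series"]

logger = logging.getLogger("qpidense")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def analyze_plate_scene(image, pixel_size_um, constants, baseline, min_area_px=30) -> pd.DataFrame:
    """Plate analysis: per-cell table with RI and dry-mass density appended."""
    cells = measure_plate_image(image, pixel_size_um, min_area_px=min_area_px)
    cells["ri"] = [
        ri_plate(o, d, constants.n_media)
        for o, d in zip(cells["opd_stat_nm"], cells["height_um"])
    ]
    cells["density_mg_ml"] = [
        density_from_ri(r, baseline, constants.alpha) for r in cells["ri"]
    ]
    return cells


def analyze_chamber_series(scenes, calib, constants, baseline) -> list[ChamberObservation]:
    """Measure each chamber scene's mean signed OPD and convert to RI/density."""
    observations = []
    for scene in scenes:
        mean_opd = float(scene.image[scene.interior_mask].mean())
        gip = scene.truth["gip_mpa"]
        ri = ri_chamber(mean_opd, gip, calib, constants)
        observations.append(
            ChamberObservation(
                gip_mpa=gip,
                mean_opd_vs_pdms_nm=mean_opd,
                chamber_height_um=calib.predict(gip, warn_extrapolation=False),
                ri=ri,
                density_mg_ml=density_from_ri(ri, baseline, constants.alpha),
                underestimated=bool(scene.truth["underestimated"]),
            )
        )
    return observations


def _plate_stage(cfg: RunConfig, seed: int):
    side_um = max(32.0, math.ceil(math.sqrt(cfg.n_cells * 180.0)))
    npx = int(round(side_um / cfg.pixel_size_um))
    cells = sample_plate_population(
        cfg.n_cells, cfg.ri_mean, cfg.ri_sd, cfg.height_mean_um, cfg.height_sd_um,
        field_um=(side_um, side_um), seed=seed, constants=cfg.constants,
    )
    scene = render_plate_scene(
        cells, cfg.constants, cfg.pixel_size_um, (npx, npx),
        noise_sd=cfg.noise_sd_nm, seed=seed + 1 if cfg.noise_sd_nm > 0 else None,
    )
    table = analyze_plate_scene(
        scene.image, cfg.pixel_size_um, cfg.constants, baseline_ri(cfg),
        min_area_px=cfg.min_region_area_px,
    )
    return scene, table


def _chamber_truth(cfg: RunConfig, seed: int | None) -> SyntheticChamberTruth:
    return SyntheticChamberTruth.from_anchor(
        pi_c0_true=cfg.pi_c0_true_mpa,
        ri_at_zero=cfg.ri_mean,
        n_water=cfg.constants.n_water,
        chamber_height0=cfg.chamber_height0_um,
        height_slope=cfg.chamber_height_slope_um_per_mpa,
        noise_sd=cfg.noise_sd_nm,
        seed=seed,
    )


def _calibration_stage(cfg: RunConfig, truth: SyntheticChamberTruth, seed: int):
    pressures = np.linspace(0.0, cfg.gip_max_mpa, 6)
    rows = []
    for i, p in enumerate(pressures):
        scene = render_chamber_scene(
            replace(truth, seed=seed + i),
            float(p), cfg.constants, cfg.pixel_size_um, packing_fraction=0.0,
        )
        rows.append({"pressure_mpa": p,
                     "opd_nm": float(scene.image[scene.interior_mask].mean())})
    table = pd.DataFrame(rows)
    return table, fit_height_calibration(table, cfg.constants)


def gip_schedule(cfg: RunConfig) -> np.ndarray:
    """The pressure levels of the chamber series: a few unpressurised chambers
    plus an even spread up to the maximum GIP."""
    n_pos = cfg.n_chamber_obs - cfg.n_gip_zero_obs
    positive = np.linspace(cfg.gip_max_mpa / n_pos, cfg.gip_max_mpa, n_pos)
    return np.concatenate([np.zeros(cfg.n_gip_zero_obs), positive])


def _gfp_stage(cfg: RunConfig, observations, truth, seed: int):
    """Simulate per-chamber GFP stacks with brightness tracking the true
    density, then quantify them blind through the fluorescence pipeline."""
    gips = np.linspace(cfg.gip_max_mpa / 6, cfg.gip_max_mpa, 6)
    base_cells = [
        SyntheticCell(center_xy=(4.0 + 4.5 * k, 4.0 + 2.1 * k), semi_axes=(2.2, 1.8), ri=1.384)
        for k in range(3)
    ]
    fi_per_density = 10.0  # a.u. per (mg/ml), arbitrary instrument scale
    background, autofluor = 50.0, 20.0
    baseline = baseline_ri(cfg)
    rows = []
    for i, gip in enumerate(gips):
        rho_true = density_from_ri(truth.ri_at(gip), baseline, cfg.constants.alpha)
        brightness = [fi_per_density * rho_true] * len(base_cells)
        labeled, blank = generate_gfp_stack(
            base_cells, brightness, autofluor, background,
            z_step_um=0.5, noise_sd=0.5, seed=seed + i,
            pixel_size_um=0.25, image_shape=(96, 96),
        )
        cell_free = np.zeros(labeled.shape[1:], dtype=bool)
        cell_free[:, 64:] = True  # cells occupy the left of the field
        bg_est = estimate_background(labeled, cell_free)
        af_est = estimate_autofluorescence(blank, bg_est)
        raw = sum_zstack(labeled)
        meas = correct_fluorescence(
            raw, af_est, bg_est, n_pixels=labeled.shape[1] * labeled.shape[2],
            n_z=labeled.shape[0],
        )
        rows.append({"gip_mpa": gip, "fi_corrected_au": meas.total_intensity,
                     "density_true_mg_ml": rho_true})
    gfp = pd.DataFrame(rows)
    # pair fluorescence with the measured chamber densities at the nearest GIP
    obs_g = np.array([o.gip_mpa for o in observations if not o.underestimated])
    obs_d = np.array([o.density_mg_ml for o in observations if not o.underestimated])
    matched = [obs_d[np.argmin(np.abs(obs_g - g))] for g in gfp["gip_mpa"]]
    prop = proportionality_check(np.asarray(matched), gfp["fi_corrected_au"].to_numpy())
    return gfp, prop


def run_pipeline(cfg: RunConfig, output_dir: str | Path | None = None) -> dict:
    """Run the full simulate→analyze pipeline and return the report dict.

    When ``output_dir`` (or ``cfg.output_dir``) is set, writes cells.csv,
    chamber.csv, gfp.csv and report.json there. The report carries full
    provenance: package version, seed and config hash; identical inputs give
    a byte-identical report.
    """
    out = Path(output_dir or cfg.output_dir) if (output_dir or cfg.output_dir) else None
    seeds = _stage_seeds(cfg.seed, 5)
    report: dict = {
        "provenance": {
            "package": "qpidense",
            "version": __version__,
            "seed": cfg.seed,
            "config_hash": config_hash(cfg),
        }
    }

    def stage(name, fn, *args):
        logger.info("stage %s", name)
        try:
            return fn(*args)
        except Exception as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc

    _, cell_table = stage("plate", _plate_stage, cfg, seeds[0])
    baseline = baseline_ri(cfg)
    plate_ri = float(cell_table["ri"].mean())
    report["plate"] = {
        "n_cells": int(len(cell_table)),
        "mean_ri": plate_ri,
        "sd_ri": float(cell_table["ri"].std(ddof=1)),
        "mean_density_mg_ml": float(cell_table["density_mg_ml"].mean()),
        "mean_opd_stat_nm": float(cell_table["opd_stat_nm"].mean()),
        "mean_height_um": float(cell_table["height_um"].mean()),
        "density_baseline": cfg.density_baseline,
    }

    truth = _chamber_truth(cfg, seeds[1])
    cal_table, calib = stage("calibrate", _calibration_stage, cfg, truth, seeds[2])
    report["height_calibration"] = {
        "height0_um": calib.height0_um,
        "slope_um_per_mpa": calib.slope_um_per_mpa,
        "n_points": calib.n_points,
    }

    def chamber_stage():
        scenes, _ = generate_pressure_series(
            truth, gip_schedule(cfg), cfg.constants, cfg.pixel_size_um,
            packing_fraction_gip0=cfg.packing_fraction_gip0,
        )
        return analyze_chamber_series(scenes, calib, cfg.constants, baseline)

    observations = stage("chamber", chamber_stage)

    def fit_stage():
        fit = fit_ri_vs_gip(
            observations, anchor_point=(0.0, plate_ri),
            exclude_flagged=cfg.exclude_gip_zero,
        )
        est = nominal_pressure(
            fit, cfg.constants, method=cfg.ci_method, n_boot=cfg.n_boot, seed=seeds[3],
        )
        return fit, est

    fit, est = stage("fit", fit_stage)
    report["fit"] = {
        "intercept_ri": fit.intercept,
        "slope_ri_per_mpa": fit.slope,
        "cov": np.asarray(fit.cov).tolist(),
        "n_points": fit.n_points,
    }
    report["nominal_pressure"] = {
        "pi_c0_mpa": est.pi_c0_mpa,
        "ci95_mpa": list(est.ci95_mpa),
        "method": est.method,
        "seed": est.seed,
        "p_nwater_mpa": est.p_nwater_mpa,
    }

    gfp_table, prop = stage("gfp", _gfp_stage, cfg, observations, truth, seeds[4])
    report["gfp"] = {
        "slope_au_per_mg_ml": prop.slope,
        "intercept_au": prop.intercept,
        "intercept_ci95_au": list(prop.intercept_ci95),
        "proportional": prop.proportional,
        "n_points": prop.n_points,
    }

    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        write_table(cell_table, out / "cells.csv")
        obs_table = pd.DataFrame(
            [{"gip_mpa": o.gip_mpa, "mean_opd_vs_pdms_nm": o.mean_opd_vs_pdms_nm,
              "chamber_height_um": o.chamber_height_um, "ri": o.ri,
              "density_mg_ml": o.density_mg_ml, "underestimated": o.underestimated}
             for o in observations]
        )
        write_table(obs_table, out / "chamber.csv")
        write_table(gfp_table, out / "gfp.csv")
        write_table(cal_table, out / "height_calibration.csv")
        (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")
    return report
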
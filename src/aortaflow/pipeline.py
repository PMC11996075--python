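"""Stage orchestration: tie the modules into a reproducible pipeline run.

Every stage reads what earlier stages produced (in memory within one
:func:`run`, or from disk when invoked standalone through the CLI), writes
plain-text artifacts into the output directory, and contributes to a
manifest that records inputs, outputs, seed and package version — enough
to rerun the pipeline bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .errors import ConvergenceError
from .flowmri import (
    Acquisition4D,
    TimeCurve,
    apply_mask,
    area_average,
    decode_phase,
    estimate_noise,
    extract_plane_series,
)
from .hemodynamics import flowfield_from_mri, summarize
from .inlet import (
    extract_inlet,
    secondary_fraction,
    synthesize_healthy_inlet,
    two_phase_schedule,
)
from .inlet import PlaneLumen, circular_plane_lumen
from .io import write_acquisition, write_ground_truth
from .outlet import calibrate
from .synth import generate_acquisition, section_flux
from .validation import bias_check, pair_curves, regress

logger = logging.getLogger("aortaflow")

__all__ = ["run"]


def _mri_curves(acq: Acquisition4D, rois) -> list[TimeCurve]:
    velocity = apply_mask(decode_phase(acq), acq.mask)
    curves = []
    for roi in rois:
        frames = extract_plane_series(
            velocity, roi, origin=acq.origin, spacing=acq.spacing, mask=acq.mask
        )
        values = [area_average(f) for f in frames]
        curves.append(TimeCurve(times=acq.frame_times, values=np.asarray(values), label=roi.label))
    return curves


def _stage_synth(cfg: RunConfig, outdir: Path, manifest: dict):
    synth_cfg = replace(cfg.synth, seed=cfg.seed)
    acq, truth = generate_acquisition(synth_cfg)
    acq_dir = outdir / "acquisition"
    write_acquisition(acq, acq_dir, seed=cfg.seed)
    write_ground_truth(truth, acq_dir)
    manifest["outputs"]["acquisition"] = str(acq_dir)
    return acq, truth


def _stage_noise(cfg: RunConfig, acq: Acquisition4D, outdir: Path, manifest: dict):
    sigma, ratio = estimate_noise(acq)
    path = outdir / "noise.json"
    path.write_text(json.dumps({"sigma_mm_s": sigma, "sigma_over_venc": ratio}, indent=2))
    manifest["outputs"]["noise"] = str(path)
    logger.info("noise sigma %.2f mm/s (%.3f of venc)", sigma, ratio)


def _stage_inlet_extract(cfg: RunConfig, acq: Acquisition4D, outdir: Path, manifest: dict):
    series = extract_inlet(acq, cfg.rois[0])
    rows = []
    uu, vv = np.meshgrid(series.u, series.v, indexing="ij")
    for i, t in enumerate(series.times):
        f = series.fields[i]
        rows.append(
            pd.DataFrame(
                {
                    "t_s": t,
                    "u_mm": uu.ravel(),
                    "v_mm": vv.ravel(),
                    "vx": f[..., 0].ravel(),
                    "vy": f[..., 1].ravel(),
                    "vz": f[..., 2].ravel(),
                    "in_lumen": series.lumen_flags.ravel().astype(int),
                }
            )
        )
    path = outdir / "inlet_profile.csv"
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    manifest["outputs"]["inlet_profile"] = str(path)
    return series


def _stage_inlet_synth(cfg: RunConfig, acq: Acquisition4D, outdir: Path, manifest: dict):
    block = cfg.raw.get("inlet_synth", {})
    f_sys = float(block.get("systolic_fraction", 0.32))
    f_dia = float(block.get("diastolic_fraction", 1.11))
    velocity = apply_mask(decode_phase(acq), acq.mask)
    mid = velocity.shape[3] // 2
    flux = section_flux(velocity, acq.spacing)[:, mid]
    period = acq.n_frames * acq.frame_duration
    times = acq.frame_times
    t_sys = float(times[int(np.argmax(np.abs(flux)))])
    schedule = two_phase_schedule(period, times, t_sys, f_sys, f_dia)
    synth = cfg.synth
    lumen = circular_plane_lumen(synth.lumen_radius, synth.grid_spacing)
    flux_curve = TimeCurve(times=times, values=flux, label="inlet flux")
    series = synthesize_healthy_inlet(
        flux_curve, schedule, cfg.rois[0], lumen, target_times=times
    )
    recovered = secondary_fraction(series)
    path = outdir / "inlet_synth.json"
    path.write_text(
        json.dumps(
            {
                "systolic_time_s": t_sys,
                "prescribed_fraction": schedule.fraction.tolist(),
                "recovered_fraction": recovered.fraction.tolist(),
                "flux_ml_s": flux.tolist(),
            },
            indent=2,
        )
    )
    manifest["outputs"]["inlet_synth"] = str(path)
    return series


def _stage_outlet(cfg: RunConfig, outdir: Path, manifest: dict):
    specs, state, log = calibrate(
        cfg.outlets, cfg.inlet_flow_kg_s, cfg.rho_kg_m3
    )
    path = outdir / "outlet_calibration.json"
    path.write_text(
        json.dumps(
            {
                "converged": log.converged,
                "iterations": log.iterations,
                "fractions": {
                    o.name: float(f) for o, f in zip(specs, state.fractions)
                },
                "xi": {o.name: o.xi for o in specs},
                "pressures_pa": {
                    o.name: float(p) for o, p in zip(specs, state.pressures)
                },
                "max_error_history": log.max_errors,
            },
            indent=2,
        )
    )
    manifest["outputs"]["outlet_calibration"] = str(path)
    if not log.converged:
        raise ConvergenceError(
            f"outlet calibration did not converge in {log.iterations} iterations"
        )


def _stage_metrics(cfg: RunConfig, acq: Acquisition4D, outdir: Path, manifest: dict):
    velocity = apply_mask(decode_phase(acq), acq.mask)
    fields = [
        flowfield_from_mri(velocity[f], acq.spacing, acq.origin, mask=acq.mask)
        for f in range(acq.n_frames)
    ]
    table = summarize(fields, acq.frame_times, cfg.rois, cfg.rheology)
    path = outdir / "metrics.csv"
    table.to_csv(path, index=False)
    manifest["outputs"]["metrics"] = str(path)


def _stage_validate(cfg: RunConfig, acq: Acquisition4D, outdir: Path, manifest: dict):
    reference = _mri_curves(acq, cfg.rois)
    # self-validation: with no external solver fields, the candidate is the
    # decoded MRI itself, whose regression must be exactly the identity
    candidate = reference
    pairs = pair_curves(reference, candidate)
    result = regress(pairs)
    mean_diff, frac_above = bias_check(pairs)
    path = outdir / "validation.json"
    path.write_text(
        json.dumps(
            {
                "slope": result.slope,
                "intercept_mm_s": result.intercept,
                "r_squared": result.r_squared,
                "p_value": result.p_value,
                "n": result.n,
                "mean_bias_mm_s": mean_diff,
                "fraction_above_identity": frac_above,
            },
            indent=2,
        )
    )
    manifest["outputs"]["validation"] = str(path)


def run(cfg: RunConfig) -> dict:
    """Execute the configured stages in dependency order; return the manifest."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    outdir = cfg.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "version": __version__,
        "stages": list(cfg.stages),
        "config": cfg.raw,
        "outputs": {},
    }
    acq = None
    if "synth" in cfg.stages:
        acq, _ = _stage_synth(cfg, outdir, manifest)
    if acq is None:
        from .io import read_acquisition

        acq_dir = Path(cfg.raw.get("acquisition_dir", outdir / "acquisition"))
        if not acq_dir.exists():
            raise FileNotFoundError(f"acquisition directory not found: {acq_dir}")
        acq = read_acquisition(acq_dir)
    if "decode" in cfg.stages:
        velocity = apply_mask(decode_phase(acq), acq.mask)
        path = outdir / "decoded_velocity.npz"
        np.savez_compressed(path, velocity_mm_s=velocity, times_s=acq.frame_times)
        manifest["outputs"]["decoded_velocity"] = str(path)
    if "noise" in cfg.stages:
        _stage_noise(cfg, acq, outdir, manifest)
    if "inlet-extract" in cfg.stages:
        _stage_inlet_extract(cfg, acq, outdir, manifest)
    if "inlet-synth" in cfg.stages:
        _stage_inlet_synth(cfg, acq, outdir, manifest)
    if "outlet-calibrate" in cfg.stages:
        _stage_outlet(cfg, outdir, manifest)
    if "metrics" in cfg.stages:
        _stage_metrics(cfg, acq, outdir, manifest)
    if "validate" in cfg.stages:
        _stage_validate(cfg, acq, outdir, manifest)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
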
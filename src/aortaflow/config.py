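"""Run configuration: JSON schema, parsing and validation.

All dimensional fields carry their unit in the field name (``venc_mm_s``,
``inlet_flow_kg_s``); this is the package's guard against the MRI-side
(mm, mm/s) versus CFD-side (SI) unit boundary.  Validation failures raise
:class:`~aortaflow.errors.ConfigError` naming the offending field.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .errors import ConfigError
from .flowmri import PlaneROI
from .hemodynamics import RheologyParams
from .outlet import AORTIC_ARCH_TARGETS, BLOOD_DENSITY, OutletSpec
from .synth import DEFAULT_FLUX_WAVEFORM, SynthConfig

__all__ = ["RunConfig", "load_config", "DEFAULT_STAGES"]

DEFAULT_STAGES = (
    "synth",
    "decode",
    "noise",
    "inlet-extract",
    "outlet-calibrate",
    "metrics",
    "validate",
)


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int
    output_dir: Path
    stages: tuple[str, ...]
    synth: SynthConfig
    outlets: list[OutletSpec]
    inlet_flow_kg_s: float
    rho_kg_m3: float
    rheology: RheologyParams
    rois: list[PlaneROI]
    log_level: str = "INFO"
    raw: dict[str, Any] = field(default_factory=dict)


def _get(d: dict, key: str, default, caster, where: str):
    try:
        value = d.get(key, default)
        return caster(value)
    except ConfigError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with field context
        raise ConfigError(f"{where}.{key}", str(exc)) from exc


def _parse_synth(block: dict) -> SynthConfig:
    try:
        return SynthConfig(
            lumen_radius=float(block.get("lumen_radius_mm", 12.5)),
            lumen_length=float(block.get("lumen_length_mm", 40.0)),
            grid_spacing=float(block.get("grid_spacing_mm", 2.0)),
            grid_margin=float(block.get("grid_margin_mm", 8.0)),
            n_frames=int(block.get("n_frames", 20)),
            cycle_period=float(block.get("cycle_period_s", 0.8)),
            flux_waveform=[
                (float(t), float(q))
                for t, q in block.get("flux_waveform_s_ml_s", DEFAULT_FLUX_WAVEFORM)
            ],
            venc=block.get("venc_mm_s", 2000.0),
            noise_sigma_frac=float(block.get("noise_sigma_frac", 0.05)),
            jet_orifice_frac=float(block.get("jet_orifice_frac", 1.0)),
            jet_eccentricity_frac=float(block.get("jet_eccentricity_frac", 0.0)),
            helical_frac=float(block.get("helical_frac", 0.0)),
            seed=int(block.get("seed", 0)),
        )
    except (ValueError, TypeError) as exc:
        raise ConfigError("synth", str(exc)) from exc


def _parse_outlets(block: dict) -> tuple[list[OutletSpec], float, float]:
    targets = block.get("targets", AORTIC_ARCH_TARGETS)
    areas = block.get("areas_m2", {})
    default_area = float(block.get("default_area_m2", 2e-4))
    pb = float(block.get("pb_pa", 0.0))
    try:
        outlets = [
            OutletSpec(
                name=name,
                area=float(areas.get(name, default_area)),
                target_fraction=float(frac),
                xi=float(block.get("initial_xi", 1.0)),
                pb=pb,
            )
            for name, frac in targets.items()
        ]
    except ValueError as exc:
        raise ConfigError("outlet.targets", str(exc)) from exc
    total = sum(o.target_fraction for o in outlets)
    if abs(total - 1.0) > 1e-4:   # printed-precision rounding admitted
        raise ConfigError("outlet.targets", f"fractions sum to {total}, expected 1")
    inlet_flow = float(block.get("inlet_flow_kg_s", 0.3))
    rho = float(block.get("rho_kg_m3", BLOOD_DENSITY))
    if inlet_flow <= 0:
        raise ConfigError("outlet.inlet_flow_kg_s", "must be positive")
    return outlets, inlet_flow, rho


def _parse_rheology(block: dict) -> RheologyParams:
    try:
        return RheologyParams(
            eta0=float(block.get("eta0_pa_s", 0.16)),
            eta_inf=float(block.get("eta_inf_pa_s", 0.0035)),
            lam=float(block.get("lambda_s", 8.2)),
            a=float(block.get("a", 0.64)),
            n=float(block.get("n", 0.2128)),
            rho=float(block.get("rho_kg_m3", BLOOD_DENSITY)),
        )
    except ValueError as exc:
        raise ConfigError("rheology", str(exc)) from exc


def _parse_rois(items: list[dict], synth: SynthConfig) -> list[PlaneROI]:
    if not items:
        # default: one mid-tube cross-section matching the synthetic lumen
        extent = 2.0 * (synth.lumen_radius + synth.grid_spacing)
        items = [
            {
                "label": "ROI A",
                "origin_mm": [0.0, 0.0, synth.lumen_length / 2.0],
                "normal": [0.0, 0.0, 1.0],
                "basis_u": [1.0, 0.0, 0.0],
                "basis_v": [0.0, 1.0, 0.0],
                "extent_mm": [extent, extent],
                "sample_spacing_mm": synth.grid_spacing,
            }
        ]
    rois = []
    for i, item in enumerate(items):
        try:
            rois.append(
                PlaneROI(
                    label=str(item.get("label", f"ROI {i}")),
                    origin=np.asarray(item["origin_mm"], dtype=float),
                    normal=np.asarray(item["normal"], dtype=float),
                    basis_u=np.asarray(item["basis_u"], dtype=float),
                    basis_v=np.asarray(item["basis_v"], dtype=float),
                    extent=tuple(float(x) for x in item["extent_mm"]),
                    sample_spacing=float(item["sample_spacing_mm"]),
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise ConfigError(f"rois[{i}]", str(exc)) from exc
    return rois


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError("config", f"file not found: {path}")
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError("config", f"invalid JSON: {exc}") from exc

    seed = _get(raw, "seed", 0, int, "")
    output_dir = Path(raw.get("output_dir", "aortaflow_out"))
    stages = tuple(raw.get("stages", DEFAULT_STAGES))
    unknown = set(stages) - set(DEFAULT_STAGES) - {"inlet-synth"}
    if unknown:
        raise ConfigError("stages", f"unknown stage(s): {sorted(unknown)}")
    synth = _parse_synth(raw.get("synth", {}))
    outlets, inlet_flow, rho = _parse_outlets(raw.get("outlet", {}))
    rheology = _parse_rheology(raw.get("rheology", {}))
    rois = _parse_rois(raw.get("rois", []), synth)
    return RunConfig(
        seed=seed,
        output_dir=output_dir,
        stages=stages,
        synth=synth,
        outlets=outlets,
        inlet_flow_kg_s=inlet_flow,
        rho_kg_m3=rho,
        rheology=rheology,
        rois=rois,
        log_level=str(raw.get("log_level", "INFO")),
        raw=raw,
    )
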
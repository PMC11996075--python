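"""On-disk layout for acquisitions, ground truth and derived curves.

An acquisition is written as one scalar NIfTI volume per velocity component
per frame (``phase_f<frame>_c<comp>.nii.gz``), the magnitude volumes, a
byte mask volume, and a JSON sidecar carrying the velocity-encoding limits
(mm/s per axis), frame duration (s), voxel spacing and origin (mm) and the
generator seed.  Ground truth goes into a compressed array archive plus
JSON.  Plane fields and time curves are exported as plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .flowmri import Acquisition4D, PlaneField, TimeCurve
from .synth import GroundTruth

__all__ = [
    "write_acquisition",
    "read_acquisition",
    "write_ground_truth",
    "read_ground_truth",
    "write_plane_field_csv",
    "write_time_curve_csv",
    "read_time_curve_csv",
]

SIDECAR_NAME = "acquisition.json"


def _affine(spacing: np.ndarray, origin: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def write_acquisition(acq: Acquisition4D, directory: str | Path, seed: int | None = None) -> Path:
    """Write the NIfTI + JSON sidecar layout; returns the sidecar path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aff = _affine(acq.spacing, acq.origin)
    for f in range(acq.n_frames):
        for c in range(3):
            img = nib.Nifti1Image(acq.phase[f, ..., c].astype(np.float32), aff)
            nib.save(img, directory / f"phase_f{f:03d}_c{c}.nii.gz")
        nib.save(
            nib.Nifti1Image(acq.magnitude[f].astype(np.float32), aff),
            directory / f"magnitude_f{f:03d}.nii.gz",
        )
    nib.save(
        nib.Nifti1Image(acq.mask.astype(np.uint8), aff), directory / "mask.nii.gz"
    )
    sidecar = {
        "venc_mm_s": acq.venc.tolist(),
        "frame_duration_s": acq.frame_duration,
        "spacing_mm": acq.spacing.tolist(),
        "origin_mm": acq.origin.tolist(),
        "n_frames": acq.n_frames,
        "seed": seed,
    }
    path = directory / SIDECAR_NAME
    path.write_text(json.dumps(sidecar, indent=2))
    return path


def read_acquisition(directory: str | Path) -> Acquisition4D:
    """Read an acquisition from the layout written by :func:`write_acquisition`."""
    directory = Path(directory)
    meta = json.loads((directory / SIDECAR_NAME).read_text())
    n_frames = int(meta["n_frames"])
    mask = np.asanyarray(nib.load(directory / "mask.nii.gz").dataobj).astype(bool)
    phase = np.zeros((n_frames,) + mask.shape + (3,))
    magnitude = np.zeros((n_frames,) + mask.shape)
    for f in range(n_frames):
        for c in range(3):
            phase[f, ..., c] = np.asanyarray(
                nib.load(directory / f"phase_f{f:03d}_c{c}.nii.gz").dataobj
            )
        magnitude[f] = np.asanyarray(
            nib.load(directory / f"magnitude_f{f:03d}.nii.gz").dataobj
        )
    # float32 round-trips can overshoot the [-1, 1] phase bound by one ulp
    phase = np.clip(phase, -1.0, 1.0)
    return Acquisition4D(
        phase=phase,
        magnitude=magnitude,
        mask=mask,
        venc=np.asarray(meta["venc_mm_s"], dtype=float),
        frame_duration=float(meta["frame_duration_s"]),
        spacing=np.asarray(meta["spacing_mm"], dtype=float),
        origin=np.asarray(meta["origin_mm"], dtype=float),
    )


def write_ground_truth(truth: GroundTruth, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        directory / "ground_truth.npz",
        noiseless_velocity=truth.noiseless_velocity,
        analytic_flux=truth.analytic_flux,
        injected_noise_sigma=truth.injected_noise_sigma,
        frame_times=truth.frame_times,
    )
    meta = {
        "analytic_flux_ml_s": truth.analytic_flux.tolist(),
        "injected_noise_sigma_mm_s": truth.injected_noise_sigma.tolist(),
        "frame_times_s": truth.frame_times.tolist(),
    }
    path = directory / "ground_truth.json"
    path.write_text(json.dumps(meta, indent=2))
    return path


def read_ground_truth(directory: str | Path) -> GroundTruth:
    with np.load(Path(directory) / "ground_truth.npz") as npz:
        return GroundTruth(
            noiseless_velocity=npz["noiseless_velocity"],
            analytic_flux=npz["analytic_flux"],
            injected_noise_sigma=npz["injected_noise_sigma"],
            frame_times=npz["frame_times"],
        )


def write_plane_field_csv(field: PlaneField, path: str | Path) -> Path:
    """Export a sampled plane field as CSV (world mm, mm/s, lumen flag)."""
    _, _, pts = field.plane.sample_coords()
    df = pd.DataFrame(
        {
            "x_mm": pts[..., 0].ravel(),
            "y_mm": pts[..., 1].ravel(),
            "z_mm": pts[..., 2].ravel(),
            "vx": field.velocity[..., 0].ravel(),
            "vy": field.velocity[..., 1].ravel(),
            "vz": field.velocity[..., 2].ravel(),
            "in_lumen": field.in_lumen.ravel().astype(int),
        }
    )
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def write_time_curve_csv(curve: TimeCurve, path: str | Path) -> Path:
    pd.DataFrame({"t_s": curve.times, "value": curve.values}).to_csv(
        Path(path), index=False
    )
    return Path(path)


def read_time_curve_csv(path: str | Path, label: str = "") -> TimeCurve:
    df = pd.read_csv(path)
    return TimeCurve(times=df["t_s"].to_numpy(), values=df["value"].to_numpy(), label=label)
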
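"""Velocity-encoded 4D acquisition handling.

A phase-contrast acquisition stores, per cardiac timeframe, three phase
volumes (one per velocity-encoding axis), a magnitude volume and a binary
lumen mask.  Phase is kept as a signed value normalised to [-1, 1]; decoding
multiplies by the per-axis velocity-encoding limit ``venc`` so that a phase
of +1 maps to +venc.  All MRI-side quantities are in mm and mm/s; conversion
to SI happens only when fields enter the hemodynamics module.

Array convention (fixed throughout the package): velocity-like arrays are
indexed ``[frame, i0, i1, i2, component]``, 0-based and voxel-centred, with
world coordinate ``origin + spacing * index``.  Component ``c`` points along
world axis ``c``; the tube axis of synthetic acquisitions runs along the
third spatial axis (``i2``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .errors import EstimationError, GeometryError

__all__ = [
    "Acquisition4D",
    "PlaneROI",
    "PlaneField",
    "TimeCurve",
    "decode_phase",
    "apply_mask",
    "estimate_noise",
    "detect_diastole",
    "extract_plane_series",
    "area_average",
]


@dataclass
class Acquisition4D:
    """Time-resolved, three-directionally velocity-encoded acquisition.

    Attributes
    ----------
    phase:
        ``(n_frames, n0, n1, n2, 3)`` signed normalised phase in [-1, 1].
    magnitude:
        ``(n_frames, n0, n1, n2)`` anatomical signal magnitude (arbitrary
        units); used for segmentation upstream, carried through here.
    mask:
        ``(n0, n1, n2)`` binary lumen segmentation (one static mask, applied
        to every frame).
    venc:
        Velocity-encoding limit per axis, mm/s, shape ``(3,)``.
    frame_duration:
        Temporal resolution of the acquisition, s.
    spacing, origin:
        Voxel spacing and world position of voxel (0,0,0), mm.
    """

    phase: np.ndarray
    magnitude: np.ndarray
    mask: np.ndarray
    venc: np.ndarray
    frame_duration: float
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.phase = np.asarray(self.phase, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        self.venc = np.broadcast_to(np.asarray(self.venc, dtype=float), (3,)).copy()
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.phase.ndim != 5 or self.phase.shape[-1] != 3:
            raise ValueError("phase must have shape (n_frames, n0, n1, n2, 3)")
        if self.phase.shape[1:4] != self.mask.shape:
            raise ValueError("mask shape does not match phase volumes")
        if self.n_frames < 2:
            raise ValueError("acquisition needs at least 2 frames")
        if self.frame_duration <= 0:
            raise ValueError("frame_duration must be positive")
        if np.any(self.venc <= 0):
            raise ValueError("venc must be positive on every axis")
        if np.nanmax(np.abs(self.phase)) > 1.0 + 1e-12:
            raise ValueError("phase values must lie in [-1, 1]")

    @property
    def n_frames(self) -> int:
        return self.phase.shape[0]

    @property
    def frame_times(self) -> np.ndarray:
        """Frame-centre times over one cycle, s."""
        return np.arange(self.n_frames) * self.frame_duration


@dataclass
class PlaneROI:
    """Oriented, finite sampling plane (a cross-sectional region of interest).

    The plane is spanned by the orthonormal in-plane basis ``(basis_u,
    basis_v)`` around ``origin``; samples are laid out on a regular grid of
    pitch ``sample_spacing`` covering ``extent = (len_u, len_v)`` mm, centred
    on the origin.
    """

    label: str
    origin: np.ndarray
    normal: np.ndarray
    basis_u: np.ndarray
    basis_v: np.ndarray
    extent: tuple[float, float]
    sample_spacing: float

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.normal = np.asarray(self.normal, dtype=float).reshape(3)
        self.basis_u = np.asarray(self.basis_u, dtype=float).reshape(3)
        self.basis_v = np.asarray(self.basis_v, dtype=float).reshape(3)
        vecs = [self.normal, self.basis_u, self.basis_v]
        for a in range(3):
            for b in range(a, 3):
                want = 1.0 if a == b else 0.0
                if abs(float(vecs[a] @ vecs[b]) - want) > 1e-10:
                    raise ValueError("normal/basis_u/basis_v must be orthonormal")
        if self.sample_spacing <= 0:
            raise ValueError("sample_spacing must be positive")

    def sample_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (u, v, points): in-plane sample offsets and world points.

        ``points`` has shape ``(nu, nv, 3)`` in mm.
        """
        half_u, half_v = self.extent[0] / 2.0, self.extent[1] / 2.0
        u = np.arange(-half_u, half_u + 1e-9, self.sample_spacing)
        v = np.arange(-half_v, half_v + 1e-9, self.sample_spacing)
        pts = (
            self.origin[None, None, :]
            + u[:, None, None] * self.basis_u[None, None, :]
            + v[None, :, None] * self.basis_v[None, None, :]
        )
        return u, v, pts


@dataclass
class PlaneField:
    """Vector field sampled on a :class:`PlaneROI` grid (one timeframe)."""

    plane: PlaneROI
    u: np.ndarray           # (nu,) in-plane offsets, mm
    v: np.ndarray           # (nv,)
    velocity: np.ndarray    # (nu, nv, 3) mm/s, world components
    in_lumen: np.ndarray    # (nu, nv) bool

    def axial_component(self) -> np.ndarray:
        """Signed velocity component along the plane normal, mm/s."""
        return self.velocity @ self.plane.normal

    def inplane_speed(self) -> np.ndarray:
        """Magnitude of the velocity projection onto the plane, mm/s."""
        axial = self.axial_component()
        inplane = self.velocity - axial[..., None] * self.plane.normal
        return np.linalg.norm(inplane, axis=-1)


@dataclass
class TimeCurve:
    """Scalar time series over (typically) one cardiac cycle."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D and equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    def shifted(self, offset: float) -> "TimeCurve":
        return replace(self, values=self.values + offset)


def decode_phase(acq: Acquisition4D) -> np.ndarray:
    """Decode normalised phase into velocity, mm/s.

    Component ``c`` of the returned field is ``phase_c * venc_c`` at every
    voxel and frame.
    """
    if np.any(acq.venc <= 0):
        raise ValueError("venc must be positive")
    return acq.phase * acq.venc[None, None, None, None, :]


def apply_mask(velocity: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero the velocity field outside the lumen segmentation.

    ``velocity`` is ``(n_frames, n0, n1, n2, 3)``; ``mask`` is the static
    ``(n0, n1, n2)`` segmentation.  Returns the segmented velocity volume.
    """
    velocity = np.asarray(velocity, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if velocity.shape[1:4] != mask.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match velocity spatial shape "
            f"{velocity.shape[1:4]}"
        )
    return velocity * mask[None, :, :, :, None]


def background_region(mask: np.ndarray, margin: int = 3) -> np.ndarray:
    """Non-vessel voxels safely away from the lumen.

    The lumen mask is morphologically dilated by ``margin`` voxels and the
    complement is returned, excluding the partial-volume rim around the
    vessel wall.
    """
    dilated = ndimage.binary_dilation(np.asarray(mask).astype(bool), iterations=margin)
    return ~dilated


def detect_diastole(acq: Acquisition4D, threshold_frac: float = 0.10) -> np.ndarray:
    """Frames belonging to diastole, detected from the lumen-mean speed.

    A frame is diastolic when the mask-averaged velocity magnitude sits in
    the lowest ``threshold_frac`` of its cycle range.  The range (rather
    than the raw maximum) makes the rule robust to the noise floor, which
    lifts the speed magnitude of genuinely quiescent frames; for noiseless
    data the two readings coincide.
    """
    vel = decode_phase(acq)
    speed = np.linalg.norm(vel, axis=-1)
    lumen_mean = np.array([s[acq.mask].mean() for s in speed])
    lo, hi = lumen_mean.min(), lumen_mean.max()
    frames = np.nonzero(lumen_mean <= lo + threshold_frac * (hi - lo))[0]
    return frames


def estimate_noise(
    acq: Acquisition4D,
    diastole_frames: Sequence[int] | None = None,
    margin: int = 3,
) -> tuple[float, float]:
    """Estimate velocity noise from background voxels during diastole.

    The noise level of an acquisition is the standard deviation of the
    decoded velocity in surrounding non-vessel regions during diastole,
    where no flow signal should exist.  Returns ``(sigma_mm_s, sigma/venc)``
    where the ratio averages the per-axis ratios (axes may have different
    encoding limits).
    """
    if diastole_frames is None:
        diastole_frames = detect_diastole(acq)
    diastole_frames = np.asarray(list(diastole_frames), dtype=int)
    if diastole_frames.size == 0:
        raise EstimationError("no diastolic frames given or detected")
    background = background_region(acq.mask, margin=margin)
    if not background.any():
        raise EstimationError("background region empty after exclusion margin")
    vel = decode_phase(acq)[diastole_frames]
    samples = vel[:, background, :]            # (n_frames, n_bg, 3)
    per_axis = samples.reshape(-1, 3).std(axis=0, ddof=1)
    sigma = float(np.sqrt(np.mean(per_axis**2)))
    ratio = float(np.mean(per_axis / acq.venc))
    return sigma, ratio


def _world_to_index(points: np.ndarray, origin: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    return (points - origin) / spacing


def extract_plane_series(
    velocity: np.ndarray,
    plane: PlaneROI,
    origin: np.ndarray,
    spacing: np.ndarray,
    mask: np.ndarray | None = None,
) -> list[PlaneField]:
    """Sample the velocity volume on a plane grid, one field per frame.

    Each component is interpolated trilinearly at the plane sample points.
    Samples outside the lumen mask (or outside the grid) are flagged
    out-of-lumen; their velocity is zeroed.
    """
    velocity = np.asarray(velocity, dtype=float)
    origin = np.asarray(origin, dtype=float).reshape(3)
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    u, v, pts = plane.sample_coords()
    idx = _world_to_index(pts, origin, spacing)        # (nu, nv, 3)
    shape = np.array(velocity.shape[1:4])

    inside_grid = np.all((idx >= 0) & (idx <= shape - 1), axis=-1)
    if not inside_grid.any():
        raise GeometryError(f"plane '{plane.label}' lies entirely outside the grid")

    coords = idx.reshape(-1, 3).T                       # (3, n_samples)
    if mask is not None:
        mask_val = ndimage.map_coordinates(
            np.asarray(mask, dtype=float), coords, order=1, mode="constant", cval=0.0
        ).reshape(idx.shape[:2])
        in_lumen = inside_grid & (mask_val >= 0.5)
    else:
        in_lumen = inside_grid

    fields = []
    for f in range(velocity.shape[0]):
        comp = [
            ndimage.map_coordinates(
                velocity[f, ..., c], coords, order=1, mode="constant", cval=0.0
            ).reshape(idx.shape[:2])
            for c in range(3)
        ]
        vel = np.stack(comp, axis=-1)
        vel[~in_lumen] = 0.0
        fields.append(PlaneField(plane=plane, u=u, v=v, velocity=vel, in_lumen=in_lumen.copy()))
    return fields


def area_average(
    field: PlaneField,
    scalar: Callable[[PlaneField], np.ndarray] | None = None,
) -> float:
    """Arithmetic mean of a scalar over in-lumen plane samples.

    By default the scalar is the velocity magnitude.  Out-of-lumen samples
    are excluded (not zero-filled), so wall-adjacent means are unbiased.
    """
    values = (
        np.linalg.norm(field.velocity, axis=-1) if scalar is None else scalar(field)
    )
    flags = field.in_lumen
    if not flags.any():
        raise EstimationError("area average over zero in-lumen samples")
    return float(values[flags].mean())
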
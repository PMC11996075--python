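"""Inlet boundary-condition construction.

Two routes produce a time-resolved inlet velocity profile for a CFD model:

* *measured*: extract the velocity field on a plane just above the aortic
  valve from a decoded 4D acquisition, then refine it in space and time
  (separable linear interpolation) onto the solver's grid and time base;
* *synthetic healthy*: prescribe a flux-matched parabolic axial profile
  whose volumetric flux follows a Fourier-series fit of the measured
  per-frame flux, plus an in-plane swirl whose area-averaged speed is a
  scheduled percentage of the axial speed — the schedule itself derived
  from a healthy reference acquisition and Fourier-fitted.

All velocities are mm/s, lengths mm, fluxes mL/s, times s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import EstimationError, FittingError, GeometryError
from .flowmri import (
    Acquisition4D,
    PlaneField,
    PlaneROI,
    TimeCurve,
    apply_mask,
    decode_phase,
    extract_plane_series,
)

__all__ = [
    "FourierSeries",
    "SecondaryFlowSchedule",
    "InletProfileSeries",
    "PlaneLumen",
    "circular_plane_lumen",
    "elliptical_plane_lumen",
    "fit_fourier",
    "solver_timestep",
    "extract_inlet",
    "refine_space_time",
    "parabolic_inlet",
    "secondary_fraction",
    "synthesize_healthy_inlet",
    "two_phase_schedule",
]


@dataclass
class FourierSeries:
    """Truncated real Fourier series on a fixed period.

    ``f(t) = a0 + sum_k a_k cos(2 pi k t / period) + b_k sin(2 pi k t / period)``
    """

    period: float
    a0: float
    cosine_coeffs: np.ndarray
    sine_coeffs: np.ndarray
    residual_rms: float = 0.0

    def __post_init__(self):
        self.cosine_coeffs = np.atleast_1d(np.asarray(self.cosine_coeffs, dtype=float))
        self.sine_coeffs = np.atleast_1d(np.asarray(self.sine_coeffs, dtype=float))
        if self.cosine_coeffs.shape != self.sine_coeffs.shape:
            raise ValueError("cosine and sine coefficient arrays must match")
        if self.period <= 0:
            raise ValueError("period must be positive")

    @property
    def order(self) -> int:
        return len(self.cosine_coeffs)

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.a0, dtype=float)
        for k in range(1, self.order + 1):
            w = 2.0 * np.pi * k * t / self.period
            out += self.cosine_coeffs[k - 1] * np.cos(w)
            out += self.sine_coeffs[k - 1] * np.sin(w)
        return out if out.ndim else float(out)


@dataclass
class SecondaryFlowSchedule:
    """Per-frame in-plane/axial speed ratio and its Fourier fit.

    ``fraction[i]`` is the ratio of area-averaged in-plane speed to
    area-averaged axial speed at ``frame_times[i]`` (NaN where the axial
    flow vanished and the ratio is undefined).
    """

    frame_times: np.ndarray
    fraction: np.ndarray
    fitted: FourierSeries

    def __post_init__(self):
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any(self.fraction[np.isfinite(self.fraction)] < 0):
                raise ValueError("fractions must be non-negative")


@dataclass
class InletProfileSeries:
    """Time-resolved vector field on an inlet plane.

    ``fields`` has shape ``(n_times, nu, nv, 3)`` (world components, mm/s);
    samples flagged out-of-lumen carry zero velocity.  ``period`` enables
    periodic extension in time (one cardiac cycle).
    """

    plane: PlaneROI
    times: np.ndarray
    u: np.ndarray
    v: np.ndarray
    fields: np.ndarray
    lumen_flags: np.ndarray
    period: float | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.fields = np.asarray(self.fields, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.fields.shape[0] != len(self.times):
            raise ValueError("one field per time required")
        if np.any(self.fields[:, ~self.lumen_flags, :] != 0.0):
            raise ValueError("out-of-lumen samples must carry zero velocity")

    def frame(self, i: int) -> PlaneField:
        return PlaneField(
            plane=self.plane, u=self.u, v=self.v,
            velocity=self.fields[i], in_lumen=self.lumen_flags,
        )


@dataclass
class PlaneLumen:
    """In-plane lumen geometry on a regular (u, v) sample grid."""

    u: np.ndarray
    v: np.ndarray
    in_lumen: np.ndarray

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.in_lumen = np.asarray(self.in_lumen).astype(bool)
        if self.in_lumen.shape != (len(self.u), len(self.v)):
            raise ValueError("in_lumen must be (len(u), len(v))")

    @property
    def sample_area(self) -> float:
        du = float(self.u[1] - self.u[0])
        dv = float(self.v[1] - self.v[0])
        return du * dv

    @property
    def centroid(self) -> tuple[float, float]:
        uu, vv = np.meshgrid(self.u, self.v, indexing="ij")
        return float(uu[self.in_lumen].mean()), float(vv[self.in_lumen].mean())


def circular_plane_lumen(radius: float, spacing: float, margin: float = 2.0) -> PlaneLumen:
    """Circular lumen of given radius (mm) on a centred sample grid."""
    half = radius + margin
    c = np.arange(-half, half + 1e-9, spacing)
    uu, vv = np.meshgrid(c, c, indexing="ij")
    return PlaneLumen(u=c, v=c, in_lumen=np.hypot(uu, vv) <= radius)


def elliptical_plane_lumen(a: float, b: float, spacing: float, margin: float = 2.0) -> PlaneLumen:
    """Elliptical lumen with semi-axes ``a`` (u) and ``b`` (v), mm."""
    cu = np.arange(-(a + margin), a + margin + 1e-9, spacing)
    cv = np.arange(-(b + margin), b + margin + 1e-9, spacing)
    uu, vv = np.meshgrid(cu, cv, indexing="ij")
    return PlaneLumen(u=cu, v=cv, in_lumen=(uu / a) ** 2 + (vv / b) ** 2 <= 1.0)


def solver_timestep(frame_duration: float, subdivision: int = 40) -> float:
    """CFD time step: the MRI frame duration divided into ``subdivision`` steps."""
    if frame_duration <= 0:
        raise ValueError("frame_duration must be positive")
    if subdivision < 1:
        raise ValueError("subdivision must be at least 1")
    return frame_duration / subdivision


def fit_fourier(
    times: Sequence[float],
    values: Sequence[float],
    period: float,
    order: int,
) -> FourierSeries:
    """Least-squares Fourier fit of scattered periodic samples.

    Requires at least ``2 * order + 1`` samples; when the sample count
    equals the parameter count and the design is nonsingular the fit
    interpolates (zero residual).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-D and equal length")
    n_params = 2 * order + 1
    if len(t) < n_params:
        raise FittingError(
            f"need at least {n_params} samples for order {order}, got {len(t)}"
        )
    cols = [np.ones_like(t)]
    for k in range(1, order + 1):
        w = 2.0 * np.pi * k * t / period
        cols.append(np.cos(w))
        cols.append(np.sin(w))
    design = np.stack(cols, axis=1)
    if np.linalg.matrix_rank(design) < n_params:
        raise FittingError("singular Fourier design (duplicate or degenerate times)")
    coeffs, *_ = np.linalg.lstsq(design, y, rcond=None)
    if not np.all(np.isfinite(coeffs)):
        raise FittingError("non-finite Fourier coefficients")
    resid = y - design @ coeffs
    return FourierSeries(
        period=period,
        a0=float(coeffs[0]),
        cosine_coeffs=coeffs[1::2],
        sine_coeffs=coeffs[2::2],
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def extract_inlet(acq: Acquisition4D, plane: PlaneROI) -> InletProfileSeries:
    """Extract the measured inlet profile series on ``plane``.

    The acquisition is decoded, the lumen segmentation applied, and every
    frame sampled trilinearly on the plane grid; out-of-lumen samples are
    zeroed and flagged.
    """
    velocity = apply_mask(decode_phase(acq), acq.mask)
    frames = extract_plane_series(
        velocity, plane, origin=acq.origin, spacing=acq.spacing, mask=acq.mask
    )
    if not frames[0].in_lumen.any():
        raise GeometryError(f"plane '{plane.label}' does not intersect the lumen")
    fields = np.stack([f.velocity for f in frames])
    return InletProfileSeries(
        plane=plane,
        times=acq.frame_times,
        u=frames[0].u,
        v=frames[0].v,
        fields=fields,
        lumen_flags=frames[0].in_lumen,
        period=acq.n_frames * acq.frame_duration,
    )


def _interp_linear_periodic(
    times: np.ndarray, fields: np.ndarray, t: float, period: float | None
) -> np.ndarray:
    """Linear-in-time interpolation of a field stack, periodic if period given."""
    if period is not None:
        t = times[0] + np.mod(t - times[0], period)
        ext_times = np.concatenate([times, [times[0] + period]])
        ext_fields = np.concatenate([fields, fields[:1]], axis=0)
    else:
        ext_times, ext_fields = times, fields
        if t < ext_times[0] - 1e-12 or t > ext_times[-1] + 1e-12:
            raise ValueError(f"time {t} outside the non-periodic series range")
    i = int(np.clip(np.searchsorted(ext_times, t, side="right") - 1, 0, len(ext_times) - 2))
    t0, t1 = ext_times[i], ext_times[i + 1]
    w = 0.0 if t1 == t0 else (t - t0) / (t1 - t0)
    return (1.0 - w) * ext_fields[i] + w * ext_fields[i + 1]


def _bilinear_plane(u_src, v_src, field2d, u_tgt, v_tgt):
    """Separable bilinear interpolation of (nu, nv, ...) onto target axes."""
    du = u_src[1] - u_src[0]
    dv = v_src[1] - v_src[0]
    iu = (np.asarray(u_tgt) - u_src[0]) / du
    iv = (np.asarray(v_tgt) - v_src[0]) / dv
    iuu, ivv = np.meshgrid(iu, iv, indexing="ij")
    coords = np.stack([iuu.ravel(), ivv.ravel()])
    if field2d.ndim == 2:
        out = ndimage.map_coordinates(field2d, coords, order=1, mode="nearest")
        return out.reshape(len(iu), len(iv))
    comps = [
        ndimage.map_coordinates(field2d[..., c], coords, order=1, mode="nearest").reshape(
            len(iu), len(iv)
        )
        for c in range(field2d.shape[-1])
    ]
    return np.stack(comps, axis=-1)


def refine_space_time(
    series: InletProfileSeries,
    target_u: Sequence[float],
    target_v: Sequence[float],
    target_times: Sequence[float],
) -> InletProfileSeries:
    """Interpolate an inlet series linearly in space and time.

    Bilinear over the in-plane grid, linear over time (with periodic
    extension when the series carries a period); exact at source nodes and
    frame times.
    """
    target_u = np.asarray(target_u, dtype=float)
    target_v = np.asarray(target_v, dtype=float)
    target_times = np.asarray(target_times, dtype=float)
    if target_u.size == 0 or target_v.size == 0 or target_times.size == 0:
        raise ValueError("target grid and times must be non-empty")

    time_interp = np.stack(
        [
            _interp_linear_periodic(series.times, series.fields, t, series.period)
            for t in target_times
        ]
    )
    fields = np.stack(
        [_bilinear_plane(series.u, series.v, f, target_u, target_v) for f in time_interp]
    )
    flag_float = _bilinear_plane(
        series.u, series.v, series.lumen_flags.astype(float), target_u, target_v
    )
    flags = flag_float >= 0.5
    fields[:, ~flags, :] = 0.0
    return InletProfileSeries(
        plane=series.plane,
        times=target_times,
        u=target_u,
        v=target_v,
        fields=fields,
        lumen_flags=flags,
        period=series.period,
    )


def parabolic_inlet(lumen: PlaneLumen, flux: float) -> np.ndarray:
    """Flux-matched generalized parabolic axial profile, mm/s.

    The profile is ``v = v_peak * (1 - r_tilde**2)`` with
    ``r_tilde = 1 - d / d_max`` built from the in-plane Euclidean distance
    ``d`` to the lumen boundary (zero at the wall; on a circular lumen this
    is the Poiseuille parabola).  ``v_peak`` is scaled so the numerically
    integrated flux equals ``flux`` (mL/s) to machine precision.
    """
    if not lumen.in_lumen.any():
        raise GeometryError("lumen has zero area")
    du = float(lumen.u[1] - lumen.u[0]) if len(lumen.u) > 1 else 1.0
    dv = float(lumen.v[1] - lumen.v[0]) if len(lumen.v) > 1 else 1.0
    d = ndimage.distance_transform_edt(lumen.in_lumen, sampling=(du, dv))
    d_max = d.max()
    if d_max <= 0:
        raise GeometryError("degenerate lumen: no interior samples")
    r_tilde = 1.0 - d / d_max
    shape = np.where(lumen.in_lumen, 1.0 - r_tilde**2, 0.0)
    shape_flux = shape.sum() * du * dv / 1000.0        # mL/s at unit peak
    if flux == 0.0:
        return np.zeros_like(shape)
    return shape * (flux / shape_flux)


def secondary_fraction(
    series: InletProfileSeries, order: int | None = None
) -> SecondaryFlowSchedule:
    """Per-frame in-plane/axial area-averaged speed ratio, Fourier-fitted.

    Frames with vanishing axial flow have an undefined ratio; they are
    flagged NaN and excluded from the fit.
    """
    n = len(series.times)
    fraction = np.full(n, np.nan)
    flags = series.lumen_flags
    if not flags.any():
        raise EstimationError("series has no in-lumen samples")
    for i in range(n):
        f = series.frame(i)
        axial = np.abs(f.axial_component())[flags].mean()
        inplane = f.inplane_speed()[flags].mean()
        if axial > 0:
            fraction[i] = inplane / axial
    valid = np.isfinite(fraction)
    if not valid.any():
        raise EstimationError("axial flow vanished at every frame")
    n_valid = int(valid.sum())
    if order is None:
        order = min(8, (n_valid - 1) // 2)
    period = series.period if series.period is not None else float(
        series.times[-1] - series.times[0]
    )
    fitted = fit_fourier(series.times[valid], fraction[valid], period, order)
    return SecondaryFlowSchedule(
        frame_times=series.times, fraction=fraction, fitted=fitted
    )


def two_phase_schedule(
    period: float,
    frame_times: Sequence[float],
    t_systole: float,
    f_systole: float,
    f_diastole: float,
) -> SecondaryFlowSchedule:
    """Schedule through a systolic and a diastolic secondary-flow fraction.

    Builds per-frame data points on the single-harmonic curve that passes
    through ``(t_systole, f_systole)`` and through ``f_diastole`` half a
    cycle later, then Fourier-fits them (order 1, hence the fit reproduces
    the two anchor values exactly).  Used when only per-phase fractions,
    not a full measured schedule, are available.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    mean = 0.5 * (f_systole + f_diastole)
    amp = 0.5 * (f_diastole - f_systole)
    fraction = mean - amp * np.cos(2.0 * np.pi * (frame_times - t_systole) / period)
    if np.any(fraction < 0):
        raise ValueError("schedule would be negative between the anchor phases")
    fitted = fit_fourier(frame_times, fraction, period, order=1)
    return SecondaryFlowSchedule(frame_times=frame_times, fraction=fraction, fitted=fitted)


def _swirl_pattern(lumen: PlaneLumen) -> np.ndarray:
    """Unit-scale solid-body rotation about the lumen centroid, (nu, nv, 2).

    Right-handed with respect to the plane normal (counter-clockwise in the
    (u, v) frame when the normal points toward the viewer).
    """
    uc, vc = lumen.centroid
    uu, vv = np.meshgrid(lumen.u, lumen.v, indexing="ij")
    pu = -(vv - vc)
    pv = uu - uc
    pat = np.stack([pu, pv], axis=-1)
    pat[~lumen.in_lumen] = 0.0
    return pat


def synthesize_healthy_inlet(
    flux_series: TimeCurve,
    schedule: SecondaryFlowSchedule,
    plane: PlaneROI,
    lumen: PlaneLumen,
    target_times: Sequence[float],
    flux_order: int | None = None,
) -> InletProfileSeries:
    """Compose the synthetic healthy inlet boundary condition.

    At every target time the axial field is the flux-matched parabolic
    profile evaluated at the Fourier-fitted flux (``flux_series`` in mL/s,
    fit order defaulting to the interpolating order for the given frames);
    the in-plane field is a solid-body swirl scaled so the in-plane/axial
    area-averaged speed ratio equals the fitted schedule.  Negative fitted
    flux reverses the axial direction (retrograde flow); the swirl scaling
    uses the speed magnitude.
    """
    period = schedule.fitted.period
    n = len(flux_series.times)
    if flux_order is None:
        flux_order = min((n - 1) // 2, 10)
    flux_fit = fit_fourier(flux_series.times, flux_series.values, period, flux_order)

    pattern = _swirl_pattern(lumen)
    pattern_speed = np.linalg.norm(pattern, axis=-1)
    mean_pattern = pattern_speed[lumen.in_lumen].mean()
    if mean_pattern <= 0:
        raise GeometryError("degenerate swirl pattern (single-sample lumen)")

    target_times = np.asarray(target_times, dtype=float)
    nu, nv = len(lumen.u), len(lumen.v)
    fields = np.zeros((len(target_times), nu, nv, 3))
    for i, t in enumerate(target_times):
        q = float(flux_fit(t))
        if not np.isfinite(q):
            raise FittingError("non-finite fitted flux")
        axial = parabolic_inlet(lumen, abs(q)) * np.sign(q) if q != 0 else np.zeros((nu, nv))
        s = max(float(schedule.fitted(t)), 0.0)
        mean_axial = np.abs(axial)[lumen.in_lumen].mean()
        scale = s * mean_axial / mean_pattern
        inplane = pattern * scale
        fields[i] = (
            axial[..., None] * plane.normal
            + inplane[..., 0, None] * plane.basis_u
            + inplane[..., 1, None] * plane.basis_v
        )
    fields[:, ~lumen.in_lumen, :] = 0.0
    return InletProfileSeries(
        plane=plane,
        times=target_times,
        u=lumen.u,
        v=lumen.v,
        fields=fields,
        lumen_flags=lumen.in_lumen,
        period=period,
    )
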
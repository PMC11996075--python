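"""Bulk hemodynamic quantities on gridded velocity fields.

Everything a blood-damage-oriented analysis reads off a resolved (or
Reynolds-averaged) flow field: shear rate and non-Newtonian viscosity
(Carreau-Yasuda), the scalar shear-stress decomposition acting on
circulating cells (viscous + Reynolds = total), turbulent kinetic energy,
vorticity, helicity density and local normalized helicity (LNH), and
Reynolds numbers.  This module works in SI units (m, s, Pa); MRI-side
fields in mm/s are converted on entry.

Scalarizations: the viscous shear stress is ``VSS = eta(gamma_dot) *
gamma_dot`` with ``gamma_dot = sqrt(2 S:S)``; the Reynolds shear stress
uses the eddy-viscosity analogy ``RSS = mu_t * gamma_dot``; ``TSS = VSS +
RSS`` pointwise.  Turbulence fields (k, eddy viscosity) are inputs,
produced upstream by a RANS closure, or estimated from velocity ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GeometryError
from .flowmri import PlaneROI

__all__ = [
    "RheologyParams",
    "FlowField3D",
    "carreau_yasuda",
    "velocity_gradients",
    "stress_decomposition",
    "tke_from_ensemble",
    "helicity_lnh",
    "reynolds_numbers",
    "summarize",
    "flowfield_from_mri",
]

#: Product |v|*|omega| below which LNH is reported as 0 and flagged, SI units.
LNH_EPS = 1e-12


@dataclass
class RheologyParams:
    """Carreau-Yasuda blood rheology parameters.

    eta(gamma_dot) = eta_inf + (eta0 - eta_inf) *
                     [1 + (lam * gamma_dot)**a]**((n - 1) / a)

    Defaults are the standard human-blood fit used in aortic CFD:
    eta0 = 0.16 Pa s, eta_inf = 0.0035 Pa s, lam = 8.2 s, a = 0.64,
    n = 0.2128, with a constant density of 1060 kg/m^3.
    """

    eta0: float = 0.16
    eta_inf: float = 0.0035
    lam: float = 8.2
    a: float = 0.64
    n: float = 0.2128
    rho: float = 1060.0

    def __post_init__(self):
        if not self.eta0 >= self.eta_inf > 0:
            raise ValueError("require eta0 >= eta_inf > 0")
        if self.lam <= 0 or self.a <= 0:
            raise ValueError("lam and a must be positive")
        if self.rho <= 0:
            raise ValueError("rho must be positive")

    @classmethod
    def newtonian(cls, eta: float = 0.0035, rho: float = 1060.0) -> "RheologyParams":
        return cls(eta0=eta, eta_inf=eta, lam=1.0, a=2.0, n=1.0, rho=rho)


@dataclass
class FlowField3D:
    """Velocity (and optional turbulence) fields on a uniform structured grid.

    ``velocity`` is ``(n0, n1, n2, 3)`` in m/s; ``spacing`` in m.  ``tke_k``
    (m^2/s^2) and ``eddy_viscosity`` (Pa s) are optional upstream RANS
    outputs; ``mask`` flags in-domain points (all-true by default).
    """

    velocity: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    tke_k: np.ndarray | None = None
    eddy_viscosity: np.ndarray | None = None
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.velocity.ndim != 4 or self.velocity.shape[-1] != 3:
            raise ValueError("velocity must be (n0, n1, n2, 3)")
        if not np.all(np.isfinite(self.velocity)):
            raise ValueError("velocity must be finite")
        if self.mask is None:
            self.mask = np.ones(self.velocity.shape[:3], dtype=bool)
        else:
            self.mask = np.asarray(self.mask).astype(bool)
        if self.tke_k is not None:
            self.tke_k = np.asarray(self.tke_k, dtype=float)
            if np.any(self.tke_k[self.mask] < 0):
                raise ValueError("tke_k must be non-negative")
        if self.eddy_viscosity is not None:
            self.eddy_viscosity = np.asarray(self.eddy_viscosity, dtype=float)
            if np.any(self.eddy_viscosity[self.mask] < 0):
                raise ValueError("eddy_viscosity must be non-negative")


def flowfield_from_mri(
    velocity_mm_s: np.ndarray,
    spacing_mm: Sequence[float],
    origin_mm: Sequence[float] = (0.0, 0.0, 0.0),
    mask: np.ndarray | None = None,
) -> FlowField3D:
    """Convert an MRI-side velocity volume (mm, mm/s) to an SI flow field."""
    return FlowField3D(
        velocity=np.asarray(velocity_mm_s, dtype=float) / 1000.0,
        spacing=np.asarray(spacing_mm, dtype=float) / 1000.0,
        origin=np.asarray(origin_mm, dtype=float) / 1000.0,
        mask=mask,
    )


def carreau_yasuda(gamma_dot: np.ndarray | float, params: RheologyParams) -> np.ndarray | float:
    """Shear-rate dependent viscosity, Pa s.

    Monotone non-increasing in the shear rate for ``n < 1``; tends to
    ``eta0`` at zero shear and ``eta_inf`` at high shear.
    """
    g = np.asarray(gamma_dot, dtype=float)
    if np.any(g < 0):
        raise ValueError("shear rate must be non-negative")
    eta = params.eta_inf + (params.eta0 - params.eta_inf) * (
        1.0 + (params.lam * g) ** params.a
    ) ** ((params.n - 1.0) / params.a)
    return eta if eta.ndim else float(eta)


def _masked_gradient(f: np.ndarray, axis: int, h: float, mask: np.ndarray) -> np.ndarray:
    """d f / d x_axis with central differences where both neighbours are in
    the mask, one-sided differences at domain/mask boundaries, 0 where the
    point is isolated along the axis."""
    fwd = np.roll(f, -1, axis=axis)
    bwd = np.roll(f, 1, axis=axis)
    m_fwd = np.roll(mask, -1, axis=axis)
    m_bwd = np.roll(mask, 1, axis=axis)
    # rolled-over edges are outside the domain
    edge_lo = [slice(None)] * f.ndim
    edge_lo[axis] = slice(0, 1)
    edge_hi = [slice(None)] * f.ndim
    edge_hi[axis] = slice(-1, None)
    m_fwd = m_fwd.copy()
    m_bwd = m_bwd.copy()
    m_fwd[tuple(edge_hi[: mask.ndim])] = False
    m_bwd[tuple(edge_lo[: mask.ndim])] = False

    both = m_fwd & m_bwd
    only_f = m_fwd & ~m_bwd
    only_b = m_bwd & ~m_fwd
    out = np.zeros_like(f)
    out[both] = (fwd[both] - bwd[both]) / (2.0 * h)
    out[only_f] = (fwd[only_f] - f[only_f]) / h
    out[only_b] = (f[only_b] - bwd[only_b]) / h
    return out


def velocity_gradients(
    flow: FlowField3D,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Velocity-gradient tensor, strain-rate tensor, shear rate, vorticity.

    Returns ``(G, S, gamma_dot, omega)`` where ``G[..., i, j] = d v_i / d
    x_j``, ``S = (G + G^T) / 2``, ``gamma_dot = sqrt(2 S:S)`` (1/s) and
    ``omega = curl(v)`` (1/s).  Central differences in the interior,
    one-sided at domain and mask boundaries; exact for fields affine in
    space.
    """
    if any(s < 3 for s in flow.velocity.shape[:3]):
        raise GeometryError("need at least 3 grid points along every axis")
    mask = flow.mask
    G = np.zeros(flow.velocity.shape[:3] + (3, 3))
    for i in range(3):
        for j in range(3):
            G[..., i, j] = _masked_gradient(
                flow.velocity[..., i], axis=j, h=float(flow.spacing[j]), mask=mask
            )
    S = 0.5 * (G + np.swapaxes(G, -1, -2))
    gamma_dot = np.sqrt(2.0 * np.einsum("...ij,...ij->...", S, S))
    omega = np.stack(
        [
            G[..., 2, 1] - G[..., 1, 2],
            G[..., 0, 2] - G[..., 2, 0],
            G[..., 1, 0] - G[..., 0, 1],
        ],
        axis=-1,
    )
    return G, S, gamma_dot, omega


def stress_decomposition(
    flow: FlowField3D, params: RheologyParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise viscous, Reynolds and total scalar shear stress, Pa.

    ``VSS = eta(gamma_dot) * gamma_dot``; ``RSS = mu_t * gamma_dot`` (zero
    when no eddy-viscosity field is present); ``TSS = VSS + RSS``.
    """
    if params is None:
        raise ValueError("rheology parameters are required")
    _, _, gamma_dot, _ = velocity_gradients(flow)
    vss = carreau_yasuda(gamma_dot, params) * gamma_dot
    if flow.eddy_viscosity is not None:
        rss = flow.eddy_viscosity * gamma_dot
    else:
        rss = np.zeros_like(vss)
    return vss, rss, vss + rss


def tke_from_ensemble(realizations: Sequence[np.ndarray]) -> np.ndarray:
    """Turbulent kinetic energy from an ensemble of velocity fields.

    ``k = (1/2) (<u'^2> + <v'^2> + <w'^2>)`` with fluctuations about the
    ensemble mean (unbiased variance).  All realizations must share a grid.
    """
    if len(realizations) < 2:
        raise ValueError("need at least 2 realizations")
    stack = np.stack([np.asarray(r, dtype=float) for r in realizations])
    if any(r.shape != stack.shape[1:] for r in map(np.asarray, realizations)):
        raise ValueError("realizations must share one grid")
    var = stack.var(axis=0, ddof=1)
    return 0.5 * var.sum(axis=-1)


def helicity_lnh(flow: FlowField3D) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Helicity density and local normalized helicity.

    ``H = v . omega`` (m/s^2) and ``LNH = H / (|v| |omega|)`` in [-1, 1];
    positive LNH marks right-handed swirl.  Where ``|v||omega|`` is below a
    degeneracy threshold LNH is reported as 0 and flagged.  Returns
    ``(H, LNH, degenerate_flags)``.
    """
    _, _, _, omega = velocity_gradients(flow)
    h = np.einsum("...i,...i->...", flow.velocity, omega)
    denom = np.linalg.norm(flow.velocity, axis=-1) * np.linalg.norm(omega, axis=-1)
    degenerate = denom < LNH_EPS
    lnh = np.where(degenerate, 0.0, h / np.where(degenerate, 1.0, denom))
    lnh = np.clip(lnh, -1.0, 1.0)
    return h, lnh, degenerate


def reynolds_numbers(
    flow: FlowField3D, diameter: float, params: RheologyParams
) -> tuple[float, float]:
    """Volume-averaged and maximum pointwise Reynolds number.

    ``Re(x) = rho * |v(x)| * D / eta(gamma_dot(x))`` with the local
    Carreau-Yasuda viscosity; statistics are taken over the mask.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    _, _, gamma_dot, _ = velocity_gradients(flow)
    speed = np.linalg.norm(flow.velocity, axis=-1)
    re = params.rho * speed * diameter / carreau_yasuda(gamma_dot, params)
    re_masked = re[flow.mask]
    return float(re_masked.mean()), float(re_masked.max())


def _sample_plane(
    values: np.ndarray, flow: FlowField3D, plane: PlaneROI
) -> tuple[np.ndarray, np.ndarray]:
    """Trilinearly sample a scalar volume on a plane ROI (plane in mm)."""
    _, _, pts_mm = plane.sample_coords()
    idx = (pts_mm / 1000.0 - flow.origin) / flow.spacing
    shape = np.array(values.shape)
    inside = np.all((idx >= 0) & (idx <= shape - 1), axis=-1)
    coords = idx.reshape(-1, 3).T
    sampled = ndimage.map_coordinates(
        values, coords, order=1, mode="constant", cval=0.0
    ).reshape(idx.shape[:2])
    mask_val = ndimage.map_coordinates(
        flow.mask.astype(float), coords, order=1, mode="constant", cval=0.0
    ).reshape(idx.shape[:2])
    return sampled, inside & (mask_val >= 0.5)


def summarize(
    fields: Sequence[FlowField3D],
    times: Sequence[float],
    rois: Sequence[PlaneROI],
    params: RheologyParams,
) -> pd.DataFrame:
    """Per-ROI, per-time area averages of the bulk-flow quantities.

    Returns a long-format table with columns ``roi, t_s, quantity, value``
    covering speed (mm/s), VSS/RSS/TSS (Pa), TKE (m^2/s^2), helicity
    (m/s^2) and mean LNH.  ROIs that do not intersect the domain at a
    frame are flagged (NaN) and excluded from downstream use.
    """
    rows = []
    for t, flow in zip(times, fields):
        vss, rss, tss = stress_decomposition(flow, params)
        h, lnh, _ = helicity_lnh(flow)
        speed_mm = np.linalg.norm(flow.velocity, axis=-1) * 1000.0
        quantities = {
            "speed_mm_s": speed_mm,
            "vss_pa": vss,
            "rss_pa": rss,
            "tss_pa": tss,
            "helicity_m_s2": h,
            "lnh": lnh,
        }
        if flow.tke_k is not None:
            quantities["tke_m2_s2"] = flow.tke_k
        for roi in rois:
            flags = None
            for name, vol in quantities.items():
                sampled, in_dom = _sample_plane(vol, flow, roi)
                flags = in_dom if flags is None else flags
                value = float(sampled[in_dom].mean()) if in_dom.any() else float("nan")
                rows.append({"roi": roi.label, "t_s": t, "quantity": name, "value": value})
    return pd.DataFrame(rows)
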
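"""MRI-versus-model validation statistics.

The model is validated by pairing area-averaged velocity curves on a set of
analysis planes between the reference (measured MRI) and the candidate
(simulated) fields at every MRI timeframe, pooling all planes into one
ordinary least-squares regression, and inspecting bias against the
identity line.  Measurement noise is visualised as a symmetric band around
the reference curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError
from .flowmri import TimeCurve

__all__ = [
    "RegressionResult",
    "pair_curves",
    "regress",
    "noise_band",
    "bias_check",
    "scatter_plot",
]


@dataclass
class RegressionResult:
    """OLS fit of candidate on reference values."""

    slope: float
    intercept: float      # mm/s
    r_squared: float
    p_value: float
    n: int

    def __post_init__(self):
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared outside [0, 1]")
        if self.n < 3:
            raise ValueError("need at least 3 pairs")


def pair_curves(
    reference: list[TimeCurve], candidate: list[TimeCurve]
) -> pd.DataFrame:
    """Pair reference and candidate curves by label at reference times.

    Candidate curves are resampled linearly in time onto the reference
    frame times; the result has one row per (ROI, frame) with columns
    ``roi, t_s, reference, candidate``, pooled across ROIs.
    """
    cand_by_label = {c.label: c for c in candidate}
    missing = [r.label for r in reference if r.label not in cand_by_label]
    if missing:
        raise ValueError(f"candidate curves missing for labels: {missing}")
    rows = []
    for ref in reference:
        cand = cand_by_label[ref.label]
        resampled = np.interp(ref.times, cand.times, cand.values)
        for t, rv, cv in zip(ref.times, ref.values, resampled):
            rows.append(
                {"roi": ref.label, "t_s": t, "reference": rv, "candidate": cv}
            )
    return pd.DataFrame(rows)


def regress(pairs: pd.DataFrame) -> RegressionResult:
    """OLS of candidate on reference with R**2 and the slope's p-value."""
    x = pairs["reference"].to_numpy(dtype=float)
    y = pairs["candidate"].to_numpy(dtype=float)
    if len(x) < 3:
        raise EstimationError("need at least 3 pairs to regress")
    if np.var(x) == 0:
        raise EstimationError("reference values have zero variance")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(x),
    )


def noise_band(sigma: float, curve: TimeCurve) -> tuple[TimeCurve, TimeCurve]:
    """Symmetric noise band of half-width ``sigma`` (mm/s) around a curve."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    return curve.shifted(-sigma), curve.shifted(sigma)


def scatter_plot(pairs: pd.DataFrame, path: str, result: RegressionResult | None = None):
    """Save a reference-vs-candidate scatter with the identity line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for roi, group in pairs.groupby("roi"):
        ax.scatter(group["reference"], group["candidate"], s=12, label=str(roi))
    lim = [0.0, float(pairs[["reference", "candidate"]].to_numpy().max()) * 1.05]
    ax.plot(lim, lim, "--", color="grey", label="x = y")
    ax.set_xlabel("MRI area-averaged velocity (mm/s)")
    ax.set_ylabel("model area-averaged velocity (mm/s)")
    if result is not None:
        ax.set_title(f"R² = {result.r_squared:.3f}, n = {result.n}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def bias_check(pairs: pd.DataFrame) -> tuple[float, float]:
    """Mean signed difference and fraction of points above the identity line.

    Ties (candidate exactly equal to reference) count one half, so an
    unbiased identical pairing reports a fraction of 0.5.
    """
    if len(pairs) < 1:
        raise EstimationError("no pairs to check")
    diff = pairs["candidate"].to_numpy(dtype=float) - pairs["reference"].to_numpy(dtype=float)
    above = float(np.mean(np.where(diff > 0, 1.0, np.where(diff < 0, 0.0, 0.5))))
    return float(diff.mean()), above
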
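"""Detection of signal-dependent noise (SDN) in ROI time series.

If a constant-variance autoregressive model fits the signal, its squared
residuals carry no information about the lagged signal strength.  The test
here regresses the signal under one of three residual models (linear AR, AR
plus a squared-lag term, or a 6th-order Fourier curve in the lagged signal),
forms pairs of squared lagged signal and squared residual, filters 3-sigma
outliers, and reports the Pearson correlation.  A significant positive
correlation is evidence of SDN and invalidates constant-variance causality
models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SDNTestResult",
    "BinnedProfile",
    "ar_fit_residuals",
    "sdn_pairs",
    "sdn_test",
    "binned_profile",
]

ModelKind = Literal["ar", "ar_quadratic", "fourier6"]


@dataclass(frozen=True)
class SDNTestResult:
    model_kind: str
    pairs_offered: int
    pairs_used: int
    correlation: float
    p_value: float
    ar_order: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.correlation <= 1.0:
            raise ValueError("correlation must lie in [-1, 1]")
        if self.pairs_used > self.pairs_offered:
            raise ValueError("pairs_used cannot exceed pairs offered")


def _lag_matrix(x: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Response x[order:] and design of lagged values (no intercept —
    segments are demeaned)."""
    n = len(x)
    if n <= order + 2:
        raise ValueError("series too short for the requested AR order")
    y = x[order:]
    design = np.column_stack([x[order - i : n - i] for i in range(1, order + 1)])
    return y, design


def ar_fit_residuals(series: Sequence[float], order: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares AR(order) fit; returns (residuals, coefficients).

    Residuals are defined for t > order.  A constant series produces a
    singular design and raises.
    """
    x = np.asarray(series, dtype=float)
    y, design = _lag_matrix(x, order)
    if np.allclose(design.std(axis=0), 0.0):
        raise np.linalg.LinAlgError("constant series: singular AR design")
    coeffs, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coeffs
    return resid, coeffs


def _residuals(x: np.ndarray, model_kind: ModelKind, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Residuals u_t and the aligned lag-1 signal X_{t-1} for one series."""
    x = np.asarray(x, dtype=float)
    if model_kind == "ar":
        resid, _ = ar_fit_residuals(x, order)
        lag1 = x[order - 1 : -1]
    elif model_kind == "ar_quadratic":
        y, design = _lag_matrix(x, order)
        design = np.column_stack([design, design[:, 0] ** 2])
        coeffs, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coeffs
        lag1 = x[order - 1 : -1]
    elif model_kind == "fourier6":
        # Nonlinear curve fit of X_t on X_{t-1}: 6th-order Fourier series with
        # the lagged signal rescaled to [0, 2*pi].
        y = x[1:]
        z = x[:-1]
        span = z.max() - z.min()
        if span <= 0:
            raise np.linalg.LinAlgError("constant series: Fourier fit undefined")
        phi = 2 * np.pi * (z - z.min()) / span
        cols = [np.ones_like(phi)]
        for k in range(1, 7):
            cols.append(np.sin(k * phi))
            cols.append(np.cos(k * phi))
        design = np.column_stack(cols)
        coeffs, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coeffs
        lag1 = z
    else:
        raise ValueError(f"unknown model_kind {model_kind!r}")
    return resid, lag1


def sdn_pairs(
    series: Sequence[float], model_kind: ModelKind = "ar", order: int = 1
) -> np.ndarray:
    """Pairs (X^2_{t-1}, u^2_t) for one series under the chosen residual model."""
    resid, lag1 = _residuals(np.asarray(series, dtype=float), model_kind, order)
    return np.column_stack([lag1**2, resid**2])


def sdn_test(
    series: Sequence[float] | Iterable[Sequence[float]],
    model_kind: ModelKind = "ar",
    order: int = 1,
    pooled: bool = False,
) -> SDNTestResult:
    """Correlation between squared residuals and the squared lagged signal.

    With ``pooled=True``, ``series`` is an iterable of per-region series whose
    pairs are pooled before testing.  Pairs in which either coordinate lies
    more than 3 SDs from its mean are filtered out (single pass, each
    coordinate marginally).
    """
    if pooled:
        pairs = np.vstack([sdn_pairs(s, model_kind, order) for s in series])
    else:
        pairs = sdn_pairs(series, model_kind, order)
    offered = pairs.shape[0]
    if np.allclose(pairs[:, 1], 0.0):
        raise ValueError("degenerate residuals: series is perfectly predictable")
    mean = pairs.mean(axis=0)
    sd = pairs.std(axis=0, ddof=1)
    keep = np.all(np.abs(pairs - mean) <= 3.0 * np.where(sd > 0, sd, np.inf), axis=1)
    kept = pairs[keep]
    if kept.shape[0] < 10:
        raise ValueError(f"only {kept.shape[0]} pairs survive outlier filtering (< 10)")
    r, p = stats.pearsonr(kept[:, 0], kept[:, 1])
    return SDNTestResult(
        model_kind=model_kind,
        pairs_offered=offered,
        pairs_used=int(kept.shape[0]),
        correlation=float(r),
        p_value=float(p),
        ar_order=order,
    )


@dataclass(frozen=True)
class BinnedProfile:
    """Binned noise-versus-signal profile and its linear fit.

    ``bin_centers`` are the geometric midpoints (for plotting);
    ``bin_x_means`` the within-bin mean signal strengths, which the line is
    fit against so that an exactly linear noise-signal relation is recovered
    exactly regardless of how points distribute inside bins.
    """

    bin_centers: np.ndarray
    bin_x_means: np.ndarray
    bin_means: np.ndarray  # NaN for empty bins
    bin_ses: np.ndarray
    bin_counts: np.ndarray
    slope: float
    intercept: float


def binned_profile(pairs: np.ndarray, n_bins: int = 7) -> BinnedProfile:
    """Bin squared lagged-signal strengths into equal-width bins and summarize
    the squared-residual level per bin, with a least-squares line through the
    non-empty bin means."""
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[0] == 0:
        raise ValueError("pairs must be a non-empty (n, 2) array")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x2, u2 = pairs[:, 0], pairs[:, 1]
    edges = np.linspace(x2.min(), x2.max(), n_bins + 1)
    # np.digitize puts the right edge in the last bin
    idx = np.clip(np.digitize(x2, edges[1:-1]), 0, n_bins - 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    x_means = np.full(n_bins, np.nan)
    means = np.full(n_bins, np.nan)
    ses = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = u2[idx == b]
        counts[b] = sel.size
        if sel.size:
            x_means[b] = x2[idx == b].mean()
            means[b] = sel.mean()
            ses[b] = sel.std(ddof=1) / np.sqrt(sel.size) if sel.size > 1 else 0.0
    ok = ~np.isnan(means)
    if ok.sum() >= 2 and np.ptp(x_means[ok]) > 0:
        slope, intercept = np.polyfit(x_means[ok], means[ok], 1)
    else:
        slope, intercept = np.nan, np.nan
    return BinnedProfile(
        centers, x_means, means, ses, counts, float(slope), float(intercept)
    )
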
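"""Voxelwise T1/T2 parametric mapping of magnitude image series.

T1 is estimated per voxel from an inversion-recovery series with the
magnitude signal model

    S(TI) = S0 · |1 − (1 + d)·e^(−TI/T1) + e^(−TR/T1)|,

where d is the inversion efficiency scale factor (d = 1 for a perfect 180°
pulse), and T2 from a multi-echo series with

    S(TE) = S0 · e^(−TE/T2).

The absolute-value model is fitted directly (magnitude data never recover
signal polarity), which makes the objective non-convex around the signal
null; a coarse multi-start over T1 avoids the null-point local minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ImageSeries",
    "VoxelFit",
    "ParametricMap",
    "ir_signal",
    "se_signal",
    "fit_t1_voxel",
    "fit_t2_voxel",
    "map_volume",
    "roi_statistics",
    "normalized_intensity",
]

T1_BOUNDS_MS = (1.0, 20000.0)
T2_BOUNDS_MS = (1.0, 5000.0)
D_BOUNDS = (0.0, 1.2)
T1_STARTS_MS = (50.0, 200.0, 800.0, 2000.0)


@dataclass
class ImageSeries:
    """Stack of magnitude volumes indexed by TI or TE.

    data has shape (rows, cols, slices, n_index); index_ms holds the TI or
    TE values in milliseconds, strictly increasing.
    """

    data: np.ndarray
    index_ms: np.ndarray
    tr_ms: float
    field_T: float
    mode: str  # "inversion_recovery" or "echo_decay"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.index_ms = np.asarray(self.index_ms, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (rows, cols, slices, index)")
        if self.data.shape[-1] != self.index_ms.size:
            raise ValueError("last data axis must match the TI/TE list")
        if np.any(self.index_ms <= 0) or np.any(np.diff(self.index_ms) <= 0):
            raise ValueError("TI/TE values must be positive and strictly increasing")
        if np.any(self.data < 0):
            raise ValueError("magnitude data must be non-negative")
        if self.mode not in ("inversion_recovery", "echo_decay"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def spatial_shape(self):
        return self.data.shape[:3]


@dataclass
class VoxelFit:
    """Single-voxel relaxation fit."""

    T_ms: float
    S0: float
    d: float | None
    residual_norm: float
    converged: bool


@dataclass
class ParametricMap:
    """Per-voxel fit results aligned to the source ImageSeries grid."""

    T_ms: np.ndarray
    S0: np.ndarray
    d: np.ndarray | None
    residual_norm: np.ndarray
    converged: np.ndarray
    mask: np.ndarray
    mode: str
    field_T: float

    @property
    def spatial_shape(self):
        return self.T_ms.shape


def ir_signal(TI_ms, TR_ms, T1_ms, S0=1.0, d=1.0):
    """Magnitude inversion-recovery signal S0·|1 − (1+d)e^(−TI/T1) + e^(−TR/T1)|."""
    T1_ms = np.asarray(T1_ms, dtype=float)
    if np.any(T1_ms <= 0):
        raise ValueError("T1 must be positive")
    TI = np.asarray(TI_ms, dtype=float)
    out = S0 * np.abs(1.0 - (1.0 + d) * np.exp(-TI / T1_ms) + np.exp(-TR_ms / T1_ms))
    return out if out.ndim else float(out)


def se_signal(TE_ms, T2_ms, S0=1.0):
    """Mono-exponential echo decay S0·e^(−TE/T2)."""
    T2_ms = np.asarray(T2_ms, dtype=float)
    if np.any(T2_ms <= 0):
        raise ValueError("T2 must be positive")
    out = S0 * np.exp(-np.asarray(TE_ms, dtype=float) / T2_ms)
    return out if out.ndim else float(out)


def _near_bound(value, bounds, rel=1e-3):
    lo, hi = bounds
    span = hi - lo
    return value - lo < rel * span / 1e3 + 1e-9 or hi - value < rel * span


def fit_t1_voxel(ti_ms, signal, tr_ms, fit_d: bool = True, d_fixed: float = 1.0) -> VoxelFit:
    """Nonlinear least-squares fit of the magnitude IR model to one voxel.

    Multi-start over a coarse T1 grid guards against the local minimum the
    absolute value creates around the signal null.  With fit_d=False the
    inversion factor is frozen at ``d_fixed``.
    """
    ti = np.asarray(ti_ms, dtype=float)
    sig = np.asarray(signal, dtype=float)
    if ti.size < 4:
        raise ValueError("need at least 4 inversion times")
    if ti.shape != sig.shape:
        raise ValueError("TI and signal must have the same length")
    if np.allclose(sig, 0.0):
        raise ValueError("all-zero signal cannot be fitted")

    s0_init = max(float(np.max(sig)), 1e-12)
    s0_hi = 10.0 * s0_init

    best = None
    for t1_start in T1_STARTS_MS:
        if fit_d:
            def resid(p):
                return ir_signal(ti, tr_ms, p[0], p[1], p[2]) - sig
            x0 = [t1_start, s0_init, 1.0]
            lb = [T1_BOUNDS_MS[0], 0.0, D_BOUNDS[0]]
            ub = [T1_BOUNDS_MS[1], s0_hi, D_BOUNDS[1]]
        else:
            def resid(p):
                return ir_signal(ti, tr_ms, p[0], p[1], d_fixed) - sig
            x0 = [t1_start, s0_init]
            lb = [T1_BOUNDS_MS[0], 0.0]
            ub = [T1_BOUNDS_MS[1], s0_hi]
        res = least_squares(resid, x0, bounds=(lb, ub), x_scale=[t1_start, s0_init] + ([1.0] if fit_d else []))
        if best is None or res.cost < best.cost:
            best = res

    t1 = float(best.x[0])
    s0 = float(best.x[1])
    dval = float(best.x[2]) if fit_d else float(d_fixed)
    converged = bool(best.success) and not _near_bound(t1, T1_BOUNDS_MS)
    # unidentifiable fit: the model curve shows no TI dependence (e.g. a
    # constant signal absorbed by T1 far below the first TI, or T1 -> inf)
    model = ir_signal(ti, tr_ms, t1, s0, dval)
    if np.ptp(model) < 1e-6 * max(np.max(model), 1e-12):
        converged = False
    return VoxelFit(T_ms=t1, S0=s0, d=dval,
                    residual_norm=float(np.sqrt(2.0 * best.cost)),
                    converged=converged)


def fit_t2_voxel(te_ms, signal) -> VoxelFit:
    """Nonlinear least-squares mono-exponential T2 fit for one voxel.

    Initialized from a log-linear regression on the positive samples, then
    refined on the untransformed data.
    """
    te = np.asarray(te_ms, dtype=float)
    sig = np.asarray(signal, dtype=float)
    if te.size < 3:
        raise ValueError("need at least 3 echo times")
    if te.shape != sig.shape:
        raise ValueError("TE and signal must have the same length")
    if np.allclose(sig, 0.0):
        raise ValueError("all-zero signal cannot be fitted")

    pos = sig > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(te[pos], np.log(sig[pos]), 1)
        t2_init = float(np.clip(-1.0 / slope if slope < 0 else T2_BOUNDS_MS[1] / 2,
                                *T2_BOUNDS_MS))
        s0_init = float(np.exp(intercept))
    else:
        t2_init, s0_init = 100.0, float(np.max(sig))

    def resid(p):
        return se_signal(te, p[0], p[1]) - sig

    res = least_squares(
        resid, [t2_init, max(s0_init, 1e-12)],
        bounds=([T2_BOUNDS_MS[0], 0.0], [T2_BOUNDS_MS[1], 10.0 * max(np.max(sig), s0_init)]),
    )
    t2 = float(res.x[0])
    converged = bool(res.success) and not _near_bound(t2, T2_BOUNDS_MS)
    return VoxelFit(T_ms=t2, S0=float(res.x[1]), d=None,
                    residual_norm=float(np.sqrt(2.0 * res.cost)),
                    converged=converged)


def _estimate_noise_sigma(series: ImageSeries) -> float:
    """Rayleigh noise estimate from the image border (assumed signal-free)."""
    border = np.concatenate([
        series.data[0, :, :, :].ravel(),
        series.data[-1, :, :, :].ravel(),
        series.data[:, 0, :, :].ravel(),
        series.data[:, -1, :, :].ravel(),
    ])
    # for magnitude noise alone, E[s²] = 2 sigma²
    return float(np.sqrt(np.mean(border**2) / 2.0))


def map_volume(series: ImageSeries, mask=None, noise_sigma=None,
               fit_d: bool = True) -> ParametricMap:
    """Fit the matching relaxation model in every masked voxel.

    Without an explicit mask, voxels whose maximum signal is below five
    times the background noise estimate are excluded from fitting.  Voxels
    that fail to converge are flagged in the map, not dropped.
    """
    shape = series.spatial_shape
    if mask is None:
        if noise_sigma is None:
            noise_sigma = _estimate_noise_sigma(series)
        peak = series.data.max(axis=-1)
        mask = peak >= max(5.0 * noise_sigma, 1e-12)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError("mask shape must match the series spatial shape")

    T = np.full(shape, np.nan)
    S0 = np.full(shape, np.nan)
    dmap = np.full(shape, np.nan) if series.mode == "inversion_recovery" else None
    resid = np.full(shape, np.nan)
    conv = np.zeros(shape, dtype=bool)

    for idx in np.argwhere(mask):
        i, j, k = idx
        sig = series.data[i, j, k, :]
        try:
            if series.mode == "inversion_recovery":
                vf = fit_t1_voxel(series.index_ms, sig, series.tr_ms, fit_d=fit_d)
                dmap[i, j, k] = vf.d
            else:
                vf = fit_t2_voxel(series.index_ms, sig)
        except ValueError:
            continue
        T[i, j, k] = vf.T_ms
        S0[i, j, k] = vf.S0
        resid[i, j, k] = vf.residual_norm
        conv[i, j, k] = vf.converged

    return ParametricMap(T_ms=T, S0=S0, d=dmap, residual_norm=resid,
                         converged=conv, mask=mask, mode=series.mode,
                         field_T=series.field_T)


def roi_statistics(volume, mask):
    """(mean, sample SD, n) over the masked voxels of a volume."""
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    vals = volume[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("empty ROI")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return mean, sd, int(vals.size)


def normalized_intensity(roi_means, reference=None):
    """ROI means divided by a reference (default: the maximum mean)."""
    means = np.asarray(roi_means, dtype=float)
    ref = float(np.max(means)) if reference is None else float(reference)
    if ref <= 0:
        raise ValueError("reference must be positive")
    return means / ref
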
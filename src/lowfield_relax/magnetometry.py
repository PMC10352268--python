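"""Langevin analysis of magnetization curves.

A monodisperse superparamagnetic particle suspension at thermal equilibrium
magnetizes along an applied field B according to

    M(B) = Ms · L(mu·B / kB·T),      L(x) = coth(x) − 1/x,

where Ms is the mass saturation magnetization (A·m²/kg) and mu the magnetic
moment of a single particle (J/T).  Fitting M(B) therefore yields Ms and mu;
mu converts to an effective magnetic diameter through the volumetric
saturation magnetization of the core material,

    d_mag = (6·mu / (pi · Ms_vol))^(1/3).

The magnetic diameter is typically smaller than the physical core diameter
because of spin canting and crystalline defects at the particle surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .constants import BOLTZMANN, MAGNETITE_DENSITY_KG_M3, ROOM_TEMPERATURE_K

__all__ = [
    "langevin",
    "magnetization_model",
    "MagnetizationCurve",
    "LangevinFit",
    "fit_langevin",
    "magnetic_diameter",
    "moment_from_diameter",
    "propagate_ms_error",
    "saturation_fraction",
]

_SERIES_CUTOFF = 1e-3


def langevin(x):
    """Langevin function L(x) = coth(x) − 1/x, stable through x = 0.

    Below |x| = 1e-3 the Taylor series x/3 − x³/45 is used: its truncation
    error there (≈ 2x⁵/945 < 3e-18) is far below the cancellation error of
    the direct formula, which loses ~1e-12 absolute accuracy by x = 1e-4.
    """
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < _SERIES_CUTOFF
    xs = np.where(small, 1.0, x)  # avoid 0-division in the masked branch
    direct = 1.0 / np.tanh(xs) - 1.0 / xs
    series = x / 3.0 - x**3 / 45.0
    out = np.where(small, series, direct)
    return out if out.ndim else float(out)


def magnetization_model(B, Ms, mu, temperature=ROOM_TEMPERATURE_K):
    """Langevin magnetization Ms·L(mu·B/kB·T).

    Parameters
    ----------
    B : array_like, applied field in tesla.
    Ms : saturation magnetization (any magnetization unit; A·m²/kg here).
    mu : per-particle magnetic moment, J/T.
    temperature : K.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return Ms * langevin(mu * np.asarray(B, dtype=float) / (BOLTZMANN * temperature))


@dataclass
class MagnetizationCurve:
    """M(B) data with acquisition temperature."""

    fields_T: np.ndarray
    M_Am2_per_kg: np.ndarray
    temperature_K: float = ROOM_TEMPERATURE_K
    label: str = ""

    def __post_init__(self):
        self.fields_T = np.asarray(self.fields_T, dtype=float)
        self.M_Am2_per_kg = np.asarray(self.M_Am2_per_kg, dtype=float)
        if self.fields_T.shape != self.M_Am2_per_kg.shape:
            raise ValueError("fields and magnetization must have the same shape")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class LangevinFit:
    """Result of a single-population Langevin fit."""

    Ms: float
    Ms_se: float
    mu: float
    mu_se: float
    magnetic_diameter_nm: float
    temperature_K: float
    residual_norm: float
    n_points: int
    converged: bool = True
    density_kg_m3: float = field(default=MAGNETITE_DENSITY_KG_M3, repr=False)


def fit_langevin(
    curve: MagnetizationCurve,
    density_kg_m3: float = MAGNETITE_DENSITY_KG_M3,
) -> LangevinFit:
    """Least-squares fit of a single Langevin function to an M(B) curve.

    Initial values come from the curve itself: Ms from the largest |M|,
    mu from the low-field slope (M ≈ Ms·mu·B/3kB·T).  The field grid should
    extend far enough to constrain the saturation plateau (|B|max ≥ 2 T).
    """
    B = curve.fields_T
    M = curve.M_Am2_per_kg
    T = curve.temperature_K
    if np.allclose(M, 0.0):
        raise ValueError("degenerate all-zero magnetization curve")

    ms0 = float(np.max(np.abs(M)))
    nz = np.abs(B) > 0
    # low-field slope estimate, restricted to the weakest quartile of fields
    order = np.argsort(np.abs(B[nz]))
    bl = B[nz][order][: max(3, nz.sum() // 4)]
    ml = M[nz][order][: max(3, nz.sum() // 4)]
    slope = float(np.polyfit(bl, ml, 1)[0]) if bl.size >= 2 else ms0
    mu0 = abs(3.0 * BOLTZMANN * T * slope / ms0) if slope != 0 else 1e-19
    mu0 = min(max(mu0, 1e-22), 1e-16)

    def resid(p):
        return magnetization_model(B, p[0], p[1], T) - M

    res = least_squares(
        resid,
        x0=[ms0, mu0],
        bounds=([0.0, 1e-24], [np.inf, 1e-14]),
        x_scale=[max(ms0, 1e-3), mu0],
    )
    ms, mu = res.x
    dof = max(B.size - 2, 1)
    # covariance from the Jacobian at the solution
    try:
        jtj = res.jac.T @ res.jac
        cov = np.linalg.inv(jtj) * 2.0 * res.cost / dof
        ses = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        ses = np.array([np.nan, np.nan])
    return LangevinFit(
        Ms=float(ms),
        Ms_se=float(ses[0]),
        mu=float(mu),
        mu_se=float(ses[1]),
        magnetic_diameter_nm=magnetic_diameter(mu, ms * density_kg_m3),
        temperature_K=T,
        residual_norm=float(np.sqrt(2.0 * res.cost)),
        n_points=int(B.size),
        converged=bool(res.success),
        density_kg_m3=density_kg_m3,
    )


def magnetic_diameter(mu: float, Ms_volumetric: float) -> float:
    """Effective magnetic diameter (nm) of a sphere of moment mu (J/T).

    Ms_volumetric is the volumetric saturation magnetization in A/m
    (mass Ms × material density).
    """
    if mu <= 0 or Ms_volumetric <= 0:
        raise ValueError("moment and volumetric Ms must be positive")
    d_m = (6.0 * mu / (np.pi * Ms_volumetric)) ** (1.0 / 3.0)
    return d_m * 1e9


def moment_from_diameter(d_nm: float, Ms_volumetric: float) -> float:
    """Inverse of :func:`magnetic_diameter`: moment (J/T) of a d_nm sphere."""
    if d_nm <= 0 or Ms_volumetric <= 0:
        raise ValueError("diameter and volumetric Ms must be positive")
    return (np.pi / 6.0) * (d_nm * 1e-9) ** 3 * Ms_volumetric


def propagate_ms_error(moment, sd_moment, conc, sd_conc):
    """Saturation magnetization with quadrature error propagation.

    Ms is a quotient of a magnetometry moment and an independently measured
    iron content, so its relative uncertainty combines both sources:

        sd_Ms / Ms = sqrt((sd_moment/moment)² + (sd_conc/conc)²).

    Returns (Ms, sd_Ms) with Ms = moment / conc.
    """
    if moment <= 0 or conc <= 0:
        raise ValueError("central values must be positive")
    ms = moment / conc
    rel = np.sqrt((sd_moment / moment) ** 2 + (sd_conc / conc) ** 2)
    return ms, ms * rel


def saturation_fraction(fit, B: float, temperature: float = ROOM_TEMPERATURE_K) -> float:
    """Fraction of saturation L(mu·B/kB·T) reached at field B.

    ``fit`` may be a LangevinFit (its mu is used) or a bare moment in J/T.
    """
    mu = getattr(fit, "mu", fit)
    return float(langevin(mu * B / (BOLTZMANN * temperature)))
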
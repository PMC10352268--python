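"""Relaxivity estimation from concentration series of relaxation rates.

The relaxivity r1 (or r2) of a contrast agent is the slope of the linear
relation between relaxation rate and metal concentration,

    1/T = 1/T' + r · [CM],

with T' the relaxation time of the agent-free matrix.  This module fits that
line, applies the low-field measurement exclusion rule (fitted T1 below the
first inversion time cannot be trusted and is removed from all fits for that
agent), rescales nominal concentrations to assayed stock concentrations, and
computes the derived comparison metrics (r2/r1 ratio, fold enhancement over
a reference agent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy import stats

__all__ = [
    "ConcentrationSeries",
    "RelaxivityFit",
    "rescale_concentrations",
    "apply_exclusion_rule",
    "fit_relaxivity",
    "relaxivity_ratio",
    "fold_enhancement",
    "t1_at_concentration",
    "report_round",
]


def rescale_concentrations(nominal, stock_nominal: float, stock_measured: float):
    """Rescale label concentrations by the assayed/nominal stock ratio."""
    if stock_nominal <= 0 or stock_measured <= 0:
        raise ValueError("stock concentrations must be positive")
    out = np.asarray(nominal, dtype=float) * (stock_measured / stock_nominal)
    return out if out.ndim else float(out)


def apply_exclusion_rule(t1_ms_values, first_ti_ms: float):
    """Indices whose fitted T1 passes the first-inversion-time check.

    A fitted T1 below the first inversion time of the protocol cannot be
    measured reliably, so that concentration is excluded — and, by the
    consistency convention, excluded from every other (field × channel) fit
    for the same agent.

    Returns (included_indices, reasons) where ``reasons`` maps each excluded
    index to a human-readable explanation.
    """
    t1 = np.asarray(t1_ms_values, dtype=float)
    if t1.size == 0:
        raise ValueError("empty T1 list")
    included, reasons = [], {}
    for i, v in enumerate(t1):
        if np.isfinite(v) and v >= first_ti_ms:
            included.append(i)
        else:
            reasons[i] = (
                f"fitted T1 = {v:.1f} ms below first inversion time "
                f"{first_ti_ms:.0f} ms"
            )
    return included, reasons


@dataclass
class ConcentrationSeries:
    """Per-concentration relaxation rates for one agent/field/channel."""

    agent: str
    field_T: float
    channel: str                      # "R1" or "R2"
    conc_nominal_mM: np.ndarray
    conc_actual_mM: np.ndarray
    rate_s: np.ndarray
    rate_sd: np.ndarray | None = None
    included: np.ndarray | None = None
    exclusion_reason: dict = field(default_factory=dict)

    def __post_init__(self):
        self.conc_nominal_mM = np.asarray(self.conc_nominal_mM, dtype=float)
        self.conc_actual_mM = np.asarray(self.conc_actual_mM, dtype=float)
        self.rate_s = np.asarray(self.rate_s, dtype=float)
        n = self.conc_nominal_mM.size
        if self.conc_actual_mM.size != n or self.rate_s.size != n:
            raise ValueError("concentration and rate arrays must align")
        if self.channel not in ("R1", "R2"):
            raise ValueError("channel must be 'R1' or 'R2'")
        if self.included is None:
            self.included = np.ones(n, dtype=bool)
        else:
            self.included = np.asarray(self.included, dtype=bool)
        for i in np.nonzero(~self.included)[0]:
            self.exclusion_reason.setdefault(int(i), "excluded")


@dataclass
class RelaxivityFit:
    """Ordinary least-squares relaxivity fit."""

    r: float                     # slope, L·mmol⁻¹·s⁻¹
    intercept: float             # s⁻¹, estimates the matrix rate 1/T'
    r_se: float
    intercept_se: float
    n_used: int
    excluded: tuple = ()


def fit_relaxivity(series: ConcentrationSeries) -> RelaxivityFit:
    """OLS slope/intercept of rate versus actual concentration (included rows)."""
    inc = series.included & np.isfinite(series.rate_s)
    if inc.sum() < 2:
        raise ValueError(
            f"{series.agent} {series.channel}@{series.field_T} T: "
            f"fewer than 2 included concentrations"
        )
    x = series.conc_actual_mM[inc]
    y = series.rate_s[inc]
    if np.allclose(x, x[0]):
        raise ValueError("concentrations are degenerate (no spread)")
    res = stats.linregress(x, y)
    return RelaxivityFit(
        r=float(res.slope),
        intercept=float(res.intercept),
        r_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
        n_used=int(inc.sum()),
        excluded=tuple(int(i) for i in np.nonzero(~inc)[0]),
    )


def relaxivity_ratio(r2, r1, r2_se=0.0, r1_se=0.0):
    """r2/r1 with its standard error propagated in quadrature.

    Accepts RelaxivityFit objects or bare numbers.
    """
    r2v, r2e = (r2.r, r2.r_se) if isinstance(r2, RelaxivityFit) else (float(r2), r2_se)
    r1v, r1e = (r1.r, r1.r_se) if isinstance(r1, RelaxivityFit) else (float(r1), r1_se)
    if r1v <= 0:
        raise ValueError("r1 must be positive")
    ratio = r2v / r1v
    se = abs(ratio) * np.sqrt((r2e / r2v) ** 2 + (r1e / r1v) ** 2) if r2v else 0.0
    return ratio, se


def fold_enhancement(r_agent: float, r_reference: float) -> float:
    """How many times larger one relaxivity is than a reference relaxivity."""
    if r_reference <= 0:
        raise ValueError("reference relaxivity must be positive")
    return float(r_agent) / float(r_reference)


def t1_at_concentration(r1: float, baseline_T1_ms: float, conc_mM: float) -> float:
    """Predicted T1 (ms) at a given concentration from a known relaxivity."""
    if baseline_T1_ms <= 0:
        raise ValueError("baseline T1 must be positive")
    if conc_mM < 0:
        raise ValueError("concentration must be non-negative")
    rate = 1000.0 / baseline_T1_ms + r1 * conc_mM  # s⁻¹
    return 1000.0 / rate


def report_round(x: float, ndigits: int = 1) -> float:
    """Half-up rounding for report tables (matches printed-table convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
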
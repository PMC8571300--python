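"""Xrn1 decay kinetics: control normalization, exponential rate fits,
reporter-control relative rates and structure-function correlations.

The exonuclease-resistance assay follows the loss of fluorescence of a
malachite-green (MG) aptamer appended downstream of the RNA element as
Xrn1 degrades it.  Each experimental (+Xrn1) trace is normalized to a
parallel no-enzyme control,

    F(t) = (F_exp(t) / F_exp(0)) / (F_con(t) / F_con(0)),

which cancels any instrument drift shared by the two channels, and the
normalized trace is fitted with a single exponential to give the decay
rate.  Construct rates are reported relative to the bare MG-aptamer
control at the matched Mg2+ concentration, which corrects for the Mg2+
dependence of Xrn1 activity itself.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress, pearsonr

from .trace import DecayTrace

__all__ = [
    "normalize_decay",
    "fit_decay_rate",
    "relative_rate",
    "correlate",
    "DecayFit",
    "RelativeRate",
    "CorrelationReport",
]


def normalize_decay(trace: DecayTrace) -> np.ndarray:
    """Control-normalized fluorescence; F(0) = 1 exactly.

    Time points where the control reads zero are masked as NaN with a
    warning.
    """
    if trace.f_exp[0] <= 0 or trace.f_con[0] <= 0:
        raise ValueError("t=0 fluorescence must be positive in both channels")
    con = trace.f_con
    bad = con == 0
    if np.any(bad):
        warnings.warn(f"{bad.sum()} control points are zero; masked", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (trace.f_exp / trace.f_exp[0]) / (con / con[0])
    f[bad] = np.nan
    return f


@dataclass
class DecayFit:
    """Single-exponential fit of a normalized decay trace."""

    rate: float  # 1/min
    se: float
    amplitude: float
    plateau: float
    r_squared: float
    flags: list = field(default_factory=list)


def fit_decay_rate(
    time_min,
    f_norm,
    plateau_free: bool = False,
    fit_start_min: float = 0.0,
) -> DecayFit:
    """Least-squares single-exponential fit F(t) = p + (1-p)*exp(-k*t).

    The plateau p is fixed at 0 by default (a pure single exponential);
    ``plateau_free=True`` frees it, which is appropriate for strongly
    resistant constructs whose fluorescence levels off at the protected
    fraction.  ``fit_start_min`` trims an initial window (e.g. the
    pre-enzyme binding period) before fitting.
    """
    t = np.asarray(time_min, dtype=float)
    f = np.asarray(f_norm, dtype=float)
    keep = np.isfinite(f) & (t >= fit_start_min)
    t, f = t[keep] - fit_start_min, f[keep]
    if len(t) < 5:
        raise ValueError("at least 5 points are required for the decay fit")

    flags = []
    f_end = np.mean(f[-max(3, len(f) // 10):])
    k0 = 1e-3
    if 0 < f_end < 1:
        k0 = max(-math.log(max(f_end, 1e-6)) / max(t[-1], 1e-9), 1e-6)

    if plateau_free:
        model = lambda tt, k, p: p + (1.0 - p) * np.exp(-k * tt)
        p0, bounds = (k0, max(min(f_end, 0.99), 0.0)), ([0.0, 0.0], [np.inf, 1.0])
    else:
        model = lambda tt, k: np.exp(-k * tt)
        p0, bounds = (k0,), ([-1e-6], [np.inf])
    try:
        popt, pcov = curve_fit(model, t, f, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"decay fit did not converge: {exc}") from exc
    rate = float(popt[0])
    plateau = float(popt[1]) if plateau_free else 0.0
    se = float(np.sqrt(pcov[0, 0]))
    resid = f - model(t, *popt)
    ss_tot = np.sum((f - f.mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid**2) / ss_tot) if ss_tot > 0 else 1.0
    if rate < 0:
        flags.append("negative_rate")
    return DecayFit(
        rate=max(rate, 0.0) if abs(rate) < 1e-12 else rate,
        se=se,
        amplitude=1.0 - plateau,
        plateau=plateau,
        r_squared=r2,
        flags=flags,
    )


@dataclass
class RelativeRate:
    """Construct decay rate divided by the MG-aptamer control rate."""

    value: float
    se: float
    mg_mM: float | None = None


def relative_rate(
    construct_fit: DecayFit, control_fit: DecayFit, mg_mM: float | None = None
) -> RelativeRate:
    """Ratio of construct to control decay rates with propagated s.e."""
    if control_fit.rate <= 0:
        raise ValueError("control decay rate must be positive")
    ratio = construct_fit.rate / control_fit.rate
    if construct_fit.rate > 0:
        rel = math.sqrt(
            (construct_fit.se / construct_fit.rate) ** 2
            + (control_fit.se / control_fit.rate) ** 2
        )
        se = ratio * rel
    else:
        se = construct_fit.se / control_fit.rate
    return RelativeRate(value=ratio, se=se, mg_mM=mg_mM)


@dataclass
class CorrelationReport:
    """Pearson correlation between two paired quantities."""

    r: float
    p_value: float
    slope: float
    intercept: float
    n: int
    log_x: bool = False
    log_y: bool = False


def correlate(
    x, y, log_x: bool = False, log_y: bool = False
) -> CorrelationReport:
    """Pearson correlation (optionally on log axes) with a fitted slope.

    Used for the structure-function analyses: decay rates against
    H-state fractions, transition rates or free-energy differences,
    pooled across constructs and Mg2+ conditions.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("at least 3 paired finite values are required")
    if log_x:
        if np.any(x <= 0):
            raise ValueError("log_x requires positive x")
        x = np.log10(x)
    if log_y:
        if np.any(y <= 0):
            raise ValueError("log_y requires positive y")
        y = np.log10(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the series")
    r, p = pearsonr(x, y)
    reg = linregress(x, y)
    return CorrelationReport(
        r=float(r),
        p_value=float(p),
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        n=len(x),
        log_x=log_x,
        log_y=log_y,
    )
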
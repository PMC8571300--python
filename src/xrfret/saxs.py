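"""Minimal SAXS metrics for foldedness classification.

Guinier analysis fits ln I(q) = ln I(0) - (q*Rg)^2/3 over the low-q
window, yielding the radius of gyration Rg and forward scattering I(0);
the dimensionless Kratky transform (q*Rg)^2 * I(q)/I(0) versus q*Rg is
the standard parameter-free representation in which compactly folded
RNA shows a bell-shaped peak (at sqrt(3), height 3/e, for an ideal
globular scatterer) while unfolded chains plateau or rise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace import ScatteringCurve

__all__ = ["guinier_fit", "dimensionless_kratky", "GuinierResult", "KratkyCurve", "GuinierError"]


class GuinierError(ValueError):
    pass


@dataclass
class GuinierResult:
    """Guinier fit: Rg (Angstrom), I(0), their standard errors, and the
    self-consistent low-q window actually used."""

    rg: float
    rg_se: float
    i0: float
    i0_se: float
    q_min: float
    q_max: float
    n_points: int
    q_rg_max: float


def _weighted_linfit(x, y, w):
    """Weighted least squares y = a + b*x; returns (a, b, se_a, se_b)."""
    sw = w.sum()
    mx = (w * x).sum() / sw
    my = (w * y).sum() / sw
    sxx = (w * (x - mx) ** 2).sum()
    b = (w * (x - mx) * (y - my)).sum() / sxx
    a = my - b * mx
    # parameter variances from the weight model (weights = 1/sigma^2)
    se_b = np.sqrt(1.0 / sxx)
    se_a = np.sqrt(1.0 / sw + mx**2 / sxx)
    return a, b, se_a, se_b


def guinier_fit(
    curve: ScatteringCurve,
    qrg_limit: float = 1.3,
    min_points: int = 5,
    max_iter: int = 50,
) -> GuinierResult:
    """Self-consistent Guinier fit over the largest valid low-q window.

    Weighted linear regression of ln I on q^2 over the window
    q*Rg <= ``qrg_limit`` (the community convention for compact
    particles), iterated until the window stabilizes.  A non-negative
    slope means the data have no Guinier region.
    """
    pos = curve.intensity > 0
    q = curve.q[pos]
    i = curve.intensity[pos]
    sig = curve.sigma[pos] if curve.sigma is not None else None
    if len(q) < min_points:
        raise GuinierError("too few positive-intensity points")

    y = np.log(i)
    x = q**2
    # sigma(ln I) = sigma/I; fall back to unit weights without errors
    w_all = (i / sig) ** 2 if sig is not None and np.all(sig > 0) else np.ones_like(i)

    n_win = max(min_points, min(10, len(q)))
    prev = -1
    for _ in range(max_iter):
        a, b, se_a, se_b = _weighted_linfit(x[:n_win], y[:n_win], w_all[:n_win])
        if b >= 0:
            raise GuinierError("no Guinier region (non-negative slope)")
        rg = float(np.sqrt(-3.0 * b))
        q_limit = qrg_limit / rg
        n_new = int(np.searchsorted(q, q_limit, side="right"))
        n_new = max(min_points, min(n_new, len(q)))
        if n_new == prev or n_new == n_win:
            n_win = n_new
            break
        prev, n_win = n_win, n_new
    a, b, se_a, se_b = _weighted_linfit(x[:n_win], y[:n_win], w_all[:n_win])
    if b >= 0:
        raise GuinierError("no Guinier region (non-negative slope)")
    rg = float(np.sqrt(-3.0 * b))
    rg_se = float(1.5 * se_b / rg)  # delta method on Rg = sqrt(-3b)
    i0 = float(np.exp(a))
    return GuinierResult(
        rg=rg,
        rg_se=rg_se,
        i0=i0,
        i0_se=float(i0 * se_a),
        q_min=float(q[0]),
        q_max=float(q[n_win - 1]),
        n_points=n_win,
        q_rg_max=float(q[n_win - 1] * rg),
    )


@dataclass
class KratkyCurve:
    """Dimensionless Kratky transform: x = q*Rg, y = x^2 * I(q)/I(0)."""

    x: np.ndarray
    y: np.ndarray


def dimensionless_kratky(curve: ScatteringCurve, guinier: GuinierResult) -> KratkyCurve:
    """Pointwise dimensionless Kratky transform of a scattering curve.

    The transform is invariant to global intensity rescaling and, for an
    ideal Guinier curve, independent of Rg (peak at sqrt(3), height 3/e).
    """
    x = curve.q * guinier.rg
    y = x**2 * curve.intensity / guinier.i0
    return KratkyCurve(x=x, y=y)
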
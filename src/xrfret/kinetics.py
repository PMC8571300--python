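"""Dwell-time kinetics, transition rates, free-energy landscapes,
transition density plots, Hill titration fits and the critical Mg2+.

The estimator chain follows the classical dwell-counting scheme: runs of
identical hidden-state labels become dwells, every observed state change
is a transition event, state lifetimes tau come from exponential fits of
the uncensored dwell distributions, and the six rate constants are

    k_XY = (1 / tau_X) * n_XY / (n_XY + n_XZ)

i.e. the inverse lifetime of the departing state split by the observed
branching fractions.  By construction k_XY + k_XZ = 1/tau_X exactly.
Relative state free energies follow from rate ratios,
dG_b - dG_a = -kBT * ln(k_ab / k_ba), with L as the ground state, and
illustrative barrier heights are drawn as -kBT*ln(k_ab) + 1.8 kBT.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, curve_fit
from scipy.stats import linregress, pearsonr

from .trace import STATE_LABELS, IdealizedTrace

__all__ = [
    "DwellRecord",
    "TransitionCounts",
    "LifetimeSet",
    "RateSet",
    "EnergyLandscape",
    "TDP",
    "HillFit",
    "CriticalMg",
    "extract_dwells",
    "fit_lifetimes",
    "transition_rates",
    "build_tdp",
    "free_energy_landscape",
    "fractional_populations",
    "fit_hill",
    "critical_mg",
]

#: Boltzmann constant in kcal/(mol*K)
KB_KCAL = 1.987204259e-3
#: offset of the illustrative barrier convention, in units of kBT
BARRIER_OFFSET_KBT = 1.8

_PAIRS = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]


def _pair_name(i: int, j: int) -> str:
    return f"{STATE_LABELS[i]}{STATE_LABELS[j]}".lower()


@dataclass
class DwellRecord:
    """One continuous residence in a state.

    The first and last dwell of every trace are censored (their true
    length is unknown) and are excluded from lifetime fits.
    """

    state: int
    duration: float
    trace_id: str = ""
    censored_start: bool = False
    censored_end: bool = False

    @property
    def censored(self) -> bool:
        return self.censored_start or self.censored_end

    @property
    def label(self) -> str:
        return STATE_LABELS[self.state]


@dataclass
class TransitionCounts:
    """Counts of observed transitions between the three states."""

    matrix: np.ndarray = field(default_factory=lambda: np.zeros((3, 3), dtype=int))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=int)
        if self.matrix.shape != (3, 3):
            raise ValueError("counts matrix must be 3x3")
        if np.any(self.matrix < 0):
            raise ValueError("counts must be non-negative")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("self-transitions are not counted")

    def n(self, a, b) -> int:
        ia = STATE_LABELS.index(a) if isinstance(a, str) else a
        ib = STATE_LABELS.index(b) if isinstance(b, str) else b
        return int(self.matrix[ia, ib])

    def exits(self, a) -> int:
        ia = STATE_LABELS.index(a) if isinstance(a, str) else a
        return int(self.matrix[ia].sum())

    def as_dict(self) -> dict[str, int]:
        return {f"n_{_pair_name(i, j)}": int(self.matrix[i, j]) for i, j in _PAIRS}

    @property
    def total(self) -> int:
        return int(self.matrix.sum())


def extract_dwells(idealized_traces) -> tuple[list[DwellRecord], TransitionCounts]:
    """Run-length encode idealized traces into dwells and transitions.

    Consecutive frames with the same label merge into one dwell of
    duration n_frames * frame_interval.  Every observed state change is
    one transition event; the first and last dwell of each trace are
    flagged censored.  Frames with an invalid label (masked FRET) split
    the trace and censor the adjacent dwells.
    """
    dwells: list[DwellRecord] = []
    counts = np.zeros((3, 3), dtype=int)
    for tr in idealized_traces:
        dt = tr.frame_interval
        states = tr.states
        # split on invalid frames so censoring is honest around gaps
        valid = states >= 0
        boundaries = np.flatnonzero(np.diff(valid.astype(int)) != 0) + 1
        for chunk in np.split(np.arange(len(states)), boundaries):
            if len(chunk) == 0 or not valid[chunk[0]]:
                continue
            seg = states[chunk]
            change = np.flatnonzero(np.diff(seg) != 0) + 1
            bounds = np.concatenate([[0], change, [len(seg)]])
            n_runs = len(bounds) - 1
            for r in range(n_runs):
                s = int(seg[bounds[r]])
                dur = (bounds[r + 1] - bounds[r]) * dt
                dwells.append(
                    DwellRecord(
                        state=s,
                        duration=dur,
                        trace_id=tr.trace_id,
                        censored_start=(r == 0),
                        censored_end=(r == n_runs - 1),
                    )
                )
                if r > 0:
                    counts[int(seg[bounds[r - 1]]), s] += 1
    return dwells, TransitionCounts(matrix=counts)


@dataclass
class LifetimeSet:
    """State lifetimes tau_L, tau_I, tau_H (s) from dwell distributions."""

    tau: np.ndarray
    se: np.ndarray
    n_dwells: np.ndarray
    method: str = "mle"
    flags: list = field(default_factory=list)

    def tau_of(self, state) -> float:
        i = STATE_LABELS.index(state) if isinstance(state, str) else state
        return float(self.tau[i])

    def as_dict(self) -> dict[str, float]:
        return {f"tau_{lbl}": float(t) for lbl, t in zip(STATE_LABELS, self.tau)}


def fit_lifetimes(
    dwells,
    method: str = "mle",
    min_dwells: int = 25,
    bin_width: float | None = None,
) -> LifetimeSet:
    """Exponential fit of the uncensored dwell distribution per state.

    ``method='mle'`` uses the closed-form maximum-likelihood estimate
    (tau = mean dwell, s.e. = tau/sqrt(n)); ``method='binned'`` fits
    A*exp(-t/tau) to the binned dwell histogram by least squares.  A
    state with no uncensored dwells gets tau = NaN and a flag; states
    with fewer than ``min_dwells`` dwells are fitted anyway with a
    warning.
    """
    flags = []
    tau = np.full(3, np.nan)
    se = np.full(3, np.nan)
    n_used = np.zeros(3, dtype=int)
    for s in range(3):
        durs = np.array(
            [d.duration for d in dwells if d.state == s and not d.censored]
        )
        n_used[s] = len(durs)
        if len(durs) == 0:
            flags.append(f"no_uncensored_dwells_{STATE_LABELS[s]}")
            continue
        if len(durs) < min_dwells:
            warnings.warn(
                f"only {len(durs)} uncensored {STATE_LABELS[s]} dwells "
                f"(< {min_dwells}); lifetime is noisy",
                stacklevel=2,
            )
        if np.ptp(durs) == 0:
            # all dwells share one duration: resolution-limited
            tau[s] = durs[0]
            se[s] = durs[0] / math.sqrt(len(durs))
            flags.append(f"resolution_limited_{STATE_LABELS[s]}")
            continue
        if method == "mle":
            tau[s] = durs.mean()
            se[s] = tau[s] / math.sqrt(len(durs))
        elif method == "binned":
            bw = bin_width or max(np.median(durs) / 5, durs.min())
            edges = np.arange(0, durs.max() + bw, bw)
            counts, _ = np.histogram(durs, bins=edges)
            centers = 0.5 * (edges[:-1] + edges[1:])
            keep = counts > 0
            p0 = (counts.max(), durs.mean())
            popt, pcov = curve_fit(
                lambda t, a, tt: a * np.exp(-t / tt),
                centers[keep],
                counts[keep],
                p0=p0,
                maxfev=10000,
            )
            tau[s] = popt[1]
            se[s] = float(np.sqrt(pcov[1, 1]))
        else:
            raise ValueError(f"unknown lifetime method {method!r}")
    return LifetimeSet(tau=tau, se=se, n_dwells=n_used, method=method, flags=flags)


@dataclass
class RateSet:
    """The six transition rate constants (1/s) with uncertainties.

    Built from a :class:`LifetimeSet` and :class:`TransitionCounts` via
    the branching-fraction equations; the algebraic identity
    k_XY + k_XZ = 1/tau_X holds exactly for every state with exits.
    """

    matrix: np.ndarray
    se: np.ndarray
    lifetimes: LifetimeSet
    counts: TransitionCounts
    flags: list = field(default_factory=list)

    def k(self, a, b) -> float:
        ia = STATE_LABELS.index(a) if isinstance(a, str) else a
        ib = STATE_LABELS.index(b) if isinstance(b, str) else b
        return float(self.matrix[ia, ib])

    def as_dict(self) -> dict[str, float]:
        return {f"k_{_pair_name(i, j)}": float(self.matrix[i, j]) for i, j in _PAIRS}

    def se_dict(self) -> dict[str, float]:
        return {f"k_{_pair_name(i, j)}_se": float(self.se[i, j]) for i, j in _PAIRS}


def transition_rates(lifetimes: LifetimeSet, counts: TransitionCounts) -> RateSet:
    """Apply the six branching-fraction rate equations literally.

    For each state X with partners Y, Z:
    k_XY = (1/tau_X) * n_XY / (n_XY + n_XZ).  A state with no observed
    exits gets both rates 0 with a flag; a missing lifetime combined
    with nonzero exit counts is an error.
    """
    k = np.zeros((3, 3))
    se = np.zeros((3, 3))
    flags = list(lifetimes.flags)
    for x in range(3):
        n_x = counts.matrix[x].sum()
        if n_x == 0:
            flags.append(f"no_exits_{STATE_LABELS[x]}")
            continue
        tau_x = lifetimes.tau[x]
        if not np.isfinite(tau_x):
            raise ValueError(
                f"lifetime of state {STATE_LABELS[x]} undefined but "
                f"{n_x} exits were observed"
            )
        for y in range(3):
            if y == x:
                continue
            p = counts.matrix[x, y] / n_x
            k[x, y] = p / tau_x
            if counts.matrix[x, y] > 0:
                rel_tau = (lifetimes.se[x] / tau_x) ** 2
                rel_branch = (1 - p) / counts.matrix[x, y]  # binomial
                se[x, y] = k[x, y] * math.sqrt(rel_tau + rel_branch)
    return RateSet(matrix=k, se=se, lifetimes=lifetimes, counts=counts, flags=flags)


@dataclass
class TDP:
    """Transition density plot: 2D histogram of transition events.

    Each observed transition contributes one count at (mean FRET of the
    departing dwell, mean FRET of the arriving dwell); the matrix is
    normalized by the total number of transitions.
    """

    density: np.ndarray
    edges: np.ndarray
    n_transitions: int

    def mass_in(self, initial_range, final_range) -> float:
        """Fraction of transitions inside a rectangular FRET region."""
        c = 0.5 * (self.edges[:-1] + self.edges[1:])
        sel_i = (c >= initial_range[0]) & (c < initial_range[1])
        sel_f = (c >= final_range[0]) & (c < final_range[1])
        return float(self.density[np.ix_(sel_i, sel_f)].sum())


def build_tdp(idealized_traces, bin_width: float = 0.02) -> TDP:
    """Construct the transition density plot from idealized traces."""
    initial, final = [], []
    for tr in idealized_traces:
        states = tr.states
        valid = states >= 0
        boundaries = np.flatnonzero(np.diff(valid.astype(int)) != 0) + 1
        for chunk in np.split(np.arange(len(states)), boundaries):
            if len(chunk) == 0 or not valid[chunk[0]]:
                continue
            seg = states[chunk]
            fret = tr.fret[chunk]
            change = np.flatnonzero(np.diff(seg) != 0) + 1
            bounds = np.concatenate([[0], change, [len(seg)]])
            run_means = [
                np.nanmean(fret[bounds[r] : bounds[r + 1]])
                for r in range(len(bounds) - 1)
            ]
            initial.extend(run_means[:-1])
            final.extend(run_means[1:])
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    if not initial:
        warnings.warn("no transitions observed; TDP is empty", stacklevel=2)
        return TDP(density=np.zeros((n_bins, n_bins)), edges=edges, n_transitions=0)
    h, _, _ = np.histogram2d(
        np.clip(initial, 0, 1), np.clip(final, 0, 1), bins=(edges, edges)
    )
    return TDP(density=h / h.sum(), edges=edges, n_transitions=len(initial))


@dataclass
class EnergyLandscape:
    """Relative state free energies and illustrative barriers (kcal/mol).

    L is the ground state (dG_L = 0); dG_I comes from the L<->I rate
    pair and dG_H adds the I<->H pair (the sequential folding pathway).
    ``closure_residual`` is the detailed-balance diagnostic: the
    difference between dG_H computed directly from the H<->L pair and
    the sequential value (zero, within estimation error, when the
    underlying kinetics satisfy detailed balance).  Barriers follow the
    plotting convention -kBT*ln(k) + 1.8 kBT with rates in 1/s; the
    L->H barrier is not drawn because the direct rate is too rarely
    sampled to be reliable.
    """

    dg: np.ndarray  # (dG_L=0, dG_I, dG_H)
    barriers: dict
    temperature: float
    kbt: float
    closure_residual: float

    def dg_of(self, state) -> float:
        i = STATE_LABELS.index(state) if isinstance(state, str) else state
        return float(self.dg[i])


def barrier_height(k_ab: float, temperature: float = 298.15) -> float:
    """Illustrative barrier -kBT*ln(k_ab) + 1.8 kBT, in kcal/mol (k in 1/s)."""
    if k_ab <= 0:
        raise ValueError("rate must be positive for a barrier height")
    kbt = KB_KCAL * temperature
    return -kbt * math.log(k_ab) + BARRIER_OFFSET_KBT * kbt


def free_energy_landscape(rates: RateSet, temperature: float = 298.15) -> EnergyLandscape:
    """Relative free energies from rate-constant ratios.

    Requires the four sequential-pathway rates k_LI, k_IL, k_IH, k_HI
    to be positive; raises naming the offending rate otherwise.
    """
    kbt = KB_KCAL * temperature
    required = {"k_li": rates.k(0, 1), "k_il": rates.k(1, 0),
                "k_ih": rates.k(1, 2), "k_hi": rates.k(2, 1)}
    for name, v in required.items():
        if v <= 0:
            raise ValueError(f"rate {name} must be positive to compute the landscape")
    dg_i = -kbt * math.log(required["k_li"] / required["k_il"])
    dg_h = dg_i - kbt * math.log(required["k_ih"] / required["k_hi"])
    if rates.k(0, 2) > 0 and rates.k(2, 0) > 0:
        dg_h_direct = -kbt * math.log(rates.k(0, 2) / rates.k(2, 0))
        closure = dg_h_direct - dg_h
    else:
        closure = float("nan")
    barriers = {}
    for i, j in _PAIRS:
        if (i, j) == (0, 2):  # direct L->H rate is not used for a barrier
            continue
        kk = rates.k(i, j)
        if kk > 0:
            barriers[f"{STATE_LABELS[i]}->{STATE_LABELS[j]}"] = barrier_height(
                kk, temperature
            )
    return EnergyLandscape(
        dg=np.array([0.0, dg_i, dg_h]),
        barriers=barriers,
        temperature=temperature,
        kbt=kbt,
        closure_residual=closure,
    )


def fractional_populations(source, condition=None):
    """Fractional population of (L, I, H).

    ``source`` may be a list of :class:`IdealizedTrace` (frame-occupancy
    fractions over all valid frames) or a
    :class:`~xrfret.idealize.StatePopulations` (mixture weights).
    Returns (fractions, provenance).
    """
    from .idealize import StatePopulations

    if isinstance(source, StatePopulations):
        return np.asarray(source.fractions, dtype=float), "mixture_weights"
    counts = np.zeros(3)
    for tr in source:
        valid = tr.states >= 0
        counts += np.bincount(tr.states[valid], minlength=3)[:3]
    if counts.sum() == 0:
        raise ValueError("no valid frames")
    return counts / counts.sum(), "frame_occupancy"


@dataclass
class HillFit:
    """Hill-equation fit of a fractional population vs Mg2+.

    f(c) = baseline + amplitude * c^n / (K^n + c^n); a decreasing
    titration is fitted with negative amplitude.
    """

    amplitude: float
    k_mid: float
    n_hill: float
    baseline: float
    se: dict
    state: str | None = None
    flags: list = field(default_factory=list)

    def __call__(self, c):
        c = np.asarray(c, dtype=float)
        return self.baseline + self.amplitude * c**self.n_hill / (
            self.k_mid**self.n_hill + c**self.n_hill
        )


def _hill(c, baseline, amplitude, k_mid, n_hill):
    return baseline + amplitude * c**n_hill / (k_mid**n_hill + c**n_hill)


def fit_hill(
    mg_concs,
    fractions,
    state: str | None = None,
    allow_intermediate: bool = False,
) -> HillFit:
    """Least-squares Hill fit of a state's fractional population.

    Following the titration-analysis convention, only the H- and
    L-state fractions are fitted; fitting the intermediate state is
    refused unless ``allow_intermediate`` is set.
    """
    if state == "I" and not allow_intermediate:
        raise ValueError(
            "the intermediate-state fraction is conventionally not fitted; "
            "pass allow_intermediate=True to override"
        )
    c = np.asarray(mg_concs, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if len(c) < 4:
        raise ValueError("at least 4 concentrations are required")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive (mM)")
    increasing = f[np.argmax(c)] >= f[np.argmin(c)]
    amp0 = (f.max() - f.min()) * (1 if increasing else -1)
    base0 = f[np.argmin(c)]
    k0 = float(np.exp(np.mean(np.log(c))))
    flags = []
    if abs(amp0) < 1e-3:
        flags.append("flat_data_midpoint_unidentifiable")
    try:
        popt, pcov = curve_fit(
            _hill,
            c,
            f,
            p0=(base0, amp0 if amp0 != 0 else 1e-3, k0, 1.0),
            bounds=([-1.0, -2.0, 1e-9, 0.05], [2.0, 2.0, 1e6, 10.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"Hill fit did not converge: {exc}") from exc
    perr = np.sqrt(np.diag(pcov))
    if abs(popt[1]) < 1e-3:
        flags.append("amplitude_near_zero")
    return HillFit(
        amplitude=float(popt[1]),
        k_mid=float(popt[2]),
        n_hill=float(popt[3]),
        baseline=float(popt[0]),
        se={
            "baseline": float(perr[0]),
            "amplitude": float(perr[1]),
            "k_mid": float(perr[2]),
            "n_hill": float(perr[3]),
        },
        state=state,
        flags=flags,
    )


@dataclass
class CriticalMg:
    """Lowest Mg2+ at which the H fraction exceeds the L fraction."""

    value: float  # mM; +inf when the curves never cross in range
    flag: str | None = None


def critical_mg(
    hill_h: HillFit,
    hill_l: HillFit,
    mg_range=(1e-3, 100.0),
    n_grid: int = 2000,
) -> CriticalMg:
    """Smallest concentration where the fitted H fraction exceeds L.

    Scans the fitted curves on a log grid over ``mg_range`` and refines
    the first upward crossing by bisection.  If H > L over the whole
    range the range minimum is returned (flagged); if H never exceeds L,
    +inf (flagged).
    """
    lo, hi = mg_range
    grid = np.geomspace(lo, hi, n_grid)
    diff = hill_h(grid) - hill_l(grid)
    if diff[0] > 0:
        return CriticalMg(value=float(lo), flag="H_exceeds_L_at_range_minimum")
    above = np.flatnonzero(diff > 0)
    if len(above) == 0:
        return CriticalMg(value=float("inf"), flag="no_crossing_in_range")
    i = above[0]
    root = brentq(lambda c: hill_h(c) - hill_l(c), grid[i - 1], grid[i], xtol=1e-9)
    return CriticalMg(value=float(root))
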
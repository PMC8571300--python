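"""High-level modelling interface.

Each class follows the model/results convention: a model object is
built from data, ``fit()`` runs the estimation and returns a results
object carrying estimates, uncertainties and diagnostics, with a
``summary()`` text table.  The classes are thin compositions of the
functional modules (:mod:`~xrfret.idealize`, :mod:`~xrfret.kinetics`,
:mod:`~xrfret.decay`, :mod:`~xrfret.saxs`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import decay as _decay
from . import idealize as _idealize
from . import kinetics as _kinetics
from . import saxs as _saxs
from .trace import STATE_LABELS


class FoldingKinetics:
    """Three-state folding-kinetics model for an ensemble of smFRET traces.

    Fits one Gaussian-emission HMM shared across all traces of a
    condition, idealizes every trace (Viterbi), and derives dwell-time
    lifetimes, the six transition rate constants, fractional state
    populations, the transition density plot and the relative
    free-energy landscape.

    Parameters
    ----------
    traces : list of :class:`~xrfret.trace.FretTrace`
    n_states : number of conformational states (3: L, I, H).
    temperature : K, used for free energies (default 298.15, i.e. 25 C).
    """

    def __init__(self, traces, n_states: int = 3, temperature: float = 298.15):
        if not traces:
            raise ValueError("at least one trace is required")
        self.traces = list(traces)
        self.n_states = n_states
        self.temperature = temperature

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, frame_interval: float | None = None, **kw):
        """Build from a long-format table with columns trace_id, time_s,
        I_donor, I_acceptor (the trace TSV layout)."""
        from .trace import FretTrace

        traces = []
        for tid, g in df.groupby("trace_id", sort=False):
            t = g["time_s"].to_numpy()
            dt = frame_interval or (float(t[1] - t[0]) if len(t) > 1 else 0.025)
            traces.append(
                FretTrace(
                    time=t,
                    donor=g["I_donor"].to_numpy(),
                    acceptor=g["I_acceptor"].to_numpy(),
                    frame_interval=dt,
                    trace_id=str(tid),
                )
            )
        return cls(traces, **kw)

    def fit(
        self,
        seed=None,
        decoding: str = "viterbi",
        lifetime_method: str = "mle",
        condition=None,
    ) -> "FoldingKineticsResults":
        fret = [_idealize.compute_fret(tr) for tr in self.traces]
        hmm = _idealize.fit_hmm(fret, n_states=self.n_states, seed=seed)
        idealized = [
            _idealize.idealize_trace(
                hmm, f, trace_id=tr.trace_id,
                frame_interval=tr.frame_interval, method=decoding,
            )
            for tr, f in zip(self.traces, fret)
        ]
        dwells, counts = _kinetics.extract_dwells(idealized)
        lifetimes = _kinetics.fit_lifetimes(dwells, method=lifetime_method)
        rates = _kinetics.transition_rates(lifetimes, counts)
        tdp = _kinetics.build_tdp(idealized)
        histogram = _idealize.build_histogram(fret, min_molecules=0)
        try:
            populations = _idealize.fit_state_populations(
                fret, n_states=self.n_states, seed=seed, condition=condition
            )
        except ValueError:
            populations = None
        occupancy, _ = _kinetics.fractional_populations(idealized)
        try:
            landscape = _kinetics.free_energy_landscape(rates, self.temperature)
        except ValueError:
            landscape = None
        return FoldingKineticsResults(
            model=self,
            hmm=hmm,
            idealized=idealized,
            fret=fret,
            dwells=dwells,
            counts=counts,
            lifetimes=lifetimes,
            rates=rates,
            tdp=tdp,
            histogram=histogram,
            populations=populations,
            occupancy=occupancy,
            landscape=landscape,
            condition=condition,
        )


@dataclass
class FoldingKineticsResults:
    """Estimates and diagnostics of a fitted :class:`FoldingKinetics`."""

    model: FoldingKinetics
    hmm: object
    idealized: list
    fret: list
    dwells: list
    counts: object
    lifetimes: object
    rates: object
    tdp: object
    histogram: object
    populations: object
    occupancy: np.ndarray
    landscape: object
    condition: object = None

    def rates_frame(self) -> pd.DataFrame:
        rows = []
        for name, k in self.rates.as_dict().items():
            rows.append({"transition": name, "rate_per_s": k,
                         "se": self.rates.se_dict()[name + "_se"]})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Three-state folding kinetics", "=" * 34]
        lines.append(f"traces: {len(self.model.traces)}   "
                     f"frames: {sum(len(f) for f in self.fret)}")
        if self.condition is not None:
            lines.append(f"condition: {self.condition}")
        lines.append("")
        lines.append("state   E_mean   E_sd    occupancy  lifetime(s)")
        for i, lbl in enumerate(STATE_LABELS[: self.hmm.n_states]):
            tau = self.lifetimes.tau[i] if i < 3 else np.nan
            lines.append(
                f"  {lbl}     {self.hmm.means[i]:6.3f}  {self.hmm.sds[i]:6.3f} "
                f"   {self.occupancy[i]:6.3f}    {tau:8.3f}"
            )
        lines.append("")
        lines.append("transition   k (1/s)      s.e.       n")
        for (i, j) in [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]:
            lines.append(
                f"  {STATE_LABELS[i]}->{STATE_LABELS[j]}      "
                f"{self.rates.matrix[i, j]:9.4f}  {self.rates.se[i, j]:9.4f} "
                f"{self.counts.matrix[i, j]:7d}"
            )
        if self.landscape is not None:
            lines.append("")
            lines.append(
                "free energies (kcal/mol, L ground state): "
                f"dG_I = {self.landscape.dg[1]:+.3f}, "
                f"dG_H = {self.landscape.dg[2]:+.3f}, "
                f"closure residual = {self.landscape.closure_residual:+.3f}"
            )
        return "\n".join(lines)

    def plot_histogram(self, ax=None):
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        h = self.histogram
        ax.bar(h.centers, h.frequencies, width=np.diff(h.edges), color="0.6")
        ax.set_xlabel("FRET efficiency")
        ax.set_ylabel("probability")
        return ax

    def plot_tdp(self, ax=None):
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        ax.imshow(
            self.tdp.density.T, origin="lower", extent=(0, 1, 0, 1),
            aspect="equal", cmap="viridis",
        )
        ax.set_xlabel("initial FRET")
        ax.set_ylabel("final FRET")
        return ax


class XrnDecay:
    """Xrn1 decay-kinetics model for one experimental/control trace pair."""

    def __init__(self, trace, plateau_free: bool = False, fit_start_min: float = 0.0):
        self.trace = trace
        self.plateau_free = plateau_free
        self.fit_start_min = fit_start_min

    def fit(self) -> "XrnDecayResults":
        normalized = _decay.normalize_decay(self.trace)
        fit = _decay.fit_decay_rate(
            self.trace.time_min,
            normalized,
            plateau_free=self.plateau_free,
            fit_start_min=self.fit_start_min,
        )
        return XrnDecayResults(model=self, normalized=normalized, fit=fit)


@dataclass
class XrnDecayResults:
    model: XrnDecay
    normalized: np.ndarray
    fit: object

    @property
    def rate(self) -> float:
        return self.fit.rate

    def relative_to(self, control: "XrnDecayResults", mg_mM=None):
        return _decay.relative_rate(self.fit, control.fit, mg_mM=mg_mM)

    def summary(self) -> str:
        f = self.fit
        cond = self.model.trace.condition
        lines = ["Xrn1 decay kinetics", "=" * 24]
        if cond:
            lines.append(f"condition: {cond}")
        lines.append(f"decay rate: {f.rate:.4f} +/- {f.se:.4f} 1/min")
        lines.append(f"plateau: {f.plateau:.3f}   R^2: {f.r_squared:.4f}")
        if f.flags:
            lines.append(f"flags: {', '.join(f.flags)}")
        return "\n".join(lines)


class GuinierAnalysis:
    """Guinier model for a scattering curve."""

    def __init__(self, curve, qrg_limit: float = 1.3):
        self.curve = curve
        self.qrg_limit = qrg_limit

    def fit(self) -> "GuinierResults":
        res = _saxs.guinier_fit(self.curve, qrg_limit=self.qrg_limit)
        kratky = _saxs.dimensionless_kratky(self.curve, res)
        return GuinierResults(model=self, guinier=res, kratky=kratky)


@dataclass
class GuinierResults:
    model: GuinierAnalysis
    guinier: object
    kratky: object

    def summary(self) -> str:
        g = self.guinier
        return "\n".join(
            [
                "Guinier analysis",
                "=" * 20,
                f"Rg   = {g.rg:.3f} +/- {g.rg_se:.3f} A",
                f"I(0) = {g.i0:.4g} +/- {g.i0_se:.2g}",
                f"window: q in [{g.q_min:.4f}, {g.q_max:.4f}] "
                f"({g.n_points} pts, qRg_max = {g.q_rg_max:.3f})",
            ]
        )
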
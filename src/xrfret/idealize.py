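"""FRET computation, three-state HMM idealization and state populations.

The FRET efficiency per frame is E = I_A / (I_A + I_D) with no gamma or
donor-leakage correction.  A single Gaussian-emission hidden Markov
model is fitted jointly to all traces of a condition (Baum-Welch), each
trace is idealized with the Viterbi path, and state populations are
obtained either as Viterbi frame occupancies or from a three-Gaussian
mixture fit to the pooled FRET values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from hmmlearn.hmm import GaussianHMM
from sklearn.mixture import GaussianMixture

from .trace import STATE_LABELS, FretTrace, IdealizedTrace

__all__ = [
    "compute_fret",
    "detect_bleach",
    "fit_hmm",
    "idealize_trace",
    "build_histogram",
    "fit_state_populations",
    "HmmModel",
    "FretHistogram",
    "StatePopulations",
]


def detect_bleach(
    total: np.ndarray, min_drop_factor: float = 0.5, min_sigma: float = 4.0
) -> int | None:
    """Locate a single-step photobleach in a total-intensity series.

    Finds the two-segment change point minimizing the residual sum of
    squares, and accepts it as a bleach when the post-step mean is below
    ``min_drop_factor`` of the pre-step mean and the step exceeds
    ``min_sigma`` pooled standard deviations.  Returns the index of the
    first post-bleach frame, or None.
    """
    total = np.asarray(total, dtype=float)
    n = len(total)
    if n < 4:
        return None
    csum = np.cumsum(total)
    csum2 = np.cumsum(total**2)
    ks = np.arange(2, n - 1)  # at least 2 frames on each side
    n1 = ks.astype(float)
    n2 = n - n1
    m1 = csum[ks - 1] / n1
    m2 = (csum[-1] - csum[ks - 1]) / n2
    ss1 = csum2[ks - 1] - n1 * m1**2
    ss2 = (csum2[-1] - csum2[ks - 1]) - n2 * m2**2
    cost = ss1 + ss2
    best = int(np.argmin(cost))
    k = int(ks[best])
    pooled_var = cost[best] / max(n - 2, 1)
    pooled_sd = np.sqrt(max(pooled_var, 1e-30))
    drop = m1[best] - m2[best]
    if m2[best] < min_drop_factor * m1[best] and drop > min_sigma * pooled_sd:
        return k
    return None


def compute_fret(
    trace: FretTrace,
    truncate_at_bleach: bool = True,
    clip: bool = True,
) -> np.ndarray:
    """Per-frame FRET efficiency E = I_A / (I_A + I_D).

    Frames at and after a detected photobleach step are excluded (the
    returned array is shortened); frames whose total intensity is zero
    are masked as NaN; values are clipped to [0, 1] (negative
    background-subtracted intensities would otherwise push E outside
    the physical range).
    """
    donor = trace.donor
    acceptor = trace.acceptor
    total = donor + acceptor
    if not np.any(total > 0):
        raise ValueError("trace has no frame with positive total intensity")
    if truncate_at_bleach:
        k = detect_bleach(total)
        if k is not None:
            donor, acceptor, total = donor[:k], acceptor[:k], total[:k]
    with np.errstate(divide="ignore", invalid="ignore"):
        fret = acceptor / total
    fret[total == 0] = np.nan
    if clip:
        fret = np.clip(fret, 0.0, 1.0)
    return fret


@dataclass
class HmmModel:
    """Fitted Gaussian-emission HMM, states sorted by ascending mean.

    State 0/1/2 correspond to the L/I/H conformations.  ``transmat`` is
    the per-frame transition probability matrix and ``history`` the
    Baum-Welch log-likelihood trajectory (non-decreasing).
    """

    means: np.ndarray
    sds: np.ndarray
    transmat: np.ndarray
    startprob: np.ndarray
    log_likelihood: float
    converged: bool
    history: list = field(default_factory=list)
    flags: list = field(default_factory=list)
    n_states: int = 3

    def _hmm(self) -> GaussianHMM:
        m = GaussianHMM(n_components=self.n_states, covariance_type="diag")
        m.means_ = self.means.reshape(-1, 1)
        m.covars_ = (self.sds**2).reshape(-1, 1)
        # floor vanishing probabilities so decoding never hits log(0)
        tm = np.maximum(self.transmat, 1e-12)
        m.transmat_ = tm / tm.sum(axis=1, keepdims=True)
        sp = np.maximum(self.startprob, 1e-12)
        m.startprob_ = sp / sp.sum()
        return m

    def predict(self, fret: np.ndarray, method: str = "viterbi") -> np.ndarray:
        """Decode a FRET series into state indices (NaN frames carried over)."""
        fret = np.asarray(fret, dtype=float)
        good = np.isfinite(fret)
        out = np.full(len(fret), -1, dtype=int)
        if good.sum() == 0:
            return out
        x = fret[good].reshape(-1, 1)
        m = self._hmm()
        if method == "viterbi":
            out[good] = m.predict(x)
        elif method == "posterior":
            out[good] = m.predict_proba(x).argmax(axis=1)
        else:
            raise ValueError(f"unknown decoding method {method!r}")
        return out

    def state_labels(self) -> list[str]:
        return list(STATE_LABELS[: self.n_states])


def _clean_series(fret_series) -> list[np.ndarray]:
    series = []
    for s in fret_series:
        s = np.asarray(s, dtype=float)
        s = s[np.isfinite(s)]
        if len(s):
            series.append(s)
    return series


def fit_hmm(
    fret_series,
    n_states: int = 3,
    seed=None,
    n_iter: int = 200,
    tol: float = 1e-4,
    init_means=None,
    self_prob: float = 0.95,
) -> HmmModel:
    """Baum-Welch fit of one Gaussian HMM shared across all traces.

    Initial emission means default to spread quantiles of the pooled
    data (or explicit ``init_means``); the transition matrix starts
    nearly diagonal.  After fitting, states are relabeled by ascending
    emission mean so state order always reads L < I < H regardless of
    initialization.  A state occupying fewer than 0.1% of frames is
    flagged as degenerate.
    """
    series = _clean_series(fret_series)
    if not series:
        raise ValueError("no usable FRET series")
    if any(len(s) < 10 for s in series):
        warnings.warn("series shorter than 10 frames are unreliable", stacklevel=2)
    x = np.concatenate(series).reshape(-1, 1)
    lengths = [len(s) for s in series]

    if init_means is None:
        # spread the initial means across the populated FRET range;
        # occupancy-weighted quantiles would collapse onto a dominant state
        lo, hi = np.quantile(x, [0.02, 0.98])
        init_means = (
            np.array([np.median(x)]) if n_states == 1
            else np.linspace(lo, hi, n_states)
        )
    init_means = np.sort(np.asarray(init_means, dtype=float))

    model = GaussianHMM(
        n_components=n_states,
        covariance_type="diag",
        n_iter=n_iter,
        tol=tol,
        random_state=np.random.default_rng(seed).integers(2**31 - 1),
        init_params="",
        params="stmc",
        min_covar=1e-6,
    )
    model.means_ = init_means.reshape(-1, 1)
    model.covars_ = np.full((n_states, 1), 0.05**2)
    if n_states == 1:
        tm = np.ones((1, 1))
    else:
        tm = np.full((n_states, n_states), (1 - self_prob) / (n_states - 1))
        np.fill_diagonal(tm, self_prob)
    model.transmat_ = tm
    model.startprob_ = np.full(n_states, 1.0 / n_states)
    model.fit(x, lengths)

    history = list(model.monitor_.history)
    order = np.argsort(model.means_.ravel())
    means = model.means_.ravel()[order]
    sds = np.sqrt(model.covars_.ravel()[order])
    transmat = model.transmat_[np.ix_(order, order)]
    startprob = model.startprob_[order]

    flags = []
    states = model.predict(x, lengths)
    occ = np.bincount(states, minlength=n_states).astype(float) / len(states)
    occ = occ[order]
    for i, f in enumerate(occ):
        if f < 1e-3:
            flags.append(f"degenerate_state_{STATE_LABELS[i] if n_states == 3 else i}")
            warnings.warn(
                f"HMM state {i} occupies {f:.2%} of frames (degenerate)", stacklevel=2
            )

    return HmmModel(
        means=means,
        sds=sds,
        transmat=transmat,
        startprob=startprob,
        log_likelihood=float(model.monitor_.history[-1]),
        converged=bool(model.monitor_.converged),
        history=history,
        flags=flags,
        n_states=n_states,
    )


def select_n_states_bic(fret_series, candidates=(1, 2, 3, 4), seed=None) -> int:
    """Pick the state count minimizing the BIC of the fitted HMM.

    Provided for constructs whose ensembles collapse to fewer than three
    resolvable states (e.g. loop variants with shifted state centers).
    """
    series = _clean_series(fret_series)
    x = np.concatenate(series)
    n = len(x)
    best, best_bic = None, np.inf
    for k in candidates:
        m = fit_hmm(series, n_states=k, seed=seed)
        # free parameters: k means + k sds + k(k-1) transitions + (k-1) start
        p = 2 * k + k * (k - 1) + (k - 1)
        bic = -2 * m.log_likelihood + p * np.log(n)
        if bic < best_bic:
            best, best_bic = k, bic
    return best


def idealize_trace(
    model: HmmModel,
    fret: np.ndarray,
    trace_id: str = "",
    frame_interval: float = 0.025,
    method: str = "viterbi",
) -> IdealizedTrace:
    """Most-probable (Viterbi) state path for one FRET series."""
    states = model.predict(fret, method=method)
    return IdealizedTrace(
        states=states,
        fret=np.asarray(fret, dtype=float),
        state_means=model.means,
        frame_interval=frame_interval,
        trace_id=trace_id,
    )


@dataclass
class FretHistogram:
    """Pooled FRET histogram normalized by the total number of data points."""

    edges: np.ndarray
    frequencies: np.ndarray
    n_molecules: int
    n_points: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def build_histogram(
    fret_series,
    bin_width: float = 0.02,
    min_molecules: int = 200,
) -> FretHistogram:
    """Pool per-frame FRET values of all molecules into one histogram.

    Frequencies are normalized by the total number of FRET data points
    (they sum to 1).  Ensemble histograms are conventionally built from
    more than ``min_molecules`` molecules; fewer triggers a warning.
    """
    series = _clean_series(fret_series)
    if not series:
        raise ValueError("no usable FRET series")
    if len(series) < min_molecules:
        warnings.warn(
            f"histogram built from {len(series)} molecules "
            f"(fewer than the conventional {min_molecules})",
            stacklevel=2,
        )
    pooled = np.concatenate(series)
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(np.clip(pooled, 0, 1), bins=edges)
    return FretHistogram(
        edges=edges,
        frequencies=counts / counts.sum(),
        n_molecules=len(series),
        n_points=len(pooled),
    )


@dataclass
class StatePopulations:
    """Gaussian-mixture decomposition of the pooled FRET distribution.

    ``fractions`` are the mixture weights (summing to 1), interpreted as
    the fractional population of each conformational state; centers are
    ascending and labeled L/I/H.
    """

    centers: np.ndarray
    widths: np.ndarray
    fractions: np.ndarray
    condition: float | str | None = None
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if abs(self.fractions.sum() - 1.0) > 1e-6:
            raise ValueError("fractions must sum to 1")
        if np.any(np.diff(self.centers) < 0):
            raise ValueError("centers must be ascending")


class MixtureConvergenceError(RuntimeError):
    """Raised when the Gaussian-mixture fit fails to converge."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


def fit_state_populations(
    data,
    n_states: int = 3,
    seed=None,
    means_init=None,
    condition=None,
    max_iter: int = 500,
) -> StatePopulations:
    """Fit an ``n_states``-component Gaussian mixture to pooled FRET data.

    ``data`` may be a list of FRET series or a single pooled array.
    Component weights are the fractional state populations; components
    are sorted by ascending center and labeled L/I/H.
    """
    if isinstance(data, np.ndarray) and data.ndim == 1:
        pooled = data[np.isfinite(data)]
    else:
        pooled = np.concatenate(_clean_series(data))
    if len(pooled) < 10 * n_states:
        raise ValueError("too few data points for a mixture fit")
    if means_init is None:
        lo, hi = np.quantile(pooled, [0.02, 0.98])
        means_init = (
            np.array([np.median(pooled)]) if n_states == 1
            else np.linspace(lo, hi, n_states)
        )
    gm = GaussianMixture(
        n_components=n_states,
        means_init=np.asarray(means_init).reshape(-1, 1),
        weights_init=np.full(n_states, 1.0 / n_states),
        # start from a FRET-scale component width so overlapping states
        # are not merged during the first EM steps
        precisions_init=np.full((n_states, 1, 1), 1.0 / 0.05**2),
        random_state=np.random.default_rng(seed).integers(2**31 - 1),
        max_iter=max_iter,
        reg_covar=1e-8,
    )
    gm.fit(pooled.reshape(-1, 1))
    if not gm.converged_:
        raise MixtureConvergenceError(
            f"mixture fit did not converge in {max_iter} iterations",
            last_iterate={
                "centers": gm.means_.ravel(),
                "widths": np.sqrt(gm.covariances_.ravel()),
                "fractions": gm.weights_,
            },
        )
    order = np.argsort(gm.means_.ravel())
    centers = gm.means_.ravel()[order]
    widths = np.sqrt(gm.covariances_.ravel()[order])
    fractions = gm.weights_[order]
    fractions = fractions / fractions.sum()
    flags = [
        f"vanishing_component_{i}" for i, w in enumerate(fractions) if w < 1e-3
    ]
    return StatePopulations(
        centers=centers,
        widths=widths,
        fractions=fractions,
        condition=condition,
        flags=flags,
    )
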
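"""Core data containers shared across the package.

Conventions: the three conformational states of the RNA are labeled
``L`` (low FRET, unfolded), ``I`` (intermediate, partially folded) and
``H`` (high FRET, folded), always in that order; integer state indices
0/1/2 map onto those labels everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STATE_LABELS = ("L", "I", "H")


def state_label(index: int) -> str:
    return STATE_LABELS[index]


@dataclass
class FretTrace:
    """Per-frame donor/acceptor intensities for one molecule.

    Parameters
    ----------
    time : array of frame start times in seconds, uniformly spaced.
    donor, acceptor : per-frame background-subtracted intensities.
    frame_interval : camera integration time per frame in seconds.
    truth_state : optional ground-truth majority-state index per frame
        (only populated by the synthetic generator).
    truth_bleach_time : optional ground-truth photobleach time (s).
    """

    time: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    frame_interval: float
    trace_id: str = ""
    truth_state: np.ndarray | None = None
    truth_bleach_time: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if not (len(self.time) == len(self.donor) == len(self.acceptor)):
            raise ValueError("time, donor and acceptor must have equal length")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if len(self.time) > 1:
            dt = np.diff(self.time)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("frame times must be uniformly spaced")

    @property
    def n_frames(self) -> int:
        return len(self.time)

    @property
    def total(self) -> np.ndarray:
        return self.donor + self.acceptor


@dataclass
class IdealizedTrace:
    """Hidden-state assignment of one FRET trace.

    ``states`` holds integer indices into the fitted model's states
    (0=L < 1=I < 2=H by emission mean); ``fret`` is the per-frame FRET
    efficiency the assignment was computed from (NaN for masked frames).
    """

    states: np.ndarray
    fret: np.ndarray
    state_means: np.ndarray
    frame_interval: float
    trace_id: str = ""

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        self.fret = np.asarray(self.fret, dtype=float)
        if len(self.states) != len(self.fret):
            raise ValueError("states and fret must have equal length")
        # -1 marks frames with no valid assignment (masked FRET)
        if self.states.size and (
            self.states.min() < -1 or self.states.max() >= len(self.state_means)
        ):
            raise ValueError("state index outside the model's states")

    @property
    def labels(self) -> list[str]:
        return [STATE_LABELS[s] for s in self.states]


@dataclass
class DecayTrace:
    """Paired Xrn1 decay fluorescence time courses.

    ``f_exp`` is the +Xrn1 (experimental) channel, ``f_con`` the -Xrn1
    control measured in parallel; both on the same time grid (minutes).
    """

    time_min: np.ndarray
    f_exp: np.ndarray
    f_con: np.ndarray
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.f_exp = np.asarray(self.f_exp, dtype=float)
        self.f_con = np.asarray(self.f_con, dtype=float)
        if not (len(self.time_min) == len(self.f_exp) == len(self.f_con)):
            raise ValueError("experimental and control series must share the time grid")


@dataclass
class ScatteringCurve:
    """Small-angle scattering curve: q (1/Angstrom), I(q), sigma(q)."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if len(self.sigma) != len(self.q):
                raise ValueError("sigma must match q")
        if len(self.q) != len(self.intensity):
            raise ValueError("q and intensity must have equal length")
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be positive and strictly ascending")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")
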
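"""Image-stack front end: spot detection, channel registration and
trace extraction for dual-channel TIRF movies.

Fluorescent molecules appear as diffraction-limited spots; each local
maximum above threshold is refined by least-squares fitting of a 2D
Gaussian within a 9x9 pixel window, and the background-subtracted
Gaussian volume (2*pi*A*sigma^2) is used as the raw fluorescence
intensity.  Donor and acceptor channels are registered by a
Hough-style vote over candidate translations implied by all spot pairs.
Coordinates are 0-based pixel indices; a spot position is the Gaussian
center in pixel units.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.stats import pearsonr

from .trace import FretTrace

__all__ = [
    "detect_spots",
    "register_channels",
    "extract_trace",
    "select_traces",
    "SpotFit",
    "ChannelTransform",
    "SelectionCriteria",
    "RegistrationError",
]

log = logging.getLogger(__name__)

WINDOW = 9  # side of the square fit window, pixels


@dataclass
class SpotFit:
    """Sub-pixel 2D-Gaussian fit of one fluorescence spot."""

    x: float
    y: float
    amplitude: float
    sigma: float
    background: float
    residual: float

    @property
    def volume(self) -> float:
        """Background-subtracted total volume of the Gaussian peak."""
        return 2.0 * np.pi * self.amplitude * self.sigma**2


def _gauss2d(params, xx, yy):
    x0, y0, a, s, b = params
    return b + a * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * s**2))


def _fit_window(window, x0, y0, sigma0=1.2, fix_position=None):
    """Least-squares 2D Gaussian fit over one window.

    ``fix_position`` freezes (x, y) and fits amplitude/width/background
    only (used for per-frame refits at a known spot position).
    """
    h, w = window.shape
    yy, xx = np.mgrid[0:h, 0:w]
    border = np.concatenate(
        [window[0, :], window[-1, :], window[1:-1, 0], window[1:-1, -1]]
    )
    b0 = float(np.median(border))
    a0 = float(window.max() - b0)
    if fix_position is not None:
        fx, fy = fix_position

        def resid(p):
            return (_gauss2d((fx, fy, p[0], p[1], p[2]), xx, yy) - window).ravel()

        sol = least_squares(
            resid,
            x0=[max(a0, 1e-3), sigma0, b0],
            bounds=([-np.inf, 0.3, -np.inf], [np.inf, w, np.inf]),
        )
        a, s, b = sol.x
        x_fit, y_fit = fx, fy
    else:

        def resid(p):
            return (_gauss2d(p, xx, yy) - window).ravel()

        sol = least_squares(
            resid,
            x0=[x0, y0, max(a0, 1e-3), sigma0, b0],
            bounds=(
                [-1.0, -1.0, 0.0, 0.3, -np.inf],
                [w, h, np.inf, w, np.inf],
            ),
        )
        x_fit, y_fit, a, s, b = sol.x
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return SpotFit(
        x=float(x_fit), y=float(y_fit), amplitude=float(a),
        sigma=float(s), background=float(b), residual=rms,
    ), sol.success


def detect_spots(
    image: np.ndarray,
    intensity_threshold: float,
    sigma_bounds: tuple[float, float] = (0.5, 4.0),
    min_separation: int = 3,
) -> list[SpotFit]:
    """Detect and sub-pixel-fit fluorescence spots in one image.

    Local maxima above ``intensity_threshold`` seed least-squares 2D
    Gaussian fits over the 9x9 window centered on each maximum.  Fits
    that fail to converge or whose width falls outside ``sigma_bounds``
    are dropped; maxima whose window would be clipped by the frame edge
    are skipped (logged).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or not np.all(np.isfinite(image)):
        raise ValueError("image must be a finite 2D array")
    half = WINDOW // 2
    footprint = np.ones((min_separation, min_separation), dtype=bool)
    local_max = (image == ndimage.maximum_filter(image, footprint=footprint)) & (
        image > intensity_threshold
    )
    spots = []
    for py, px in zip(*np.nonzero(local_max)):
        if (
            py - half < 0
            or px - half < 0
            or py + half >= image.shape[0]
            or px + half >= image.shape[1]
        ):
            log.info("spot at (%d, %d) skipped: window clipped by frame edge", px, py)
            continue
        window = image[py - half : py + half + 1, px - half : px + half + 1]
        fit, ok = _fit_window(window, half, half)
        if not ok or not (sigma_bounds[0] <= fit.sigma <= sigma_bounds[1]):
            continue
        fit.x += px - half
        fit.y += py - half
        spots.append(fit)
    return spots


class RegistrationError(RuntimeError):
    pass


@dataclass
class ChannelTransform:
    """Donor-to-acceptor channel mapping: translation (+ matched pairs)."""

    dx: float
    dy: float
    rotation: float = 0.0
    pairs: list = field(default_factory=list)  # (donor_index, acceptor_index)
    match_score: float = 0.0

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        if self.rotation != 0.0:
            c, s = np.cos(self.rotation), np.sin(self.rotation)
            xy = xy @ np.array([[c, s], [-s, c]])
        return xy + [self.dx, self.dy]


def register_channels(
    donor_spots,
    acceptor_spots,
    max_offset: float = 20.0,
    bin_width: float = 0.5,
    min_votes: int = 3,
    inlier_tol: float = 1.0,
) -> ChannelTransform:
    """Register the two channels by translation voting.

    Every donor/acceptor spot pair within ``max_offset`` casts a vote
    for its implied translation on a grid of ``bin_width`` pixels; the
    modal bin selects the candidate translation, which is refined by a
    least-squares (mean-difference) fit over the inlier pairs.  Inlier
    pairs are matched one-to-one (greedy nearest-residual).
    """
    d = np.array([[s.x, s.y] for s in donor_spots], dtype=float).reshape(-1, 2)
    a = np.array([[s.x, s.y] for s in acceptor_spots], dtype=float).reshape(-1, 2)
    if len(d) == 0 or len(a) == 0:
        raise RegistrationError("registration failed: a channel has no spots")
    if min(len(d), len(a)) < 3:
        warnings.warn("fewer than 3 spots per channel; registration is fragile",
                      stacklevel=2)
    diffs = (a[None, :, :] - d[:, None, :]).reshape(-1, 2)
    within = np.all(np.abs(diffs) <= max_offset, axis=1)
    diffs = diffs[within]
    if len(diffs) == 0:
        raise RegistrationError("registration failed: no candidate pairs in range")

    n_bins = int(np.ceil(2 * max_offset / bin_width))
    edges = np.linspace(-max_offset, max_offset, n_bins + 1)
    hist, _, _ = np.histogram2d(diffs[:, 0], diffs[:, 1], bins=(edges, edges))
    peak = np.unravel_index(np.argmax(hist), hist.shape)
    if hist[peak] < min_votes:
        raise RegistrationError(
            f"registration failed: modal translation bin has {int(hist[peak])} "
            f"votes (< {min_votes})"
        )
    cand = np.array(
        [
            0.5 * (edges[peak[0]] + edges[peak[0] + 1]),
            0.5 * (edges[peak[1]] + edges[peak[1] + 1]),
        ]
    )

    # one-to-one greedy matching of inliers around the candidate shift
    resid = a[None, :, :] - d[:, None, :] - cand
    dist = np.linalg.norm(resid, axis=2)
    pairs = []
    used_d, used_a = set(), set()
    for idx in np.argsort(dist, axis=None):
        i, j = np.unravel_index(idx, dist.shape)
        if dist[i, j] > inlier_tol:
            break
        if i in used_d or j in used_a:
            continue
        pairs.append((int(i), int(j)))
        used_d.add(i)
        used_a.add(j)
    if len(pairs) < min_votes:
        raise RegistrationError("registration failed: too few inlier pairs")
    di = np.array([p[0] for p in pairs])
    ai = np.array([p[1] for p in pairs])
    shift = (a[ai] - d[di]).mean(axis=0)
    return ChannelTransform(
        dx=float(shift[0]),
        dy=float(shift[1]),
        pairs=sorted(pairs),
        match_score=len(pairs) / min(len(d), len(a)),
    )


def extract_trace(
    donor_stack: np.ndarray,
    acceptor_stack: np.ndarray,
    donor_spot: SpotFit,
    transform: ChannelTransform,
    frame_interval: float = 0.025,
    refit_shape: bool = True,
    trace_id: str = "",
) -> FretTrace:
    """Per-frame intensity extraction at a registered spot pair.

    At each frame the 2D Gaussian is refit at fixed position (amplitude,
    width and local background free by default; ``refit_shape=False``
    freezes the width at the detection value) and the intensity is the
    background-subtracted Gaussian volume.  Frames whose fit diverges
    fall back to a windowed background-subtracted sum (flagged in the
    log).
    """
    half = WINDOW // 2
    ax, ay = transform.apply([donor_spot.x, donor_spot.y])[0]

    def series(stack, x, y):
        px, py = int(round(x)), int(round(y))
        px = int(np.clip(px, half, stack.shape[2] - half - 1))
        py = int(np.clip(py, half, stack.shape[1] - half - 1))
        fx, fy = x - (px - half), y - (py - half)
        out = np.empty(stack.shape[0])
        for f in range(stack.shape[0]):
            window = stack[f, py - half : py + half + 1, px - half : px + half + 1]
            if refit_shape:
                fit, ok = _fit_window(window, fx, fy, fix_position=(fx, fy))
            else:
                fit, ok = _fit_window(
                    window, fx, fy, sigma0=donor_spot.sigma, fix_position=(fx, fy)
                )
                fit.sigma = donor_spot.sigma
            if ok:
                out[f] = 2.0 * np.pi * fit.amplitude * fit.sigma**2
            else:
                border = np.concatenate(
                    [window[0, :], window[-1, :], window[1:-1, 0], window[1:-1, -1]]
                )
                out[f] = window.sum() - window.size * np.median(border)
                log.info("frame %d: Gaussian refit diverged; windowed sum used", f)
        return out

    donor = series(donor_stack, donor_spot.x, donor_spot.y)
    acceptor = series(acceptor_stack, ax, ay)
    t = np.arange(donor_stack.shape[0]) * frame_interval
    return FretTrace(
        time=t, donor=donor, acceptor=acceptor,
        frame_interval=frame_interval, trace_id=trace_id,
    )


@dataclass
class SelectionCriteria:
    """Trace-selection thresholds.

    A trace is accepted when both channels carry signal, the donor and
    acceptor are anticorrelated over the pre-bleach segment (Pearson
    r at or below ``max_correlation``), and any detected bleach is a
    single step.
    """

    min_signal: float = 50.0
    max_correlation: float = -0.3


def select_traces(traces, criteria: SelectionCriteria | None = None):
    """Split traces into accepted molecules and rejects with reasons.

    Returns ``(accepted, reasons)`` where ``reasons`` maps the index of
    every rejected trace to a short explanation.
    """
    from .idealize import detect_bleach

    if not traces:
        raise ValueError("no traces supplied")
    criteria = criteria or SelectionCriteria()
    accepted, reasons = [], {}
    for i, tr in enumerate(traces):
        k = detect_bleach(tr.total)
        end = k if k is not None else tr.n_frames
        donor = tr.donor[:end]
        acceptor = tr.acceptor[:end]
        if len(donor) < 10:
            reasons[i] = "too short before bleach"
            continue
        if np.mean(acceptor) < criteria.min_signal:
            reasons[i] = "no acceptor"
            continue
        if np.mean(donor) < criteria.min_signal:
            reasons[i] = "no donor"
            continue
        if np.std(donor) == 0 or np.std(acceptor) == 0:
            reasons[i] = "constant channel"
            continue
        r, _ = pearsonr(donor, acceptor)
        if r > criteria.max_correlation:
            reasons[i] = f"no anticorrelation (r={r:.2f})"
            continue
        accepted.append(tr)
    return accepted, reasons
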
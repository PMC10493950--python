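"""Optical vulnerability analysis: from a time-lapse image stack of a
dehydrating leaf to a vulnerability curve and P50.

Cavitation of a leaf vein shows up as a sudden local brightness change
between consecutive frames.  The pipeline is: absolute consecutive-frame
differencing with a global threshold, removal of small connected components
(leaf-shrinkage flicker) and optionally of pixels outside a region mask,
accumulation of the retained event area over frames, interpolation of the
psychrometer water-potential trace onto frame times, and finally reading the
water potential at 50% cumulative embolised area (P50) off the curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize
from skimage import measure

__all__ = [
    "ImageStack",
    "PsiTrace",
    "EventMap",
    "VulnerabilityCurve",
    "difference_stack",
    "filter_noise",
    "cumulative_embolism",
    "assign_psi",
    "build_curve",
    "extract_px",
    "extract_px_logistic",
    "species_p50",
    "IncompleteDehydrationError",
]


class IncompleteDehydrationError(RuntimeError):
    """The vulnerability curve never reaches the requested percentage."""


@dataclass
class ImageStack:
    """Ordered grayscale frames with acquisition times (seconds from start)."""
    frames: np.ndarray       # (n_frames, H, W)
    frame_times: np.ndarray  # s, strictly increasing

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("stack needs >= 2 frames of identical shape")
        if self.frame_times.shape != (self.frames.shape[0],):
            raise ValueError("one time per frame required")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class PsiTrace:
    """Water potential (MPa, <= 0) vs time from the stem psychrometer."""
    times: np.ndarray
    psi: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if self.times.size < 2 or self.times.shape != self.psi.shape:
            raise ValueError("psi trace needs >= 2 matched samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trace times must be strictly increasing")
        if np.any(self.psi > 0):
            raise ValueError("water potentials must be <= 0 MPa")


@dataclass
class EventMap:
    """Per-frame binary change masks and retained-event pixel counts."""
    masks: np.ndarray   # (n_frames, H, W) bool; frame 0 all False
    counts: np.ndarray  # (n_frames,) int

    def __post_init__(self):
        self.masks = np.asarray(self.masks, dtype=bool)
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ValueError("negative event counts")


@dataclass
class VulnerabilityCurve:
    """Cumulative embolised area (%) against water potential per frame."""
    frame_index: np.ndarray
    psi: np.ndarray
    cum_px: np.ndarray
    cum_percent: np.ndarray
    complete: bool
    warnings: list[str] = field(default_factory=list)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.psi, self.cum_percent, drawstyle="steps-post")
        ax.set_xlabel("water potential (MPa)")
        ax.set_ylabel("cumulative embolised area (%)")
        ax.invert_xaxis()
        return ax


def difference_stack(stack: ImageStack, diff_threshold: float = 1000.0) -> EventMap:
    """Threshold absolute consecutive-frame differences.

    Differencing is done in a signed widened dtype (no unsigned wraparound).
    Frame 0 has an empty mask; mask_k flags pixels where
    |frame_k - frame_{k-1}| > diff_threshold.
    """
    if diff_threshold <= 0:
        raise ValueError("diff_threshold must be positive")
    frames = stack.frames.astype(np.int64, copy=False) \
        if np.issubdtype(stack.frames.dtype, np.integer) \
        else stack.frames.astype(np.float64, copy=False)
    diffs = np.abs(np.diff(frames, axis=0))
    masks = np.zeros(stack.frames.shape, dtype=bool)
    masks[1:] = diffs > diff_threshold
    counts = masks.sum(axis=(1, 2))
    return EventMap(masks, counts)


def filter_noise(events: EventMap, min_event_px: int = 4,
                 region_mask: np.ndarray | None = None) -> EventMap:
    """Remove shrinkage flicker: small connected components and off-region pixels.

    Connected components use 8-connectivity; components smaller than
    ``min_event_px`` are dropped per frame, as are pixels outside the
    optional binary ``region_mask`` (e.g. a vein mask).
    """
    if min_event_px < 1:
        raise ValueError("min_event_px must be >= 1")
    masks = events.masks.copy()
    if region_mask is not None:
        region_mask = np.asarray(region_mask, dtype=bool)
        if region_mask.shape != masks.shape[1:]:
            raise ValueError(
                f"region mask shape {region_mask.shape} does not match "
                f"frame shape {masks.shape[1:]}")
        masks &= region_mask[None, :, :]
    if min_event_px > 1:
        for k in range(masks.shape[0]):
            if not masks[k].any():
                continue
            lab = measure.label(masks[k], connectivity=2)
            sizes = np.bincount(lab.ravel())
            small = np.flatnonzero(sizes < min_event_px)
            if small.size:
                masks[k][np.isin(lab, small[small > 0])] = False
    return EventMap(masks, masks.sum(axis=(1, 2)))


def cumulative_embolism(events: EventMap) -> tuple[np.ndarray, np.ndarray, bool]:
    """Running sum of retained event pixels and the percent-of-final curve.

    Returns ``(cum_px, cum_percent, complete)``; if no events were retained
    at all the percent curve is all zero and ``complete`` is False (a
    completeness warning is emitted).
    """
    cum = np.cumsum(events.counts)
    total = cum[-1]
    if total == 0:
        warnings.warn("no cavitation events retained; curve is empty")
        return cum, np.zeros_like(cum, dtype=float), False
    return cum, 100.0 * cum / total, True


def assign_psi(frame_times: np.ndarray, trace: PsiTrace) -> np.ndarray:
    """Water potential at each frame time by linear interpolation of the trace.

    Frame times outside the trace's span are clamped to the nearest endpoint
    with a warning.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    if frame_times.size == 0:
        raise ValueError("no frame times given")
    lo, hi = trace.times[0], trace.times[-1]
    n_out = int(np.sum((frame_times < lo) | (frame_times > hi)))
    if n_out:
        warnings.warn(f"{n_out} frame time(s) outside the psi trace span; "
                      "clamped to nearest endpoint")
    return np.interp(frame_times, trace.times, trace.psi)


def build_curve(stack: ImageStack, trace: PsiTrace, diff_threshold: float = 1000.0,
                min_event_px: int = 4,
                region_mask: np.ndarray | None = None) -> VulnerabilityCurve:
    """Full optical pipeline: differencing, filtering, accumulation, psi mapping."""
    events = filter_noise(difference_stack(stack, diff_threshold),
                          min_event_px, region_mask)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cum, pct, complete = cumulative_embolism(events)
        psi = assign_psi(stack.frame_times, trace)
    return VulnerabilityCurve(
        frame_index=np.arange(stack.n_frames), psi=psi, cum_px=cum,
        cum_percent=pct, complete=complete,
        warnings=[str(w.message) for w in caught])


def extract_px(curve: VulnerabilityCurve, x: float = 50.0) -> float:
    """Water potential at the first crossing of ``x`` percent embolism.

    The curve is scanned in frame order (decreasing water potential); the
    crossing is linearly interpolated in psi between the bracketing frames.
    """
    if not (0.0 < x < 100.0):
        raise ValueError("x must be strictly between 0 and 100 percent")
    if not curve.complete:
        raise IncompleteDehydrationError(
            "curve is incomplete (no events retained); cannot read P_x")
    pct, psi = curve.cum_percent, curve.psi
    idx = np.flatnonzero(pct >= x)
    if idx.size == 0:
        raise IncompleteDehydrationError(
            f"curve never reaches {x}% cumulative embolism")
    k = idx[0]
    if pct[k] == x or k == 0:
        return float(psi[k])
    frac = (x - pct[k - 1]) / (pct[k] - pct[k - 1])
    return float(psi[k - 1] + frac * (psi[k] - psi[k - 1]))


def extract_px_logistic(curve: VulnerabilityCurve, x: float = 50.0) -> float:
    """Alternative P_x readout: fit a logistic to the empirical curve.

    Fits F(psi) = 100 / (1 + exp(s/25 * (psi - p50))) by least squares and
    evaluates the x% point analytically — a sensitivity check on the
    interpolation readout, not the default.
    """
    if not curve.complete:
        raise IncompleteDehydrationError("curve is incomplete")

    def model(psi, p50, s):
        return 100.0 / (1.0 + np.exp(np.clip(s / 25.0 * (psi - p50), -500, 500)))

    p0 = (float(np.interp(50.0, curve.cum_percent, curve.psi)), 50.0)
    popt, _ = optimize.curve_fit(model, curve.psi, curve.cum_percent, p0=p0,
                                 maxfev=10000)
    p50, s = popt
    return float(p50 + 25.0 / s * np.log(100.0 / x - 1.0))


def species_p50(replicate_p50s: Sequence[float]) -> tuple[float, float]:
    """Species mean P50 and its standard error across replicates.

    SE is sd/sqrt(n); reported as NaN for a single replicate.
    """
    vals = np.asarray(list(replicate_p50s), dtype=float)
    if vals.size == 0:
        raise ValueError("at least one replicate P50 required")
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else float("nan")
    return mean, se
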
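"""Respiratory waveform assembly, smoothing, valley detection, and rate.

Respiration modulates how firmly the trunk presses on the mat, so the sum
of all sensor voltages in one frame traces a breathing waveform, one point
per frame.  The analysis convention is that *valleys* mark end-inhalation:
supine recordings (back/waist on the mat) already satisfy it, prone
recordings (chest/abdomen) are flipped about their mean first.

Waveforms are smoothed with a cubic smoothing spline that minimizes

    p * sum_k (y_k - s(t_k))^2 + (1 - p) * integral s''(t)^2 dt,

so p = 1 interpolates and p = 0 gives the least-squares straight line; the
default p = 0.96812749 keeps breathing-band curvature while attenuating
per-frame reconstruction noise.  Respiratory rate per 30-s epoch is
RR = 60 / INT with INT the mean interval between successive valleys, which
telescopes to (t_last - t_first) / (n - 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.signal import find_peaks

from .errors import InsufficientValleysError
from .gridframe import FrameSequence

logger = logging.getLogger(__name__)

DEFAULT_SMOOTHING_P = 0.96812749
DEFAULT_EPOCH_LENGTH = 30.0
ORIENTATIONS = ("supine_back_waist", "prone_chest_abdomen")


@dataclass
class RespiratoryWaveform:
    """Total mat pressure over time (V-sum units)."""

    times: np.ndarray
    totals: np.ndarray
    orientation: str = "supine_back_waist"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.totals = np.asarray(self.totals, dtype=float)
        if self.times.shape != self.totals.shape or self.times.ndim != 1:
            raise ValueError("times and totals must be equal-length 1-D arrays")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.totals)):
            raise ValueError("totals must be finite")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")


@dataclass
class Epoch:
    """Half-open slice [start, end) of a waveform; the RR computation unit."""

    index: int
    start: float
    end: float
    waveform: RespiratoryWaveform


@dataclass
class ValleySet:
    """Strictly increasing end-inhalation valley times within one epoch."""

    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("valley times must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.times)


@dataclass
class RRResult:
    INT: float  # mean valley interval, seconds
    RR: float  # breaths per minute


def build_waveform(
    seq: FrameSequence, orientation: str = "supine_back_waist"
) -> RespiratoryWaveform:
    """Sum every frame's cells into one waveform point per frame."""
    if len(seq) == 0:
        raise ValueError("frame sequence is empty")
    totals = np.array([f.total_pressure() for f in seq.frames])
    return RespiratoryWaveform(
        times=seq.timestamps.copy(), totals=totals, orientation=orientation
    )


def orient_waveform(w: RespiratoryWaveform) -> RespiratoryWaveform:
    """Ensure valleys mark end-inhalation: flip prone waveforms about the mean."""
    if w.orientation == "supine_back_waist":
        return RespiratoryWaveform(w.times.copy(), w.totals.copy(), w.orientation)
    flipped = 2.0 * w.totals.mean() - w.totals
    return RespiratoryWaveform(w.times.copy(), flipped, w.orientation)


def smooth_waveform(
    w: RespiratoryWaveform, p: float = DEFAULT_SMOOTHING_P
) -> RespiratoryWaveform:
    """Cubic smoothing spline evaluated at the original sample times."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    if len(w.times) < 4:
        raise ValueError("smoothing needs at least 4 points")
    if p == 0.0:
        slope, intercept = np.polyfit(w.times, w.totals, 1)
        smoothed = slope * w.times + intercept
    elif p == 1.0:
        smoothed = w.totals.copy()
    else:
        lam = (1.0 - p) / p
        spline = make_smoothing_spline(w.times, w.totals, lam=lam)
        smoothed = spline(w.times)
    return RespiratoryWaveform(w.times.copy(), smoothed, w.orientation)


def detect_valleys(
    w: RespiratoryWaveform,
    min_separation: float = 1.5,
    min_prominence_frac: float = 0.10,
) -> ValleySet:
    """Local minima with prominence and separation guards.

    A valley must be prominent by at least ``min_prominence_frac`` of the
    waveform's peak-to-peak range and lie at least ``min_separation``
    seconds from its neighbours (1.5 s caps detectable RR at 40/min).  Of
    two close minima the deeper one wins.  Constant input yields an empty
    set.
    """
    span = float(np.ptp(w.totals))
    # a numerically flat series (e.g. spline round-off on constant input)
    # carries no breathing information at all
    if span <= 1e-9 * max(1.0, float(np.max(np.abs(w.totals)))) or len(w.times) < 3:
        return ValleySet(np.empty(0))
    dt = float(np.median(np.diff(w.times)))
    distance = max(1, math.ceil(min_separation / dt))
    idx, _ = find_peaks(
        -w.totals, prominence=min_prominence_frac * span, distance=distance
    )
    return ValleySet(w.times[idx])


def respiratory_rate(valleys: ValleySet) -> RRResult:
    """RR = 60 / INT, with INT the mean successive-valley interval."""
    if valleys.n < 2:
        raise InsufficientValleysError(
            f"need at least 2 valleys to estimate RR, found {valleys.n}"
        )
    INT = float(valleys.times[-1] - valleys.times[0]) / (valleys.n - 1)
    return RRResult(INT=INT, RR=60.0 / INT)


def split_epochs(
    w: RespiratoryWaveform, epoch_length: float = DEFAULT_EPOCH_LENGTH
) -> list[Epoch]:
    """Partition a waveform into contiguous half-open epochs [t0+k*L, t0+(k+1)*L).

    A trailing partial epoch is dropped (and logged).  A recording shorter
    than one epoch is an error.
    """
    if epoch_length <= 0:
        raise ValueError("epoch_length must be positive")
    t0 = w.times[0]
    duration = w.times[-1] - t0
    n_epochs = int(duration // epoch_length)
    if n_epochs < 1:
        raise ValueError(
            f"recording of {duration:.3g} s is shorter than one "
            f"{epoch_length:.3g}-s epoch"
        )
    remainder = duration - n_epochs * epoch_length
    if remainder > 0:
        logger.info("dropping trailing partial epoch of %.3g s", remainder)
    epochs = []
    for k in range(n_epochs):
        start = t0 + k * epoch_length
        end = start + epoch_length
        mask = (w.times >= start) & (w.times < end)
        epochs.append(
            Epoch(
                index=k,
                start=float(start),
                end=float(end),
                waveform=RespiratoryWaveform(
                    w.times[mask], w.totals[mask], w.orientation
                ),
            )
        )
    return epochs
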
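"""Evaluation statistics: image error rate, waveform correlation, RR accuracy.

Image error rate (per image, averaged over the set):

    err = sum_{x,y} [f*(x,y) - f(x,y)]^2 / sum_{x,y} f(x,y)^2

-- a ratio of sums of squares, deliberately without a square root, so 0 is
a perfect reconstruction and 1 the all-zero estimate.  Scale-invariant.

Waveform agreement is the Pearson correlation after both series are
resampled (linear interpolation in time) onto their common time support.

RR accuracy (per epoch, averaged, reported in percent):

    acc = 1 - (RR_est - RR_ref)^2 / RR_ref^2

which is 1 exactly when the estimate matches the reference and can go
negative for gross errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ZeroVarianceError
from .gridframe import PressureFrame
from .respiratory import RespiratoryWaveform


@dataclass
class EvaluationReport:
    """Per-item metric values with their mean and sample SD."""

    values: np.ndarray
    metric: str
    units: str = "fraction"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_items(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        if len(self.values) < 2:
            return 0.0
        return float(self.values.std(ddof=1))

    def __str__(self) -> str:
        scale = 100.0 if self.units == "fraction" else 1.0
        suffix = "%" if self.units in ("fraction", "percent") else ""
        return (
            f"{self.metric}: {scale * self.mean:.2f}{suffix} "
            f"± {scale * self.sd:.2f}{suffix} (n={self.n_items})"
        )


def image_error_rate(
    truths: list[PressureFrame], estimates: list[PressureFrame]
) -> EvaluationReport:
    """Mean squared-error ratio over paired ground-truth/reconstruction frames."""
    if len(truths) != len(estimates):
        raise ValueError("truths and estimates must have equal length")
    if not truths:
        raise ValueError("need at least one frame pair")
    ratios = []
    for i, (t, e) in enumerate(zip(truths, estimates)):
        if t.values.shape != e.values.shape:
            raise ValueError(f"frame {i}: shape mismatch")
        denom = float(np.sum(t.values**2))
        if denom == 0.0:
            raise ZeroDivisionError(
                f"frame {i}: ground truth is identically zero, error rate undefined"
            )
        ratios.append(float(np.sum((e.values - t.values) ** 2)) / denom)
    return EvaluationReport(np.array(ratios), metric="image error rate")


def waveform_correlation(
    a: RespiratoryWaveform, b: RespiratoryWaveform
) -> float:
    """Pearson correlation of two waveforms on their common time grid."""
    lo = max(a.times[0], b.times[0])
    hi = min(a.times[-1], b.times[-1])
    if hi <= lo:
        raise ValueError("waveforms have no overlapping time support")
    grid = np.union1d(a.times, b.times)
    grid = grid[(grid >= lo) & (grid <= hi)]
    if len(grid) < 3:
        raise ValueError("need at least 3 overlapping points")
    ya = np.interp(grid, a.times, a.totals)
    yb = np.interp(grid, b.times, b.totals)
    if np.ptp(ya) == 0.0 or np.ptp(yb) == 0.0:
        raise ZeroVarianceError("correlation undefined for a constant series")
    return float(np.corrcoef(ya, yb)[0, 1])


def rr_accuracy(
    rr_est: np.ndarray | list[float], rr_ref: np.ndarray | list[float]
) -> EvaluationReport:
    """Per-epoch RR accuracy (percent), mean and SD over epochs."""
    est = np.asarray(rr_est, dtype=float)
    ref = np.asarray(rr_ref, dtype=float)
    if est.shape != ref.shape or est.ndim != 1:
        raise ValueError("rr_est and rr_ref must be equal-length 1-D arrays")
    if len(est) == 0:
        raise ValueError("need at least one epoch")
    if np.any(ref <= 0):
        raise ValueError("reference RR must be positive")
    acc = 1.0 - (est - ref) ** 2 / ref**2
    return EvaluationReport(100.0 * acc, metric="RR accuracy", units="percent")


def relative_rmse(truth: PressureFrame, estimate: PressureFrame) -> float:
    """Relative root-mean-square error (square-rooted variant of the error
    rate; provided for convenience, not used by the standard reports)."""
    denom = float(np.sum(truth.values**2))
    if denom == 0.0:
        raise ZeroDivisionError("ground truth is identically zero")
    return float(np.sqrt(np.sum((estimate.values - truth.values) ** 2) / denom))
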
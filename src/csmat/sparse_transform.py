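"""Orthonormal 2D-DCT sparsifying transform and sparsity estimation.

Body-contact pressure images are smooth blobs, so nearly all of their
energy concentrates in a few low-frequency coefficients of the type-II
two-dimensional discrete cosine transform,

    F(u, v) = a(u) b(v) sum_x sum_y f(x, y)
              cos[pi (2x-1)(u-1) / (2P)] cos[pi (2y-1)(v-1) / (2Q)],

with a(1) = sqrt(1/P), a(u) = sqrt(2/P) for u >= 2 (and b likewise in Q).
This is the orthonormal DCT-II as provided by :func:`scipy.fft.dctn`.

The practical sparsity S of an image is the number of coefficients whose
magnitude is at least a given fraction of a reference maximum.  Numerical
compressed-sensing experience is that most S-sparse signals are recovered
exactly once the number of random measurements reaches about 4S, which is
the ``min_samples_rule`` here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft

from .gridframe import PressureFrame

#: Corpus-average maximum 2D-DCT coefficient of body-part pressure images
#: acquired by the 32x32 mat prototype (in ADC voltage-sum units).
CORPUS_REFERENCE_MAX = 2.85e3


@dataclass
class CoefficientMatrix:
    """P x Q matrix of 2D-DCT coefficients F(u, v); z when flattened row-major."""

    coeffs: np.ndarray

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 2:
            raise ValueError("coefficient matrix must be 2-D")
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("coefficient matrix contains non-finite values")

    @property
    def P(self) -> int:
        return self.coeffs.shape[0]

    @property
    def Q(self) -> int:
        return self.coeffs.shape[1]

    def vec(self) -> np.ndarray:
        """Row-major flattening (u, v) -> (u-1) * Q + (v-1); the vector z."""
        return self.coeffs.reshape(-1)


@dataclass
class SparsityReport:
    """Sparsity count S and the 4S least-sampling-points figure."""

    threshold_fraction: float
    reference_max: float
    S: int
    min_samples: float


def dct2(frame: PressureFrame | np.ndarray) -> CoefficientMatrix:
    """Forward orthonormal 2D-DCT of a frame (energy preserving)."""
    values = frame.values if isinstance(frame, PressureFrame) else np.asarray(frame, float)
    return CoefficientMatrix(scipy.fft.dctn(values, type=2, norm="ortho"))


def idct2(coeffs: CoefficientMatrix | np.ndarray, v_max: float = 5.0) -> PressureFrame:
    """Inverse orthonormal 2D-DCT; returns an (unvalidated) pressure frame.

    The inverse of an arbitrary coefficient matrix may leave the nominal
    voltage range, so range validation is deliberately off.
    """
    arr = coeffs.coeffs if isinstance(coeffs, CoefficientMatrix) else np.asarray(coeffs, float)
    values = scipy.fft.idctn(arr, type=2, norm="ortho")
    return PressureFrame(values, v_max=v_max, validate=False)


def estimate_sparsity(
    coeffs: CoefficientMatrix,
    threshold_fraction: float = 0.05,
    reference_max: float | None = None,
) -> SparsityReport:
    """Count coefficients that survive a fractional magnitude threshold.

    Coefficients with ``|F(u,v)| < threshold_fraction * reference_max`` are
    treated as zero; the survivors (ties kept) are the sparsity S, and
    ``min_samples = 4 * S`` measurements suffice for exact recovery of most
    S-sparse signals.

    ``reference_max`` defaults to the per-image maximum magnitude; pass
    :data:`CORPUS_REFERENCE_MAX` to use the corpus-average convention.
    """
    if not (0.0 < threshold_fraction < 1.0):
        raise ValueError("threshold_fraction must lie in (0, 1)")
    if reference_max is None:
        reference_max = float(np.abs(coeffs.coeffs).max())
    if reference_max <= 0:
        raise ValueError("reference_max must be positive")
    S = int(np.count_nonzero(np.abs(coeffs.coeffs) >= threshold_fraction * reference_max))
    return SparsityReport(
        threshold_fraction=threshold_fraction,
        reference_max=reference_max,
        S=S,
        min_samples=min_samples_rule(S),
    )


def min_samples_rule(S: float) -> float:
    """Least number of random measurements for exact recovery: 4 * S.

    Accepts fractional S (e.g. a corpus mean sparsity).
    """
    if S < 0:
        raise ValueError("sparsity S must be nonnegative")
    return 4.0 * S
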
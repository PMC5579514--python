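"""Random sub-sampling plans, sample extraction, sensing matrix, scan-time model.

The scanning hardware can address any sensor cell directly, so the
measurement matrix is realized simply as an ordered list of M distinct
1-based grid addresses (x_m, y_m).  Three address generators are provided:

``uniform``
    Draw M cells uniformly without replacement (the default: duplicate
    addresses would waste measurements).
``gaussian_prng``
    Center-weighted draws from a rounded bivariate normal, de-duplicated by
    redraw; emulates a microcontroller pseudorandom generator biased toward
    the middle of the mat.
``latin_hypercube``
    Two-dimensional Latin-hypercube points scaled onto the grid and
    de-duplicated by redraw; stratifies rows and columns.

Row m of the sensing matrix A evaluates every 2D-DCT basis function at the
sampled cell,

    A[m, (u,v)] = a(u) b(v) cos[pi (2 x_m - 1)(u-1) / (2P)]
                           cos[pi (2 y_m - 1)(v-1) / (2Q)],

so that A @ vec(dct2(f)) reproduces the sampled voltages exactly.  Columns
are flattened row-major over (u, v).

The acquisition-time model reflects that each sub-sampled point must be
transmitted with its address: a full 1024-point scan takes ``t_full``
(default 0.2 s), sub-sampling only pays off below 512 points, and each
reduction of 100 points below that break-even removes 20% of the full scan
time (floored at 5% of ``t_full``, where the linear rule runs out).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.stats import qmc

from .errors import AddressError
from .gridframe import PressureFrame
from .sparse_transform import CoefficientMatrix

MODES = ("uniform", "gaussian_prng", "latin_hypercube")


@dataclass
class AddressPlan:
    """Ordered list of M distinct 1-based grid addresses (x_m, y_m)."""

    addresses: np.ndarray  # shape (M, 2), int, 1-based
    P: int
    Q: int
    mode: str = "uniform"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.addresses = np.asarray(self.addresses, dtype=int)
        if self.addresses.ndim != 2 or self.addresses.shape[1] != 2:
            raise ValueError("addresses must have shape (M, 2)")
        x, y = self.addresses[:, 0], self.addresses[:, 1]
        if self.M < 1 or self.M > self.P * self.Q:
            raise AddressError(f"M={self.M} outside [1, {self.P * self.Q}]")
        if np.any((x < 1) | (x > self.P) | (y < 1) | (y > self.Q)):
            raise AddressError("address outside 1-based grid bounds")
        if len({(int(a), int(b)) for a, b in self.addresses}) != self.M:
            raise AddressError("addresses must be distinct")

    @property
    def M(self) -> int:
        return len(self.addresses)


@dataclass
class SampleSet:
    """Measurement vector b with the plan that produced it."""

    plan: AddressPlan
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.plan.M,):
            raise ValueError("values must have length M")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sample values must be finite")

    @property
    def M(self) -> int:
        return self.plan.M


@dataclass
class SensingMatrix:
    """M x N matrix A = Phi Psi; columns flattened row-major over (u, v)."""

    entries: np.ndarray
    plan: AddressPlan
    P: int
    Q: int
    flattening: str = "row-major (u, v)"


class AcquisitionTime(NamedTuple):
    seconds: float
    reduction: float  # fraction of the full-scan time saved


@dataclass
class CostModel:
    """Linear scan-time model with break-even point and floor."""

    t_full: float = 0.2
    break_even: int = 512
    reduction_per_100: float = 0.20
    floor_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.t_full <= 0 or not (0 < self.floor_fraction < 1):
            raise ValueError("invalid cost model")


def generate_addresses(
    M: int, P: int = 32, Q: int = 32, mode: str = "uniform", seed: int | None = 0
) -> AddressPlan:
    """Generate M distinct random 1-based grid addresses.

    Deterministic in (M, P, Q, mode, seed).
    """
    N = P * Q
    if not (1 <= M <= N):
        raise AddressError(f"M={M} outside [1, {N}]")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    rng = np.random.default_rng(seed)
    if mode == "uniform":
        flat = rng.choice(N, size=M, replace=False)
        x, y = np.divmod(flat, Q)
        addresses = np.column_stack([x + 1, y + 1])
    elif mode == "gaussian_prng":
        addresses = _dedup_draw(M, lambda n: _gaussian_cells(rng, n, P, Q))
    else:  # latin_hypercube
        sampler = qmc.LatinHypercube(d=2, seed=rng)
        def draw(n: int) -> np.ndarray:
            pts = sampler.random(n)
            return np.column_stack([
                np.minimum((pts[:, 0] * P).astype(int), P - 1) + 1,
                np.minimum((pts[:, 1] * Q).astype(int), Q - 1) + 1,
            ])
        addresses = _dedup_draw(M, draw)
    return AddressPlan(addresses, P=P, Q=Q, mode=mode, seed=seed)


def _gaussian_cells(rng: np.random.Generator, n: int, P: int, Q: int) -> np.ndarray:
    """Center-weighted candidate cells from a rounded bivariate normal."""
    x = np.rint(rng.normal((P + 1) / 2.0, P / 4.0, size=n)).astype(int)
    y = np.rint(rng.normal((Q + 1) / 2.0, Q / 4.0, size=n)).astype(int)
    keep = (x >= 1) & (x <= P) & (y >= 1) & (y <= Q)
    return np.column_stack([x[keep], y[keep]])


def _dedup_draw(M: int, draw) -> np.ndarray:
    """Accumulate draws, dropping repeats, until M distinct cells are held."""
    seen: set[tuple[int, int]] = set()
    out: list[tuple[int, int]] = []
    while len(out) < M:
        for x, y in draw(max(M - len(out), 8)):
            cell = (int(x), int(y))
            if cell not in seen:
                seen.add(cell)
                out.append(cell)
                if len(out) == M:
                    break
    return np.array(out, dtype=int)


def subsample(frame: PressureFrame, plan: AddressPlan) -> SampleSet:
    """Extract the planned cells from a frame, preserving plan order."""
    if (plan.P, plan.Q) != (frame.P, frame.Q):
        raise AddressError(
            f"plan grid {plan.P}x{plan.Q} does not match frame {frame.P}x{frame.Q}"
        )
    values = frame.values[plan.addresses[:, 0] - 1, plan.addresses[:, 1] - 1]
    return SampleSet(plan=plan, values=values)


def _cos_basis(n: int) -> np.ndarray:
    """Matrix C with C[x-1, u-1] = a(u) cos(pi (2x-1)(u-1) / (2n))."""
    x = np.arange(1, n + 1)[:, None]
    u = np.arange(1, n + 1)[None, :]
    weights = np.full(n, np.sqrt(2.0 / n))
    weights[0] = np.sqrt(1.0 / n)
    return weights[None, :] * np.cos(np.pi * (2 * x - 1) * (u - 1) / (2.0 * n))


def build_sensing_matrix(plan: AddressPlan) -> SensingMatrix:
    """Assemble A by evaluating the 2D-DCT basis at each sampled cell."""
    Cx = _cos_basis(plan.P)
    Cy = _cos_basis(plan.Q)
    rows_x = Cx[plan.addresses[:, 0] - 1]  # (M, P) over u
    rows_y = Cy[plan.addresses[:, 1] - 1]  # (M, Q) over v
    entries = (rows_x[:, :, None] * rows_y[:, None, :]).reshape(plan.M, plan.P * plan.Q)
    return SensingMatrix(entries=entries, plan=plan, P=plan.P, Q=plan.Q)


def acquisition_time(M: int, model: CostModel | None = None) -> AcquisitionTime:
    """Frame acquisition time for M sampled points, and the fraction saved."""
    if model is None:
        model = CostModel()
    if M < 1:
        raise ValueError("M must be at least 1")
    if M >= model.break_even:
        seconds = model.t_full
    else:
        fraction = 1.0 - model.reduction_per_100 * (model.break_even - M) / 100.0
        seconds = model.t_full * max(fraction, model.floor_fraction)
    return AcquisitionTime(seconds=seconds, reduction=1.0 - seconds / model.t_full)


def sensing_consistency_error(
    A: SensingMatrix, frame: PressureFrame, coeffs: CoefficientMatrix
) -> float:
    """max |A @ vec(F) - b| over the plan; a self-check of the Eq.-level model."""
    b = subsample(frame, A.plan).values
    return float(np.max(np.abs(A.entries @ coeffs.vec() - b)))
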
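"""Frame and sample-record data model, normalization, and text-file I/O.

A *frame* is one complete snapshot of the P x Q pressure-sensor grid
(default 32 x 32, voltages in [0, 5] V).  Grid addresses follow the
sensor-array convention used throughout the package: ``x`` is the 1-based
row index and ``y`` the 1-based column index.  In-memory arrays are
0-based; the 1-based convention is applied exactly once, at the file-codec
and sensing-matrix boundaries.

Frame files are plain delimited text (whitespace or comma), one row of the
grid per line, optionally preceded by a ``# P Q v_max`` header line.
Sample files are CSV with header ``x,y,value`` and 1-based addresses,
mirroring what the scanning hardware transmits (address alongside value).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np

from .errors import (
    AddressError,
    DuplicateAddressError,
    FrameParseError,
    FrameRangeError,
)

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .sampler import SampleSet

DEFAULT_VMAX = 5.0


@dataclass
class PressureFrame:
    """A P x Q grid of sensor voltages.

    Parameters
    ----------
    values
        Real matrix of voltages, shape ``(P, Q)``.
    v_max
        Full-scale voltage of the acquisition ADC chain (default 5.0 V).
    validate
        When true (default), enforce that every value is finite and lies in
        ``[0, v_max]``.  Reconstructed frames may legitimately carry small
        negative excursions or overshoots, so reconstruction code builds
        frames with ``validate=False``.
    """

    values: np.ndarray
    v_max: float = DEFAULT_VMAX
    validate: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("frame values must be a non-empty 2-D matrix")
        if not np.all(np.isfinite(self.values)):
            raise FrameRangeError("frame contains non-finite values")
        if self.validate:
            if self.v_max <= 0:
                raise ValueError("v_max must be positive")
            bad = np.argwhere(
                (self.values < 0) | (self.values > self.v_max)
            )
            if bad.size:
                x, y = bad[0] + 1
                raise FrameRangeError(
                    f"value {self.values[bad[0][0], bad[0][1]]!r} at cell "
                    f"(x={x}, y={y}) outside [0, {self.v_max}]"
                )

    @property
    def P(self) -> int:
        return self.values.shape[0]

    @property
    def Q(self) -> int:
        return self.values.shape[1]

    @property
    def N(self) -> int:
        return self.values.size

    def total_pressure(self) -> float:
        """Sum of all cell voltages; one point of the respiratory waveform."""
        return float(self.values.sum())


@dataclass
class NormalizedImage:
    """P x Q integer image with intensities in {0, ..., 255}."""

    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=int)
        if self.intensities.min(initial=0) < 0 or self.intensities.max(initial=0) > 255:
            raise ValueError("intensities must lie in [0, 255]")


@dataclass
class FrameSequence:
    """An ordered sequence of frames with strictly increasing timestamps."""

    frames: list[PressureFrame]
    timestamps: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.frames) != len(self.timestamps):
            raise ValueError("frames and timestamps must have equal length")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


def normalize_frame(frame: PressureFrame, v_max: float | None = None) -> NormalizedImage:
    """Map voltages in [0, v_max] to display intensities in {0, ..., 255}.

    Uses round-half-up: ``intensity = floor(255 * value / v_max + 0.5)``,
    which is monotone in the voltage.
    """
    if v_max is None:
        v_max = frame.v_max
    if v_max <= 0:
        raise ValueError("v_max must be positive")
    bad = np.argwhere((frame.values < 0) | (frame.values > v_max))
    if bad.size:
        x, y = bad[0] + 1
        raise FrameRangeError(
            f"value {frame.values[bad[0][0], bad[0][1]]!r} at cell (x={x}, y={y}) "
            f"outside [0, {v_max}]"
        )
    scaled = 255.0 * frame.values / v_max
    return NormalizedImage(np.floor(scaled + 0.5).astype(int))


_HEADER_RE = re.compile(r"^#\s*(\d+)\s+(\d+)\s+([0-9.eE+-]+)\s*$")


def write_frame(path: str | Path, frame: PressureFrame, header: bool = True) -> None:
    """Write a frame as a delimited text matrix, row index = x, column = y."""
    path = Path(path)
    with path.open("w") as fh:
        if header:
            fh.write(f"# {frame.P} {frame.Q} {frame.v_max}\n")
        for row in frame.values:
            fh.write(" ".join(format(v, ".12g") for v in row) + "\n")


def read_frame(path: str | Path, v_max: float | None = None,
               validate: bool = True) -> PressureFrame:
    """Read a delimited-text frame matrix (optional ``# P Q v_max`` header).

    Raises :class:`FrameParseError` with the offending line number on ragged
    rows, non-numeric cells, or a header/body dimension mismatch.
    """
    path = Path(path)
    rows: list[list[float]] = []
    header: tuple[int, int, float] | None = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            m = _HEADER_RE.match(text)
            if m and not rows and header is None:
                header = (int(m.group(1)), int(m.group(2)), float(m.group(3)))
                continue
            if text.startswith("#"):
                continue
            cells = [c for c in re.split(r"[,\s]+", text) if c]
            try:
                row = [float(c) for c in cells]
            except ValueError as exc:
                raise FrameParseError(f"non-numeric cell: {exc}", line=lineno) from exc
            if rows and len(row) != len(rows[0]):
                raise FrameParseError(
                    f"ragged row: expected {len(rows[0])} values, got {len(row)}",
                    line=lineno,
                )
            rows.append(row)
    if not rows:
        raise FrameParseError(f"no numeric rows found in {path}")
    values = np.array(rows, dtype=float)
    if header is not None:
        P, Q, v_hdr = header
        if values.shape != (P, Q):
            raise FrameParseError(
                f"header declares {P}x{Q} but file holds "
                f"{values.shape[0]}x{values.shape[1]}"
            )
        if v_max is None:
            v_max = v_hdr
    if v_max is None:
        v_max = DEFAULT_VMAX
    return PressureFrame(values, v_max=v_max, validate=validate)


def write_samples(path: str | Path, samples: "SampleSet") -> None:
    """Write a sample set as CSV ``x,y,value`` with 1-based addresses."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("x,y,value\n")
        for (x, y), v in zip(samples.plan.addresses, samples.values):
            fh.write(f"{int(x)},{int(y)},{format(float(v), '.12g')}\n")


def read_samples(path: str | Path, P: int, Q: int) -> "SampleSet":
    """Read a CSV sample file back into a :class:`~csmat.sampler.SampleSet`.

    Order is preserved.  Out-of-range (1-based) addresses and duplicate
    cells are rejected.
    """
    from .sampler import AddressPlan, SampleSet  # local import: cycle guard

    path = Path(path)
    addresses: list[tuple[int, int]] = []
    values: list[float] = []
    seen: set[tuple[int, int]] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.lower().replace(" ", "") == "x,y,value":
                continue
            cells = [c for c in re.split(r"[,\s]+", text) if c]
            if len(cells) != 3:
                raise FrameParseError(
                    f"expected 3 fields (x,y,value), got {len(cells)}", line=lineno
                )
            try:
                x, y, v = int(cells[0]), int(cells[1]), float(cells[2])
            except ValueError as exc:
                raise FrameParseError(f"bad record: {exc}", line=lineno) from exc
            if not (1 <= x <= P and 1 <= y <= Q):
                raise AddressError(
                    f"address (x={x}, y={y}) outside 1-based grid {P}x{Q} "
                    f"(line {lineno})"
                )
            if (x, y) in seen:
                raise DuplicateAddressError(
                    f"duplicate address (x={x}, y={y}) at line {lineno}"
                )
            seen.add((x, y))
            addresses.append((x, y))
            values.append(v)
    plan = AddressPlan(np.array(addresses, dtype=int), P=P, Q=Q, mode="file", seed=None)
    return SampleSet(plan=plan, values=np.array(values, dtype=float))
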
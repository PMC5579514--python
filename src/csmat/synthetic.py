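"""Synthetic body-pressure phantoms, breathing sequences, and sparse signals.

Real recordings from the mat are smooth pressure blobs where the back,
waist, chest, or abdomen contacts the sensor grid, modulated in time by
respiration and perturbed by per-sensor electrical noise.  The generators
here emulate exactly that structure so every other module can be exercised
without hardware:

* a *phantom* is a sum of anisotropic Gaussian blobs plus a baseline and
  additive per-sensor Gaussian noise, clipped to the ADC range — smooth,
  hence approximately sparse in the 2D-DCT domain;
* a *breathing sequence* scales all blob amplitudes by
  ``1 + depth * sin(2 pi (RR/60) t + phase)`` with fresh noise per frame,
  so the total mat pressure is a noisy sinusoid at the true RR;
* an exactly S-sparse DCT coefficient matrix with its paired frame serves
  the exact-recovery experiments.

Default noise (0.02 V per sensor on a 0-5 V scale) and breathing depth
(0.2 of blob amplitude) are fixed study conditions chosen to mimic a quiet
supine recording; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .gridframe import FrameSequence, PressureFrame
from .sparse_transform import CoefficientMatrix, idct2

DEFAULT_NOISE_SD = 0.02  # V per sensor
DEFAULT_MODULATION_DEPTH = 0.2


@dataclass
class Blob:
    """One anisotropic Gaussian pressure blob (grid units, volts)."""

    cx: float
    cy: float
    sigma_x: float
    sigma_y: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("blob widths must be positive")
        if self.amplitude < 0:
            raise ValueError("blob amplitude must be nonnegative")


@dataclass
class PhantomSpec:
    blobs: list[Blob]
    baseline: float = 0.0
    noise_sd: float = DEFAULT_NOISE_SD
    v_max: float = 5.0


@dataclass
class BreathingSpec:
    rr_true: float = 15.0  # breaths per minute
    modulation_depth: float = DEFAULT_MODULATION_DEPTH
    duration: float = 60.0  # seconds
    frame_period: float = 0.2  # seconds (full-scan default)
    phase: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rr_true <= 0:
            raise ValueError("rr_true must be positive")
        if not (0.0 <= self.modulation_depth < 1.0):
            raise ValueError("modulation_depth must lie in [0, 1)")
        if self.frame_period <= 0 or self.duration <= 0:
            raise ValueError("duration and frame_period must be positive")


#: Body-part phantom presets: blob layouts on the default 32x32 grid.
_BODY_PARTS: dict[str, PhantomSpec] = {
    "back": PhantomSpec(
        blobs=[
            Blob(10.0, 11.0, 4.5, 5.0, 3.0),
            Blob(10.0, 22.0, 4.5, 5.0, 3.0),
            Blob(23.0, 16.5, 5.0, 7.0, 2.2),
        ]
    ),
    "waist": PhantomSpec(
        blobs=[Blob(16.0, 16.5, 6.0, 9.0, 2.8)]
    ),
    "chest": PhantomSpec(
        blobs=[
            Blob(12.0, 10.0, 5.0, 4.5, 3.2),
            Blob(12.0, 23.0, 5.0, 4.5, 3.2),
        ]
    ),
    "abdomen": PhantomSpec(
        blobs=[
            Blob(16.0, 16.5, 7.0, 8.0, 3.0),
            Blob(8.0, 16.5, 4.0, 6.0, 1.5),
        ]
    ),
}


def body_phantom(part: str = "back", noise_sd: float = DEFAULT_NOISE_SD) -> PhantomSpec:
    """Preset phantom for a trunk body part: back, waist, chest, or abdomen."""
    if part not in _BODY_PARTS:
        raise ValueError(f"unknown body part {part!r}; choose from {sorted(_BODY_PARTS)}")
    preset = _BODY_PARTS[part]
    return replace(preset, blobs=list(preset.blobs), noise_sd=noise_sd)


def _blob_field(spec: PhantomSpec, P: int, Q: int, scale: float = 1.0) -> np.ndarray:
    x = np.arange(1, P + 1)[:, None]
    y = np.arange(1, Q + 1)[None, :]
    values = np.full((P, Q), spec.baseline, dtype=float)
    for blob in spec.blobs:
        if not (1 <= blob.cx <= P and 1 <= blob.cy <= Q):
            raise ValueError(
                f"blob center ({blob.cx}, {blob.cy}) outside grid {P}x{Q}"
            )
        values += (scale * blob.amplitude) * np.exp(
            -((x - blob.cx) ** 2 / (2 * blob.sigma_x**2)
              + (y - blob.cy) ** 2 / (2 * blob.sigma_y**2))
        )
    return values


def gen_phantom(
    spec: PhantomSpec,
    P: int = 32,
    Q: int = 32,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> PressureFrame:
    """Render a phantom frame: blobs + baseline + per-sensor noise, clipped."""
    if rng is None:
        rng = np.random.default_rng(seed)
    values = _blob_field(spec, P, Q)
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=(P, Q))
    return PressureFrame(np.clip(values, 0.0, spec.v_max), v_max=spec.v_max)


def gen_breathing_sequence(
    phantom: PhantomSpec,
    breath: BreathingSpec,
    P: int = 32,
    Q: int = 32,
) -> FrameSequence:
    """Breathing-modulated frame sequence with ground-truth RR in metadata."""
    n_frames = int(np.floor(breath.duration / breath.frame_period)) + 1
    times = np.arange(n_frames) * breath.frame_period
    freq = breath.rr_true / 60.0
    rng = np.random.default_rng(breath.seed)
    frames = []
    for t in times:
        scale = 1.0 + breath.modulation_depth * np.sin(
            2.0 * np.pi * freq * t + breath.phase
        )
        values = _blob_field(phantom, P, Q, scale=scale)
        if phantom.noise_sd > 0:
            values = values + rng.normal(0.0, phantom.noise_sd, size=(P, Q))
        frames.append(
            PressureFrame(np.clip(values, 0.0, phantom.v_max), v_max=phantom.v_max)
        )
    metadata = {"rr_true": breath.rr_true, "frame_period": breath.frame_period}
    if breath.duration < 60.0 / breath.rr_true:
        metadata["warning"] = "duration shorter than one breath period"
    return FrameSequence(frames=frames, timestamps=times, metadata=metadata)


def gen_sparse_signal(
    P: int = 32,
    Q: int = 32,
    S: int = 10,
    amp_range: tuple[float, float] = (1.0, 10.0),
    seed: int | None = 0,
) -> tuple[CoefficientMatrix, PressureFrame]:
    """Exactly S-sparse DCT coefficients at random cells, with the paired frame."""
    N = P * Q
    if not (1 <= S <= N):
        raise ValueError(f"S={S} outside [1, {N}]")
    rng = np.random.default_rng(seed)
    support = rng.choice(N, size=S, replace=False)
    amplitudes = rng.uniform(*amp_range, size=S) * rng.choice([-1.0, 1.0], size=S)
    flat = np.zeros(N)
    flat[support] = amplitudes
    coeffs = CoefficientMatrix(flat.reshape(P, Q))
    return coeffs, idct2(coeffs)
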
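"""Quantitative phase reconstruction from four-LED oblique illumination.

A raw acquisition cycles four LEDs (left, right, top, bottom).  Each
opposing pair yields a normalized differential phase contrast image

    I_DPC = (I_a - I_b) / (I_a + I_b),

linear in the object phase for weak objects, and the two orthogonal DPC
images are jointly inverted to quantitative phase (radians) by Tikhonov-
regularized deconvolution:

    φ = F⁻¹ { Σ_k Ī_DPC^k · C_k* / ( Σ_k |C_k|² + α·max_q Σ_k |C_k|² ) } .

The regularization weight α is specified relative to the peak of the
summed transfer-function energy so its meaning is grid-independent.
Because C_k(0) = 0 the image mean is unobservable; reconstructions are
reported zero-mean by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np

from .optics import TransferFunction

logger = logging.getLogger(__name__)

LED_ORDER: Tuple[str, str, str, str] = ("left", "right", "top", "bottom")


def net_phase_rate(raw_fps: float) -> float:
    """Net phase-imaging rate in Hz: raw camera frame rate / 4 LED frames."""
    return raw_fps / 4.0


@dataclass(frozen=True)
class RawFrameSet:
    """Four co-registered single-LED intensity frames for one phase image."""

    left: np.ndarray
    right: np.ndarray
    top: np.ndarray
    bottom: np.ndarray
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        shapes = {f.shape for f in self.frames.values()}
        if len(shapes) != 1:
            raise ValueError(f"frames must share one shape, got {shapes}")
        for name, f in self.frames.items():
            if np.any(f < 0):
                raise ValueError(f"negative intensities in frame {name!r}")
        for a, b in (("left", "right"), ("top", "bottom")):
            if not (self.frames[a].any() or self.frames[b].any()):
                raise ValueError(f"opposing pair ({a}, {b}) is entirely zero")

    @property
    def frames(self) -> dict[str, np.ndarray]:
        return {
            "left": self.left,
            "right": self.right,
            "top": self.top,
            "bottom": self.bottom,
        }

    @property
    def shape(self) -> Tuple[int, int]:
        return self.left.shape


@dataclass
class DPCPair:
    """The two orthogonal normalized DPC images (k=1 horizontal, k=2 vertical)."""

    horizontal: np.ndarray
    vertical: np.ndarray

    @property
    def images(self) -> Tuple[np.ndarray, np.ndarray]:
        return (self.horizontal, self.vertical)

    def spectra(self) -> Tuple[np.ndarray, np.ndarray]:
        """2D Fourier transforms of the two DPC images (computed on demand)."""
        return (np.fft.fft2(self.horizontal), np.fft.fft2(self.vertical))


@dataclass(frozen=True)
class ReconParams:
    """Deconvolution parameters.

    ``alpha`` is the Tikhonov weight relative to max_q Σ_k|C_k|²; must be
    positive.  ``zero_mean`` subtracts the (unobservable) image mean.
    """

    alpha: float = 1e-3
    zero_mean: bool = True

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")


@dataclass(frozen=True)
class PhaseImage:
    """Quantitative phase in radians with its object-space sampling."""

    values: np.ndarray
    pixel_size: float


@dataclass(frozen=True)
class PhaseMovie:
    """T×H×W quantitative phase stack with a uniform time base (seconds)."""

    values: np.ndarray
    dt: float
    pixel_size: float

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("PhaseMovie values must be T x H x W")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


def compute_dpc(raw: RawFrameSet) -> DPCPair:
    """Form the two normalized DPC images from a four-LED frame set.

    Pixels where an opposing pair sums to zero are set to 0; if they exceed
    1% of the image a warning is logged.
    """
    images = []
    for a, b in (("left", "right"), ("top", "bottom")):
        fa = np.asarray(raw.frames[a], dtype=float)
        fb = np.asarray(raw.frames[b], dtype=float)
        den = fa + fb
        bad = den == 0
        n_bad = int(bad.sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            img = np.where(bad, 0.0, (fa - fb) / np.where(bad, 1.0, den))
        if n_bad > 0.01 * den.size:
            logger.warning(
                "DPC (%s-%s): %d/%d pixels with zero denominator set to 0",
                a, b, n_bad, den.size,
            )
        images.append(img)
    return DPCPair(horizontal=images[0], vertical=images[1])


def sum_absorption(raw: RawFrameSet) -> np.ndarray:
    """Absorption image: pixelwise sum of the four raw acquisitions."""
    return sum(np.asarray(f, dtype=float) for f in raw.frames.values())


def tikhonov_deconvolve(
    dpc: DPCPair,
    transfers: Sequence[TransferFunction],
    params: ReconParams = ReconParams(),
) -> PhaseImage:
    """Invert a DPC pair to quantitative phase.

    ``transfers`` must hold the horizontal-shear and vertical-shear transfer
    functions, in that order, on the same grid as the DPC images.
    """
    t_h, t_v = transfers
    axes = (t_h.shear_axis, t_v.shear_axis)
    if axes != ("horizontal", "vertical"):
        raise ValueError(
            f"transfers must be (horizontal, vertical) shear, got {axes}"
        )
    for img, t in zip(dpc.images, (t_h, t_v)):
        if img.shape != t.values.shape:
            raise ValueError("DPC image and transfer-function grids differ")

    energy = t_h.values**2 + t_v.values**2
    peak = float(energy.max())
    if peak <= 0:
        raise ValueError("transfer functions are identically zero")

    num = np.zeros(energy.shape, dtype=complex)
    for spec, t in zip(dpc.spectra(), (t_h, t_v)):
        num += spec * np.conj(t.complex_values)
    phase_spec = num / (energy + params.alpha * peak)
    phase = np.fft.ifft2(phase_spec)

    resid = np.linalg.norm(phase.imag) / max(np.linalg.norm(phase.real), 1e-300)
    if resid > 1e-8:
        logger.warning("deconvolution imaginary residue %.2e discarded", resid)
    values = phase.real
    if params.zero_mean:
        values = values - values.mean()
    return PhaseImage(values=values, pixel_size=t_h.config.pixel_size)


def reconstruct_movie(
    frames: Iterable[RawFrameSet] | np.ndarray,
    transfers: Sequence[TransferFunction],
    params: ReconParams = ReconParams(),
    frame_rate: float | None = None,
    led_order: Sequence[str] = LED_ORDER,
) -> PhaseMovie:
    """Reconstruct a phase time-lapse from a raw frame stream.

    ``frames`` is either an iterable of :class:`RawFrameSet` or a raw
    (N, H, W) intensity array cycling the LEDs in ``led_order``; in the
    latter case ``frame_rate`` (raw camera fps) is required and a trailing
    partial four-frame set is dropped with a warning.  The movie time step
    is 4 / frame_rate (one phase image per four raw frames).
    """
    if isinstance(frames, np.ndarray):
        if frame_rate is None:
            raise ValueError("frame_rate is required for a raw frame array")
        n = frames.shape[0]
        if n < 4:
            raise ValueError(f"need at least 4 raw frames, got {n}")
        if n % 4:
            logger.warning("dropping %d trailing raw frames (not a full set)", n % 4)
        sets = []
        for i in range(n // 4):
            chunk = {led: frames[4 * i + j] for j, led in enumerate(led_order)}
            sets.append(RawFrameSet(**chunk, timestamp=4 * i / frame_rate))
        frame_sets: Sequence[RawFrameSet] = sets
        dt = 4.0 / frame_rate
    else:
        frame_sets = list(frames)
        if not frame_sets:
            raise ValueError("empty frame stream")
        if frame_rate is not None:
            dt = 4.0 / frame_rate
        elif len(frame_sets) > 1:
            dt = frame_sets[1].timestamp - frame_sets[0].timestamp
            if not dt > 0:
                raise ValueError("cannot infer dt from timestamps; pass frame_rate")
        else:
            dt = 1.0

    stack = np.stack(
        [
            tikhonov_deconvolve(compute_dpc(fs), transfers, params).values
            for fs in frame_sets
        ]
    )
    logger.info(
        "reconstructed %d phase frames, net rate %.3g Hz",
        stack.shape[0], 1.0 / dt,
    )
    return PhaseMovie(values=stack, dt=dt, pixel_size=transfers[0].config.pixel_size)
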
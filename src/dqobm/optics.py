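"""Pupil, oblique source and DPC transfer-function models.

Differential phase contrast (DPC) under oblique partially coherent
illumination is, for weak objects, a linear system: the spectrum of the
normalized DPC image equals the object phase spectrum multiplied by a
transfer function determined by the pupil ``P`` and the effective source
angular distribution ``S``,

    C_DPC(q) = -i * ∫ [S(u) - S(u')] P(u + q) P*(u) d²u
                    / ∫ S(u) |P(u)|² d²u ,

where ``u'`` mirrors ``u`` along the shear (illumination) axis.  For a real
nonnegative source and a real pupil the integral is real, so ``C_DPC`` is
purely imaginary; this module stores the real odd coefficient array ``R(q)``
with ``C_DPC = -i R`` and re-attaches the ``-i`` inside the forward model.

All spatial frequencies are in cycles/μm on the FFT grid implied by the
image sampling (standard FFT ordering, DC at index ``[0, 0]``); illumination
angles map to frequency through the Abbe relation ``u = sinθ / λ``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Tuple

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

ShearAxis = Literal["horizontal", "vertical"]

#: array axis carrying each shear direction: horizontal shear varies along
#: image columns (axis 1), vertical along rows (axis 0)
_SHEAR_TO_ARRAY_AXIS = {"horizontal": 1, "vertical": 0}


class ConfigurationError(ValueError):
    """Raised when an optical configuration cannot be realized on the grid."""


# ---------------------------------------------------------------------------
# configuration and frequency grids
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OpticalConfig:
    """Imaging-system parameters.

    Parameters
    ----------
    wavelength : float
        Illumination wavelength in μm.
    numerical_aperture : float
        Objective NA (dimensionless), 0 < NA < 1.5.
    pixel_size : float
        Object-space sampling in μm per pixel.
    grid_shape : (int, int)
        Image grid (rows, cols); each dimension even and ≥ 8.
    """

    wavelength: float
    numerical_aperture: float
    pixel_size: float
    grid_shape: Tuple[int, int]

    def __post_init__(self) -> None:
        if not self.wavelength > 0:
            raise ValueError(f"wavelength must be > 0, got {self.wavelength}")
        if not 0 < self.numerical_aperture < 1.5:
            raise ValueError(
                f"numerical_aperture must be in (0, 1.5), got {self.numerical_aperture}"
            )
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        rows, cols = self.grid_shape
        for n in (rows, cols):
            if n < 8 or n % 2:
                raise ValueError(
                    f"grid_shape dimensions must be even and >= 8, got {self.grid_shape}"
                )

    @property
    def cutoff(self) -> float:
        """Pupil cutoff frequency NA/λ in cycles/μm."""
        return self.numerical_aperture / self.wavelength

    @property
    def nyquist(self) -> float:
        """Sampling Nyquist frequency 1/(2·pixel_size) in cycles/μm."""
        return 1.0 / (2.0 * self.pixel_size)

    def frequency_grid(self) -> Tuple[np.ndarray, np.ndarray]:
        """Return (fy, fx) broadcastable FFT-ordered frequency axes (cycles/μm)."""
        rows, cols = self.grid_shape
        fy = np.fft.fftfreq(rows, d=self.pixel_size)[:, None]
        fx = np.fft.fftfreq(cols, d=self.pixel_size)[None, :]
        return fy, fx


def rayleigh_resolution(config: OpticalConfig) -> float:
    """Diffraction-limited Rayleigh resolution 0.61·λ/NA in μm."""
    return 0.61 * config.wavelength / config.numerical_aperture


# ---------------------------------------------------------------------------
# pupil and sources
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Pupil:
    """Binary circular pupil on the FFT frequency grid.

    ``values`` is 1 inside the cutoff NA/λ and exactly 0 outside; an
    aberration-free system is assumed throughout.
    """

    values: np.ndarray
    cutoff: float
    config: OpticalConfig


@dataclass(frozen=True)
class SourceDistribution:
    """Nonnegative, unit-sum effective source weights on the pupil grid."""

    values: np.ndarray
    shear_axis: ShearAxis
    config: OpticalConfig


def make_pupil(config: OpticalConfig) -> Pupil:
    """Build the binary circular pupil for ``config``.

    Raises
    ------
    ConfigurationError
        If the cutoff NA/λ exceeds the grid Nyquist frequency, i.e. the
        sampling cannot contain the aperture.
    """
    cutoff = config.cutoff
    if cutoff > config.nyquist:
        raise ConfigurationError(
            f"pupil cutoff {cutoff:.4f} cycles/um exceeds Nyquist "
            f"{config.nyquist:.4f}; decrease pixel_size or NA"
        )
    fy, fx = config.frequency_grid()
    values = (fy * fy + fx * fx <= cutoff * cutoff).astype(float)
    return Pupil(values=values, cutoff=cutoff, config=config)


def make_oblique_source(
    config: OpticalConfig,
    offset: float | Tuple[float, float],
    width: float,
    shear_axis: ShearAxis,
    truncation: float = 3.5,
) -> SourceDistribution:
    """Parametric oblique source: truncated Gaussian lobe in frequency.

    The lobe stands in for the angular distribution of multiply scattered
    light returning through the focal plane; its offset along the shear axis
    sets the effective illumination obliquity.

    Parameters
    ----------
    offset : float or (float, float)
        Lobe center in cycles/μm.  A scalar displaces along ``shear_axis``;
        a pair gives the (fy, fx) center directly.
    width : float
        Gaussian σ in cycles/μm (> 0).
    truncation : float
        Radius of support in units of ``width``.
    """
    if not width > 0:
        raise ValueError(f"width must be > 0, got {width}")
    if np.isscalar(offset):
        center = [0.0, 0.0]
        center[_SHEAR_TO_ARRAY_AXIS[shear_axis]] = float(offset)  # type: ignore[index]
    else:
        center = list(offset)  # type: ignore[arg-type]
    fy, fx = config.frequency_grid()
    r2 = (fy - center[0]) ** 2 + (fx - center[1]) ** 2
    values = np.exp(-0.5 * r2 / width**2)
    values[r2 > (truncation * width) ** 2] = 0.0
    total = values.sum()
    if total <= 0:
        raise ValueError(
            f"source lobe centered at {tuple(center)} cycles/um lies entirely "
            "outside the frequency grid"
        )
    return SourceDistribution(values=values / total, shear_axis=shear_axis, config=config)


def default_source(config: OpticalConfig, shear_axis: ShearAxis) -> SourceDistribution:
    """Default oblique source: lobe at 0.5×cutoff with σ = 0.2×cutoff."""
    c = config.cutoff
    return make_oblique_source(config, offset=0.5 * c, width=0.2 * c, shear_axis=shear_axis)


def monte_carlo_source(
    config: OpticalConfig,
    scattering_mfp: float,
    anisotropy: float,
    n_photons: int,
    seed: int,
    shear_axis: ShearAxis = "horizontal",
    led_offset: float = 150.0,
    focal_depth: float = 30.0,
    collection_radius: float = 80.0,
    max_steps: int = 400,
) -> SourceDistribution:
    """Toy random-walk estimate of the effective oblique source.

    Photons are launched downward into a homogeneous scattering half-space
    from a lateral LED position, propagated with exponential step lengths
    (mean ``scattering_mfp``, μm) and Henyey–Greenstein scattering
    (``anisotropy`` = ⟨cosθ⟩), and binned by transverse direction u = sinθ/λ
    when they cross the focal plane travelling upward within the collection
    cone and within ``collection_radius`` (μm) of the optical axis — the
    lateral offset between LED and detection field is what makes the
    effective source oblique.  This is a qualitative stand-in for a full
    photon-transport simulation of the sample: it reproduces the sign and
    rough scale of the source obliquity, nothing more.

    Deterministic for a fixed seed.
    """
    if not scattering_mfp > 0:
        raise ValueError("scattering_mfp must be > 0")
    if not -1 < anisotropy < 1:
        raise ValueError("anisotropy must be in (-1, 1)")
    if n_photons < 10_000:
        raise ValueError("n_photons must be >= 10000 for a usable histogram")

    rng = np.random.default_rng(seed)
    axis = _SHEAR_TO_ARRAY_AXIS[shear_axis]

    # positions (n, 3) = (y, x, z), z down; LED displaced along the shear axis
    pos = np.zeros((n_photons, 3))
    pos[:, axis] = -led_offset
    direction = np.zeros((n_photons, 3))
    direction[:, 2] = 1.0

    g = anisotropy
    na = config.numerical_aperture
    collected_u = []
    alive = np.ones(n_photons, bool)

    for _ in range(max_steps):
        n_alive = int(alive.sum())
        if n_alive == 0:
            break
        step = rng.exponential(scattering_mfp, size=n_alive)
        new_pos = pos[alive] + direction[alive] * step[:, None]

        # crossing the focal plane upward: record direction if within the NA
        # cone and the detection field of view about the axis
        d = direction[alive]
        p0 = pos[alive]
        crossed = (p0[:, 2] > focal_depth) & (new_pos[:, 2] <= focal_depth)
        if crossed.any():
            dc = d[crossed]
            a0 = p0[crossed]
            a1 = new_pos[crossed]
            frac = (a0[:, 2] - focal_depth) / (a0[:, 2] - a1[:, 2])
            cross_xy = a0[:, :2] + frac[:, None] * (a1[:, :2] - a0[:, :2])
            in_fov = np.hypot(cross_xy[:, 0], cross_xy[:, 1]) <= collection_radius
            sin_t = np.hypot(dc[:, 0], dc[:, 1])
            in_cone = (sin_t <= na) & in_fov
            if in_cone.any():
                collected_u.append(dc[in_cone, :2] / config.wavelength)
            # collected or not, these photons leave the simulation upward
            idx = np.flatnonzero(alive)
            alive[idx[crossed]] = False
            keep = ~crossed
            new_pos = new_pos[keep]
            d = d[keep]

        # photons escaping through the surface without collection die
        idx = np.flatnonzero(alive)
        escaped = new_pos[:, 2] < 0
        alive[idx[escaped]] = False
        keep = ~escaped
        idx = idx[keep]
        pos[idx] = new_pos[keep]

        # Henyey-Greenstein deflection about the current direction
        nk = idx.size
        if nk == 0:
            continue
        if abs(g) > 1e-9:
            u = rng.uniform(size=nk)
            cos_t = (1 + g * g - ((1 - g * g) / (1 - g + 2 * g * u)) ** 2) / (2 * g)
        else:
            cos_t = rng.uniform(-1, 1, size=nk)
        cos_t = np.clip(cos_t, -1.0, 1.0)
        sin_t = np.sqrt(1 - cos_t**2)
        phi = rng.uniform(0, 2 * np.pi, size=nk)
        d0 = direction[idx]
        # orthonormal frame around d0
        ref = np.zeros_like(d0)
        ref[:, 0] = 1.0
        swap = np.abs(d0[:, 0]) > 0.9
        ref[swap] = [0.0, 1.0, 0.0]
        e1 = np.cross(d0, ref)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(d0, e1)
        direction[idx] = (
            cos_t[:, None] * d0
            + sin_t[:, None] * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
        )

    if not collected_u:
        raise RuntimeError(
            "no photons returned within the collection cone; increase n_photons "
            "or shorten scattering_mfp"
        )
    u = np.concatenate(collected_u, axis=0)

    rows, cols = config.grid_shape
    dy = np.fft.fftfreq(rows, d=config.pixel_size)
    dx = np.fft.fftfreq(cols, d=config.pixel_size)
    # histogram on the centered grid, then back to FFT ordering
    ey = np.sort(np.fft.fftshift(dy))
    ex = np.sort(np.fft.fftshift(dx))
    step_y, step_x = ey[1] - ey[0], ex[1] - ex[0]
    edges_y = np.concatenate([ey - step_y / 2, [ey[-1] + step_y / 2]])
    edges_x = np.concatenate([ex - step_x / 2, [ex[-1] + step_x / 2]])
    hist, _, _ = np.histogram2d(u[:, 0], u[:, 1], bins=(edges_y, edges_x))
    hist = np.fft.ifftshift(hist)
    total = hist.sum()
    if total <= 0:
        raise RuntimeError("all returning photons fell outside the frequency grid")
    logger.info(
        "monte_carlo_source: %d/%d photons collected", int(total), n_photons
    )
    return SourceDistribution(values=hist / total, shear_axis=shear_axis, config=config)


# ---------------------------------------------------------------------------
# shear reflection
# ---------------------------------------------------------------------------


def _reflect_fft_axis(a: np.ndarray, axis: int) -> np.ndarray:
    """Map f -> -f along ``axis`` for an FFT-ordered array (u' operation)."""
    return np.roll(np.flip(a, axis=axis), 1, axis=axis)


def reflect_shear(source: SourceDistribution) -> SourceDistribution:
    """Mirror the source along its shear axis (the u → u' map); an involution."""
    axis = _SHEAR_TO_ARRAY_AXIS[source.shear_axis]
    return SourceDistribution(
        values=_reflect_fft_axis(source.values, axis),
        shear_axis=source.shear_axis,
        config=source.config,
    )


# ---------------------------------------------------------------------------
# transfer function
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransferFunction:
    """DPC weak-object transfer function on the FFT frequency grid.

    ``values`` holds the real odd array R(q); the physical complex transfer
    is C_DPC(q) = -i·R(q), which is Hermitian-symmetric (R real and odd), so
    DPC images of real phase objects are real.
    """

    values: np.ndarray
    shear_axis: ShearAxis
    config: OpticalConfig

    @property
    def complex_values(self) -> np.ndarray:
        """The complex transfer C_DPC = -i·R used by the forward model."""
        return -1j * self.values


def compute_dpc_transfer(source: SourceDistribution, pupil: Pupil) -> TransferFunction:
    """Evaluate the DPC transfer function from source and pupil.

    The numerator ∫[S(u) − S(u′)] P(u+q) P*(u) d²u is evaluated as a discrete
    cross-correlation over the pupil grid (a Riemann sum; the grid cell area
    cancels against the denominator ∫S|P|²).  ``P(u+q)`` is evaluated on a
    doubled frequency range so no periodic wrap-around occurs — frequencies
    beyond the grid see the true (zero) pupil.

    Raises
    ------
    ValueError
        If the source mass does not overlap the pupil (denominator ≤ 0) or
        the grids differ.
    """
    if source.values.shape != pupil.values.shape:
        raise ValueError("source and pupil must share the same frequency grid")
    cfg = pupil.config
    rows, cols = cfg.grid_shape

    den = float(np.sum(source.values * np.abs(pupil.values) ** 2))
    if den <= 0:
        raise ValueError(
            "source and pupil are disjoint in frequency: denominator of the "
            "transfer function is not positive"
        )

    axis = _SHEAR_TO_ARRAY_AXIS[source.shear_axis]
    diff = source.values - _reflect_fft_axis(source.values, axis)
    # integrand factor D(u) = [S(u) - S(u')] P*(u), centered ordering
    d_c = np.fft.fftshift(diff * np.conj(pupil.values)).real

    # pupil on the doubled grid covering u + q without wrap
    dfy = 1.0 / (rows * cfg.pixel_size)
    dfx = 1.0 / (cols * cfg.pixel_size)
    by = (np.arange(2 * rows) - rows) * dfy
    bx = (np.arange(2 * cols) - cols) * dfx
    p_big = (
        by[:, None] ** 2 + bx[None, :] ** 2 <= pupil.cutoff**2
    ).astype(float)

    # num_c[k] = sum_i D[i] * P_big[i + k]  (valid cross-correlation); with
    # even grids the centered index arithmetic aligns with no extra offset
    num_c = signal.correlate(p_big, d_c, mode="valid")[:rows, :cols]

    values = np.fft.ifftshift(num_c) / den
    # enforce exact discrete odd symmetry along the shear axis: the raw sum
    # is odd to rounding except at the self-conjugate Nyquist bins, which a
    # real-valued forward model requires to be zero
    values = 0.5 * (values - _reflect_fft_axis(values, axis))
    values[0, 0] = 0.0  # analytically zero by the u -> u' change of variables
    return TransferFunction(values=values, shear_axis=source.shear_axis, config=cfg)


def forward_dpc(phase: np.ndarray, transfer: TransferFunction) -> np.ndarray:
    """Weak-object forward model: DPC image with spectrum C_DPC(q)·φ̃(q).

    ``phase`` is the object phase in radians (weak, |φ| ≲ 0.5 rad for the
    linearization to describe a real system; the map itself is linear for
    any amplitude).  The result is real and zero-mean since C_DPC(0) = 0.
    """
    phase = np.asarray(phase, dtype=float)
    if phase.shape != transfer.values.shape:
        raise ValueError(
            f"phase shape {phase.shape} does not match transfer grid "
            f"{transfer.values.shape}"
        )
    spec = np.fft.fft2(phase) * transfer.complex_values
    img = np.fft.ifft2(spec)
    # Hermitian symmetry of C·φ̃ makes the image real up to rounding
    return img.real
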
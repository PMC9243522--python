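"""Standard-format I/O: TIFF stacks, JSON sidecars, manifests and renders.

Raw acquisitions travel as multi-page grayscale TIFF with a JSON (or YAML)
sidecar carrying the frame-rate and LED-order metadata; phase movies,
transfer functions and phasor maps are written as 32-bit float TIFF with
JSON sidecars describing grid spacing, time base and parameters; functional
images export as 8-bit RGB PNG.  ``write_outputs`` collects files into a
manifest with SHA-256 checksums so a rerun with the same config and seed
can be verified bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import tifffile
import yaml

from .dynamics import PhasorMap
from .optics import OpticalConfig, TransferFunction
from .recon import LED_ORDER, PhaseMovie, RawFrameSet

logger = logging.getLogger(__name__)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _load_sidecar(path: Path) -> dict:
    """Load the JSON (or YAML) sidecar next to a TIFF, or an empty dict."""
    for cand in (_sidecar_path(path), path.with_suffix(".json"), path.with_suffix(".yaml")):
        if cand.exists() and cand != path:
            with open(cand) as fh:
                if cand.suffix == ".yaml":
                    return yaml.safe_load(fh) or {}
                return json.load(fh)
    return {}


# ---------------------------------------------------------------------------
# raw stacks
# ---------------------------------------------------------------------------


def write_raw_stack(
    path: str | Path,
    frames: Iterable[RawFrameSet],
    frame_rate: float,
    led_order: Sequence[str] = LED_ORDER,
) -> Path:
    """Write a raw frame stream as multi-page float32 TIFF plus JSON sidecar."""
    path = Path(path)
    pages: List[np.ndarray] = []
    for fs in frames:
        for led in led_order:
            pages.append(np.asarray(fs.frames[led], dtype=np.float32))
    tifffile.imwrite(path, np.stack(pages), photometric="minisblack")
    sidecar = {
        "frame_rate_hz": frame_rate,
        "led_order": list(led_order),
        "n_pages": len(pages),
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return path


def read_raw_stack(
    path: str | Path,
    led_order: Optional[Sequence[str]] = None,
    frame_rate: Optional[float] = None,
) -> Tuple[List[RawFrameSet], float]:
    """Read a multi-page TIFF into four-frame sets, returning (sets, frame_rate).

    LED order and frame rate come from arguments or, failing that, the JSON
    /YAML sidecar; a missing frame rate raises an error naming the sidecar
    key.  A page count not divisible by four is truncated with a warning.
    """
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    n = stack.shape[0]
    if n < 4:
        raise ValueError(f"stack has {n} pages; at least 4 are required")
    meta = _load_sidecar(path)
    if frame_rate is None:
        frame_rate = meta.get("frame_rate_hz")
    if frame_rate is None:
        raise ValueError(
            f"no frame rate for {path}: pass frame_rate or provide the "
            "'frame_rate_hz' key in the sidecar"
        )
    if led_order is None:
        led_order = meta.get("led_order", LED_ORDER)
    if sorted(led_order) != sorted(LED_ORDER):
        raise ValueError(f"led_order must permute {LED_ORDER}, got {tuple(led_order)}")
    if n % 4:
        logger.warning("truncating %d trailing pages (not a full 4-frame set)", n % 4)
    sets = []
    for i in range(n // 4):
        frames = {led: np.asarray(stack[4 * i + j], dtype=float) for j, led in enumerate(led_order)}
        sets.append(RawFrameSet(**frames, timestamp=4 * i / frame_rate))
    return sets, float(frame_rate)


# ---------------------------------------------------------------------------
# float TIFF arrays with sidecars
# ---------------------------------------------------------------------------


def write_phase_movie(path: str | Path, movie: PhaseMovie) -> Path:
    """Write a phase movie as 32-bit float TIFF with time-step/pixel-size tags."""
    path = Path(path)
    tifffile.imwrite(path, movie.values.astype(np.float32), photometric="minisblack")
    with open(_sidecar_path(path), "w") as fh:
        json.dump(
            {"dt_s": movie.dt, "pixel_size_um": movie.pixel_size, "units": "radians"},
            fh,
            indent=2,
        )
    return path


def read_phase_movie(path: str | Path) -> PhaseMovie:
    path = Path(path)
    values = np.asarray(tifffile.imread(path), dtype=float)
    meta = _load_sidecar(path)
    return PhaseMovie(
        values=values,
        dt=float(meta["dt_s"]),
        pixel_size=float(meta["pixel_size_um"]),
    )


def write_transfer_function(path: str | Path, transfer: TransferFunction) -> Path:
    """Export a transfer function as float32 TIFF + JSON sidecar (grid, axis)."""
    path = Path(path)
    cfg = transfer.config
    tifffile.imwrite(path, transfer.values.astype(np.float32), photometric="minisblack")
    with open(_sidecar_path(path), "w") as fh:
        json.dump(
            {
                "shear_axis": transfer.shear_axis,
                "wavelength_um": cfg.wavelength,
                "numerical_aperture": cfg.numerical_aperture,
                "pixel_size_um": cfg.pixel_size,
                "grid_shape": list(cfg.grid_shape),
                "frequency_units": "cycles/um",
                "ordering": "fft",
            },
            fh,
            indent=2,
        )
    return path


def read_transfer_function(path: str | Path) -> TransferFunction:
    path = Path(path)
    values = np.asarray(tifffile.imread(path), dtype=float)
    meta = _load_sidecar(path)
    cfg = OpticalConfig(
        wavelength=meta["wavelength_um"],
        numerical_aperture=meta["numerical_aperture"],
        pixel_size=meta["pixel_size_um"],
        grid_shape=tuple(meta["grid_shape"]),
    )
    return TransferFunction(values=values, shear_axis=meta["shear_axis"], config=cfg)


def write_phasor_map(path: str | Path, phasors: PhasorMap) -> Path:
    """Store (g, s, amplitude) as a 3-channel float32 TIFF + sidecar."""
    path = Path(path)
    stack = np.stack([phasors.g, phasors.s, phasors.amplitude]).astype(np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack")
    with open(_sidecar_path(path), "w") as fh:
        json.dump({"tau_s": phasors.tau, "channels": ["g", "s", "amplitude"]}, fh, indent=2)
    return path


def write_functional_png(path: str | Path, rgb: np.ndarray) -> Path:
    """Export a functional image as 8-bit RGB PNG."""
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path, (np.clip(rgb, 0, 1) * 255).astype(np.uint8))
    return path


def plot_phasor_histogram(
    path: str | Path, counts: np.ndarray, g_edges: np.ndarray, s_edges: np.ndarray
) -> Path:
    """Render a phasor histogram with the universal-semicircle overlay."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(5, 4))
    with np.errstate(divide="ignore"):
        img = np.log10(np.where(counts > 0, counts, np.nan))
    ax.imshow(
        img.T,
        origin="lower",
        extent=(g_edges[0], g_edges[-1], s_edges[0], s_edges[-1]),
        aspect="auto",
        cmap="viridis",
    )
    theta = np.linspace(0, np.pi, 200)
    ax.plot(0.5 + 0.5 * np.cos(theta), 0.5 * np.sin(theta), "k--", lw=1,
            label="universal semicircle")
    ax.set_xlabel("g")
    ax.set_ylabel("s")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(files: Sequence[str | Path], out_dir: str | Path,
                  params: Optional[dict] = None) -> Path:
    """Write a manifest listing every output file with its SHA-256 checksum.

    ``files`` are paths already written under ``out_dir``; ``params`` (the
    effective run parameters) are embedded so a run is reproducible from its
    manifest alone.  Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for f in files:
        f = Path(f)
        entries.append(
            {
                "path": str(f.relative_to(out_dir) if f.is_relative_to(out_dir) else f),
                "sha256": _sha256(f),
                "bytes": f.stat().st_size,
            }
        )
    manifest = {"files": entries, "parameters": params or {}}
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("wrote manifest with %d files to %s", len(entries), manifest_path)
    return manifest_path


def verify_manifest(manifest_path: str | Path) -> bool:
    """Re-hash every file in a manifest; True iff all checksums match."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base = manifest_path.parent
    for entry in manifest["files"]:
        p = Path(entry["path"])
        if not p.is_absolute():
            p = base / p
        if _sha256(p) != entry["sha256"]:
            logger.warning("checksum mismatch for %s", p)
            return False
    return True
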
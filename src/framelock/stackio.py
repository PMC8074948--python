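"""Reading and writing frame stacks, images and result sidecars.

Two stack dialects are supported:

* multi-page TIFF (``.tif``/``.tiff``), 32-bit float, one page per frame;
* a directory of zero-padded 16-bit PNG frames (``frame_0000.png``, ...)
  with the linear scaling recorded in the metadata sidecar.

Either dialect carries a JSON sidecar (``<name>.json`` next to the TIFF,
``metadata.json`` inside a PNG directory) echoing the acquisition
configuration and seed so any stack on disk is self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .simulate import FrameStack, ModulationConfig

__all__ = [
    "write_stack",
    "read_stack",
    "write_image",
    "read_image",
    "write_results",
]

_PNG_SCALE = 65535.0


def _sidecar_path(path: Path) -> Path:
    if path.suffix.lower() in (".tif", ".tiff"):
        return path.with_suffix(".json")
    return path / "metadata.json"


def write_stack(stack: FrameStack, path) -> Path:
    """Write ``stack`` as multi-page float TIFF or a PNG frame directory.

    The dialect is chosen by the path: ``.tif``/``.tiff`` for TIFF,
    anything else is treated as a directory of 16-bit PNGs scaled to the
    stack's value range.
    """
    path = Path(path)
    meta = {"config": stack.config.to_dict(), "n_frames": len(stack)}
    if path.suffix.lower() in (".tif", ".tiff"):
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, stack.frames.astype(np.float32))
        meta["format"] = "tiff-float32"
    else:
        path.mkdir(parents=True, exist_ok=True)
        lo = float(stack.frames.min())
        hi = float(stack.frames.max())
        span = (hi - lo) or 1.0
        meta.update({"format": "png16", "scale_lo": lo, "scale_hi": hi})
        for i, frame in enumerate(stack.frames):
            coded = np.round((frame - lo) / span * _PNG_SCALE).astype(np.uint16)
            iio.imwrite(path / f"frame_{i:04d}.png", coded)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_stack(path) -> FrameStack:
    """Read a stack written by :func:`write_stack` (either dialect)."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    config = (
        ModulationConfig.from_dict(meta["config"])
        if "config" in meta
        else ModulationConfig()
    )
    if path.suffix.lower() in (".tif", ".tiff"):
        frames = tifffile.imread(path).astype(np.float64)
        if frames.ndim == 2:
            frames = frames[None]
    else:
        files = sorted(path.glob("frame_*.png"))
        if not files:
            raise FileNotFoundError(f"no frame_*.png files in {path}")
        coded = np.stack([iio.imread(f) for f in files]).astype(np.float64)
        lo = meta.get("scale_lo", 0.0)
        hi = meta.get("scale_hi", 1.0)
        frames = coded / _PNG_SCALE * ((hi - lo) or 1.0) + lo
    return FrameStack(frames=frames, config=config)


def write_image(image: np.ndarray, path) -> Path:
    """Write a single grayscale image as 32-bit float TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    return path


def read_image(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.float64)


def write_results(results, directory) -> Path:
    """Write demodulated channel images plus a JSON sidecar.

    One ``<channel>.tif`` per channel (and ``<channel>_amplitude.tif`` /
    ``<channel>_phase.tif`` when I/Q maps are present) and a
    ``demodulation.json`` recording the window and configuration.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for ch, img in results.channel_images.items():
        write_image(img, directory / f"{ch}.tif")
    if results.amplitude_images:
        for ch, img in results.amplitude_images.items():
            write_image(img, directory / f"{ch}_amplitude.tif")
    if results.phase_images:
        for ch, img in results.phase_images.items():
            write_image(img, directory / f"{ch}_phase.tif")
    sidecar = {
        "window_used": results.window_used,
        "snr_gain_db": results.snr_gain_db,
        "channels": list(results.channels),
        "config": results.config.to_dict(),
    }
    (directory / "demodulation.json").write_text(json.dumps(sidecar, indent=2))
    return directory
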
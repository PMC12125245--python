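"""File formats and provenance records.

Axis convention throughout the package: (channel, row, column), row 0 at
the top; enforced here at the I/O boundary.  Autofluorescence stacks and
intermediates travel as 32-bit float multi-plane TIFF, final stains as
8-bit PNG (or TIFF), both lossless.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

AF_CHANNEL_NAMES = ("DAPI", "TxRed", "FITC", "Cy5")

__all__ = [
    "AF_CHANNEL_NAMES",
    "read_af_stack",
    "write_af_stack",
    "read_rgb",
    "write_rgb",
    "write_provenance",
]


def read_af_stack(path, expected_channels: int | None = None):
    """Read a multi-plane autofluorescence TIFF as (C, H, W) float32.

    Returns ``(stack, metadata)``; metadata declares the channel order
    (DAPI, TxRed, FITC, Cy5, truncated to the plane count).  A plane count
    different from ``expected_channels`` (a model's configured input
    channels) is an error.
    """
    path = Path(path)
    stack = np.asarray(tifffile.imread(path))
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3 or not 1 <= stack.shape[0] <= 4:
        raise ValueError(
            f"{path}: expected a TIFF with 1-4 planes, got shape "
            f"{stack.shape}")
    if expected_channels is not None and stack.shape[0] != expected_channels:
        raise ValueError(
            f"{path}: stack has {stack.shape[0]} planes but the model is "
            f"configured for {expected_channels} autofluorescence channels")
    meta = {"channels": AF_CHANNEL_NAMES[:stack.shape[0]],
            "path": str(path)}
    return stack.astype(np.float32), meta


def write_af_stack(path, stack: np.ndarray, force: bool = False) -> None:
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists (pass force=True to replace)")
    stack = np.asarray(stack, dtype=np.float32)
    if stack.ndim != 3:
        raise ValueError("stack must be (C, H, W)")
    tifffile.imwrite(path, stack, photometric="minisblack")


def read_rgb(path) -> np.ndarray:
    """Read an 8-bit RGB image as channel-first (3, H, W)."""
    img = iio.imread(Path(path))
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError(f"{path}: not an RGB image (shape {img.shape})")
    return np.ascontiguousarray(img[:, :, :3].transpose(2, 0, 1))


def write_rgb(path, image: np.ndarray, force: bool = False) -> None:
    """Write a channel-first 8-bit RGB image losslessly (PNG or TIFF)."""
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists (pass force=True to replace)")
    image = np.asarray(image)
    if image.dtype != np.uint8:
        raise ValueError(
            "write_rgb expects 8-bit data; denormalize / quantize the "
            "float image first")
    if image.ndim != 3 or image.shape[0] != 3:
        raise ValueError("image must be (3, H, W)")
    hwc = np.ascontiguousarray(image.transpose(1, 2, 0))
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, hwc)
    else:
        iio.imwrite(path, hwc)


def _config_hash(payload: dict) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(path, command: str, config: dict, seed) -> dict:
    """Write the provenance record (config hash, seed, package version)
    that accompanies every artifact a command produces."""
    from . import __version__
    record = {
        "command": command,
        "config": config,
        "config_hash": _config_hash(config),
        "seed": seed,
        "package_version": __version__,
    }
    Path(path).write_text(json.dumps(record, indent=2, default=str))
    return record
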
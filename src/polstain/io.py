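"""Multipage-TIFF / PNG persistence with JSON provenance sidecars.

Multichannel stacks (8-channel DoFP intensities, 4-channel Stokes,
16-channel Mueller, 1/3-channel encodings) are stored as float32 multipage
TIFFs, one page per channel, channel-last in memory.  Every stack gets a
``<name>.json`` sidecar recording what the channels are plus any
configuration the caller supplies.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = ["write_stack", "read_stack", "write_png", "read_png", "write_sidecar", "read_sidecar"]


def write_sidecar(path: Path, meta: dict) -> None:
    Path(path).with_suffix(Path(path).suffix + ".json").write_text(
        json.dumps(meta, indent=1, sort_keys=True, default=str)
    )


def read_sidecar(path: Path) -> dict | None:
    p = Path(path).with_suffix(Path(path).suffix + ".json")
    return json.loads(p.read_text()) if p.exists() else None


def write_stack(path, data: np.ndarray, meta: dict | None = None) -> None:
    """Write an (H, W, C) array as a C-page float32 TIFF plus sidecar."""
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[..., None]
    if data.ndim != 3:
        raise ValueError(f"expected (H, W, C) stack, got shape {data.shape}")
    pages = np.moveaxis(data.astype(np.float32), -1, 0)
    tifffile.imwrite(Path(path), pages, photometric="minisblack")
    write_sidecar(path, {"channels": data.shape[-1], "shape": list(data.shape), **(meta or {})})


def read_stack(path) -> np.ndarray:
    """Read a multipage TIFF back to (H, W, C) float32."""
    pages = tifffile.imread(Path(path))
    if pages.ndim == 2:
        pages = pages[None]
    return np.moveaxis(pages, 0, -1).astype(np.float32)


def write_png(path, rgb: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(rgb, dtype=np.uint8))


def read_png(path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path)))
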
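"""Translator-ready encodings of polarimetric image stacks.

Two input representations feed the translation model:

* **PCA of Mueller channels** — the 16 Mueller element images are strongly
  correlated; a dataset-level PCA over pooled training pixels compresses
  them to the top one (PCA1) or three (PCA3) principal channels, each
  affinely mapped to [-1, 1].
* **S0-normalized Stokes** — the snapshot route: channels
  ``(S1/S0, S2/S0, S3/S0)`` are already dimensionless in [-1, 1] and
  invariant to illumination intensity.

Patch extraction / stitching tiles large scenes into the fixed patch size
the translator consumes (256x256 by default, smaller at toy scale).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "PCABasis",
    "EncodedImage",
    "PatchLayout",
    "fit_pca",
    "apply_pca",
    "encode_stokes",
    "encode_brightfield",
    "decode_brightfield",
    "extract_patches",
    "stitch_patches",
]

#: Illumination floor for S0 division, as a fraction of the image maximum.
S0_FLOOR_FRACTION = 1e-6


@dataclass
class EncodedImage:
    """H x W x C image in [-1, 1] with a provenance tag."""

    data: np.ndarray
    provenance: str  # stokes | pca1 | pca3 | brightfield

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim == 2:
            self.data = self.data[..., None]
        if self.data.shape[-1] not in (1, 3):
            raise ValueError(f"encoded image must have 1 or 3 channels, got {self.data.shape}")


@dataclass
class PCABasis:
    """Principal axes of the pooled 16-channel Mueller pixel cloud.

    ``scale_bounds[c] = (low, high)`` are the per-component score bounds
    (1st/99th percentile of the training scores) used for the affine map to
    [-1, 1]; stored so the same mapping is reused at test time.
    """

    means: np.ndarray
    loadings: np.ndarray  # (16, k), orthonormal columns
    explained_ratio: np.ndarray
    scale_bounds: np.ndarray  # (k, 2)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def to_json(self) -> str:
        return json.dumps(
            {
                "means": self.means.tolist(),
                "loadings": self.loadings.tolist(),
                "explained_ratio": self.explained_ratio.tolist(),
                "scale_bounds": self.scale_bounds.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PCABasis":
        d = json.loads(text)
        return cls(
            np.array(d["means"]),
            np.array(d["loadings"]),
            np.array(d["explained_ratio"]),
            np.array(d["scale_bounds"]),
        )


def _pool_pixels(stacks) -> np.ndarray:
    mats = []
    for s in stacks:
        s = np.asarray(s, dtype=float)
        if s.ndim != 3 or s.shape[-1] != 16:
            raise ValueError(f"Mueller stack must be (H, W, 16), got {s.shape}")
        mats.append(s.reshape(-1, 16))
    return np.concatenate(mats, axis=0)


def fit_pca(stacks, k: int) -> PCABasis:
    """Fit a dataset-level PCA over pooled pixels of Mueller stacks.

    Channels are mean-centered but not variance-scaled: Mueller elements
    share physical units.  Component signs are fixed so the largest-
    magnitude loading entry is positive, making the basis deterministic.

    Parameters
    ----------
    k : {1, 3}
        Number of principal channels to keep.
    """
    if k not in (1, 3):
        raise ValueError(f"k must be 1 or 3, got {k}")
    x = _pool_pixels(stacks)
    if x.shape[0] < 16:
        raise ValueError(f"need at least 16 pixels to fit PCA, got {x.shape[0]}")
    if np.allclose(x.var(axis=0), 0.0):
        raise ValueError("degenerate (constant) Mueller data: PCA undefined")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    loadings = pca.components_.T.copy()  # (16, k)
    for c in range(k):
        j = np.argmax(np.abs(loadings[:, c]))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    bounds = np.stack(
        [np.percentile(scores, 1, axis=0), np.percentile(scores, 99, axis=0)], axis=1
    )
    # Guard collapse of degenerate trailing components.
    flat = bounds[:, 1] - bounds[:, 0] <= 0
    bounds[flat, 1] = bounds[flat, 0] + 1e-12
    return PCABasis(pca.mean_.copy(), loadings, pca.explained_variance_ratio_.copy(), bounds)


def apply_pca(stack: np.ndarray, basis: PCABasis, k: int | None = None) -> EncodedImage:
    """Project a Mueller stack onto the fitted principal channels.

    Each component score is mapped affinely to [-1, 1] using the basis'
    stored training-score bounds, then clipped.
    """
    stack = np.asarray(stack, dtype=float)
    k = basis.n_components if k is None else k
    if basis.loadings.size == 0 or basis.n_components < k:
        raise ValueError(f"basis has {basis.n_components} components, need {k}")
    h, w = stack.shape[:2]
    scores = (stack.reshape(-1, 16) - basis.means) @ basis.loadings[:, :k]
    lo, hi = basis.scale_bounds[:k, 0], basis.scale_bounds[:k, 1]
    scaled = 2.0 * (scores - lo) / (hi - lo) - 1.0
    data = np.clip(scaled, -1.0, 1.0).reshape(h, w, k)
    return EncodedImage(data, "pca1" if k == 1 else "pca3")


def encode_stokes(stokes_map: np.ndarray, s0_floor_fraction: float = S0_FLOOR_FRACTION) -> EncodedImage:
    """S0-normalized three-channel Stokes encoding.

    Channels are ``(S1/S0, S2/S0, S3/S0)`` clipped to [-1, 1]; pixels whose
    intensity falls below ``s0_floor_fraction * max(S0)`` (unilluminated)
    are set to (0, 0, 0).  The encoding is invariant to any positive
    rescaling of the Stokes map.
    """
    s = np.asarray(stokes_map, dtype=float)
    if s.ndim != 3 or s.shape[-1] != 4:
        raise ValueError(f"stokes map must be (H, W, 4), got {s.shape}")
    s0 = s[..., 0]
    floor = s0_floor_fraction * max(float(s0.max()), 0.0)
    dark = s0 <= floor
    if dark.any():
        logger.info("encode_stokes: %d unilluminated pixels floored to 0", int(dark.sum()))
    safe = np.where(dark, 1.0, s0)
    data = np.clip(s[..., 1:] / safe[..., None], -1.0, 1.0)
    data[dark] = 0.0
    return EncodedImage(data, "stokes")


def encode_brightfield(rgb: np.ndarray) -> EncodedImage:
    """Map an 8-bit RGB bright-field image to the generator's tanh range:
    ``x / 127.5 - 1``."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"bright-field image must be (H, W, 3), got {rgb.shape}")
    return EncodedImage(rgb / 127.5 - 1.0, "brightfield")


def decode_brightfield(data: np.ndarray) -> np.ndarray:
    """Inverse of :func:`encode_brightfield`: [-1, 1] -> uint8 0..255."""
    return np.clip(np.rint((np.asarray(data, dtype=float) + 1.0) * 127.5), 0, 255).astype(np.uint8)


@dataclass
class PatchLayout:
    """Row-major tiling record: image shape, patch size and patch offsets."""

    image_shape: tuple[int, int]
    size: int
    offsets: list[tuple[int, int]] = field(default_factory=list)


def _tile_starts(extent: int, size: int, stride: int) -> list[int]:
    starts = list(range(0, extent - size + 1, stride))
    if starts[-1] != extent - size:  # flush-to-edge remainder patch
        starts.append(extent - size)
    return starts


def extract_patches(image: np.ndarray, size: int = 256, stride: int | None = None):
    """Tile an image into ``size`` x ``size`` patches, row-major.

    Right/bottom remainders are covered by patches flush to the edge (which
    may overlap interior patches), so every pixel is covered.

    Returns
    -------
    (patches, layout) : list of (size, size, C) arrays and the layout
        needed by :func:`stitch_patches`.
    """
    image = np.asarray(image)
    stride = size if stride is None else stride
    h, w = image.shape[:2]
    if h < size or w < size:
        raise ValueError(f"image {h}x{w} smaller than patch size {size}")
    layout = PatchLayout((h, w), size)
    patches = []
    for r in _tile_starts(h, size, stride):
        for c in _tile_starts(w, size, stride):
            layout.offsets.append((r, c))
            patches.append(image[r : r + size, c : c + size].copy())
    return patches, layout


def stitch_patches(patches, layout: PatchLayout) -> np.ndarray:
    """Reassemble patches into the original image frame, averaging overlaps.

    Exact inverse of :func:`extract_patches` when ``stride == size``.
    """
    if len(patches) != len(layout.offsets):
        raise ValueError(f"{len(patches)} patches but layout records {len(layout.offsets)}")
    h, w = layout.image_shape
    s = layout.size
    proto = np.asarray(patches[0], dtype=float)
    extra = proto.shape[2:]
    acc = np.zeros((h, w) + extra)
    cnt = np.zeros((h, w) + (1,) * len(extra))
    for p, (r, c) in zip(patches, layout.offsets):
        p = np.asarray(p, dtype=float)
        if p.shape[:2] != (s, s) or p.shape[2:] != extra:
            raise ValueError(f"patch shape {p.shape} inconsistent with layout ({s}, {s}, {extra})")
        if r + s > h or c + s > w:
            raise ValueError(f"patch offset ({r}, {c}) exceeds image {h}x{w}")
        acc[r : r + s, c : c + s] += p
        cnt[r : r + s, c : c + s] += 1.0
    if (cnt == 0).any():
        raise ValueError("layout leaves pixels uncovered")
    return acc / cnt
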
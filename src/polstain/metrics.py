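"""Four-way image-quality assessment for translated bright-field images.

* **SSIM** — mean local structural similarity (11x11 gaussian window,
  sigma 1.5, stabilizers K1=0.01 / K2=0.03, dynamic range 255), averaged
  over channels: image-level agreement.
* **RMSE** — root mean squared pixel difference on the [0, 1] scale.
* **JSD** — Jensen-Shannon divergence (base 2, so bounded by 1) between
  256-bin intensity histograms, per channel then averaged: distance
  between the two images' gray-level distributions.
* **EMD** — earth mover's distance between the same histograms along the
  0-255 gray-level axis (units: gray levels).

Evaluation supports paired ground-truth mode (prediction vs reference) and
cycle-reconstruction mode (input x vs F(G(x))) for unpaired settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import jensenshannon
from skimage.metrics import structural_similarity

__all__ = ["MetricReport", "ssim", "rmse", "jsd", "emd", "evaluate_pairs"]

N_BINS = 256


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"image shape mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty images")
    if a.ndim == 2:
        a, b = a[..., None], b[..., None]
    return a, b


def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Structural similarity on 0-255 images, channel-averaged."""
    a, b = _check_pair(a, b)
    vals = [
        structural_similarity(
            a[..., c],
            b[..., c],
            win_size=11,
            gaussian_weights=True,
            sigma=1.5,
            K1=0.01,
            K2=0.03,
            use_sample_covariance=False,
            data_range=255.0,
        )
        for c in range(a.shape[-1])
    ]
    return float(np.mean(vals))


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root mean squared error with images rescaled to [0, 1]."""
    a, b = _check_pair(a, b)
    return float(np.sqrt(np.mean((a / 255.0 - b / 255.0) ** 2)))


def _histograms(a: np.ndarray, b: np.ndarray):
    for c in range(a.shape[-1]):
        ha, _ = np.histogram(a[..., c], bins=N_BINS, range=(0, 255))
        hb, _ = np.histogram(b[..., c], bins=N_BINS, range=(0, 255))
        yield ha / ha.sum(), hb / hb.sum()


def jsd(a: np.ndarray, b: np.ndarray) -> float:
    """Jensen-Shannon divergence (base 2) between intensity histograms."""
    a, b = _check_pair(a, b)
    vals = [jensenshannon(ha, hb, base=2) ** 2 for ha, hb in _histograms(a, b)]
    return float(np.mean(vals))


def emd(a: np.ndarray, b: np.ndarray) -> float:
    """Earth mover's distance between intensity histograms, in gray levels.

    For 1-D histograms this is the cumulative-difference sum
    ``sum |CDF_a - CDF_b| * bin_width`` with unit bin width on 0-255.
    """
    a, b = _check_pair(a, b)
    binw = 255.0 / (N_BINS - 1)
    vals = [
        np.abs(np.cumsum(ha) - np.cumsum(hb)).sum() * binw for ha, hb in _histograms(a, b)
    ]
    return float(np.mean(vals))


@dataclass
class MetricReport:
    """Mean metrics over an evaluation set plus the per-image breakdown."""

    ssim: float
    rmse: float
    jsd: float
    emd: float
    per_image: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "ssim": self.ssim,
            "rmse": self.rmse,
            "jsd": self.jsd,
            "emd": self.emd,
            "per_image": self.per_image,
            "config": self.config,
        }


def evaluate_pairs(predicted, reference) -> MetricReport:
    """Score aligned prediction/reference image sets with all four metrics.

    In paired mode ``reference`` holds ground-truth bright-field images; in
    cycle-reconstruction mode pass the inputs x as ``reference`` and the
    reconstructions F(G(x)) as ``predicted``.
    """
    predicted, reference = list(predicted), list(reference)
    if len(predicted) != len(reference):
        raise ValueError(f"{len(predicted)} predictions vs {len(reference)} references")
    if not predicted:
        raise ValueError("empty evaluation set")
    rows = []
    for i, (p, r) in enumerate(zip(predicted, reference)):
        rows.append(
            {"index": i, "ssim": ssim(p, r), "rmse": rmse(p, r), "jsd": jsd(p, r), "emd": emd(p, r)}
        )
    means = {k: float(np.mean([r[k] for r in rows])) for k in ("ssim", "rmse", "jsd", "emd")}
    return MetricReport(
        means["ssim"], means["rmse"], means["jsd"], means["emd"], rows,
        {"bins": N_BINS, "ssim_window": 11, "ssim_sigma": 1.5, "data_range": 255},
    )
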
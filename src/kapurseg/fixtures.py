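"""Deterministic synthetic images and histograms with known structure.

The image generator emulates the gray-level statistics the thresholding
model assumes — a few well-separated intensity modes with additive noise,
as seen in chest-X-ray gray histograms — while returning the generating
partition so segmentation accuracy can be scored exactly.  It makes no
attempt at anatomical realism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .segmentation import Histogram2D

__all__ = [
    "SyntheticImageSpec",
    "make_multimodal_image",
    "make_toy_histogram",
    "reduce_gray_levels",
]


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Recipe for a piecewise-constant multi-modal image.

    ``modes`` is a list of (mean gray, noise std, area fraction); fractions
    must sum to 1.  Regions are contiguous horizontal bands in row-major
    order, each painted at the mode mean plus clipped Gaussian noise.
    """

    size: tuple[int, int] = (128, 128)
    modes: tuple[tuple[float, float, float], ...] = (
        (30.0, 8.0, 1 / 3),
        (128.0, 8.0, 1 / 3),
        (220.0, 8.0, 1 / 3),
    )
    L: int = 256
    seed: int = 0

    def __post_init__(self):
        fracs = [m[2] for m in self.modes]
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"mode fractions must sum to 1, got {sum(fracs)}")
        for mean, std, _ in self.modes:
            if not 0 <= mean <= self.L - 1:
                raise ValueError(f"mode mean {mean} outside [0, {self.L - 1}]")


def make_multimodal_image(spec: SyntheticImageSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate (image, label map) from a spec; pure function of spec+seed.

    Emits a warning when adjacent mode means are closer than three times
    the sum of their stds (classes overlap enough that no threshold can
    recover the partition exactly).
    """
    rng = np.random.default_rng(spec.seed)
    M, N = spec.size
    total = M * N
    labels = np.empty(total, dtype=np.int64)
    image = np.empty(total, dtype=float)
    start = 0
    bounds = []
    for idx, (mean, std, frac) in enumerate(spec.modes):
        stop = total if idx == len(spec.modes) - 1 else start + int(round(frac * total))
        labels[start:stop] = idx
        image[start:stop] = mean + (std * rng.standard_normal(stop - start) if std > 0 else 0.0)
        start = stop
    means = sorted(m for m, _, _ in spec.modes)
    stds = {m: s for m, s, _ in spec.modes}
    for a, b in zip(means, means[1:]):
        if b - a < 3.0 * (stds[a] + stds[b]):
            warnings.warn(
                f"mode means {a} and {b} overlap (separation < 3*(std sum))",
                stacklevel=2,
            )
    image = np.clip(np.rint(image), 0, spec.L - 1).astype(np.int64)
    return image.reshape(M, N), labels.reshape(M, N)


def make_toy_histogram(L: int = 16, pattern: str = "diagonal-uniform") -> Histogram2D:
    """Small named 2D histograms for oracle tests.

    Patterns: ``single-cell`` (all mass at one point), ``diagonal-uniform``
    (equal mass on every diagonal cell), ``block-k`` for integer k
    (k well-separated uniform diagonal blocks).
    """
    if L > 64:
        raise ValueError("toy histograms are capped at L=64")
    counts = np.zeros((L, L), dtype=np.int64)
    if pattern == "single-cell":
        counts[L // 2, L // 2] = 1
    elif pattern == "diagonal-uniform":
        np.fill_diagonal(counts, 1)
    elif pattern.startswith("block-"):
        try:
            k = int(pattern.split("-", 1)[1])
        except ValueError:
            raise ValueError(f"unknown pattern {pattern!r}") from None
        if not 1 <= k <= L // 2:
            raise ValueError(f"block count {k} infeasible at L={L}")
        edges = np.linspace(0, L, k + 1).astype(int)
        for a, b in zip(edges, edges[1:]):
            # leave a one-cell gap so block boundaries are unambiguous
            for i in range(a, max(a + 1, b - 1)):
                counts[i, i] = 1
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    return Histogram2D(counts=counts, L=L)


def reduce_gray_levels(image: np.ndarray, L_target: int, L: int = 256) -> np.ndarray:
    """Uniform requantization ``floor(v * L_target / L)``; pixel count
    (hence histogram mass) is preserved."""
    if L_target > L:
        raise ValueError("L_target must not exceed the current gray-level count")
    return (np.asarray(image, dtype=np.int64) * L_target) // L
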
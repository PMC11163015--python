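"""Multilevel threshold image segmentation with 2D Kapur entropy.

The model: a grayscale image and its nonlocal-means filtered companion are
combined into an L×L joint histogram; k gray-level thresholds partition the
histogram's main diagonal into k+1 square blocks, and the thresholds
maximizing the summed Shannon entropy of those blocks segment the image.
The maximization is delegated to any optimizer with the
:func:`kapurseg.optimizer.optimize` signature; a brute-force enumerator is
provided as the small-scale oracle.

The nonlocal-means variant used here weighs pixel similarity by the squared
difference of *local patch means* (not the classical patch sum of squared
differences), which is what the 2D-histogram model calls for.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy import ndimage

from .optimizer import SearchSpace, StrategyConfig, optimize as _default_optimize

__all__ = [
    "Histogram2D",
    "ThresholdSet",
    "SegmentationResult",
    "to_grayscale",
    "local_mean",
    "nlm_filter",
    "build_2d_histogram",
    "kapur_entropy_2d",
    "decode_thresholds",
    "exhaustive_kapur",
    "optimize_thresholds",
    "label_image",
    "segment",
]

# BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to grayscale by BT.601 luma; grayscale
    input is returned unchanged (as uint8)."""
    image = np.asarray(image)
    if image.ndim == 2:
        return image.astype(np.uint8)
    if image.ndim == 3 and image.shape[2] == 3:
        return np.rint(image.astype(float) @ _LUMA).clip(0, 255).astype(np.uint8)
    if image.ndim == 3 and image.shape[2] == 4:  # drop alpha
        return to_grayscale(image[..., :3])
    raise ValueError(f"unsupported image shape {image.shape}")


def local_mean(image: np.ndarray, p: tuple[int, int], m: int) -> float:
    """Mean of the m×m patch centered at ``p`` with symmetric border padding."""
    if m < 1 or m % 2 == 0:
        raise ValueError("patch side m must be odd and >= 1")
    r = m // 2
    padded = np.pad(np.asarray(image, dtype=float), r, mode="symmetric")
    y, x = p
    return float(padded[y : y + m, x : x + m].mean())


def nlm_filter(
    image: np.ndarray,
    m: int = 3,
    sigma: float = 10.0,
    window: int | None = 21,
) -> np.ndarray:
    """Nonlocal-means filter with patch-mean similarity.

    Each output pixel is the weighted average of the gray values in its
    ``window``×``window`` search neighborhood (``window=None`` sums over
    the whole image), with weights ``exp(-(mu(p)-mu(q))^2 / sigma^2)``
    where ``mu`` is the m×m local patch mean.  Borders are handled by
    symmetric padding; the result is rounded back to integer gray levels.

    Parameters
    ----------
    m : odd int
        Patch side for the local means.
    sigma : float
        Similarity decay in gray levels.
    window : odd int or None
        Search neighborhood side; None uses every pixel (quadratic cost,
        intended for small oracle images only).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if m < 1 or m % 2 == 0:
        raise ValueError("patch side m must be odd")
    img = np.asarray(image, dtype=float)
    mu = ndimage.uniform_filter(img, size=m, mode="reflect")

    if window is None:
        flat_i = img.ravel()
        flat_mu = mu.ravel()
        w = np.exp(-((flat_mu[:, None] - flat_mu[None, :]) ** 2) / sigma**2)
        out = (w @ flat_i) / w.sum(axis=1)
        out = out.reshape(img.shape)
    else:
        if window % 2 == 0:
            raise ValueError("window side must be odd")
        r = window // 2
        pad_i = np.pad(img, r, mode="symmetric")
        pad_mu = np.pad(mu, r, mode="symmetric")
        H, W = img.shape
        num = np.zeros_like(img)
        den = np.zeros_like(img)
        for dy in range(window):
            for dx in range(window):
                q_i = pad_i[dy : dy + H, dx : dx + W]
                q_mu = pad_mu[dy : dy + H, dx : dx + W]
                w = np.exp(-((mu - q_mu) ** 2) / sigma**2)
                num += w * q_i
                den += w
        out = num / den
    return np.rint(out).astype(np.int64)


@dataclass(frozen=True)
class Histogram2D:
    """L×L joint distribution of gray level and nonlocal-mean level."""

    counts: np.ndarray  # (L, L) ints
    L: int

    @property
    def P(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @cached_property
    def _tables(self) -> tuple[np.ndarray, np.ndarray]:
        """Summed-area tables of P and -P*ln(P), padded with a zero row/col
        so block sums are O(1)."""
        P = self.P
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(P > 0, -P * np.log(P), 0.0)
        sat_p = np.zeros((self.L + 1, self.L + 1))
        sat_h = np.zeros((self.L + 1, self.L + 1))
        sat_p[1:, 1:] = P.cumsum(axis=0).cumsum(axis=1)
        sat_h[1:, 1:] = plogp.cumsum(axis=0).cumsum(axis=1)
        return sat_p, sat_h

    def _block(self, sat: np.ndarray, a: int, b: int) -> float:
        """Sum over the square block [a..b] x [a..b] (inclusive)."""
        return sat[b + 1, b + 1] - sat[a, b + 1] - sat[b + 1, a] + sat[a, a]


@dataclass(frozen=True)
class ThresholdSet:
    """Strictly increasing integer gray-level thresholds in [1, L-2]."""

    t: tuple[int, ...]
    L: int = 256

    def __post_init__(self):
        t = tuple(int(v) for v in self.t)
        if len(t) < 1:
            raise ValueError("need at least one threshold")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError(f"thresholds must be strictly increasing, got {t}")
        if t[0] < 1 or t[-1] > self.L - 2:
            raise ValueError(f"thresholds must lie in [1, {self.L - 2}], got {t}")
        object.__setattr__(self, "t", t)

    @property
    def k(self) -> int:
        return len(self.t)


@dataclass
class SegmentationResult:
    labels: np.ndarray
    thresholds: ThresholdSet
    entropy: float
    segmented: np.ndarray
    trace: object | None = None


def build_2d_histogram(gray: np.ndarray, nlm: np.ndarray, L: int = 256) -> Histogram2D:
    """Joint counts of (gray value, nonlocal-mean value), normalized to a
    probability table by the pixel count."""
    gray = np.asarray(gray)
    nlm = np.asarray(nlm)
    if gray.shape != nlm.shape:
        raise ValueError("gray and nonlocal-mean images must share a shape")
    counts = np.bincount(
        (gray.astype(np.int64) * L + nlm.astype(np.int64)).ravel(), minlength=L * L
    ).reshape(L, L)
    return Histogram2D(counts=counts, L=L)


def _block_bounds(t: tuple[int, ...], L: int) -> list[tuple[int, int]]:
    """Inclusive [a, b] index ranges of the k+1 diagonal blocks."""
    edges = (-1,) + tuple(t) + (L - 1,)
    return [(edges[m] + 1, edges[m + 1]) for m in range(len(edges) - 1)]


def kapur_entropy_2d(hist: Histogram2D, thresholds: ThresholdSet | tuple) -> float:
    """2D Kapur entropy of a threshold set.

    The k thresholds cut the L×L histogram's main diagonal into k+1 square
    blocks; the criterion is the sum over blocks of the Shannon entropy of
    the block-conditional distribution (off-diagonal mass is ignored, the
    standard diagonal approximation).  Empty blocks and zero cells
    contribute 0.
    """
    if not isinstance(thresholds, ThresholdSet):
        thresholds = ThresholdSet(tuple(thresholds), L=hist.L)
    if thresholds.L != hist.L:
        raise ValueError("threshold range does not match histogram size")
    sat_p, sat_h = hist._tables
    phi = 0.0
    for a, b in _block_bounds(thresholds.t, hist.L):
        pm = hist._block(sat_p, a, b)
        if pm <= 0:
            continue
        hm = hist._block(sat_h, a, b)
        # -sum (P/pm) ln(P/pm) = (1/pm) * (-sum P ln P) + ln pm
        phi += hm / pm + math.log(pm)
    return phi


def decode_thresholds(position: np.ndarray, L: int = 256) -> ThresholdSet:
    """Map a continuous optimizer position to a valid threshold set:
    round, clamp to [1, L-2], sort, and repair duplicates by pushing the
    later duplicate up (capped at L-2, then pulling earlier ones down)."""
    k = len(position)
    if k >= L - 1:
        raise ValueError(f"cannot fit {k} distinct thresholds in [1, {L - 2}]")
    t = np.sort(np.clip(np.rint(np.asarray(position, dtype=float)), 1, L - 2)).astype(
        int
    )
    for i in range(1, k):
        if t[i] <= t[i - 1]:
            t[i] = t[i - 1] + 1
    # overflow past L-2: walk back down
    for i in range(k - 1, -1, -1):
        cap = L - 2 - (k - 1 - i)
        if t[i] > cap:
            t[i] = cap
    return ThresholdSet(tuple(int(v) for v in t), L=L)


def exhaustive_kapur(
    hist: Histogram2D, k: int, guard: int = 10**6
) -> tuple[ThresholdSet, float]:
    """Enumerate every k-threshold set and return the entropy argmax
    (lexicographically smallest on ties).  Refuses above ``guard``
    combinations."""
    L = hist.L
    n_comb = math.comb(L - 2, k)
    if n_comb > guard:
        raise ValueError(f"{n_comb} combinations exceed the enumeration guard")
    best_t, best_phi = None, -math.inf
    for comb in itertools.combinations(range(1, L - 1), k):
        phi = kapur_entropy_2d(hist, comb)
        if phi > best_phi:
            best_t, best_phi = comb, phi
    return ThresholdSet(best_t, L=L), best_phi


def optimize_thresholds(
    hist: Histogram2D,
    k: int,
    optimizer=None,
    config: StrategyConfig | None = None,
    n: int = 20,
    iterations: int = 100,
):
    """Maximize the 2D Kapur entropy over k thresholds with a population
    optimizer (population 20, 100 iterations by default).

    The optimizer minimizes, so it receives the negated entropy of the
    decoded threshold set.  Returns (ThresholdSet, entropy, trace).
    """
    if optimizer is None:
        optimizer = _default_optimize
    if config is None:
        config = StrategyConfig()
    L = hist.L
    # budget covering `iterations` full rounds: init + per-iteration
    # population pass + the 2k ADN probes
    max_evals = n + iterations * (n + (2 * k if config.use_adn else 0))
    space = SearchSpace(dim=k, lb=1.0, ub=float(L - 2), max_evals=max_evals)

    def objective(x: np.ndarray) -> float:
        return -kapur_entropy_2d(hist, decode_thresholds(x, L))

    best, trace = optimizer(objective, space, n, config)
    ts = decode_thresholds(best.position, L)
    return ts, kapur_entropy_2d(hist, ts), trace


def label_image(gray: np.ndarray, thresholds: ThresholdSet) -> np.ndarray:
    """Region labels: a pixel with gray value g in (t_r, t_{r+1}] gets
    label r, with t_0 = -1 and t_{k+1} = L-1."""
    t = np.asarray(thresholds.t)
    return np.searchsorted(t, np.asarray(gray), side="left").astype(np.int64)


def segment(
    image: np.ndarray,
    k: int,
    optimizer=None,
    config: StrategyConfig | None = None,
    n: int = 20,
    iterations: int = 100,
    L: int = 256,
    nlm_m: int = 3,
    nlm_sigma: float = 10.0,
    nlm_window: int | None = 21,
) -> SegmentationResult:
    """Full segmentation pipeline.

    Grayscale conversion → nonlocal-means filtering → L×L joint histogram
    → 2D Kapur entropy maximization over k thresholds → pixel labeling.
    The segmented image paints every region with its rounded mean gray.
    """
    if k < 1:
        raise ValueError("threshold count k must be >= 1")
    gray = to_grayscale(image)
    if L != 256:
        if gray.max() >= L:
            raise ValueError(f"gray values exceed L={L}")
    nlm = nlm_filter(gray, m=nlm_m, sigma=nlm_sigma, window=nlm_window)
    hist = build_2d_histogram(gray, nlm, L=L)
    ts, phi, trace = optimize_thresholds(
        hist, k, optimizer=optimizer, config=config, n=n, iterations=iterations
    )
    labels = label_image(gray, ts)
    segmented = np.zeros_like(gray, dtype=np.int64)
    for r in range(k + 1):
        mask = labels == r
        if mask.any():
            segmented[mask] = int(round(float(gray[mask].mean())))
    return SegmentationResult(
        labels=labels, thresholds=ts, entropy=phi, segmented=segmented, trace=trace
    )
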
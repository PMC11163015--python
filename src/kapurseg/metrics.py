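"""PSNR, SSIM and FSIM fidelity scores between an image and its
segmented rendering.

PSNR is the log-scaled inverse root-mean-squared error on the 8-bit range;
SSIM the windowed luminance/contrast/structure similarity (the windowed
default delegates to scikit-image's reference implementation, a global
single-window mode is kept for closed-form checks); FSIM weights the
pointwise combination of phase-congruency similarity and gradient-magnitude
similarity by the maximum phase congruency of the two images.  Phase
congruency uses a multi-scale log-Gabor filter bank without noise
compensation, which keeps the measure deterministic and symmetric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity as _sk_ssim

__all__ = ["QualityScores", "psnr", "ssim", "fsim", "score_pair"]


def _check_pair(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def psnr(original: np.ndarray, segmented: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB: ``20*log10(255/sqrt(MSE))``.
    Identical images return ``+inf``."""
    a, b = _check_pair(original, segmented)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return math.inf
    return 20.0 * math.log10(255.0 / math.sqrt(mse))


def ssim(
    original: np.ndarray,
    segmented: np.ndarray,
    c1: float | None = None,
    c2: float | None = None,
    window: int = 11,
    mode: str = "windowed",
) -> float:
    """Structural similarity index.

    ``mode="windowed"`` (default): mean over 11×11 Gaussian-weighted
    sliding windows (sigma 1.5), stabilizers ``c1=(0.01*255)^2``,
    ``c2=(0.03*255)^2``.  ``mode="global"``: the same formula evaluated
    once on whole-image moments (population statistics).
    """
    a, b = _check_pair(original, segmented)
    if c1 is None:
        c1 = (0.01 * 255) ** 2
    if c2 is None:
        c2 = (0.03 * 255) ** 2
    if c1 <= 0 or c2 <= 0:
        raise ValueError("c1 and c2 must be positive")
    if mode == "global":
        mu_a, mu_b = a.mean(), b.mean()
        var_a, var_b = a.var(), b.var()
        cov = float(np.mean((a - mu_a) * (b - mu_b)))
        return ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / (
            (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
        )
    if mode != "windowed":
        raise ValueError("mode must be 'windowed' or 'global'")
    return float(
        _sk_ssim(
            a,
            b,
            data_range=255.0,
            win_size=window,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=math.sqrt(c1) / 255.0,
            K2=math.sqrt(c2) / 255.0,
        )
    )


# --- phase congruency -------------------------------------------------------


def _log_gabor_bank(shape, n_scales=4, n_orient=4, min_wavelength=6.0,
                    mult=2.0, sigma_f=0.55, sigma_theta=0.52):
    """Frequency-domain log-Gabor filters (n_scales × n_orient)."""
    rows, cols = shape
    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    radius = np.sqrt(fx**2 + fy**2)
    radius[0, 0] = 1.0  # avoid log(0) at DC; the filter is zeroed there
    theta = np.arctan2(-fy, fx)
    filters = []
    for o in range(n_orient):
        angle = o * np.pi / n_orient
        dtheta = np.arctan2(
            np.sin(theta - angle), np.cos(theta - angle)
        )
        spread = np.exp(-(dtheta**2) / (2 * sigma_theta**2))
        for s in range(n_scales):
            f0 = 1.0 / (min_wavelength * mult**s)
            lg = np.exp(-(np.log(radius / f0) ** 2) / (2 * math.log(sigma_f) ** 2))
            lg[0, 0] = 0.0
            filters.append((o, lg * spread))
    return filters


def phase_congruency(image: np.ndarray, n_scales: int = 4, n_orient: int = 4) -> np.ndarray:
    """Simplified multi-orientation phase congruency.

    Per orientation, ``|sum of complex log-Gabor responses| / (sum of
    response amplitudes + eps)`` weighted by local energy, summed over
    orientations.  Constant images yield zero everywhere.
    """
    img = np.asarray(image, dtype=float)
    F = np.fft.fft2(img)
    eps = 1e-4
    pc = np.zeros_like(img)
    bank = _log_gabor_bank(img.shape, n_scales=n_scales, n_orient=n_orient)
    for o in range(n_orient):
        energy = np.zeros(img.shape, dtype=complex)
        amp_sum = np.zeros(img.shape)
        for oo, filt in bank:
            if oo != o:
                continue
            resp = np.fft.ifft2(F * filt)
            energy += resp
            amp_sum += np.abs(resp)
        pc += np.abs(energy) / (amp_sum + eps) * amp_sum
    total_amp = sum(np.abs(np.fft.ifft2(F * f)) for _, f in bank)
    return pc / (total_amp + eps)


def _gradient_magnitude(image: np.ndarray) -> np.ndarray:
    gx = ndimage.convolve(
        image, np.array([[3, 0, -3], [10, 0, -10], [3, 0, -3]]) / 16.0, mode="reflect"
    )
    gy = ndimage.convolve(
        image, np.array([[3, 10, 3], [0, 0, 0], [-3, -10, -3]]) / 16.0, mode="reflect"
    )
    return np.sqrt(gx**2 + gy**2)


def fsim(
    original: np.ndarray,
    segmented: np.ndarray,
    t1: float = 0.85,
    t2: float = 160.0,
    gradient_only: bool = False,
) -> float:
    """Feature similarity index in [0, 1].

    ``S_L = S_PC * S_G`` with ``S_PC = (2*PC1*PC2 + t1)/(PC1^2 + PC2^2 + t1)``
    and ``S_G = (2*G1*G2 + t2)/(G1^2 + G2^2 + t2)`` (Scharr gradients);
    the score is the PC_m-weighted mean of S_L with
    ``PC_m = max(PC1, PC2)``.  ``gradient_only=True`` drops the phase
    congruency term and weights by the maximum gradient instead (fast
    mode for tests).
    """
    a, b = _check_pair(original, segmented)
    g1 = _gradient_magnitude(a)
    g2 = _gradient_magnitude(b)
    s_g = (2 * g1 * g2 + t2) / (g1**2 + g2**2 + t2)
    if gradient_only:
        w = np.maximum(g1, g2)
        if w.sum() == 0:
            return 1.0
        return float((s_g * w).sum() / w.sum())
    pc1 = phase_congruency(a)
    pc2 = phase_congruency(b)
    s_pc = (2 * pc1 * pc2 + t1) / (pc1**2 + pc2**2 + t1)
    pcm = np.maximum(pc1, pc2)
    if pcm.sum() == 0:
        return 1.0
    return float((s_pc * s_g * pcm).sum() / pcm.sum())


@dataclass
class QualityScores:
    psnr: float
    ssim: float
    fsim: float

    def to_dict(self) -> dict:
        return {
            "psnr": None if math.isinf(self.psnr) else self.psnr,
            "ssim": self.ssim,
            "fsim": self.fsim,
        }


def score_pair(original: np.ndarray, segmented: np.ndarray, fast_fsim: bool = False) -> QualityScores:
    """All three metrics for one (original, segmented) pair."""
    return QualityScores(
        psnr=psnr(original, segmented),
        ssim=ssim(original, segmented),
        fsim=fsim(original, segmented, gradient_only=fast_fsim),
    )
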
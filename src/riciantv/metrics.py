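"""Image quality metrics on the 0-255 intensity scale.

PSNR = 10 log10(255^2 / MSE) in decibels (identical images report +inf).
SSIM combines luminance, contrast and covariance statistics; the default
here is the single-window (global-statistics) form

    (2 mu_a mu_b + c1)(2 cov_ab + c2) /
    ((mu_a^2 + mu_b^2 + c1)(var_a + var_b + c2))

with the standard stabilizers c1 = (0.01*255)^2, c2 = (0.03*255)^2.  The
`windowed` option instead averages local SSIM over an 11x11 Gaussian
window (sigma 1.5), the common practice for natural and MR images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["QualityReport", "psnr", "ssim", "evaluate"]

_L = 255.0
_C1 = (0.01 * _L) ** 2
_C2 = (0.03 * _L) ** 2


@dataclass(frozen=True)
class QualityReport:
    psnr: float
    ssim: float


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def psnr(u_hat: np.ndarray, u: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    u_hat, u = _check_pair(u_hat, u)
    mse = float(np.mean((u_hat - u) ** 2))
    if mse == 0:
        return float("inf")
    return 10.0 * np.log10(_L * _L / mse)


def ssim(u_hat: np.ndarray, u: np.ndarray, windowed: bool = False) -> float:
    """Structural similarity index in [-1, 1]; 1 iff identical."""
    u_hat, u = _check_pair(u_hat, u)
    if windowed:
        return float(structural_similarity(
            u_hat, u, data_range=_L, gaussian_weights=True, sigma=1.5,
            win_size=11, use_sample_covariance=False))
    mu_a, mu_b = u_hat.mean(), u.mean()
    var_a, var_b = u_hat.var(), u.var()
    cov = float(np.mean((u_hat - mu_a) * (u - mu_b)))
    return float((2 * mu_a * mu_b + _C1) * (2 * cov + _C2)
                 / ((mu_a ** 2 + mu_b ** 2 + _C1) * (var_a + var_b + _C2)))


def evaluate(u_hat: np.ndarray, u: np.ndarray,
             windowed: bool = False) -> QualityReport:
    return QualityReport(psnr=psnr(u_hat, u), ssim=ssim(u_hat, u, windowed))
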
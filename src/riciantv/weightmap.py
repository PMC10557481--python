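"""Spatially variant regularization weight for the TV term.

The weight at each pixel is an edge-stopping function of the Gaussian
pre-smoothed gradient magnitude,

    alpha(x) = alpha0 / sqrt(1 + (|grad(G_omega * x)| / kappa)^2),

so flat regions (gradient << kappa) receive the full TV weight alpha0
(strong smoothing) while edges (gradient >> kappa) are down-weighted and
preserved.  kappa is the contrast scale separating the two regimes; omega
is the pre-smoothing standard deviation in pixels that makes the gradient
estimate robust to the noise itself.

During denoising the map may be refreshed once per outer iteration from
the current restored image, sharpening the flat/edge classification as the
noise is removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import diffops

__all__ = ["WeightParams", "compute_weight", "refine_weight"]


@dataclass(frozen=True)
class WeightParams:
    alpha0: float = 10.0   # TV weight in flat regions (>= 0)
    kappa: float = 0.8     # gradient-magnitude contrast scale (> 0)
    omega: float = 1.0     # Gaussian pre-smoothing std, pixels (>= 0)

    def __post_init__(self) -> None:
        if self.alpha0 < 0:
            raise ValueError(f"alpha0 must be >= 0, got {self.alpha0}")
        if not self.kappa > 0:
            raise ValueError(f"kappa must be > 0, got {self.kappa}")
        if self.omega < 0:
            raise ValueError(f"omega must be >= 0, got {self.omega}")


def compute_weight(img: np.ndarray, params: WeightParams) -> np.ndarray:
    """Per-pixel TV weight alpha0 / sqrt(1 + (|grad G_omega*img|/kappa)^2)."""
    img = diffops.validate_image(img)
    g = diffops.grad_mag(diffops.grad(diffops.gauss_smooth(img, params.omega)))
    return params.alpha0 / np.sqrt(1.0 + (g / params.kappa) ** 2)


def refine_weight(u_current: np.ndarray, params: WeightParams) -> np.ndarray:
    """Recompute the weight map from the current restored image.

    Identical to `compute_weight`; named separately to mark the call site
    in the outer loop where the map is refreshed from u^k instead of the
    noisy input.
    """
    return compute_weight(u_current, params)
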
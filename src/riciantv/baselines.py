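"""Reference variational models for Rician denoising.

Three first-order TV models are provided for comparative experiments,
all solved on the same split Bregman scaffold as the main model:

* **GTV** — TV with the convexified Rician MAP data term: the non-convex
  per-pixel fidelity H_s(u) = u^2/(2s^2) - log I0(u f/s^2) is replaced by
  its linear extension below the inflection abscissa u = c*sigma
  (c = 0.8426), which makes the model convex.  Its published derivative
  uses a cubic rational approximation A of I1/I0 (`rician.ratio_approx_A`).
* **CZ** — MAP fidelity made strictly convex by the quadratic root term
  (1/sigma)||sqrt(u) - sqrt(f)||^2, plus TV.  This is exactly the main
  model with beta = 0 and a spatially constant TV weight, and is
  implemented as such.
* **Yuan** — MAP fidelity plus a convex gradient fidelity
  (1/sigma)||grad u - grad f||^2, plus TV.

GTV and Yuan are pure first-order models and run on a TV-only split
Bregman loop (one auxiliary field d ~ grad u); their u-steps use the same
diagonal quasi-Newton update as the main solver, with the penalty and
gradient-fidelity curvature bounds added to the step denominator (the GTV
fidelity is linear below c*sigma, so the data curvature alone can vanish).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import diffops
from .rician import bessel_ratio, log_i0, ratio_approx_A, ratio_approx_A_prime
from .solver import (DenoiseResult, SolverParams, _GTG_BOUND, _HESS_FLOOR,
                     denoise, shrink_vector)

__all__ = [
    "GtvParams",
    "YuanParams",
    "gtv_fidelity_grad",
    "denoise_gtv",
    "denoise_cz",
    "denoise_yuan",
]


@dataclass(frozen=True)
class GtvParams:
    alpha: float = 10.0
    sigma: float = 15.0
    c_point: float = 0.8426   # convexification abscissa, in units of sigma
    theta1: float = 5.0
    k_max: int = 500
    n_max: int = 1
    # the published derivative uses the cubic rational approximation A of
    # I1/I0; set True to substitute the exact (scaled-Bessel) ratio
    use_exact_ratio: bool = False

    def __post_init__(self) -> None:
        if not self.c_point > 0:
            raise ValueError(f"c_point must be > 0, got {self.c_point}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class YuanParams:
    alpha: float = 10.0
    sigma: float = 15.0
    theta1: float = 5.0
    k_max: int = 500
    n_max: int = 1
    u_floor: float = 1e-3


def gtv_fidelity_grad(u: np.ndarray, f: np.ndarray, p: GtvParams) -> np.ndarray:
    """Derivative of the convexified GTV data term.

    H'_s(u) = u/s^2 - (f/s^2) A(u f/s^2) for u >= c*sigma; constant
    H'_s(c*sigma) below (the linear branch), so the derivative is
    continuous at the junction by construction.
    """
    u = np.asarray(u, dtype=float)
    f = np.asarray(f, dtype=float)
    s2 = p.sigma * p.sigma
    uc = np.maximum(u, p.c_point * p.sigma)
    ratio = bessel_ratio if p.use_exact_ratio else ratio_approx_A
    return uc / s2 - (f / s2) * ratio(uc * f / s2)


def _ratio_prime_exact(x):
    r = bessel_ratio(x)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 1.0 - r / x - r * r
    return np.where(np.asarray(x) > 0, out, 0.5)   # r'(0) = 1/2


def _gtv_fidelity_curv(u: np.ndarray, f: np.ndarray, p: GtvParams) -> np.ndarray:
    """H''_s(u) on the curved branch, 0 on the linear branch."""
    s2 = p.sigma * p.sigma
    rprime = _ratio_prime_exact if p.use_exact_ratio else ratio_approx_A_prime
    curv = 1.0 / s2 - (f * f / (s2 * s2)) * rprime(u * f / s2)
    return np.where(u >= p.c_point * p.sigma, np.maximum(curv, 0.0), 0.0)


def _gtv_energy_pixel(u: np.ndarray, f: np.ndarray, p: GtvParams) -> np.ndarray:
    """G_s(u): the MAP fidelity for u >= c*sigma, its tangent line below.

    The curved branch uses the exact log I0 (the published derivative's
    A(.) only enters the optimizer); the linear branch is the first-order
    Taylor extension at c*sigma, which keeps G continuous and C^1.
    """
    s2 = p.sigma * p.sigma
    cs = p.c_point * p.sigma
    ratio = bessel_ratio if p.use_exact_ratio else ratio_approx_A

    def H(v):
        return v * v / (2 * s2) - log_i0(v * f / s2)

    h_cs = H(np.full_like(u, cs))
    hp_cs = cs / s2 - (f / s2) * ratio(cs * f / s2)
    return np.where(u >= cs, H(np.maximum(u, cs)), h_cs + hp_cs * (u - cs))


def _tv_split_bregman(f, u0, alpha, theta1, k_max, n_max,
                      grad_fn, den_fn, energy_fn=None,
                      u_floor=None) -> DenoiseResult:
    """First-order (TV-only) split Bregman loop shared by GTV and Yuan."""
    u = u0.copy()
    shape = f.shape
    d = (np.zeros(shape), np.zeros(shape))
    b1 = (np.zeros(shape), np.zeros(shape))
    trace: list[float] = []
    for k in range(k_max):
        gx, gy = diffops.grad(u)
        d = shrink_vector((gx + b1[0], gy + b1[1]), alpha, theta1)
        for _ in range(n_max):
            gx, gy = diffops.grad(u)
            res = (d[0] - gx - b1[0], d[1] - gy - b1[1])
            e1 = grad_fn(u) + theta1 * diffops.div(res)
            e2 = np.maximum(den_fn(u), _HESS_FLOOR)
            u = u - e1 / e2
            if not np.all(np.isfinite(u)):
                raise FloatingPointError(f"non-finite u at outer iteration {k + 1}")
            if u_floor is not None:
                u = np.maximum(u, u_floor)
        gx, gy = diffops.grad(u)
        b1 = (b1[0] + gx - d[0], b1[1] + gy - d[1])
        trace.append(float(energy_fn(u)) if energy_fn is not None else float("nan"))
    return DenoiseResult(u_hat=u, energy_trace=trace,
                         alpha_final=np.full(shape, alpha), iterations_run=k_max)


def denoise_gtv(f: np.ndarray, p: GtvParams) -> DenoiseResult:
    """Split Bregman for the convexified-fidelity TV model."""
    f = diffops.validate_image(f, "f")
    if np.any(f < 0):
        raise ValueError("noisy magnitude image must be non-negative")

    def grad_fn(u):
        return gtv_fidelity_grad(u, f, p)

    def den_fn(u):
        return _gtv_fidelity_curv(u, f, p) + p.theta1 * _GTG_BOUND

    def energy_fn(u):
        tv = np.sum(diffops.grad_mag(diffops.grad(u)))
        return np.sum(_gtv_energy_pixel(u, f, p)) + p.alpha * tv

    return _tv_split_bregman(f, f.astype(float), p.alpha, p.theta1,
                             p.k_max, p.n_max, grad_fn, den_fn, energy_fn)


def denoise_cz(f: np.ndarray, alpha: float, params: SolverParams) -> DenoiseResult:
    """Strictly convex MAP + quadratic root term + TV.

    Model containment: this is the main solver with beta = 0 and a
    spatially constant TV weight, and is delegated to it verbatim.
    """
    params = replace(params, beta=0.0)
    return denoise(f, params, alpha_map=np.full(np.asarray(f).shape, float(alpha)))


def denoise_yuan(f: np.ndarray, p: YuanParams) -> DenoiseResult:
    """MAP fidelity + gradient fidelity (1/sigma)||grad u - grad f||^2 + TV."""
    f = diffops.validate_image(f, "f")
    if np.any(f < 0):
        raise ValueError("noisy magnitude image must be non-negative")
    s2 = p.sigma * p.sigma
    gf = diffops.grad(f)

    def grad_fn(u):
        r = bessel_ratio(u * f / s2)
        gu = diffops.grad(u)
        gdiff = (gu[0] - gf[0], gu[1] - gf[1])
        return (u / s2 - (f / s2) * r
                - (2.0 / p.sigma) * diffops.div(gdiff))

    def den_fn(u):
        r = bessel_ratio(u * f / s2)
        # MAP curvature; can be negative (non-convex term), clipped at 0
        map_curv = 1.0 / s2 + (-(f * f / (s2 * s2)) * (1.0 - r * r)
                               + f * r / (s2 * np.maximum(u, p.u_floor)))
        return (np.maximum(map_curv, 0.0)
                + (2.0 / p.sigma) * _GTG_BOUND + p.theta1 * _GTG_BOUND)

    def energy_fn(u):
        gu = diffops.grad(u)
        gdiff_sq = (gu[0] - gf[0]) ** 2 + (gu[1] - gf[1]) ** 2
        tv = np.sum(diffops.grad_mag(gu))
        return (np.sum(u * u) / (2 * s2) - np.sum(log_i0(u * f / s2))
                + np.sum(gdiff_sq) / p.sigma + p.alpha * tv)

    u0 = np.maximum(f.astype(float), p.u_floor)
    return _tv_split_bregman(f, u0, p.alpha, p.theta1, p.k_max, p.n_max,
                             grad_fn, den_fn, energy_fn, u_floor=p.u_floor)
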
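"""Split Bregman solver for spatially variant TV + bounded Hessian
Rician denoising.

The model restores a magnitude MR image f by minimizing

    (1/2 sigma^2) ||u||^2 - <log I0(u f / sigma^2), 1>
        + (1/sigma) ||sqrt(u) - sqrt(f)||^2
        + || alpha(.) grad u ||_1  +  beta || hess u ||_1

where the first three terms are the strictly convexified Rician MAP data
fidelity, the fourth is total variation weighted per pixel by the
edge-stopping map alpha (see `weightmap`), and the fifth is the bounded
Hessian regularizer that suppresses the staircase artifacts of TV.

Splitting introduces auxiliary fields d ~ grad u and z ~ hess u with
Bregman (dual) variables b1, b2 and quadratic penalties theta1, theta2.
Each outer iteration performs:

1. d-step: isotropic soft shrinkage of grad u + b1 with per-pixel
   threshold alpha/theta1 (closed-form proximal map of the weighted
   two-norm TV term);
2. z-step: Frobenius shrinkage of hess u + b2 with threshold beta/theta2;
3. u-step: n_max diagonal quasi-Newton updates u <- u - E'(u)/E''(u),
   where E' is the full gradient (data fidelity + quadratic penalties,
   using the adjoint-exact div/div2 operators) and E'' is the diagonal
   data-fidelity curvature augmented, by default, with the operator-norm
   bounds of the penalty curvature (8*theta1 + 64*theta2).  The
   augmentation is required for stability: the fidelity curvature alone
   (~1/sigma^2) is orders of magnitude smaller than the penalty gradients
   at practical theta, and the unaugmented step diverges.  Setting
   ``hess_augment=False`` selects the bare fidelity-curvature step;
4. Bregman updates b1 += grad u - d, b2 += hess u - z;
5. optional refresh of the weight map from the current u.

The iteration count is the stopping criterion (fixed k_max by default; an
optional relative-change tolerance can stop early).  The solver is fully
deterministic: no randomness is used anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import diffops
from .rician import bessel_ratio, log_i0
from .weightmap import WeightParams, compute_weight, refine_weight

__all__ = [
    "SolverParams",
    "BregmanState",
    "DenoiseResult",
    "shrink_vector",
    "shrink_hessian",
    "fidelity_grad",
    "fidelity_hess",
    "newton_u_step",
    "update_bregman",
    "energy",
    "denoise",
    "tune_params",
]

VectorField = tuple[np.ndarray, np.ndarray]
HessianField = tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]

_HESS_FLOOR = 1e-8
# Spectral-norm bounds of G^T G and H^T H for unit-spaced forward/backward
# differences (each 1D difference operator has norm <= 2).
_GTG_BOUND = 8.0
_HTH_BOUND = 64.0


@dataclass(frozen=True)
class SolverParams:
    """All tunables of the denoiser.

    sigma is the Rician channel noise std on the 0-255 intensity scale.
    theta1/theta2 are the split Bregman penalty weights; beta the bounded
    Hessian weight; the TV weight map is governed by `weight`.  k_max outer
    and n_max inner (Newton) iterations; u_floor keeps u strictly positive
    so that sqrt(f/u) and u^(-3/2) in the fidelity derivatives are defined.
    """

    sigma: float = 15.0
    weight: WeightParams = field(default_factory=WeightParams)
    beta: float = 5.0
    theta1: float = 5.0
    theta2: float = 5.0
    k_max: int = 500
    n_max: int = 1
    u_floor: float = 1e-3
    refine_alpha: bool = True
    hess_augment: bool = True
    tol: float | None = None   # optional early stop on relative change

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not (self.theta1 > 0 and self.theta2 > 0):
            raise ValueError("theta1 and theta2 must be > 0")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.k_max < 1 or self.n_max < 1:
            raise ValueError("k_max and n_max must be >= 1")
        if not 0 < self.u_floor < 1:
            raise ValueError(f"u_floor must be in (0, 1), got {self.u_floor}")


@dataclass
class BregmanState:
    """All iterates of the split Bregman loop at outer iteration k."""

    u: np.ndarray
    d: VectorField
    z: HessianField
    b1: VectorField
    b2: HessianField
    alpha: np.ndarray
    k: int = 0


@dataclass
class DenoiseResult:
    u_hat: np.ndarray
    energy_trace: list[float]
    alpha_final: np.ndarray
    iterations_run: int


def shrink_vector(q: VectorField, threshold: np.ndarray | float,
                  theta1: float) -> VectorField:
    """Isotropic soft shrinkage: prox of (threshold/theta1) * |.|_2.

    Per pixel, with m = |q|: result = (q/m) * max(m - threshold/theta1, 0);
    the zero vector where m = 0.
    """
    if not theta1 > 0:
        raise ValueError(f"theta1 must be > 0, got {theta1}")
    qx, qy = q
    m = np.hypot(qx, qy)
    scale = np.maximum(m - np.asarray(threshold) / theta1, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(m > 0, scale / m, 0.0)
    return qx * scale, qy * scale


def shrink_hessian(q: HessianField, beta: float, theta2: float) -> HessianField:
    """Frobenius-norm soft shrinkage of a 4-component Hessian field."""
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    if not theta2 > 0:
        raise ValueError(f"theta2 must be > 0, got {theta2}")
    comps = [np.asarray(c, dtype=float) for c in q]
    m = np.sqrt(sum(c * c for c in comps))
    scale = np.maximum(m - beta / theta2, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(m > 0, scale / m, 0.0)
    return tuple(c * scale for c in comps)  # type: ignore[return-value]


def _check_u_floor(u: np.ndarray, u_floor: float) -> None:
    if np.any(u < u_floor):
        raise ValueError("u has entries below the positivity floor; clamp before calling")


def fidelity_grad(u: np.ndarray, f: np.ndarray, sigma: float,
                  u_floor: float = 1e-3) -> np.ndarray:
    """Per-pixel derivative of the convexified Rician data fidelity.

    d/du [ u^2/(2 s^2) - log I0(u f/s^2) + (1/s)(sqrt(u)-sqrt(f))^2 ]
      = u/s^2 - (f/s^2) r(u f/s^2) + (1/s)(1 - sqrt(f/u)),
    with r = I1/I0.
    """
    u = np.asarray(u, dtype=float)
    f = np.asarray(f, dtype=float)
    _check_u_floor(u, u_floor)
    if np.any(f < 0):
        raise ValueError("f must be non-negative")
    s2 = sigma * sigma
    r = bessel_ratio(u * f / s2)
    return u / s2 - (f / s2) * r + (1.0 / sigma) * (1.0 - np.sqrt(f / u))


def fidelity_hess(u: np.ndarray, f: np.ndarray, sigma: float,
                  u_floor: float = 1e-3) -> np.ndarray:
    """Second derivative of the data fidelity (diagonal Newton curvature).

    1/s^2 - (f^2/s^4)[1 - (s^2/(u f)) r - r^2] + (sqrt(f)/(2 s)) u^(-3/2),
    rearranged so the f = 0 pixels evaluate to the analytic limit 1/s^2
    without dividing by f.
    """
    u = np.asarray(u, dtype=float)
    f = np.asarray(f, dtype=float)
    _check_u_floor(u, u_floor)
    if np.any(f < 0):
        raise ValueError("f must be non-negative")
    s2 = sigma * sigma
    r = bessel_ratio(u * f / s2)
    # -(f^2/s^4)*[1 - (s^2/(u f)) r - r^2] = -(f^2/s^4)(1 - r^2) + f r/(s^2 u)
    bessel_term = -(f * f / (s2 * s2)) * (1.0 - r * r) + f * r / (s2 * u)
    sqrt_term = (np.sqrt(f) / (2.0 * sigma)) * u ** (-1.5)
    return 1.0 / s2 + bessel_term + sqrt_term


def _penalty_grad(u: np.ndarray, state: BregmanState,
                  params: SolverParams) -> np.ndarray:
    gx, gy = diffops.grad(u)
    hh = diffops.hessian(u)
    d_res = (state.d[0] - gx - state.b1[0], state.d[1] - gy - state.b1[1])
    z_res = tuple(zc - hc - bc for zc, hc, bc in zip(state.z, hh, state.b2))
    return (params.theta1 * diffops.div(d_res)
            - params.theta2 * diffops.div2(z_res))


def newton_u_step(state: BregmanState, f: np.ndarray,
                  params: SolverParams) -> np.ndarray:
    """n_max Newton updates of the u-subproblem.

    E'(u) combines the fidelity derivative with the adjoint-exact gradients
    of the two quadratic penalties; E''(u) is the diagonal fidelity
    curvature (floored at 1e-8), optionally augmented by the operator-norm
    bounds of the penalty curvature.  After each update u is clamped to the
    positivity floor.
    """
    u = state.u
    for it in range(params.n_max):
        e1 = fidelity_grad(u, f, params.sigma, params.u_floor) \
            + _penalty_grad(u, state, params)
        e2 = fidelity_hess(u, f, params.sigma, params.u_floor)
        if params.hess_augment:
            e2 = e2 + params.theta1 * _GTG_BOUND + params.theta2 * _HTH_BOUND
        e2 = np.maximum(e2, _HESS_FLOOR)
        u = u - e1 / e2
        if not np.all(np.isfinite(u)):
            raise FloatingPointError(
                f"non-finite u in Newton inner iteration {it + 1} "
                f"(outer iteration {state.k + 1})")
        u = np.maximum(u, params.u_floor)
    return u


def update_bregman(state: BregmanState) -> BregmanState:
    """Dual ascent on the splitting residuals: b += residual."""
    gx, gy = diffops.grad(state.u)
    hh = diffops.hessian(state.u)
    b1 = (state.b1[0] + gx - state.d[0], state.b1[1] + gy - state.d[1])
    b2 = tuple(bc + hc - zc for bc, hc, zc in zip(state.b2, hh, state.z))
    return BregmanState(u=state.u, d=state.d, z=state.z,
                        b1=b1, b2=b2, alpha=state.alpha, k=state.k)


def energy(u: np.ndarray, f: np.ndarray, params: SolverParams,
           alpha: np.ndarray) -> float:
    """Value of the full objective at u (weight map alpha held fixed)."""
    u = np.asarray(u, dtype=float)
    f = np.asarray(f, dtype=float)
    _check_u_floor(u, params.u_floor)
    s2 = params.sigma * params.sigma
    fid = (np.sum(u * u) / (2 * s2)
           - np.sum(log_i0(u * f / s2))
           + np.sum((np.sqrt(u) - np.sqrt(f)) ** 2) / params.sigma)
    svtv = np.sum(np.asarray(alpha) * diffops.grad_mag(diffops.grad(u)))
    hh = diffops.hessian(u)
    bh = params.beta * np.sum(np.sqrt(sum(c * c for c in hh)))
    return float(fid + svtv + bh)


def _zeros_vec(shape) -> VectorField:
    return np.zeros(shape), np.zeros(shape)


def _zeros_hess(shape) -> HessianField:
    return tuple(np.zeros(shape) for _ in range(4))  # type: ignore[return-value]


def denoise(f: np.ndarray, params: SolverParams,
            fidelity_grad_fn=None, fidelity_hess_fn=None,
            energy_fn=None,
            alpha_map: np.ndarray | None = None) -> DenoiseResult:
    """Run the split Bregman loop on a noisy magnitude image.

    `fidelity_grad_fn` / `fidelity_hess_fn` (and `energy_fn` for the trace)
    allow the baseline models to reuse the scaffold with their own data
    terms; `alpha_map` pins a fixed (e.g. spatially constant) TV weight,
    disabling the per-iteration refinement.
    """
    f = diffops.validate_image(f, "f")
    if np.any(f < 0):
        raise ValueError("noisy magnitude image must be non-negative")

    u = np.maximum(f, params.u_floor)
    if alpha_map is not None:
        alpha = np.broadcast_to(np.asarray(alpha_map, dtype=float), f.shape).copy()
        refine = False
    else:
        alpha = compute_weight(f, params.weight)
        refine = params.refine_alpha

    state = BregmanState(u=u, d=_zeros_vec(f.shape), z=_zeros_hess(f.shape),
                         b1=_zeros_vec(f.shape), b2=_zeros_hess(f.shape),
                         alpha=alpha)
    grad_fn = fidelity_grad_fn
    hess_fn = fidelity_hess_fn
    trace: list[float] = []
    iterations = 0
    for k in range(params.k_max):
        state.k = k
        gx, gy = diffops.grad(state.u)
        state.d = shrink_vector((gx + state.b1[0], gy + state.b1[1]),
                                state.alpha, params.theta1)
        hh = diffops.hessian(state.u)
        state.z = shrink_hessian(tuple(h + b for h, b in zip(hh, state.b2)),
                                 params.beta, params.theta2)
        u_prev = state.u
        try:
            if grad_fn is None:
                state.u = newton_u_step(state, f, params)
            else:
                state.u = _generic_newton_step(state, f, params, grad_fn, hess_fn)
        except FloatingPointError as exc:
            raise FloatingPointError(f"outer iteration {k + 1}: {exc}") from exc
        state = update_bregman(state)
        if grad_fn is None:
            trace.append(energy(state.u, f, params, state.alpha))
        elif energy_fn is not None:
            trace.append(float(energy_fn(state.u, f, state.alpha)))
        else:
            trace.append(float("nan"))
        iterations = k + 1
        if refine:
            state.alpha = refine_weight(state.u, params.weight)
        if params.tol is not None:
            rel = np.linalg.norm(state.u - u_prev) / max(np.linalg.norm(u_prev), 1e-12)
            if rel < params.tol:
                break
    return DenoiseResult(u_hat=state.u, energy_trace=trace,
                         alpha_final=state.alpha, iterations_run=iterations)


def _generic_newton_step(state: BregmanState, f: np.ndarray,
                         params: SolverParams, grad_fn, hess_fn) -> np.ndarray:
    """Newton u-step with a caller-supplied data term (baseline scaffold)."""
    u = state.u
    for it in range(params.n_max):
        e1 = grad_fn(u, f) + _penalty_grad(u, state, params)
        e2 = hess_fn(u, f)
        if params.hess_augment:
            e2 = e2 + params.theta1 * _GTG_BOUND + params.theta2 * _HTH_BOUND
        e2 = np.maximum(e2, _HESS_FLOOR)
        u = u - e1 / e2
        if not np.all(np.isfinite(u)):
            raise FloatingPointError(
                f"non-finite u in Newton inner iteration {it + 1}")
        u = np.maximum(u, params.u_floor)
    return u


def tune_params(f: np.ndarray, clean: np.ndarray, params: SolverParams,
                grid_alpha0: Sequence[float], grid_beta: Sequence[float],
                max_passes: int = 5) -> SolverParams:
    """Alternating coordinate search for (alpha0, beta) maximizing PSNR.

    Each pass sweeps the alpha0 grid with beta fixed, takes the first
    maximum, then sweeps the beta grid with the new alpha0; stops when a
    pass changes nothing or after `max_passes` passes.  Deterministic.
    """
    from .metrics import psnr

    if len(grid_alpha0) == 0 or len(grid_beta) == 0:
        raise ValueError("parameter grids must be non-empty")

    def run(alpha0: float, beta: float) -> float:
        p = replace(params, beta=beta,
                    weight=replace(params.weight, alpha0=alpha0))
        return psnr(denoise(f, p).u_hat, clean)

    alpha0 = params.weight.alpha0
    beta = params.beta
    cache: dict[tuple[float, float], float] = {}

    def score(a, b):
        key = (a, b)
        if key not in cache:
            cache[key] = run(a, b)
        return cache[key]

    for _ in range(max_passes):
        # first-maximum tie-break: scan in grid order
        best_a, best_s = grid_alpha0[0], -np.inf
        for a in grid_alpha0:
            s = score(a, beta)
            if s > best_s:
                best_a, best_s = a, s
        best_b, best_s = grid_beta[0], -np.inf
        for b in grid_beta:
            s = score(best_a, b)
            if s > best_s:
                best_b, best_s = b, s
        if best_a == alpha0 and best_b == beta:
            break
        alpha0, beta = best_a, best_b
    return replace(params, beta=beta, weight=replace(params.weight, alpha0=alpha0))
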
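"""Discrete differential operators on 2D pixel grids.

The solver relies on the gradient/divergence and Hessian/second-divergence
pairs being exact adjoints of one another, so that the closed-form gradient
of the quadratic penalty terms used in the Newton update is the true
gradient of the discretized objective.  To guarantee this, the divergence
operators are *defined* as (negative) transposes of the difference
operators rather than by independent stencils:

* ``grad`` — forward first differences with a replicate (Neumann) boundary:
  the difference at the last row/column of each axis is zero.
* ``div``  — the negative adjoint of ``grad``: ``<grad u, p> + <u, div p> = 0``
  exactly (up to float round-off).
* ``hessian`` — backward differences applied to each gradient component,
  where "backward difference" is exactly the negative adjoint of the
  forward difference, so the Hessian matrix is a product of the two
  difference matrices.
* ``div2`` — the (positive) adjoint of ``hessian``:
  ``<hessian u, z> = <u, div2 z>`` exactly.

Pixel spacing is fixed at 1; all derivatives are in intensity-per-pixel
units.  Arrays are plain ``numpy`` float arrays; a vector field is a pair
``(vx, vy)`` (x = columns, y = rows) and a Hessian field is a 4-tuple
``(hxx, hxy, hyx, hyy)``.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "validate_image",
    "grad",
    "div",
    "hessian",
    "div2",
    "gauss_smooth",
    "grad_mag",
]

_AXIS_X = 1  # columns, index j
_AXIS_Y = 0  # rows, index i


def validate_image(u: np.ndarray, name: str = "image") -> np.ndarray:
    """Check that `u` is a finite 2D array with at least 2 samples per axis."""
    u = np.asarray(u, dtype=float)
    if u.ndim != 2:
        raise ValueError(f"{name} must be 2D, got shape {u.shape}")
    if u.shape[0] < 2 or u.shape[1] < 2:
        raise ValueError(f"{name} needs at least 2 samples per axis, got {u.shape}")
    if not np.all(np.isfinite(u)):
        raise ValueError(f"{name} contains non-finite values")
    return u


def _fdiff(u: np.ndarray, axis: int) -> np.ndarray:
    """Forward difference along `axis`; zero at the trailing edge (Neumann)."""
    out = np.zeros_like(u)
    if axis == _AXIS_X:
        out[:, :-1] = u[:, 1:] - u[:, :-1]
    else:
        out[:-1, :] = u[1:, :] - u[:-1, :]
    return out


def _fdiff_adj(p: np.ndarray, axis: int) -> np.ndarray:
    """Adjoint (transpose) of `_fdiff` along `axis`.

    For the forward-difference matrix D with a zeroed last row, the
    transpose acts as: (D^T p)[0] = -p[0]; (D^T p)[j] = p[j-1] - p[j] for
    interior j; (D^T p)[last] = p[last-1].
    """
    out = np.empty_like(p)
    if axis == _AXIS_X:
        out[:, 0] = -p[:, 0]
        out[:, 1:-1] = p[:, :-2] - p[:, 1:-1]
        out[:, -1] = p[:, -2]
    else:
        out[0, :] = -p[0, :]
        out[1:-1, :] = p[:-2, :] - p[1:-1, :]
        out[-1, :] = p[-2, :]
    return out


def _bdiff(p: np.ndarray, axis: int) -> np.ndarray:
    """Backward difference = negative adjoint of the forward difference."""
    return -_fdiff_adj(p, axis)


def grad(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward-difference gradient ``(vx, vy)`` of an image."""
    u = validate_image(u)
    return _fdiff(u, _AXIS_X), _fdiff(u, _AXIS_Y)


def div(p: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Divergence of a vector field; the exact negative adjoint of `grad`."""
    vx, vy = p
    vx = np.asarray(vx, dtype=float)
    vy = np.asarray(vy, dtype=float)
    if vx.shape != vy.shape:
        raise ValueError(f"vector field components differ in shape: {vx.shape} vs {vy.shape}")
    return -(_fdiff_adj(vx, _AXIS_X) + _fdiff_adj(vy, _AXIS_Y))


def hessian(u: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Second differences ``(hxx, hxy, hyx, hyy)``: backward diff of each
    forward-difference gradient component."""
    vx, vy = grad(u)
    return (
        _bdiff(vx, _AXIS_X),
        _bdiff(vx, _AXIS_Y),
        _bdiff(vy, _AXIS_X),
        _bdiff(vy, _AXIS_Y),
    )


def div2(z: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]) -> np.ndarray:
    """Second divergence; the exact (positive) adjoint of `hessian`.

    With H = B·G (backward-after-forward differences), div2 = H^T = G^T·B^T,
    and B^T = -(forward difference).
    """
    hxx, hxy, hyx, hyy = (np.asarray(c, dtype=float) for c in z)
    if not (hxx.shape == hxy.shape == hyx.shape == hyy.shape):
        raise ValueError("Hessian field components differ in shape")
    # adjoint of hxx = Bx(vx): vx-contribution is Bx^T hxx = -fdiff_x(hxx), etc.
    px = -(_fdiff(hxx, _AXIS_X) + _fdiff(hxy, _AXIS_Y))
    py = -(_fdiff(hyx, _AXIS_X) + _fdiff(hyy, _AXIS_Y))
    return _fdiff_adj(px, _AXIS_X) + _fdiff_adj(py, _AXIS_Y)


def gauss_smooth(u: np.ndarray, omega: float) -> np.ndarray:
    """Gaussian smoothing with standard deviation `omega` pixels.

    The kernel is truncated at 4*omega and the boundary is replicated;
    ``omega == 0`` returns the input unchanged.
    """
    u = validate_image(u)
    if omega < 0:
        raise ValueError(f"omega must be >= 0, got {omega}")
    if omega == 0:
        return u.copy()
    return ndimage.gaussian_filter(u, sigma=omega, mode="nearest", truncate=4.0)


def grad_mag(p: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Per-pixel Euclidean norm of a vector field."""
    vx, vy = p
    vx = np.asarray(vx, dtype=float)
    vy = np.asarray(vy, dtype=float)
    if vx.shape != vy.shape:
        raise ValueError(f"vector field components differ in shape: {vx.shape} vs {vy.shape}")
    return np.hypot(vx, vy)


def grad_matrix(shape: tuple[int, int]) -> np.ndarray:
    """Dense matrix of `grad` (stacked x then y blocks) on a small grid.

    Intended for adjointness verification on grids up to ~12x12; builds a
    (2*m*n, m*n) dense array.
    """
    m, n = shape
    size = m * n
    G = np.zeros((2 * size, size))
    for k in range(size):
        e = np.zeros(size)
        e[k] = 1.0
        vx, vy = grad(e.reshape(m, n))
        G[:size, k] = vx.ravel()
        G[size:, k] = vy.ravel()
    return G


def hessian_matrix(shape: tuple[int, int]) -> np.ndarray:
    """Dense matrix of `hessian` (stacked xx, xy, yx, yy blocks)."""
    m, n = shape
    size = m * n
    H = np.zeros((4 * size, size))
    for k in range(size):
        e = np.zeros(size)
        e[k] = 1.0
        comps = hessian(e.reshape(m, n))
        for b, c in enumerate(comps):
            H[b * size:(b + 1) * size, k] = c.ravel()
    return H
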
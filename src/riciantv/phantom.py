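"""Synthetic test images with known structure.

Real MR slices are piecewise-smooth: large near-flat tissue regions,
sharp tissue boundaries, and slow intensity ramps (coil shading, partial
volume).  The phantoms here emulate exactly those three features — flat
regions with disks/rectangles (where TV staircasing is provoked), linear
ramps (where the bounded Hessian term shows its benefit), and a mixed
scene — with exact ground truth plus edge and ramp masks, so every solver
property can be tested without external data.  Intensities live on the
0-255 scale; default backgrounds are >= 10 so the Rician regime resembles
tissue rather than air (a dedicated zero-background fixture exercises the
f = 0 code paths).

A shape is a tuple ``(kind, geometry, intensity)``:

* ``("disk", {"center": (row, col), "radius": r}, value)``
* ``("rectangle", {"rect": (r0, c0, r1, c1)}, value)`` — half-open bounds
* ``("ramp", {"rect": (r0, c0, r1, c1), "axis": 0|1}, (v_start, v_end))``
  — linear interpolation along ``axis`` across the rectangle
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["PhantomSpec", "make_phantom", "standard_suite"]

# neighbor intensity jump (levels) above which a boundary counts as an edge
_EDGE_JUMP = 1.0


@dataclass(frozen=True)
class PhantomSpec:
    size: int = 128
    background: float = 10.0
    shapes: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("size must be >= 2")
        if not 0 <= self.background <= 255:
            raise ValueError("background intensity out of [0, 255]")


def _intensities(shape) -> list[float]:
    kind, _, value = shape
    return list(value) if kind == "ramp" else [value]


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render a spec into (image, edge_mask, ramp_mask).

    Shapes are painted back-to-front in list order.  ``edge_mask`` marks
    pixels within 1 px of an intensity discontinuity (region-label change
    with an actual jump); ``ramp_mask`` marks pixels inside ramp shapes.
    Deterministic for a fixed spec.
    """
    n = spec.size
    for shape in spec.shapes:
        for v in _intensities(shape):
            if not 0 <= v <= 255:
                raise ValueError(f"shape intensity {v} out of [0, 255]")

    img = np.full((n, n), float(spec.background))
    labels = np.zeros((n, n), dtype=int)
    ramp_mask = np.zeros((n, n), dtype=bool)
    yy, xx = np.mgrid[0:n, 0:n]

    for idx, (kind, geom, value) in enumerate(spec.shapes, start=1):
        if kind == "disk":
            (cy, cx), r = geom["center"], geom["radius"]
            mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
            img[mask] = float(value)
        elif kind == "rectangle":
            r0, c0, r1, c1 = geom["rect"]
            mask = np.zeros((n, n), dtype=bool)
            mask[r0:r1, c0:c1] = True
            img[mask] = float(value)
        elif kind == "ramp":
            r0, c0, r1, c1 = geom["rect"]
            axis = geom.get("axis", 1)
            v0, v1 = value
            mask = np.zeros((n, n), dtype=bool)
            mask[r0:r1, c0:c1] = True
            length = (r1 - r0) if axis == 0 else (c1 - c0)
            if length < 2:
                raise ValueError("ramp needs at least 2 pixels along its axis")
            t = ((yy - r0) if axis == 0 else (xx - c0)) / (length - 1)
            img[mask] = (v0 + (v1 - v0) * t)[mask]
            ramp_mask |= mask
        else:
            raise ValueError(f"unknown shape kind {kind!r}")
        labels[mask] = idx

    # edge = label boundary with a real intensity jump, dilated to 1 px
    edge = np.zeros((n, n), dtype=bool)
    for axis in (0, 1):
        lab_a = labels.take(range(n - 1), axis=axis)
        lab_b = labels.take(range(1, n), axis=axis)
        img_a = img.take(range(n - 1), axis=axis)
        img_b = img.take(range(1, n), axis=axis)
        jump = (lab_a != lab_b) & (np.abs(img_a - img_b) > _EDGE_JUMP)
        if axis == 0:
            edge[:-1, :] |= jump
            edge[1:, :] |= jump
        else:
            edge[:, :-1] |= jump
            edge[:, 1:] |= jump
    edge = ndimage.binary_dilation(edge, iterations=1)
    return img, edge, ramp_mask


def _flat_disks(size: int) -> PhantomSpec:
    s = size / 128.0
    shapes = (
        ("rectangle", {"rect": (int(8 * s), int(8 * s), int(56 * s), int(56 * s))}, 80.0),
        ("disk", {"center": (int(40 * s), int(88 * s)), "radius": int(22 * s)}, 180.0),
        ("disk", {"center": (int(90 * s), int(36 * s)), "radius": int(18 * s)}, 130.0),
        ("disk", {"center": (int(92 * s), int(92 * s)), "radius": int(12 * s)}, 230.0),
        ("disk", {"center": (int(92 * s), int(92 * s)), "radius": int(5 * s)}, 60.0),
    )
    return PhantomSpec(size=size, background=20.0, shapes=shapes)


def _ramps(size: int) -> PhantomSpec:
    n = size
    h = n // 2
    shapes = (
        ("ramp", {"rect": (int(0.1 * n), int(0.1 * n), h - 2, int(0.9 * n)),
                  "axis": 1}, (50.0, 200.0)),
        ("ramp", {"rect": (h + 2, int(0.1 * n), int(0.9 * n), int(0.9 * n)),
                  "axis": 0}, (220.0, 40.0)),
    )
    return PhantomSpec(size=size, background=15.0, shapes=shapes)


def _mixed(size: int) -> PhantomSpec:
    n = size
    h = n // 2
    shapes = (
        ("ramp", {"rect": (int(0.08 * n), int(0.08 * n), h - 3, int(0.92 * n)),
                  "axis": 1}, (40.0, 190.0)),
        ("disk", {"center": (int(0.72 * n), int(0.3 * n)),
                  "radius": int(0.14 * n)}, 160.0),
        ("rectangle", {"rect": (int(0.6 * n), int(0.55 * n),
                                int(0.9 * n), int(0.9 * n))}, 100.0),
        ("disk", {"center": (int(0.75 * n), int(0.72 * n)),
                  "radius": int(0.07 * n)}, 220.0),
    )
    return PhantomSpec(size=size, background=12.0, shapes=shapes)


def _zero_background(size: int) -> PhantomSpec:
    shapes = (
        ("disk", {"center": (size // 2, size // 2), "radius": size // 3}, 150.0),
    )
    return PhantomSpec(size=size, background=0.0, shapes=shapes)


def standard_suite() -> list[tuple[str, PhantomSpec]]:
    """Named deterministic fixtures covering the denoiser's test regimes."""
    suite = []
    for size in (64, 128):
        suite.append((f"flat+disks-{size}", _flat_disks(size)))
        suite.append((f"ramps-{size}", _ramps(size)))
        suite.append((f"mixed-{size}", _mixed(size)))
    suite.append(("zero-background-64", _zero_background(64)))
    return suite
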
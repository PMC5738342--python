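"""Shared ellipse geometry.

Conventions: 0-based coordinates, x = column, y = row, pixel centres at
integer coordinates.  Ellipse orientation theta is the angle of the major
axis against the +x axis, wrapped into [0, pi).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidInputError

__all__ = [
    "Ellipse",
    "wrap_orientation",
    "ellipse_interior_pixels",
    "ellipse_mask",
    "ellipse_overlap_area",
    "ellipse_iou",
]


def wrap_orientation(theta: float) -> float:
    """Wrap an orientation angle into [0, pi) (orientations are pi-periodic)."""
    t = float(theta) % np.pi
    if t >= np.pi:  # guard against rounding at the boundary
        t -= np.pi
    return t


@dataclass(frozen=True)
class Ellipse:
    """Parametric cell-shape candidate: centre (cx, cy), semi-axes a >= b > 0,
    major-axis orientation theta in [0, pi)."""

    cx: float
    cy: float
    a: float
    b: float
    theta: float

    def __post_init__(self):
        if not (np.isfinite([self.cx, self.cy, self.a, self.b, self.theta]).all()):
            raise InvalidInputError("ellipse parameters must be finite")
        if not (self.a >= self.b > 0):
            raise InvalidInputError(f"require a >= b > 0, got a={self.a}, b={self.b}")
        object.__setattr__(self, "theta", wrap_orientation(self.theta))

    @property
    def area(self) -> float:
        return float(np.pi * self.a * self.b)

    def scaled(self, factor: float) -> "Ellipse":
        """Isotropically scale both axes about the centre."""
        return Ellipse(self.cx, self.cy, self.a * factor, self.b * factor, self.theta)

    def contains(self, x, y) -> np.ndarray:
        """Vectorised interior test (boundary inclusive)."""
        dx = np.asarray(x, dtype=float) - self.cx
        dy = np.asarray(y, dtype=float) - self.cy
        c, s = np.cos(self.theta), np.sin(self.theta)
        u = (dx * c + dy * s) / self.a
        v = (-dx * s + dy * c) / self.b
        return u * u + v * v <= 1.0


def _bbox(e: Ellipse) -> tuple[int, int, int, int]:
    # axis-aligned extent of a rotated ellipse
    c, s = np.cos(e.theta), np.sin(e.theta)
    ex = np.sqrt((e.a * c) ** 2 + (e.b * s) ** 2)
    ey = np.sqrt((e.a * s) ** 2 + (e.b * c) ** 2)
    return (
        int(np.floor(e.cx - ex)),
        int(np.ceil(e.cx + ex)),
        int(np.floor(e.cy - ey)),
        int(np.ceil(e.cy + ey)),
    )


def ellipse_interior_pixels(e: Ellipse, shape: tuple[int, int] | None = None):
    """Integer pixel centres inside the ellipse as (xs, ys) arrays.

    When `shape` = (H, W) is given, pixels outside the image are dropped.
    """
    x0, x1, y0, y1 = _bbox(e)
    if shape is not None:
        H, W = shape
        x0, x1 = max(x0, 0), min(x1, W - 1)
        y0, y1 = max(y0, 0), min(y1, H - 1)
    if x1 < x0 or y1 < y0:
        z = np.empty(0, dtype=int)
        return z, z
    xs = np.arange(x0, x1 + 1)
    ys = np.arange(y0, y1 + 1)
    X, Y = np.meshgrid(xs, ys)
    inside = e.contains(X, Y)
    return X[inside], Y[inside]


def ellipse_mask(e: Ellipse, shape: tuple[int, int]) -> np.ndarray:
    """Boolean H x W mask of interior pixels."""
    m = np.zeros(shape, dtype=bool)
    xs, ys = ellipse_interior_pixels(e, shape)
    m[ys, xs] = True
    return m


def ellipse_overlap_area(e1: Ellipse, e2: Ellipse) -> float:
    """Interior intersection area in px^2 by dense sampling on the 1-px grid."""
    x0 = max(_bbox(e1)[0], _bbox(e2)[0])
    x1 = min(_bbox(e1)[1], _bbox(e2)[1])
    y0 = max(_bbox(e1)[2], _bbox(e2)[2])
    y1 = min(_bbox(e1)[3], _bbox(e2)[3])
    if x1 < x0 or y1 < y0:
        return 0.0
    X, Y = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    both = e1.contains(X, Y) & e2.contains(X, Y)
    return float(both.sum())


def ellipse_iou(e1: Ellipse, e2: Ellipse) -> float:
    """Intersection-over-union of interiors on the 1-px grid."""
    inter = ellipse_overlap_area(e1, e2)
    if inter == 0.0:
        return 0.0
    n1 = len(ellipse_interior_pixels(e1)[0])
    n2 = len(ellipse_interior_pixels(e2)[0])
    union = n1 + n2 - inter
    return inter / union if union > 0 else 0.0
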
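"""Elliptical cell-candidate (blob hypothesis) generation.

Foreground probability maps are converted into a *superset* of plausible
cell ellipses: seeds are local maxima of the smoothed map, each seed's
share of its thresholded component (pixels nearest that seed) fixes an
ellipse shape by second moments, and the final candidate is the largest
isotropic scaling of that shape that still *consists of* sufficiently
foreground pixels — at least ``COVERAGE_MIN`` of its interior pixels clear
the threshold and its mean interior probability (the *support*) stays at or
above it.  Maximality is therefore guaranteed by construction: scaling any
emitted ellipse by a further 5% violates the coverage or support condition
or exceeds the axis bound.  Overcounting is expected; the trajectory model
makes the final detection decision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.ndimage import gaussian_filter
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from ._geometry import Ellipse, ellipse_interior_pixels, ellipse_iou, wrap_orientation
from .exceptions import DegenerateGeometryError, InvalidInputError
from .segmentation import ForegroundMap

__all__ = [
    "Ellipse",
    "BlobHypothesis",
    "fit_ellipse",
    "ellipse_support",
    "ellipse_coverage",
    "is_admissible",
    "generate_hypotheses",
    "deduplicate",
]

#: multiplicative step of the maximality scale search; an emitted ellipse
#: scaled by this factor must fail the coverage/support or axis-bound check
SCALE_STEP = 1.05

#: minimum fraction of interior pixels that must clear the threshold for an
#: ellipse to count as "consisting of" foreground pixels
COVERAGE_MIN = 0.95


@dataclass(frozen=True)
class BlobHypothesis:
    """One elliptical cell candidate in one frame."""

    id: int
    frame: int
    ellipse: Ellipse
    support: float

    def __post_init__(self):
        if not (0.0 <= self.support <= 1.0):
            raise InvalidInputError("support must lie in [0, 1]")


def fit_ellipse(pixels) -> Ellipse:
    """Second-moment ellipse of a pixel region.

    `pixels` is an (N, 2) array of (x, y) pixel centres.  The centre is the
    centroid, the axis directions and ratio come from the eigendecomposition
    of the second central moments (with the 1/12 unit-square correction per
    pixel), and the axes are scaled so the ellipse area equals the region
    area N.
    """
    pts = np.asarray(pixels, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidInputError("expected an (N, 2) array of (x, y) pixel centres")
    n = pts.shape[0]
    if n < 5:
        raise DegenerateGeometryError(f"need >= 5 pixels to fit an ellipse, got {n}")
    c = pts.mean(axis=0)
    d = pts - c
    cov = d.T @ d / n
    # collinearity check on the raw (uncorrected) moments
    if np.linalg.eigvalsh(cov)[0] < 1e-9:
        raise DegenerateGeometryError("pixel region is collinear")
    cov = cov + np.eye(2) / 12.0  # each pixel is a unit square, not a point
    evals, evecs = np.linalg.eigh(cov)
    a0 = 2.0 * np.sqrt(evals[1])
    b0 = 2.0 * np.sqrt(evals[0])
    theta = wrap_orientation(np.arctan2(evecs[1, 1], evecs[0, 1]))
    s = np.sqrt(n / (np.pi * a0 * b0))
    return Ellipse(cx=c[0], cy=c[1], a=a0 * s, b=b0 * s, theta=theta)


def ellipse_support(ellipse: Ellipse, probs: np.ndarray) -> float:
    """Mean foreground probability over the ellipse interior.

    Interior pixels falling outside the image count as probability zero, so
    support decays as a candidate grows past the field of view.
    """
    H, W = probs.shape
    xs, ys = ellipse_interior_pixels(ellipse)
    if len(xs) == 0:
        return 0.0
    inb = (xs >= 0) & (xs < W) & (ys >= 0) & (ys < H)
    total = probs[ys[inb], xs[inb]].sum()
    return float(total / len(xs))


def ellipse_coverage(ellipse: Ellipse, probs: np.ndarray, tau: float) -> float:
    """Fraction of interior pixels whose probability clears tau
    (out-of-image interior pixels count as failing)."""
    H, W = probs.shape
    xs, ys = ellipse_interior_pixels(ellipse)
    if len(xs) == 0:
        return 0.0
    inb = (xs >= 0) & (xs < W) & (ys >= 0) & (ys < H)
    n_ok = int((probs[ys[inb], xs[inb]] >= tau).sum())
    return n_ok / len(xs)


def is_admissible(ellipse: Ellipse, probs: np.ndarray, tau: float, max_axis: float) -> bool:
    """Whether an ellipse still counts as a foreground blob: axis bound,
    interior coverage and mean support all satisfied."""
    return (
        ellipse.a <= max_axis
        and ellipse_coverage(ellipse, probs, tau) >= COVERAGE_MIN
        and ellipse_support(ellipse, probs) >= tau
    )


def generate_hypotheses(
    fmap: ForegroundMap,
    tau: float = 0.5,
    min_axis: float = 3.0,
    max_axis: float = 80.0,
    start_id: int = 0,
) -> list[BlobHypothesis]:
    """Maximal elliptical foreground candidates of one probability map.

    Every returned hypothesis has support >= tau, b >= min_axis,
    a <= max_axis, and is maximal under isotropic scaling: a 5% larger copy
    violates the coverage/support condition or the axis bound.  Near-exact
    duplicates (same blob reached from several plateau seeds) are removed;
    milder pruning is left to :func:`deduplicate`.
    """
    if not (min_axis < max_axis):
        raise InvalidInputError("require min_axis < max_axis")
    if not (0 < tau < 1):
        raise InvalidInputError("tau must lie in (0, 1)")
    probs = fmap.probs
    mask = probs >= tau
    if not mask.any():
        return []
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    # seed at ridges of the distance transform: one peak per blob core, and
    # one per constriction-separated core when blobs merged into a component
    dt = ndimage.distance_transform_edt(mask)
    seed_relief = gaussian_filter(dt, 1.0) + 0.01 * gaussian_filter(probs, 1.0)
    seeds = peak_local_max(
        seed_relief,
        min_distance=max(1, int(np.ceil(2 * min_axis))),
        threshold_abs=0.5,
        exclude_border=False,
    )
    # split merged components at their constrictions: watershed on the
    # inverted distance transform with the seeds as markers
    markers = np.zeros_like(labels)
    for k, (sy, sx) in enumerate(seeds):
        if labels[sy, sx] > 0:
            markers[sy, sx] = k + 1
    basins = watershed(-dt, markers, mask=mask)
    raw: list[BlobHypothesis] = []
    next_id = start_id
    for k in range(1, len(seeds) + 1):
        ys, xs = np.nonzero(basins == k)
        if len(ys) == 0:
            continue
        grp = np.column_stack([xs, ys]).astype(float)
        try:
            base = fit_ellipse(grp)
        except DegenerateGeometryError:
            continue
        # anchor the scale search at the smallest admissible size
        t0 = min_axis / base.b
        cand = base.scaled(t0)
        if not is_admissible(cand, probs, tau, max_axis):
            continue
        while True:
            nxt = cand.scaled(SCALE_STEP)
            if not is_admissible(nxt, probs, tau, max_axis):
                break
            cand = nxt
        raw.append(
            BlobHypothesis(
                id=next_id,
                frame=fmap.frame,
                ellipse=cand,
                support=ellipse_support(cand, probs),
            )
        )
        next_id += 1
    # drop near-exact duplicates from plateau seeds
    return deduplicate(raw, max_iou=0.95)


def deduplicate(hyps: list[BlobHypothesis], max_iou: float = 0.6) -> list[BlobHypothesis]:
    """Greedy non-maximum suppression of same-frame near-duplicates.

    Hypotheses are visited by descending support (ties by smaller id); a
    candidate is dropped when its interior IoU with an already-retained
    same-frame hypothesis exceeds max_iou.
    """
    if not (0 < max_iou < 1):
        raise InvalidInputError("max_iou must lie in (0, 1)")
    order = sorted(hyps, key=lambda h: (-h.support, h.id))
    kept: list[BlobHypothesis] = []
    for h in order:
        dup = False
        for k in kept:
            if k.frame != h.frame:
                continue
            # cheap gate before rasterised IoU
            if (k.ellipse.cx - h.ellipse.cx) ** 2 + (k.ellipse.cy - h.ellipse.cy) ** 2 > (
                k.ellipse.a + h.ellipse.a
            ) ** 2:
                continue
            if ellipse_iou(k.ellipse, h.ellipse) > max_iou:
                dup = True
                break
        if not dup:
            kept.append(h)
    kept.sort(key=lambda h: h.id)
    return kept
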
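"""Cell morphology, migration and junction-intensity quantification.

Implements the standard read-outs for endothelial monolayers:

* elongation factor — major/minor axis ratio of the best-fit
  (second-moment) ellipse of a cell;
* perimeter of a cell outline, in micrometres;
* accumulated distance (total path length of the cell centroid),
  Euclidean distance (straight start-to-end displacement), mean velocity
  and directionality;
* Rel-VEcad-C — relative VE-cadherin concentration: integrated junctional
  fluorescence of a region of interest divided by the junction length of
  that region (a.u. per micrometre);
* the total-VE-cadherin estimate (mean perimeter x mean Rel-VEcad-C),
  which is conserved when cells elongate and dilute their junction label;
* JAIL plaque count/size (junction-associated intermittent lamellipodia
  leave VE-cadherin plaques; we quantify supplied plaque masks);
* pole vs. lateral partition of a cell boundary for elongated cells
  (large plaques concentrate at the two cell poles, small ones laterally).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon

from ._geometry import Ellipse, wrap_orientation
from .exceptions import (
    DegenerateGeometryError,
    InvalidInputError,
    NotApplicableError,
)

__all__ = [
    "CellOutline",
    "MigrationSummary",
    "RelVEcadRecord",
    "PlaqueMetrics",
    "elongation_factor",
    "polygon_perimeter",
    "migration_summary",
    "rel_vecad_c",
    "total_vecad_estimate",
    "plaque_metrics",
    "pole_lateral_partition",
]

#: default ribbon width when a junction ROI is given as a polyline, px
DEFAULT_RIBBON_WIDTH_PX = 3.0
#: a cell counts as elongated (poles defined) above this aspect ratio
ELONGATION_CUTOFF = 1.5
#: default half-opening angle of the pole sectors, degrees
DEFAULT_POLE_HALF_ANGLE_DEG = 45.0


@dataclass(frozen=True)
class CellOutline:
    """Closed simple polygon of a cell border, vertices in px (x, y)."""

    vertices: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise InvalidInputError("outline needs >= 3 (x, y) vertices")
        if not np.isfinite(v).all():
            raise InvalidInputError("outline vertices must be finite")
        if self.pixel_size <= 0:
            raise InvalidInputError("pixel_size must be > 0")
        poly = Polygon(v)
        if not poly.is_valid or poly.area <= 0:
            raise InvalidInputError("outline must be a simple polygon with positive area")
        object.__setattr__(self, "vertices", v)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass(frozen=True)
class MigrationSummary:
    """Path statistics of one cell centroid."""

    accumulated_um: float
    euclidean_um: float
    mean_velocity_um_h: float
    directionality: float  # euclidean / accumulated; NaN when accumulated = 0


@dataclass(frozen=True)
class RelVEcadRecord:
    """Relative VE-cadherin concentration of one ROI."""

    cell_id: int
    rel_vecad_c: float  # a.u. per µm of junction
    junction_length_um: float


@dataclass(frozen=True)
class PlaqueMetrics:
    """Count and sizes of junctional plaques, with optional zone labels."""

    count: int
    areas_um2: tuple[float, ...]
    zones: tuple[str | None, ...] = ()

    def __post_init__(self):
        if self.count != len(self.areas_um2):
            raise InvalidInputError("count must equal the number of areas")
        if self.zones and len(self.zones) != self.count:
            raise InvalidInputError("zones, when given, must match the number of plaques")


def _polygon_moments(vertices: np.ndarray):
    """Area, centroid and central second moments of a simple polygon
    (closed-form Green's-theorem sums)."""
    x = vertices[:, 0]
    y = vertices[:, 1]
    xn = np.roll(x, -1)
    yn = np.roll(y, -1)
    cross = x * yn - xn * y
    area = cross.sum() / 2.0
    if area == 0:
        raise DegenerateGeometryError("polygon has zero area")
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    mxx = ((x * x + x * xn + xn * xn) * cross).sum() / 12.0
    myy = ((y * y + y * yn + yn * yn) * cross).sum() / 12.0
    mxy = ((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * cross).sum() / 24.0
    a = abs(area)
    sgn = 1.0 if area > 0 else -1.0
    cov = np.array(
        [
            [sgn * mxx / a - cx * cx, sgn * mxy / a - cx * cy],
            [sgn * mxy / a - cx * cy, sgn * myy / a - cy * cy],
        ]
    )
    return a, (cx, cy), cov


def best_fit_ellipse(outline: CellOutline) -> Ellipse:
    """Second-moment best-fit ellipse of the polygon interior, area-matched."""
    area, (cx, cy), cov = _polygon_moments(outline.vertices)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 1e-12:
        raise DegenerateGeometryError("outline is degenerate (zero minor moment)")
    a0 = 2.0 * math.sqrt(evals[1])
    b0 = 2.0 * math.sqrt(evals[0])
    s = math.sqrt(area / (math.pi * a0 * b0))
    theta = wrap_orientation(math.atan2(evecs[1, 1], evecs[0, 1]))
    return Ellipse(cx=cx, cy=cy, a=a0 * s, b=b0 * s, theta=theta)


def elongation_factor(shape: Ellipse | CellOutline) -> float:
    """Aspect ratio (major axis / minor axis) of the shape's best-fit ellipse."""
    if isinstance(shape, Ellipse):
        return shape.a / shape.b
    if isinstance(shape, CellOutline):
        e = best_fit_ellipse(shape)
        return e.a / e.b
    raise InvalidInputError(f"unsupported shape type {type(shape).__name__}")


def polygon_perimeter(outline: CellOutline) -> float:
    """Perimeter of the closed outline, micrometres."""
    v = outline.vertices
    d = np.diff(np.vstack([v, v[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum() * outline.pixel_size)


def migration_summary(
    centroids,
    pixel_size: float,
    frame_interval_s: float,
) -> MigrationSummary:
    """Accumulated/Euclidean distance, mean velocity and directionality of
    an ordered centroid path (positions in px)."""
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise InvalidInputError("need >= 2 (x, y) positions")
    if pixel_size <= 0 or frame_interval_s <= 0:
        raise InvalidInputError("pixel_size and frame_interval_s must be > 0")
    steps = np.diff(pts, axis=0)
    acc = float(np.hypot(steps[:, 0], steps[:, 1]).sum() * pixel_size)
    euc = float(np.hypot(*(pts[-1] - pts[0])) * pixel_size)
    elapsed_h = (pts.shape[0] - 1) * frame_interval_s / 3600.0
    vel = acc / elapsed_h if elapsed_h > 0 else 0.0
    direc = euc / acc if acc > 0 else float("nan")
    return MigrationSummary(
        accumulated_um=acc,
        euclidean_um=euc,
        mean_velocity_um_h=vel,
        directionality=direc,
    )


def _ribbon_from_polyline(polyline: np.ndarray, width_px: float, shape) -> np.ndarray:
    """Rasterise a polyline into a ribbon mask of the given width."""
    H, W = shape
    Y, X = np.mgrid[0:H, 0:W]
    pts = np.column_stack([X.ravel(), Y.ravel()]).astype(float)
    dmin = np.full(pts.shape[0], np.inf)
    for p0, p1 in zip(polyline[:-1], polyline[1:]):
        seg = p1 - p0
        L2 = seg @ seg
        if L2 == 0:
            d = np.hypot(*(pts - p0).T)
        else:
            t = np.clip((pts - p0) @ seg / L2, 0.0, 1.0)
            proj = p0 + t[:, None] * seg
            d = np.hypot(*(pts - proj).T)
        dmin = np.minimum(dmin, d)
    return (dmin <= width_px / 2.0).reshape(H, W)


def rel_vecad_c(
    intensity: np.ndarray,
    roi_mask: np.ndarray | None = None,
    polyline: np.ndarray | None = None,
    junction_length_um: float | None = None,
    pixel_size: float = 1.0,
    cell_id: int = 0,
    ribbon_width_px: float = DEFAULT_RIBBON_WIDTH_PX,
    background: str | None = None,
) -> RelVEcadRecord:
    """Relative VE-cadherin concentration of a junction ROI.

    Integrates the junction-channel intensity over the ROI (a ribbon mask,
    or a polyline rasterised at `ribbon_width_px`) and divides by the
    junction length of the ROI in micrometres.  By default the raw
    intensity is integrated; background="annulus-median" subtracts the
    median of a 2-px annulus around the ribbon first.
    """
    img = np.asarray(intensity, dtype=float)
    if img.ndim != 2:
        raise InvalidInputError("intensity image must be 2-D")
    if pixel_size <= 0:
        raise InvalidInputError("pixel_size must be > 0")
    if roi_mask is None and polyline is None:
        raise InvalidInputError("provide roi_mask or polyline")
    if polyline is not None:
        pl = np.asarray(polyline, dtype=float)
        if pl.ndim != 2 or pl.shape[1] != 2 or pl.shape[0] < 2:
            raise InvalidInputError("polyline needs >= 2 (x, y) points")
        if junction_length_um is None:
            seg = np.diff(pl, axis=0)
            junction_length_um = float(np.hypot(seg[:, 0], seg[:, 1]).sum() * pixel_size)
        roi_mask = _ribbon_from_polyline(pl, ribbon_width_px, img.shape)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != img.shape:
        raise InvalidInputError("roi mask shape must match the intensity image")
    if not roi_mask.any():
        raise InvalidInputError("ROI is empty")
    if junction_length_um is None:
        # a ribbon of uniform width: length = area / width
        junction_length_um = float(roi_mask.sum() * pixel_size / ribbon_width_px)
    if junction_length_um <= 0:
        raise InvalidInputError("junction length must be > 0")
    vals = img.copy()
    if background == "annulus-median":
        annulus = ndimage.binary_dilation(roi_mask, iterations=2) & ~roi_mask
        if annulus.any():
            vals = vals - np.median(img[annulus])
    integral = float(vals[roi_mask].sum())
    return RelVEcadRecord(
        cell_id=cell_id,
        rel_vecad_c=integral / junction_length_um,
        junction_length_um=float(junction_length_um),
    )


def total_vecad_estimate(mean_perimeter_um: float, mean_rel_vecad: float) -> float:
    """Per-cell total VE-cadherin estimate: mean perimeter x mean Rel-VEcad-C.

    Constant under shape change that conserves the junction pool: doubling
    the perimeter halves the line density, leaving the product unchanged.
    """
    if mean_perimeter_um < 0 or mean_rel_vecad < 0:
        raise InvalidInputError("inputs must be >= 0")
    return mean_perimeter_um * mean_rel_vecad


def plaque_metrics(
    plaque_mask: np.ndarray,
    pixel_size: float,
    min_area_um2: float = 0.0,
    outline: CellOutline | None = None,
    half_angle_deg: float = DEFAULT_POLE_HALF_ANGLE_DEG,
) -> PlaqueMetrics:
    """Count and sizes (µm²) of junctional plaques in a binary mask.

    Plaques are 8-connected components with area >= min_area_um2.  When an
    elongated cell outline is supplied, each plaque is labelled "pole" or
    "lateral" by the direction of its centroid from the cell centroid
    relative to the major axis.
    """
    mask = np.asarray(plaque_mask, dtype=bool)
    if mask.ndim != 2:
        raise InvalidInputError("plaque mask must be 2-D")
    if pixel_size <= 0:
        raise InvalidInputError("pixel_size must be > 0")
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    areas = []
    centroids = []
    for k in range(1, n + 1):
        npx = int((labels == k).sum())
        area = npx * pixel_size**2
        if area >= min_area_um2:
            areas.append(area)
            ys, xs = np.nonzero(labels == k)
            centroids.append((xs.mean(), ys.mean()))
    zones: tuple[str | None, ...] = tuple(None for _ in areas)
    if outline is not None and areas:
        ell = best_fit_ellipse(outline)
        if ell.a / ell.b > ELONGATION_CUTOFF:
            half = math.radians(half_angle_deg)
            zl = []
            for (px, py) in centroids:
                phi = math.atan2(py - ell.cy, px - ell.cx)
                d = abs((phi - ell.theta + math.pi / 2) % math.pi - math.pi / 2)
                zl.append("pole" if d <= half else "lateral")
            zones = tuple(zl)
    return PlaqueMetrics(count=len(areas), areas_um2=tuple(areas), zones=zones)


def pole_lateral_partition(
    outline: CellOutline,
    half_angle_deg: float = DEFAULT_POLE_HALF_ANGLE_DEG,
    spacing_px: float = 1.0,
):
    """Label boundary points of an elongated cell as pole or lateral.

    Boundary points sampled every ~spacing_px are labelled "pole" when the
    direction from the centroid lies within ±half_angle of the major axis
    (either end), otherwise "lateral".  Only defined above the elongation
    cutoff (aspect ratio > 1.5); below it a NotApplicableError is raised.

    Returns (points, labels): an (N, 2) array of boundary points (px) and a
    list of "pole"/"lateral" strings.
    """
    ell = best_fit_ellipse(outline)
    if ell.a / ell.b <= ELONGATION_CUTOFF:
        raise NotApplicableError(
            f"elongation factor {ell.a / ell.b:.2f} below cutoff {ELONGATION_CUTOFF}"
        )
    if not (0 <= half_angle_deg <= 90):
        raise InvalidInputError("half_angle_deg must lie in [0, 90]")
    boundary = outline.polygon.exterior
    n = max(8, int(math.ceil(boundary.length / spacing_px)))
    pts = np.array(
        [boundary.interpolate(i / n, normalized=True).coords[0] for i in range(n)]
    )
    half = math.radians(half_angle_deg)
    labels = []
    for px, py in pts:
        phi = math.atan2(py - ell.cy, px - ell.cx)
        # angular distance to the major-axis line (pi-periodic)
        d = abs((phi - ell.theta + math.pi / 2) % math.pi - math.pi / 2)
        labels.append("pole" if d <= half else "lateral")
    return pts, labels
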
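"""Synthetic confluent-monolayer generator with ground truth.

Simulates non-overlapping elliptical cells moving with constant velocity
plus Gaussian acceleration noise, smoothly changing shape, and (optionally)
a subpopulation that elongates at a fixed per-frame rate while conserving
its area — the shape programme that dilutes a fixed junctional protein pool
over a growing perimeter.  A soft pairwise repulsion resolves interior
overlaps each frame, so the ground truth satisfies the monolayer
non-overlap assumption the tracker encodes.  Two renderers emulate the
measurement channels:

* phase contrast — dark cell bodies, a bright 2-px halo band around each
  boundary, additive Gaussian noise;
* junction fluorescence — cell territories are the influence tessellation
  of the ellipse interiors; each cell deposits a fixed total intensity
  spread uniformly over its boundary ribbon, so integrated ribbon
  intensity per cell equals the emitted total exactly.

Everything is reproducible from ``SimConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from ._geometry import Ellipse, ellipse_overlap_area, wrap_orientation
from .exceptions import ConfigurationError, InvalidInputError
from .io import ImageStack

__all__ = ["SimConfig", "GroundTruth", "JunctionRender", "simulate_tracks",
           "render_phase_contrast", "render_junction_fluorescence"]

#: ground-truth overlap tolerance: same-frame pairwise interior overlap must
#: stay below this fraction of the smaller cell's area
OVERLAP_TOLERANCE = 0.02


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic monolayer."""

    n_cells: int = 30
    field_size: tuple[int, int] = (512, 512)  # (H, W) px
    n_frames: int = 60
    frame_interval_s: float = 300.0
    pixel_size_um: float = 0.65
    sigma_acc: float = 0.3            # px/frame^2 acceleration noise
    sigma_shape_sim: float = 0.01     # per-frame log-axis drift s.d.
    sigma_theta_sim: float = 0.02     # per-frame orientation drift s.d., rad
    elongating_fraction: float = 0.2
    elongation_rate: float = 1.01     # per-frame multiplicative growth of a
    repulsion_strength: float = 0.5
    halo_amplitude: float = 40.0      # 8-bit-like intensity scale
    noise_sd: float = 5.0
    body_contrast: float = 30.0       # background minus interior intensity
    background: float = 100.0
    junction_total_intensity: float = 1000.0  # a.u. per cell
    axis_a_range: tuple[float, float] = (28.0, 36.0)
    axis_b_range: tuple[float, float] = (20.0, 28.0)
    init_speed_range: tuple[float, float] = (0.3, 1.0)  # px/frame
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise InvalidInputError("n_cells must be >= 1")
        if self.n_frames < 1:
            raise InvalidInputError("n_frames must be >= 1")
        for v in (self.sigma_acc, self.sigma_shape_sim, self.sigma_theta_sim,
                  self.noise_sd, self.repulsion_strength):
            if v < 0:
                raise InvalidInputError("noise/strength parameters must be >= 0")
        if not (0.0 <= self.elongating_fraction <= 1.0):
            raise InvalidInputError("elongating_fraction must lie in [0, 1]")
        if self.elongation_rate < 1.0:
            raise InvalidInputError("elongation_rate must be >= 1")


@dataclass
class GroundTruth:
    """True tracks and per-cell junction bookkeeping of one simulation."""

    tracks: np.ndarray           # (n_cells, n_frames, 5): cx, cy, a, b, theta
    elongating: np.ndarray       # (n_cells,) bool
    junction_totals: np.ndarray  # (n_cells,) a.u.
    config: SimConfig
    emitted_totals: dict = field(default_factory=dict)  # frame -> (n_cells,)

    @property
    def n_cells(self) -> int:
        return self.tracks.shape[0]

    @property
    def n_frames(self) -> int:
        return self.tracks.shape[1]

    def ellipse(self, cell: int, frame: int) -> Ellipse:
        cx, cy, a, b, th = self.tracks[cell, frame]
        return Ellipse(cx=cx, cy=cy, a=a, b=b, theta=th)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in range(self.n_cells):
            for t in range(self.n_frames):
                cx, cy, a, b, th = self.tracks[c, t]
                rows.append((t, c, cx, cy, a, b, th))
        return pd.DataFrame(rows, columns=["frame", "cell_id", "cx", "cy", "a", "b", "theta"])


@dataclass
class JunctionRender:
    """One junction-fluorescence frame with its per-cell ROI bookkeeping."""

    image: np.ndarray                 # (H, W) intensities, a.u.
    territories: np.ndarray           # (H, W) cell labels
    ribbons: dict                     # cell -> boolean ribbon mask
    boundary_length_px: dict          # cell -> boundary length in px
    outlines: dict                    # cell -> (N, 2) boundary polygon (x, y)


def _ellipses_overlap(p1, p2) -> float:
    e1 = Ellipse(cx=p1[0], cy=p1[1], a=p1[2], b=p1[3], theta=p1[4])
    e2 = Ellipse(cx=p2[0], cy=p2[1], a=p2[2], b=p2[3], theta=p2[4])
    return ellipse_overlap_area(e1, e2)


def _resolve_overlaps(state: np.ndarray, cfg: SimConfig, rng, max_iter: int = 120):
    """Push overlapping pairs apart along the centre line until every
    pairwise interior overlap is below tolerance."""
    n = state.shape[0]
    H, W = cfg.field_size
    step_base = max(0.5, cfg.repulsion_strength)
    for _ in range(max_iter):
        moved = False
        for i in range(n):
            for j in range(i + 1, n):
                dx = state[j, 0] - state[i, 0]
                dy = state[j, 1] - state[i, 1]
                gate = state[i, 2] + state[j, 2]
                if dx * dx + dy * dy > gate * gate:
                    continue
                area = _ellipses_overlap(state[i], state[j])
                amin = math.pi * min(state[i, 2] * state[i, 3], state[j, 2] * state[j, 3])
                if area <= OVERLAP_TOLERANCE * amin * 0.5:  # resolve past half-tolerance
                    continue
                d = math.hypot(dx, dy)
                if d < 1e-6:
                    ang = rng.uniform(0, 2 * math.pi)
                    ux, uy = math.cos(ang), math.sin(ang)
                else:
                    ux, uy = dx / d, dy / d
                step = step_base * max(1.0, math.sqrt(area) / 4.0)
                state[i, 0] -= ux * step / 2
                state[i, 1] -= uy * step / 2
                state[j, 0] += ux * step / 2
                state[j, 1] += uy * step / 2
                moved = True
        _clamp_to_field(state, H, W)
        if not moved:
            break


def _clamp_to_field(state: np.ndarray, H: int, W: int):
    for k in range(state.shape[0]):
        a = state[k, 2]
        state[k, 0] = min(max(state[k, 0], a), W - 1 - a)
        state[k, 1] = min(max(state[k, 1], a), H - 1 - a)


def simulate_tracks(cfg: SimConfig) -> GroundTruth:
    """Generate ground-truth tracks for the configured monolayer."""
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.field_size
    n = cfg.n_cells
    a0 = rng.uniform(*cfg.axis_a_range, size=n)
    b0 = rng.uniform(*cfg.axis_b_range, size=n)
    b0 = np.minimum(b0, a0 - 1e-6)
    if (math.pi * a0 * b0).sum() > 0.9 * H * W:
        raise ConfigurationError(
            "infeasible packing: total cell area exceeds 90% of the field"
        )
    # jittered grid initialisation
    rows = max(1, int(round(math.sqrt(n * H / W))))
    cols = int(math.ceil(n / rows))
    margin = float(a0.max())
    xs = np.linspace(margin, W - 1 - margin, cols)
    ys = np.linspace(margin, H - 1 - margin, rows)
    pos = []
    for yi in ys:
        for xi in xs:
            pos.append((xi, yi))
    pos = np.array(pos[:n], dtype=float)
    jitter_scale = 0.1 * min(
        xs[1] - xs[0] if cols > 1 else W, ys[1] - ys[0] if rows > 1 else H
    )
    pos += rng.normal(0, max(jitter_scale, 1.0), size=pos.shape)

    theta = rng.uniform(0, math.pi, size=n)
    speed = rng.uniform(*cfg.init_speed_range, size=n)
    ang = rng.uniform(0, 2 * math.pi, size=n)
    vel = np.column_stack([speed * np.cos(ang), speed * np.sin(ang)])
    elong = np.zeros(n, dtype=bool)
    k = int(round(cfg.elongating_fraction * n))
    if k > 0:
        elong[rng.choice(n, size=k, replace=False)] = True

    state = np.column_stack([pos[:, 0], pos[:, 1], a0, b0, theta])
    _clamp_to_field(state, H, W)
    if cfg.repulsion_strength > 0 and n > 1:
        _resolve_overlaps(state, cfg, rng)

    tracks = np.zeros((n, cfg.n_frames, 5))
    tracks[:, 0, :] = state
    log_rate = math.log(cfg.elongation_rate)
    for t in range(1, cfg.n_frames):
        vel += rng.normal(0, cfg.sigma_acc, size=(n, 2)) if cfg.sigma_acc > 0 else 0.0
        state[:, 0] += vel[:, 0]
        state[:, 1] += vel[:, 1]
        # reflecting boundaries: keep the whole ellipse inside the field
        for c in range(n):
            a = state[c, 2]
            for d, lim in ((0, W), (1, H)):
                lo, hi = a, lim - 1 - a
                if state[c, d] < lo:
                    state[c, d] = 2 * lo - state[c, d]
                    vel[c, d] = -vel[c, d]
                elif state[c, d] > hi:
                    state[c, d] = 2 * hi - state[c, d]
                    vel[c, d] = -vel[c, d]
        # smooth shape change
        la = np.log(state[:, 2])
        lb = np.log(state[:, 3])
        if cfg.sigma_shape_sim > 0:
            d1 = rng.normal(0, cfg.sigma_shape_sim, size=n)
            d2 = rng.normal(0, cfg.sigma_shape_sim, size=n)
        else:
            d1 = d2 = np.zeros(n)
        # elongating cells: antisymmetric drift + deterministic growth keeps
        # the area pi*a*b exactly conserved
        la = np.where(elong, la + log_rate + d1, la + d1)
        lb = np.where(elong, lb - log_rate - d1, lb + d2)
        state[:, 2] = np.exp(la)
        state[:, 3] = np.exp(lb)
        swap = state[:, 3] > state[:, 2]
        if swap.any():
            tmp = state[swap, 2].copy()
            state[swap, 2] = state[swap, 3]
            state[swap, 3] = tmp
            state[swap, 4] = (state[swap, 4] + math.pi / 2) % math.pi
        if cfg.sigma_theta_sim > 0:
            state[:, 4] = (state[:, 4] + rng.normal(0, cfg.sigma_theta_sim, size=n)) % math.pi
        _clamp_to_field(state, H, W)
        if cfg.repulsion_strength > 0 and n > 1:
            _resolve_overlaps(state, cfg, rng)
        tracks[:, t, :] = state
    totals = np.full(n, cfg.junction_total_intensity, dtype=float)
    return GroundTruth(
        tracks=tracks, elongating=elong, junction_totals=totals, config=cfg
    )


def _interior_masks(gt: GroundTruth, frame: int):
    H, W = gt.config.field_size
    masks = []
    for c in range(gt.n_cells):
        e = gt.ellipse(c, frame)
        Y, X = np.mgrid[0:H, 0:W]
        masks.append(e.contains(X, Y))
    return masks


def render_phase_contrast(gt: GroundTruth, cfg: SimConfig | None = None) -> ImageStack:
    """Phase-contrast-like movie: dark bodies, bright 2-px halo, noise."""
    cfg = cfg or gt.config
    H, W = cfg.field_size
    rng = np.random.default_rng([cfg.seed, 17])
    Y, X = np.mgrid[0:H, 0:W]
    frames = np.empty((gt.n_frames, H, W), dtype=np.float32)
    for t in range(gt.n_frames):
        img = np.full((H, W), cfg.background, dtype=np.float64)
        interior_any = np.zeros((H, W), dtype=bool)
        halo_any = np.zeros((H, W), dtype=bool)
        for c in range(gt.n_cells):
            e = gt.ellipse(c, t)
            inside = e.contains(X, Y)
            outer = Ellipse(e.cx, e.cy, e.a + 2.0, e.b + 2.0, e.theta).contains(X, Y)
            interior_any |= inside
            halo_any |= outer & ~inside
        img[interior_any] = cfg.background - cfg.body_contrast
        img[halo_any & ~interior_any] = cfg.background + cfg.halo_amplitude
        if cfg.noise_sd > 0:
            img = img + rng.normal(0, cfg.noise_sd, size=(H, W))
        frames[t] = img.astype(np.float32)
    return ImageStack(
        data=frames,
        pixel_size_um=cfg.pixel_size_um,
        frame_interval_s=cfg.frame_interval_s,
    )


def render_junction_fluorescence(
    gt: GroundTruth, cfg: SimConfig | None = None, frame: int = 0
) -> JunctionRender:
    """Junction-fluorescence image of one frame plus per-cell ROI masks.

    Cell territories are the influence tessellation of the ellipses (each
    pixel belongs to the cell whose normalised elliptical distance is
    smallest).  Each cell's boundary ribbon carries the cell's total
    junction intensity spread uniformly over its ribbon pixels; emitted
    totals are recorded in ``gt.emitted_totals[frame]``.
    """
    cfg = cfg or gt.config
    if not (0 <= frame < gt.n_frames):
        raise InvalidInputError(f"frame {frame} outside 0..{gt.n_frames - 1}")
    H, W = cfg.field_size
    Y, X = np.mgrid[0:H, 0:W]
    best = np.full((H, W), np.inf)
    labels = np.zeros((H, W), dtype=np.int32)
    for c in range(gt.n_cells):
        e = gt.ellipse(c, frame)
        dx = X - e.cx
        dy = Y - e.cy
        co, si = math.cos(e.theta), math.sin(e.theta)
        u = (dx * co + dy * si) / e.a
        v = (-dx * si + dy * co) / e.b
        rho = u * u + v * v
        closer = rho < best
        best[closer] = rho[closer]
        labels[closer] = c
    image = np.zeros((H, W), dtype=np.float64)
    ribbons = {}
    lengths = {}
    outlines = {}
    cross = ndimage.generate_binary_structure(2, 1)
    for c in range(gt.n_cells):
        terr = labels == c
        if not terr.any():
            ribbons[c] = np.zeros((H, W), dtype=bool)
            lengths[c] = 0.0
            outlines[c] = np.empty((0, 2))
            continue
        eroded = ndimage.binary_erosion(terr, structure=cross, border_value=0)
        boundary = terr & ~eroded  # touches another territory or the field edge
        ribbon = ndimage.binary_dilation(boundary, structure=cross, iterations=1) & terr
        npx = int(ribbon.sum())
        if npx > 0:
            image[ribbon] += gt.junction_totals[c] / npx
        ribbons[c] = ribbon
        contours = measure.find_contours(terr.astype(float), 0.5)
        if contours:
            longest = max(contours, key=lambda q: len(q))
            seg = np.diff(longest, axis=0)
            lengths[c] = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
            outlines[c] = longest[:, ::-1]  # (row, col) -> (x, y)
        else:
            lengths[c] = 0.0
            outlines[c] = np.empty((0, 2))
    gt.emitted_totals[frame] = gt.junction_totals.copy()
    return JunctionRender(
        image=image,
        territories=labels,
        ribbons=ribbons,
        boundary_length_px=lengths,
        outlines=outlines,
    )
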
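"""Per-frame foreground/background segmentation of phase-contrast images.

The model is a binary Markov random field over the pixel grid:

    E(x) = w_u * sum_i u_i(x_i)
         + beta * sum_{(i,j) 4-neighbours} [x_i != x_j]
         + sum_c phi_c(k_c)

with unary energies u_i(1) = -f_i / 2, u_i(0) = +f_i / 2 built from a
per-pixel foreground log-likelihood ratio f_i, a pairwise Potts coupling,
and robust higher-order potentials over the regions ("cliques") of a seeded
oversegmentation.  The robust clique term is truncated-linear in the number
of minority-label pixels,

    phi_c(k) = min(gamma_max, gamma_max * min(k, n_c - k) / (q * n_c)),

so a clique may tolerate up to a fraction q of dissenting pixels before the
penalty saturates; this makes the model forgiving of oversegmentation
errors.

Phase-contrast optics map cell bodies to dark regions surrounded by a
bright halo; the unary feature scores the rectified, smoothed darkness
relative to the frame's background level so that bodies segment as
foreground while the halo walls between touching cells stay background.

``segment_frame`` returns per-pixel foreground probabilities: the Gibbs
marginals of the field at the configured temperature, estimated by a seeded
Rao-Blackwellised Gibbs sampler (the marginal estimate averages the exact
single-site conditional at every visit rather than the binary sample, which
makes the estimate exact in the factorised limit and low-variance
elsewhere).  All randomness is derived from ``MrfParams.seed``, so identical
inputs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit
from scipy.ndimage import gaussian_filter
from skimage.filters import sobel, threshold_otsu
from skimage.segmentation import watershed

from .exceptions import ComputationError, InvalidInputError

__all__ = [
    "Frame",
    "MrfParams",
    "ForegroundMap",
    "extract_unary_features",
    "unary_log_ratio",
    "build_cliques",
    "energy",
    "segment_frame",
    "binarize",
]


@dataclass(frozen=True)
class Frame:
    """One calibrated grayscale image of a movie.

    pixels : (H, W) non-negative intensities, arbitrary units.
    pixel_size : micrometres per pixel.
    time_index : 0-based frame number.
    """

    pixels: np.ndarray
    pixel_size: float = 1.0
    time_index: int = 0

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise InvalidInputError(f"frame must be at least 2x2, got shape {px.shape}")
        if not np.isfinite(px).all():
            raise InvalidInputError("frame intensities must be finite")
        if self.pixel_size <= 0:
            raise InvalidInputError("pixel_size must be > 0")
        if self.time_index < 0:
            raise InvalidInputError("time_index must be >= 0")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class MrfParams:
    """Weights and inference settings of the segmentation field.

    With beta = gamma_max = 0 the model factorises over pixels and the
    output equals the per-pixel logistic of the unary term exactly.
    """

    unary_scale: float = 1.0
    beta: float = 0.5
    gamma_max: float = 0.5
    truncation_q: float = 0.3
    n_cliques: int | None = None  # default: ~ one clique per 16x16 px block
    temperature: float = 1.0
    feature_radius: int = 4
    n_burn: int = 500
    n_sweeps: int = 4000
    seed: int = 0

    def __post_init__(self):
        if not all(
            np.isfinite(v) and v >= 0
            for v in (self.unary_scale, self.beta, self.gamma_max)
        ):
            raise InvalidInputError("unary_scale, beta, gamma_max must be finite and >= 0")
        if not (0 < self.truncation_q <= 0.5):
            raise InvalidInputError("truncation_q must lie in (0, 0.5]")
        if self.temperature <= 0:
            raise InvalidInputError("temperature must be > 0")
        if self.n_sweeps < 1 or self.n_burn < 0:
            raise InvalidInputError("need n_sweeps >= 1 and n_burn >= 0")
        if self.feature_radius < 1:
            raise InvalidInputError("feature_radius must be >= 1")


@dataclass(frozen=True)
class ForegroundMap:
    """Per-pixel foreground probabilities for one frame."""

    probs: np.ndarray
    frame: int = 0

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=np.float64)
        if p.ndim != 2:
            raise InvalidInputError("probability map must be 2-D")
        if not np.isfinite(p).all() or p.min() < 0 or p.max() > 1:
            raise InvalidInputError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "probs", p)

    @property
    def shape(self) -> tuple[int, int]:
        return self.probs.shape


def extract_unary_features(frame: Frame, radius: int) -> np.ndarray:
    """Per-pixel foreground score: higher = more cell-body-like.

    Phase-contrast optics render the cell body dark and surround it with a
    bright halo; the halo is the *wall* separating adjacent bodies in a
    confluent sheet, so it must not score as foreground or touching cells
    fuse into one blob.  The score is therefore the rectified smoothed
    darkness: max(0, median - intensity) / std, Gaussian-smoothed at
    radius / 2.  Normalising by the frame's intensity spread makes the
    score invariant under affine intensity rescaling, and the filter is
    translation-equivariant away from the image border.
    """
    if radius < 1:
        raise InvalidInputError("radius must be >= 1")
    H, W = frame.shape
    if H < 2 * radius + 1 or W < 2 * radius + 1:
        raise InvalidInputError(
            f"frame of shape {(H, W)} smaller than 2*radius+1 = {2 * radius + 1}"
        )
    img = frame.pixels
    sd = img.std()
    if sd == 0:
        return np.zeros_like(img)
    darkness = (np.median(img) - img) / sd
    smooth = gaussian_filter(darkness, radius / 2.0, mode="reflect")
    return np.clip(smooth, 0.0, None)


def unary_log_ratio(frame: Frame, radius: int = 4) -> np.ndarray:
    """Map the feature score to a two-class log-likelihood ratio.

    A two-component split of the per-frame feature distribution (Otsu
    threshold t, spread s) gives f = (score - t) / s; positive f favours
    foreground.  Constant frames yield f = 0 everywhere.
    """
    feat = extract_unary_features(frame, radius)
    if not np.isfinite(feat).all():
        bad = np.argwhere(~np.isfinite(feat))[0]
        raise ComputationError(
            f"non-finite feature value at pixel (row={bad[0]}, col={bad[1]})"
        )
    if feat.max() == feat.min():
        return np.zeros_like(feat)
    t = threshold_otsu(feat)
    s = feat.std()
    return (feat - t) / max(s, 1e-12)


def build_cliques(frame: Frame, n_cliques: int) -> np.ndarray:
    """Partition the pixel grid into connected cliques.

    Cliques are the catchment basins of a marker-controlled watershed on the
    gradient of the unary feature map, seeded from a regular grid, so each
    clique is a connected, roughly homogeneous region.  Returns an (H, W)
    integer label image with labels 0..K-1 covering every pixel.
    """
    H, W = frame.shape
    N = H * W
    if not (1 <= n_cliques <= N):
        raise InvalidInputError(f"n_cliques must lie in [1, {N}], got {n_cliques}")
    if n_cliques == 1:
        return np.zeros((H, W), dtype=np.int64)
    if n_cliques == N:
        return np.arange(N, dtype=np.int64).reshape(H, W)

    # relief: gradient of the lightly smoothed foreground feature; heavier
    # smoothing would displace basin boundaries away from texture edges
    if min(H, W) >= 3:
        relief = sobel(extract_unary_features(frame, 1))
    else:
        relief = sobel(frame.pixels)

    rows = max(1, int(round(np.sqrt(n_cliques * H / W))))
    cols = int(np.ceil(n_cliques / rows))
    seeds = []
    seen = set()
    for i in range(rows):
        for j in range(cols):
            if len(seeds) >= n_cliques:
                break
            y = min(H - 1, int((i + 0.5) * H / rows))
            x = min(W - 1, int((j + 0.5) * W / cols))
            if (y, x) not in seen:
                seen.add((y, x))
                seeds.append((y, x))
    markers = np.zeros((H, W), dtype=np.int64)
    for k, (y, x) in enumerate(seeds):
        markers[y, x] = k + 1
    labels = watershed(relief, markers) - 1
    return labels.astype(np.int64)


def _clique_phi(k: int, n: int, gamma: float, q: float) -> float:
    m = min(k, n - k)
    return min(gamma, gamma * m / (q * n))


def energy(
    labels: np.ndarray,
    frame: Frame,
    cliques: np.ndarray,
    params: MrfParams,
    llr: np.ndarray | None = None,
) -> float:
    """Total MRF energy of a binary labelling (lower = more probable)."""
    lab = np.asarray(labels)
    if lab.shape != frame.shape:
        raise InvalidInputError(
            f"label shape {lab.shape} does not match frame shape {frame.shape}"
        )
    lab = lab.astype(np.int64)
    if llr is None:
        llr = unary_log_ratio(frame, params.feature_radius)
    # u(1) = -f/2, u(0) = +f/2
    e_un = params.unary_scale * float(((0.5 - lab) * llr).sum())
    e_pair = params.beta * (
        float((lab[1:, :] != lab[:-1, :]).sum()) + float((lab[:, 1:] != lab[:, :-1]).sum())
    )
    e_cl = 0.0
    cl = np.asarray(cliques, dtype=np.int64).ravel()
    counts = np.bincount(cl, weights=lab.ravel())
    sizes = np.bincount(cl)
    for k, n in zip(counts, sizes):
        if n > 0:
            e_cl += _clique_phi(int(round(k)), int(n), params.gamma_max, params.truncation_q)
    return e_un + e_pair + e_cl


@njit(cache=True)
def _gibbs_kernel(llr, H, W, clique_id, cl_n, w_u, beta, gamma, q, T, n_burn, n_sweeps, seed):
    N = H * W
    np.random.seed(seed)
    x = np.zeros(N, dtype=np.int8)
    for p in range(N):
        pf = 1.0 / (1.0 + np.exp(-w_u * llr[p] / T))
        if np.random.random() < pf:
            x[p] = 1
    K = cl_n.shape[0]
    cl_k = np.zeros(K, dtype=np.int64)
    for p in range(N):
        if x[p] == 1:
            cl_k[clique_id[p]] += 1
    acc = np.zeros(N, dtype=np.float64)
    for it in range(n_burn + n_sweeps):
        for p in range(N):
            i = p // W
            j = p - i * W
            s = 0.0
            if i > 0:
                s += 2.0 * x[p - W] - 1.0
            if i < H - 1:
                s += 2.0 * x[p + W] - 1.0
            if j > 0:
                s += 2.0 * x[p - 1] - 1.0
            if j < W - 1:
                s += 2.0 * x[p + 1] - 1.0
            dE = w_u * llr[p] + beta * s
            ci = clique_id[p]
            if gamma > 0.0:
                n = cl_n[ci]
                km = cl_k[ci] - x[p]
                m0 = km if km <= n - km else n - km
                v0 = gamma * m0 / (q * n)
                if v0 > gamma:
                    v0 = gamma
                k1 = km + 1
                m1 = k1 if k1 <= n - k1 else n - k1
                v1 = gamma * m1 / (q * n)
                if v1 > gamma:
                    v1 = gamma
                dE += v0 - v1
            pf = 1.0 / (1.0 + np.exp(-dE / T))
            if it >= n_burn:
                acc[p] += pf
            new = 1 if np.random.random() < pf else 0
            if new != x[p]:
                cl_k[ci] += new - x[p]
                x[p] = new
    return acc / n_sweeps


def _default_n_cliques(H: int, W: int) -> int:
    return max(1, (H * W) // 256)


def segment_frame(frame: Frame, params: MrfParams = MrfParams()) -> ForegroundMap:
    """Foreground probabilities for one frame: Gibbs marginals of the MRF.

    Deterministic for fixed inputs (the sampler seed is derived from
    ``params.seed`` and the frame's time index).  With
    beta = gamma_max = 0 the result equals sigma(unary_scale * f / T)
    per pixel, exactly.
    """
    H, W = frame.shape
    llr = unary_log_ratio(frame, params.feature_radius)
    n_cliques = params.n_cliques if params.n_cliques is not None else _default_n_cliques(H, W)
    cliques = build_cliques(frame, n_cliques)
    cl = cliques.ravel()
    cl_n = np.bincount(cl).astype(np.int64)
    seed = int((params.seed * 1000003 + frame.time_index) % (2**31 - 1))
    probs = _gibbs_kernel(
        llr.ravel().astype(np.float64),
        H,
        W,
        cl.astype(np.int64),
        cl_n,
        float(params.unary_scale),
        float(params.beta),
        float(params.gamma_max),
        float(params.truncation_q),
        float(params.temperature),
        int(params.n_burn),
        int(params.n_sweeps),
        seed,
    )
    probs = np.clip(probs.reshape(H, W), 0.0, 1.0)
    return ForegroundMap(probs=probs, frame=frame.time_index)


def segment_stack(frames: list[Frame], params: MrfParams = MrfParams()) -> list[ForegroundMap]:
    """Apply ``segment_frame`` to every frame of a movie independently."""
    return [segment_frame(f, params) for f in frames]


def binarize(fmap: ForegroundMap, tau: float = 0.5) -> np.ndarray:
    """Threshold a probability map: mask[p] = probs[p] >= tau."""
    if not (0 < tau < 1):
        raise InvalidInputError(f"tau must lie in (0, 1), got {tau}")
    return fmap.probs >= tau
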
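"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — literal re-summation, exhaustive
enumeration, dense sampling — and shares no code with the implementation
paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# MRF


def mrf_energy_resum(labels, llr, clique_labels, unary_scale, beta, gamma, q, include_unary=True):
    """Literal term-by-term re-summation of the three MRF energy terms."""
    lab = np.asarray(labels).astype(int)
    H, W = lab.shape
    e = 0.0
    if include_unary:
        for i in range(H):
            for j in range(W):
                e += unary_scale * (0.5 - lab[i, j]) * llr[i, j]
    for i in range(H):
        for j in range(W):
            if i + 1 < H and lab[i, j] != lab[i + 1, j]:
                e += beta
            if j + 1 < W and lab[i, j] != lab[i, j + 1]:
                e += beta
    cl = np.asarray(clique_labels)
    for c in np.unique(cl):
        members = lab[cl == c]
        n = members.size
        k = int(members.sum())
        m = min(k, n - k)
        e += min(gamma, gamma * m / (q * n))
    return e


def gibbs_marginals_enumerated(llr, clique_labels, unary_scale, beta, gamma, q, temperature):
    """Exact Gibbs marginals of the binary MRF by exhaustive enumeration
    (Boltzmann weighting of all 2^(H*W) labelings).  Feasible up to ~4x4."""
    H, W = llr.shape
    N = H * W
    assert N <= 16, "enumeration oracle limited to 16 pixels"
    labs = ((np.arange(2**N)[:, None] >> np.arange(N)) & 1).astype(np.int8)
    llr_f = llr.ravel()
    E = unary_scale * ((0.5 - labs) * llr_f[None, :]).sum(axis=1)
    idx = np.arange(N).reshape(H, W)
    for i in range(H):
        for j in range(W):
            if i + 1 < H:
                E = E + beta * (labs[:, idx[i, j]] != labs[:, idx[i + 1, j]])
            if j + 1 < W:
                E = E + beta * (labs[:, idx[i, j]] != labs[:, idx[i, j + 1]])
    cl = np.asarray(clique_labels).ravel()
    for c in np.unique(cl):
        members = np.nonzero(cl == c)[0]
        n = len(members)
        k = labs[:, members].sum(axis=1)
        m = np.minimum(k, n - k)
        E = E + np.minimum(gamma, gamma * m / (q * n))
    w = np.exp(-(E - E.min()) / temperature)
    w = w / w.sum()
    return (w[:, None] * labs).sum(axis=0).reshape(H, W)


# ---------------------------------------------------------------------------
# ellipse rasterisation (independent of phasetrack._geometry)


def ellipse_pixels_bruteforce(cx, cy, a, b, theta, shape=None):
    """Integer pixel centres inside an ellipse by scanning a loose box."""
    pts = set()
    r = int(math.ceil(a)) + 2
    for y in range(int(math.floor(cy)) - r, int(math.ceil(cy)) + r + 1):
        for x in range(int(math.floor(cx)) - r, int(math.ceil(cx)) + r + 1):
            dx, dy = x - cx, y - cy
            u = (dx * math.cos(theta) + dy * math.sin(theta)) / a
            v = (-dx * math.sin(theta) + dy * math.cos(theta)) / b
            if u * u + v * v <= 1.0:
                if shape is not None:
                    H, W = shape
                    if not (0 <= x < W and 0 <= y < H):
                        continue
                pts.add((x, y))
    return pts


def ellipse_support_bruteforce(ellipse, probs):
    """Mean interior probability with out-of-image pixels counting zero."""
    H, W = probs.shape
    all_pts = ellipse_pixels_bruteforce(ellipse.cx, ellipse.cy, ellipse.a, ellipse.b, ellipse.theta)
    if not all_pts:
        return 0.0
    total = sum(probs[y, x] for (x, y) in all_pts if 0 <= x < W and 0 <= y < H)
    return total / len(all_pts)


def ellipse_coverage_bruteforce(ellipse, probs, tau):
    H, W = probs.shape
    all_pts = ellipse_pixels_bruteforce(ellipse.cx, ellipse.cy, ellipse.a, ellipse.b, ellipse.theta)
    if not all_pts:
        return 0.0
    ok = sum(
        1
        for (x, y) in all_pts
        if 0 <= x < W and 0 <= y < H and probs[y, x] >= tau
    )
    return ok / len(all_pts)


def ellipse_overlap_bruteforce(e1, e2):
    p1 = ellipse_pixels_bruteforce(e1.cx, e1.cy, e1.a, e1.b, e1.theta)
    p2 = ellipse_pixels_bruteforce(e2.cx, e2.cy, e2.a, e2.b, e2.theta)
    return len(p1 & p2)


# ---------------------------------------------------------------------------
# trajectory collections: exhaustive enumeration


def enumerate_trajectories(hyps):
    """All temporally contiguous hypothesis sequences (one per frame)."""
    by_frame = {}
    for h in hyps:
        by_frame.setdefault(h.frame, []).append(h.id)
    frames = sorted(by_frame)
    trajs = []
    for i, f0 in enumerate(frames):
        # require contiguity of the chosen frame window
        for j in range(i, len(frames)):
            window = frames[i : j + 1]
            if window != list(range(f0, f0 + len(window))):
                break
            for combo in itertools.product(*(by_frame[f] for f in window)):
                trajs.append((f0, combo))
    return trajs


def enumerate_collections(hyps):
    """All sets of hypothesis-disjoint trajectories (including empty)."""
    trajs = enumerate_trajectories(hyps)
    out = []

    def rec(start, used, current):
        out.append(list(current))
        for k in range(start, len(trajs)):
            ids = set(trajs[k][1])
            if ids & used:
                continue
            current.append(trajs[k])
            rec(k + 1, used | ids, current)
            current.pop()

    rec(0, frozenset(), [])
    return out


def map_collection(hyps, mm, prior, score_fn):
    """Exhaustive MAP: argmax of score_fn over all collections.

    score_fn maps a list of (t0, hyp_id_tuple) pairs to a log score;
    returns (best_collection, sorted_scores_descending).
    """
    colls = enumerate_collections(hyps)
    scored = []
    for c in colls:
        scored.append((score_fn(c), tuple(sorted(c))))
    scored.sort(key=lambda x: (-x[0], x[1]))
    return scored[0][1], [s for s, _ in scored]


# ---------------------------------------------------------------------------
# misc


def flood_fill_components_8(mask):
    """Connected components under 8-connectivity by literal flood fill."""
    mask = np.asarray(mask, dtype=bool)
    H, W = mask.shape
    seen = np.zeros_like(mask)
    comps = []
    for i in range(H):
        for j in range(W):
            if mask[i, j] and not seen[i, j]:
                stack = [(i, j)]
                seen[i, j] = True
                comp = []
                while stack:
                    y, x = stack.pop()
                    comp.append((y, x))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if 0 <= yy < H and 0 <= xx < W and mask[yy, xx] and not seen[yy, xx]:
                                seen[yy, xx] = True
                                stack.append((yy, xx))
                comps.append(comp)
    return comps


def ellipse_arc_pole_fraction(a, b, theta_half, n=200000):
    """Fraction of an ellipse boundary's arc length whose outward direction
    from the centre lies within +/- theta_half of the major axis, by dense
    parametric sampling."""
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x = a * np.cos(t)
    y = b * np.sin(t)
    dx = -a * np.sin(t)
    dy = b * np.cos(t)
    ds = np.sqrt(dx * dx + dy * dy)
    phi = np.arctan2(y, x)
    d = np.abs((phi + np.pi / 2) % np.pi - np.pi / 2)
    pole = d <= theta_half
    return float(ds[pole].sum() / ds.sum())
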
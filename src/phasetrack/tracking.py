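"""Joint probabilistic model over collections of interacting trajectories.

A trajectory is a temporally contiguous sequence of blob hypotheses, one
per frame; it may start and end at any time.  A single trajectory is a
Markov chain combining a constant-velocity motion model with smooth shape
change (Gaussian increments of log-axes, wrapped-Gaussian increments of
orientation).  A collection of trajectories is scored jointly: each
trajectory contributes its chain score plus start/end penalties and a
per-hypothesis coverage reward, and same-frame interior overlap between
trajectories is penalised (or forbidden outright), encoding the assumption
that cells of a confluent monolayer do not overlap.

Inference follows the sample-then-decide pattern: a Metropolis-Hastings
sampler with reversible structural moves (birth, death, extend, truncate,
switch) explores collections, and the final tracking is the Bayes-risk
decision under a symmetric per-link/per-inclusion 0-1 loss, i.e. every
link and every inclusion whose posterior marginal frequency exceeds 1/2 is
retained and assembled into contiguous trajectories.

The user-facing surface is statsmodels-like: build a
:class:`TrajectoryModel` from the hypotheses, call :meth:`fit`, and read
estimates and diagnostics off the returned :class:`TrackingResults`.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._geometry import Ellipse, ellipse_overlap_area
from .blobs import BlobHypothesis
from .exceptions import (
    InvalidCollectionError,
    InvalidInputError,
    InvalidReferenceError,
)

__all__ = [
    "MotionModel",
    "CollectionPrior",
    "Trajectory",
    "TrackCollection",
    "PosteriorSample",
    "transition_log_prob",
    "trajectory_log_score",
    "collection_log_score",
    "propose_move",
    "sample_posterior",
    "bayes_decision",
    "average_tracked_cells",
    "TrajectoryModel",
    "TrackingResults",
]

_LOG_2PI = math.log(2.0 * math.pi)

#: proposal mixture weights of the structural moves
MOVE_WEIGHTS = {"birth": 0.20, "death": 0.20, "extend": 0.25, "truncate": 0.15, "switch": 0.20}

#: inflation of sigma_pos for the first transition of a trajectory, which is
#: scored with zero prior velocity (constant velocity needs two points)
FIRST_STEP_SIGMA_FACTOR = 2.0


@dataclass(frozen=True)
class MotionModel:
    """Per-frame deviation scales of the trajectory Markov chain.

    sigma_pos : px, s.d. of the centre deviation from the constant-velocity
        prediction; sigma_shape : s.d. of the per-frame change of log a and
        log b; sigma_theta : rad, s.d. of the per-frame orientation change.
    """

    sigma_pos: float = 2.0
    sigma_shape: float = 0.05
    sigma_theta: float = 0.15

    def __post_init__(self):
        if not all(v > 0 for v in (self.sigma_pos, self.sigma_shape, self.sigma_theta)):
            raise InvalidInputError("motion-model deviations must be > 0")


@dataclass(frozen=True)
class CollectionPrior:
    """Structural prior of a trajectory collection.

    log_birth/log_death <= 0 penalise trajectory starts/ends,
    log_coverage >= 0 rewards every assigned hypothesis, and kappa_overlap
    >= 0 penalises each px^2 of same-frame interior overlap between
    trajectories (math.inf = hard non-overlap).
    """

    log_birth: float = -4.0
    log_death: float = -1.0
    log_coverage: float = 2.0
    kappa_overlap: float = 0.01

    def __post_init__(self):
        if self.log_birth > 0 or self.log_death > 0:
            raise InvalidInputError("log_birth and log_death must be <= 0")
        if self.log_coverage < 0:
            raise InvalidInputError("log_coverage must be >= 0")
        if self.kappa_overlap < 0:
            raise InvalidInputError("kappa_overlap must be >= 0 (inf allowed)")


@dataclass(frozen=True)
class Trajectory:
    """Ordered hypothesis ids over strictly consecutive frames t0, t0+1, ..."""

    t0: int
    hyp_ids: tuple[int, ...]

    def __post_init__(self):
        if len(self.hyp_ids) < 1:
            raise InvalidInputError("a trajectory has at least one element")
        object.__setattr__(self, "hyp_ids", tuple(self.hyp_ids))

    def __len__(self) -> int:
        return len(self.hyp_ids)

    @property
    def t1(self) -> int:
        return self.t0 + len(self.hyp_ids) - 1

    @property
    def elements(self) -> tuple[tuple[int, int], ...]:
        return tuple((self.t0 + i, h) for i, h in enumerate(self.hyp_ids))

    def alive(self, frame: int) -> bool:
        return self.t0 <= frame <= self.t1

    def at(self, frame: int) -> int:
        return self.hyp_ids[frame - self.t0]


@dataclass(frozen=True)
class TrackCollection:
    """A set of trajectories with injective hypothesis assignment."""

    trajectories: tuple[Trajectory, ...] = ()
    log_score: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "trajectories", tuple(self.trajectories))

    def __len__(self) -> int:
        return len(self.trajectories)

    def assigned_ids(self) -> list[int]:
        out = []
        for t in self.trajectories:
            out.extend(t.hyp_ids)
        return out


@dataclass(frozen=True)
class PosteriorSample:
    collection: TrackCollection
    iteration: int
    accepted: bool


# ---------------------------------------------------------------------------
# scoring


def _wrapped_normal_logpdf(delta: float, sigma: float) -> float:
    """Log density of a wrapped normal on the half-circle [0, pi)
    (orientations are pi-periodic)."""
    d = (delta + np.pi / 2) % np.pi - np.pi / 2
    dens = 0.0
    for k in (-3, -2, -1, 0, 1, 2, 3):
        z = d + k * np.pi
        dens += math.exp(-0.5 * (z / sigma) ** 2)
    dens /= sigma * math.sqrt(2.0 * math.pi)
    return math.log(dens)


def transition_log_prob(
    prev: tuple,
    nxt: Ellipse,
    mm: MotionModel,
    sigma_pos: float | None = None,
) -> float:
    """Log density of one trajectory step.

    `prev` is ((x, y), (vx, vy), (log a, log b), theta).  The step density
    is the product of an isotropic 2-D Gaussian on the deviation of the next
    centre from the constant-velocity prediction, Gaussians on the log-axis
    increments, and a wrapped Gaussian on the orientation increment.
    """
    (px, py), (vx, vy), (la, lb), th = prev
    sp = mm.sigma_pos if sigma_pos is None else sigma_pos
    dx = nxt.cx - (px + vx)
    dy = nxt.cy - (py + vy)
    lp = -_LOG_2PI - 2.0 * math.log(sp) - 0.5 * (dx * dx + dy * dy) / (sp * sp)
    for d in (math.log(nxt.a) - la, math.log(nxt.b) - lb):
        lp += (
            -0.5 * _LOG_2PI
            - math.log(mm.sigma_shape)
            - 0.5 * (d / mm.sigma_shape) ** 2
        )
    lp += _wrapped_normal_logpdf(nxt.theta - th, mm.sigma_theta)
    return lp


def _resolve(traj: Trajectory, hyps_by_id: dict[int, BlobHypothesis]) -> list[BlobHypothesis]:
    out = []
    for h in traj.hyp_ids:
        if h not in hyps_by_id:
            raise InvalidReferenceError(f"trajectory references unknown hypothesis id {h}")
        out.append(hyps_by_id[h])
    return out


def trajectory_log_score(
    traj: Trajectory,
    hyps_by_id: dict[int, BlobHypothesis],
    mm: MotionModel,
    prior: CollectionPrior,
) -> float:
    """Chain score of one trajectory: start/end penalties, per-element
    support + coverage rewards, and the motion/shape transition densities
    (first transition with zero prior velocity and inflated sigma_pos)."""
    hs = _resolve(traj, hyps_by_id)
    score = prior.log_birth + prior.log_death
    for h in hs:
        score += math.log(max(h.support, 1e-300)) + prior.log_coverage
    for i in range(len(hs) - 1):
        e = hs[i].ellipse
        if i == 0:
            vel = (0.0, 0.0)
            sp = mm.sigma_pos * FIRST_STEP_SIGMA_FACTOR
        else:
            ep = hs[i - 1].ellipse
            vel = (e.cx - ep.cx, e.cy - ep.cy)
            sp = None
        prev = ((e.cx, e.cy), vel, (math.log(e.a), math.log(e.b)), e.theta)
        score += transition_log_prob(prev, hs[i + 1].ellipse, mm, sigma_pos=sp)
    return score


def _frame_overlap_penalty(
    coll: TrackCollection,
    hyps_by_id: dict[int, BlobHypothesis],
    kappa: float,
) -> float:
    """Sum over frames of pairwise interior overlap, weighted by kappa;
    returns inf for any positive overlap when kappa is inf."""
    by_frame: dict[int, list[Ellipse]] = {}
    for t in coll.trajectories:
        for f, h in t.elements:
            by_frame.setdefault(f, []).append(hyps_by_id[h].ellipse)
    total = 0.0
    for es in by_frame.values():
        for i in range(len(es)):
            for j in range(i + 1, len(es)):
                e1, e2 = es[i], es[j]
                if (e1.cx - e2.cx) ** 2 + (e1.cy - e2.cy) ** 2 > (e1.a + e2.a) ** 2:
                    continue
                area = ellipse_overlap_area(e1, e2)
                if area > 0:
                    if math.isinf(kappa):
                        return math.inf
                    total += kappa * area
    return total


def collection_log_score(
    coll: TrackCollection,
    hyps_by_id: dict[int, BlobHypothesis],
    mm: MotionModel,
    prior: CollectionPrior,
) -> float:
    """Joint log score: sum of trajectory scores minus overlap penalties
    (-inf under hard non-overlap with any same-frame overlap)."""
    ids = coll.assigned_ids()
    if len(ids) != len(set(ids)):
        raise InvalidCollectionError("a hypothesis id is used by more than one trajectory")
    score = 0.0
    for t in coll.trajectories:
        score += trajectory_log_score(t, hyps_by_id, mm, prior)
    pen = _frame_overlap_penalty(coll, hyps_by_id, prior.kappa_overlap)
    if math.isinf(pen):
        return -math.inf
    return score - pen


# ---------------------------------------------------------------------------
# sampler state with incremental bookkeeping


class _SamplerState:
    """Mutable collection state with cached scores and O(local) move deltas."""

    def __init__(self, hyps, mm, prior, link_gate_px=25.0):
        self.mm = mm
        self.prior = prior
        self.hyps_by_id = {h.id: h for h in hyps}
        if len(self.hyps_by_id) != len(hyps):
            raise InvalidInputError("hypothesis ids must be unique")
        self.by_frame: dict[int, list[int]] = {}
        for h in hyps:
            self.by_frame.setdefault(h.frame, []).append(h.id)
        self.frames = sorted(self.by_frame)
        self.f_min = self.frames[0] if self.frames else 0
        self.f_max = self.frames[-1] if self.frames else -1
        gate2 = link_gate_px * link_gate_px
        self.cand_fwd: dict[int, list[int]] = {}
        self.cand_bwd: dict[int, list[int]] = {}
        for h in hyps:
            fwd = []
            for j in self.by_frame.get(h.frame + 1, ()):
                hj = self.hyps_by_id[j]
                d2 = (h.ellipse.cx - hj.ellipse.cx) ** 2 + (h.ellipse.cy - hj.ellipse.cy) ** 2
                if d2 <= gate2:
                    fwd.append(j)
            self.cand_fwd[h.id] = fwd
            bwd = []
            for j in self.by_frame.get(h.frame - 1, ()):
                hj = self.hyps_by_id[j]
                d2 = (h.ellipse.cx - hj.ellipse.cx) ** 2 + (h.ellipse.cy - hj.ellipse.cy) ** 2
                if d2 <= gate2:
                    bwd.append(j)
            self.cand_bwd[h.id] = bwd
        # same-frame overlap partners
        self.partners: dict[int, list[tuple[int, float]]] = {h.id: [] for h in hyps}
        for f, ids in self.by_frame.items():
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    e1 = self.hyps_by_id[ids[i]].ellipse
                    e2 = self.hyps_by_id[ids[j]].ellipse
                    if (e1.cx - e2.cx) ** 2 + (e1.cy - e2.cy) ** 2 > (e1.a + e2.a) ** 2:
                        continue
                    area = ellipse_overlap_area(e1, e2)
                    if area > 0:
                        self.partners[ids[i]].append((ids[j], area))
                        self.partners[ids[j]].append((ids[i], area))
        # dynamic state
        self.trajs: dict[int, Trajectory] = {}
        self.traj_score: dict[int, float] = {}
        self.assigned: dict[int, int] = {}  # hyp id -> traj id
        self.unassigned: list[int] = [h.id for h in hyps]
        self.un_pos: dict[int, int] = {h: i for i, h in enumerate(self.unassigned)}
        self.next_tid = 0
        self.total = 0.0
        self.overlap_pen = 0.0

    # -- bookkeeping helpers

    def _take_unassigned(self, hid: int):
        i = self.un_pos.pop(hid)
        last = self.unassigned.pop()
        if last != hid:
            self.unassigned[i] = last
            self.un_pos[last] = i

    def _put_unassigned(self, hid: int):
        self.un_pos[hid] = len(self.unassigned)
        self.unassigned.append(hid)

    def _overlap_delta_add(self, hid: int) -> float:
        """Penalty increase from assigning hid (inf under hard exclusion)."""
        kappa = self.prior.kappa_overlap
        d = 0.0
        for other, area in self.partners[hid]:
            if other in self.assigned:
                if math.isinf(kappa):
                    return math.inf
                d += kappa * area
        return d

    def n_singletons(self) -> int:
        return sum(1 for t in self.trajs.values() if len(t) == 1)

    def n_multis(self) -> int:
        return sum(1 for t in self.trajs.values() if len(t) >= 2)

    def score_of(self, traj: Trajectory) -> float:
        return trajectory_log_score(traj, self.hyps_by_id, self.mm, self.prior)

    def set_collection(self, coll: TrackCollection):
        """Reset the state to an explicit collection."""
        for tid in list(self.trajs):
            self._remove_traj(tid)
        for t in coll.trajectories:
            self._insert_traj(t)

    def _insert_traj(self, traj: Trajectory):
        tid = self.next_tid
        self.next_tid += 1
        for h in traj.hyp_ids:
            self.overlap_pen += self._overlap_delta_add(h)
            self._take_unassigned(h)
            self.assigned[h] = tid
        s = self.score_of(traj)
        self.trajs[tid] = traj
        self.traj_score[tid] = s
        self.total += s
        return tid

    def _remove_traj(self, tid: int):
        traj = self.trajs.pop(tid)
        self.total -= self.traj_score.pop(tid)
        for h in traj.hyp_ids:
            del self.assigned[h]
            self._put_unassigned(h)
        # subtract released overlap
        kappa = self.prior.kappa_overlap
        if not math.isinf(kappa):
            for h in traj.hyp_ids:
                for other, area in self.partners[h]:
                    if other in self.assigned:
                        self.overlap_pen -= kappa * area
        return traj

    def collection(self) -> TrackCollection:
        return TrackCollection(
            trajectories=tuple(self.trajs.values()),
            log_score=self.total - self.overlap_pen,
        )

    # -- moves: each returns (delta_log_target, log_q_ratio, apply) or None

    def propose(self, kind: str, rng: np.random.Generator):
        if kind == "birth":
            return self._propose_birth(rng)
        if kind == "death":
            return self._propose_death(rng)
        if kind == "extend":
            return self._propose_extend(rng)
        if kind == "truncate":
            return self._propose_truncate(rng)
        if kind == "switch":
            return self._propose_switch(rng)
        raise InvalidInputError(f"unknown move kind {kind!r}")

    def _propose_birth(self, rng):
        U = len(self.unassigned)
        if U == 0:
            return None
        hid = self.unassigned[rng.integers(U)]
        traj = Trajectory(t0=self.hyps_by_id[hid].frame, hyp_ids=(hid,))
        ds = self.score_of(traj)
        od = self._overlap_delta_add(hid)
        if math.isinf(od):
            delta = -math.inf
        else:
            delta = ds - od
        S_after = self.n_singletons() + 1
        log_q = (
            math.log(MOVE_WEIGHTS["death"] / S_after)
            - math.log(MOVE_WEIGHTS["birth"] / U)
        )

        def apply():
            self._insert_traj(traj)

        return delta, log_q, apply

    def _propose_death(self, rng):
        singles = [tid for tid, t in self.trajs.items() if len(t) == 1]
        if not singles:
            return None
        tid = singles[rng.integers(len(singles))]
        hid = self.trajs[tid].hyp_ids[0]
        kappa = self.prior.kappa_overlap
        od = 0.0
        if not math.isinf(kappa):
            for other, area in self.partners[hid]:
                if other in self.assigned and other != hid:
                    od += kappa * area
        delta = -self.traj_score[tid] + od
        U_after = len(self.unassigned) + 1
        log_q = (
            math.log(MOVE_WEIGHTS["birth"] / U_after)
            - math.log(MOVE_WEIGHTS["death"] / len(singles))
        )

        def apply():
            self._remove_traj(tid)

        return delta, log_q, apply

    def _unassigned_candidates(self, hid: int, forward: bool, extra: int | None = None):
        cands = self.cand_fwd[hid] if forward else self.cand_bwd[hid]
        return [c for c in cands if c not in self.assigned or c == extra]

    def _propose_extend(self, rng):
        T = len(self.trajs)
        if T == 0:
            return None
        tids = list(self.trajs)
        tid = tids[rng.integers(T)]
        traj = self.trajs[tid]
        tail = bool(rng.integers(2))
        end_hid = traj.hyp_ids[-1] if tail else traj.hyp_ids[0]
        cands = self._unassigned_candidates(end_hid, forward=tail)
        if not cands:
            return None
        new_hid = cands[rng.integers(len(cands))]
        if tail:
            new_traj = Trajectory(traj.t0, traj.hyp_ids + (new_hid,))
        else:
            new_traj = Trajectory(traj.t0 - 1, (new_hid,) + traj.hyp_ids)
        od = self._overlap_delta_add(new_hid)
        if math.isinf(od):
            delta = -math.inf
            new_score = None
        else:
            new_score = self.score_of(new_traj)
            delta = new_score - self.traj_score[tid] - od
        T2_after = self.n_multis() + (1 if len(traj) == 1 else 0)
        log_q = (
            math.log(MOVE_WEIGHTS["truncate"] / (T2_after * 2))
            - math.log(MOVE_WEIGHTS["extend"] / (T * 2 * len(cands)))
        )

        def apply():
            self.overlap_pen += od
            self._take_unassigned(new_hid)
            self.assigned[new_hid] = tid
            self.trajs[tid] = new_traj
            self.total += new_score - self.traj_score[tid]
            self.traj_score[tid] = new_score

        return delta, log_q, apply

    def _propose_truncate(self, rng):
        multis = [tid for tid, t in self.trajs.items() if len(t) >= 2]
        if not multis:
            return None
        tid = multis[rng.integers(len(multis))]
        traj = self.trajs[tid]
        tail = bool(rng.integers(2))
        if tail:
            removed = traj.hyp_ids[-1]
            new_traj = Trajectory(traj.t0, traj.hyp_ids[:-1])
            anchor = new_traj.hyp_ids[-1]
        else:
            removed = traj.hyp_ids[0]
            new_traj = Trajectory(traj.t0 + 1, traj.hyp_ids[1:])
            anchor = new_traj.hyp_ids[0]
        kappa = self.prior.kappa_overlap
        od = 0.0
        if not math.isinf(kappa):
            for other, area in self.partners[removed]:
                if other in self.assigned and other != removed:
                    od += kappa * area
        new_score = self.score_of(new_traj)
        delta = new_score - self.traj_score[tid] + od
        # reverse: extend picks this trajectory, same end, then `removed`
        # among the then-available candidates
        cands_rev = self._unassigned_candidates(anchor, forward=tail, extra=removed)
        T_after = len(self.trajs)  # truncation never deletes a trajectory
        log_q = (
            math.log(MOVE_WEIGHTS["extend"] / (T_after * 2 * len(cands_rev)))
            - math.log(MOVE_WEIGHTS["truncate"] / (len(multis) * 2))
        )

        def apply():
            self.overlap_pen -= od
            del self.assigned[removed]
            self._put_unassigned(removed)
            self.trajs[tid] = new_traj
            self.total += new_score - self.traj_score[tid]
            self.traj_score[tid] = new_score

        return delta, log_q, apply

    def _propose_switch(self, rng):
        if self.f_max <= self.f_min or len(self.trajs) < 2:
            return None
        t = int(self.f_min + rng.integers(self.f_max - self.f_min))
        alive = [tid for tid, tr in self.trajs.items() if tr.alive(t) and tr.alive(t + 1)]
        if len(alive) < 2:
            return None
        i, j = rng.choice(len(alive), size=2, replace=False)
        tid1, tid2 = alive[int(i)], alive[int(j)]
        tr1, tr2 = self.trajs[tid1], self.trajs[tid2]
        cut1 = t - tr1.t0 + 1
        cut2 = t - tr2.t0 + 1
        new1 = Trajectory(tr1.t0, tr1.hyp_ids[:cut1] + tr2.hyp_ids[cut2:])
        new2 = Trajectory(tr2.t0, tr2.hyp_ids[:cut2] + tr1.hyp_ids[cut1:])
        s1 = self.score_of(new1)
        s2 = self.score_of(new2)
        delta = s1 + s2 - self.traj_score[tid1] - self.traj_score[tid2]
        # the set of trajectories alive at (t, t+1) is invariant under the
        # swap, so the proposal is symmetric
        log_q = 0.0

        def apply():
            for tid, tr, s in ((tid1, new1, s1), (tid2, new2, s2)):
                for h in tr.hyp_ids:
                    self.assigned[h] = tid
                self.total += s - self.traj_score[tid]
                self.trajs[tid] = tr
                self.traj_score[tid] = s

        return delta, log_q, apply


# ---------------------------------------------------------------------------
# functional surface


def propose_move(
    coll: TrackCollection,
    hyps: list[BlobHypothesis],
    kind: str,
    rng_seed: int,
    mm: MotionModel | None = None,
    prior: CollectionPrior | None = None,
):
    """Propose one structural move from an explicit collection.

    Returns (candidate_collection, log_proposal_ratio, applicable); an
    inapplicable kind is reported as a no-op with applicable = False.
    """
    mm = mm or MotionModel()
    prior = prior or CollectionPrior()
    state = _SamplerState(hyps, mm, prior)
    state.set_collection(coll)
    rng = np.random.default_rng(rng_seed)
    prop = state.propose(kind, rng)
    if prop is None:
        return coll, 0.0, False
    _, log_q, apply = prop
    apply()
    return state.collection(), log_q, True


def sample_posterior(
    hyps: list[BlobHypothesis],
    mm: MotionModel,
    prior: CollectionPrior,
    n_iter: int,
    seed: int,
    init: TrackCollection | None = None,
    thin: int = 1,
    link_gate_px: float = 25.0,
) -> list[PosteriorSample]:
    """Metropolis-Hastings sampling of trajectory collections.

    Records the state every `thin` iterations (always including the final
    one); reproducible given the seed.
    """
    if n_iter < 1:
        raise InvalidInputError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    state = _SamplerState(hyps, mm, prior, link_gate_px=link_gate_px)
    if init is not None:
        state.set_collection(init)
    kinds = list(MOVE_WEIGHTS)
    weights = np.array([MOVE_WEIGHTS[k] for k in kinds])
    weights = weights / weights.sum()
    samples: list[PosteriorSample] = []
    for it in range(n_iter):
        kind = kinds[rng.choice(len(kinds), p=weights)]
        prop = state.propose(kind, rng)
        accepted = False
        if prop is not None:
            delta, log_q, apply = prop
            log_alpha = delta + log_q
            if log_alpha >= 0 or math.log(rng.random()) < log_alpha:
                apply()
                accepted = True
        if it % thin == 0 or it == n_iter - 1:
            samples.append(
                PosteriorSample(collection=state.collection(), iteration=it, accepted=accepted)
            )
    return samples


def bayes_decision(
    samples: list[PosteriorSample],
    burn_in: float = 0.3,
    hyps: list[BlobHypothesis] | None = None,
    mm: MotionModel | None = None,
    prior: CollectionPrior | None = None,
) -> TrackCollection:
    """Bayes-risk decision under symmetric per-link / per-inclusion 0-1 loss.

    Links (hypothesis -> next-frame hypothesis) and inclusions with
    posterior marginal frequency > 1/2 over the post-burn-in samples are
    retained and assembled greedily by descending frequency into contiguous
    trajectories.
    """
    if not samples:
        raise InvalidInputError("no samples")
    start = int(math.floor(burn_in * len(samples)))
    post = samples[start:]
    if not post:
        raise InvalidInputError("no post-burn-in samples")
    n = len(post)
    incl: Counter = Counter()
    link: Counter = Counter()
    frame_of: dict[int, int] = {}
    for s in post:
        for tr in s.collection.trajectories:
            for i, h in enumerate(tr.hyp_ids):
                incl[h] += 1
                frame_of[h] = tr.t0 + i
                if i + 1 < len(tr.hyp_ids):
                    link[(h, tr.hyp_ids[i + 1])] += 1
    keep_links = sorted(
        ((c / n, lk) for lk, c in link.items() if c / n > 0.5),
        key=lambda x: (-x[0], x[1]),
    )
    succ: dict[int, int] = {}
    pred: dict[int, int] = {}
    for _, (a, b) in keep_links:
        if a in succ or b in pred:
            continue  # conflict: lower-frequency link loses
        succ[a] = b
        pred[b] = a
    keep_incl = {h for h, c in incl.items() if c / n > 0.5}
    used = set()
    trajectories = []
    # chains first
    heads = [a for a in succ if a not in pred]
    for a in sorted(heads, key=lambda h: (frame_of[h], h)):
        chain = [a]
        while chain[-1] in succ:
            chain.append(succ[chain[-1]])
        trajectories.append(Trajectory(t0=frame_of[a], hyp_ids=tuple(chain)))
        used.update(chain)
    # remaining well-supported inclusions become singletons
    for h in sorted(keep_incl - used, key=lambda h: (frame_of[h], h)):
        trajectories.append(Trajectory(t0=frame_of[h], hyp_ids=(h,)))
    score = None
    if hyps is not None:
        score = collection_log_score(
            TrackCollection(tuple(trajectories)),
            {h.id: h for h in hyps},
            mm or MotionModel(),
            prior or CollectionPrior(),
        )
    return TrackCollection(trajectories=tuple(trajectories), log_score=score)


def average_tracked_cells(coll: TrackCollection, frame_range) -> float:
    """Mean over the given frames of the number of trajectories alive."""
    frames = list(frame_range)
    if not frames:
        raise InvalidInputError("frame_range must be non-empty")
    total = 0
    for f in frames:
        total += sum(1 for t in coll.trajectories if t.alive(f))
    return total / len(frames)


# ---------------------------------------------------------------------------
# model / results objects


class TrajectoryModel:
    """Joint trajectory-collection model over a fixed set of blob hypotheses.

    Parameters
    ----------
    hypotheses : list of BlobHypothesis (all frames of the movie).
    motion : MotionModel, per-frame deviation scales.
    prior : CollectionPrior, structural prior.
    link_gate_px : maximum centre displacement considered for a link.
    """

    def __init__(
        self,
        hypotheses: list[BlobHypothesis],
        motion: MotionModel | None = None,
        prior: CollectionPrior | None = None,
        link_gate_px: float = 25.0,
    ):
        self.hypotheses = list(hypotheses)
        self.hyps_by_id = {h.id: h for h in self.hypotheses}
        if len(self.hyps_by_id) != len(self.hypotheses):
            raise InvalidInputError("hypothesis ids must be unique")
        self.motion = motion or MotionModel()
        self.prior = prior or CollectionPrior()
        self.link_gate_px = link_gate_px

    def score(self, coll: TrackCollection) -> float:
        return collection_log_score(coll, self.hyps_by_id, self.motion, self.prior)

    def greedy_collection(self) -> TrackCollection:
        """Deterministic greedy initial collection: frame-to-frame linking by
        best transition density, new tracks for unmatched non-conflicting
        hypotheses (by descending support)."""
        state = _SamplerState(self.hypotheses, self.motion, self.prior, self.link_gate_px)
        by_frame = state.by_frame
        tracks: list[list[int]] = []
        track_t0: list[int] = []
        placed: dict[int, set[int]] = {}  # frame -> placed hyp ids

        def conflicts(hid, frame):
            kappa = self.prior.kappa_overlap
            for other, area in state.partners[hid]:
                if other in placed.get(frame, ()):  # same frame by construction
                    if math.isinf(kappa) and area > 0:
                        return True
                    hid_area = self.hyps_by_id[hid].ellipse.area
                    other_area = self.hyps_by_id[other].ellipse.area
                    if area > 0.3 * min(hid_area, other_area):
                        return True
            return False

        for f in state.frames:
            open_tracks = [
                k for k in range(len(tracks)) if track_t0[k] + len(tracks[k]) == f
            ]
            pairs = []
            for k in open_tracks:
                last = self.hyps_by_id[tracks[k][-1]]
                if len(tracks[k]) >= 2:
                    prv = self.hyps_by_id[tracks[k][-2]].ellipse
                    vel = (last.ellipse.cx - prv.cx, last.ellipse.cy - prv.cy)
                    sp = None
                else:
                    vel = (0.0, 0.0)
                    sp = self.motion.sigma_pos * FIRST_STEP_SIGMA_FACTOR
                prev = (
                    (last.ellipse.cx, last.ellipse.cy),
                    vel,
                    (math.log(last.ellipse.a), math.log(last.ellipse.b)),
                    last.ellipse.theta,
                )
                for c in state.cand_fwd[last.id]:
                    lp = transition_log_prob(
                        prev, self.hyps_by_id[c].ellipse, self.motion, sigma_pos=sp
                    )
                    pairs.append((lp, k, c))
            pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
            taken_tracks: set[int] = set()
            taken_hyps: set[int] = set()
            placed.setdefault(f, set())
            for lp, k, c in pairs:
                if k in taken_tracks or c in taken_hyps:
                    continue
                if conflicts(c, f):
                    continue
                tracks[k].append(c)
                taken_tracks.add(k)
                taken_hyps.add(c)
                placed[f].add(c)
            rest = [h for h in by_frame[f] if h not in taken_hyps]
            rest.sort(key=lambda h: (-self.hyps_by_id[h].support, h))
            for h in rest:
                if conflicts(h, f):
                    continue
                tracks.append([h])
                track_t0.append(f)
                placed[f].add(h)
        trajs = tuple(
            Trajectory(t0=t0, hyp_ids=tuple(ids)) for t0, ids in zip(track_t0, tracks)
        )
        coll = TrackCollection(trajectories=trajs)
        return TrackCollection(trajectories=trajs, log_score=self.score(coll))

    def fit(
        self,
        n_iter: int = 20000,
        seed: int = 0,
        burn_in: float = 0.3,
        thin: int = 1,
        init: str = "greedy",
    ) -> "TrackingResults":
        """Sample trajectory collections and return the Bayes-risk decision.

        init : "greedy" (default) starts the chain at the greedy linking,
        "empty" at the empty collection.
        """
        if init == "greedy":
            init_coll = self.greedy_collection()
        elif init == "empty":
            init_coll = None
        else:
            raise InvalidInputError("init must be 'greedy' or 'empty'")
        samples = sample_posterior(
            self.hypotheses,
            self.motion,
            self.prior,
            n_iter=n_iter,
            seed=seed,
            init=init_coll,
            thin=thin,
            link_gate_px=self.link_gate_px,
        )
        decision = bayes_decision(
            samples, burn_in=burn_in, hyps=self.hypotheses, mm=self.motion, prior=self.prior
        )
        return TrackingResults(self, decision, samples, n_iter=n_iter, burn_in=burn_in)


class TrackingResults:
    """Decided tracking plus the posterior samples it was derived from."""

    def __init__(self, model, collection, samples, n_iter, burn_in):
        self.model = model
        self.collection = collection
        self.samples = samples
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.acceptance_rate = (
            sum(1 for s in samples if s.accepted) / len(samples) if samples else 0.0
        )

    @property
    def frame_range(self) -> range:
        frames = [f for t in self.collection.trajectories for f in (t.t0, t.t1)]
        if not frames:
            hyp_frames = [h.frame for h in self.model.hypotheses]
            if not hyp_frames:
                return range(0)
            return range(min(hyp_frames), max(hyp_frames) + 1)
        return range(min(frames), max(frames) + 1)

    def average_tracked_cells(self, frame_range=None) -> float:
        fr = frame_range if frame_range is not None else self.frame_range
        return average_tracked_cells(self.collection, fr)

    def to_dataframe(self) -> pd.DataFrame:
        """Tracks as a tidy table: frame, cell_id, cx, cy, a, b, theta."""
        rows = []
        for cid, tr in enumerate(self.collection.trajectories):
            for f, h in tr.elements:
                e = self.model.hyps_by_id[h].ellipse
                rows.append((f, cid, e.cx, e.cy, e.a, e.b, e.theta))
        return pd.DataFrame(rows, columns=["frame", "cell_id", "cx", "cy", "a", "b", "theta"])

    def summary(self) -> str:
        coll = self.collection
        lines = [
            "Trajectory-collection tracking results",
            "=" * 44,
            f"hypotheses:           {len(self.model.hypotheses)}",
            f"iterations (thinned): {self.n_iter} ({len(self.samples)} recorded)",
            f"acceptance rate:      {self.acceptance_rate:.3f}",
            f"trajectories:         {len(coll)}",
            f"assigned hypotheses:  {len(coll.assigned_ids())}",
            f"avg tracked cells:    {self.average_tracked_cells():.2f}"
            if len(coll) > 0
            else "avg tracked cells:    0.00",
            f"log score:            {coll.log_score:.2f}"
            if coll.log_score is not None
            else "log score:            n/a",
        ]
        return "\n".join(lines)

    def plot_tracks(self, ax=None):
        """Centre trajectories over time, one line per cell."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for tr in self.collection.trajectories:
            xs = [self.model.hyps_by_id[h].ellipse.cx for h in tr.hyp_ids]
            ys = [self.model.hyps_by_id[h].ellipse.cy for h in tr.hyp_ids]
            ax.plot(xs, ys, "-", lw=1)
        ax.set_xlabel("x [px]")
        ax.set_ylabel("y [px]")
        ax.set_aspect("equal")
        return ax
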
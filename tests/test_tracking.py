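import math

import numpy as np
import pytest

from phasetrack._geometry import Ellipse
from phasetrack.exceptions import (
    InvalidCollectionError,
    InvalidInputError,
    InvalidReferenceError,
)
from phasetrack.tracking import (
    FIRST_STEP_SIGMA_FACTOR,
    CollectionPrior,
    MotionModel,
    PosteriorSample,
    TrackCollection,
    Trajectory,
    TrajectoryModel,
    average_tracked_cells,
    bayes_decision,
    collection_log_score,
    propose_move,
    sample_posterior,
    trajectory_log_score,
    transition_log_prob,
)

from _oracles import ellipse_overlap_bruteforce, map_collection

_LOG_2PI = math.log(2 * math.pi)


def prev_state(e: Ellipse, vel=(0.0, 0.0)):
    return ((e.cx, e.cy), vel, (math.log(e.a), math.log(e.b)), e.theta)


class TestTransitionLogProb:
    def test_zero_deviation_attains_the_normalising_maximum(self, motion):
        e = Ellipse(10, 10, 6, 4, 0.3)
        lp = transition_log_prob(prev_state(e), e, motion)
        expected = (
            -_LOG_2PI
            - 2 * math.log(motion.sigma_pos)
            + 2 * (-0.5 * _LOG_2PI - math.log(motion.sigma_shape))
            + math.log(
                sum(
                    math.exp(-0.5 * (k * math.pi / motion.sigma_theta) ** 2)
                    for k in range(-3, 4)
                )
                / (motion.sigma_theta * math.sqrt(2 * math.pi))
            )
        )
        assert lp == pytest.approx(expected, abs=1e-12)
        # and no deviated step scores higher
        worse = transition_log_prob(prev_state(e), Ellipse(11, 10, 6, 4, 0.3), motion)
        assert worse < lp

    def test_symmetric_in_deviation_sign(self, motion):
        e = Ellipse(10, 10, 6, 4, 0.3)
        up = transition_log_prob(prev_state(e), Ellipse(12.5, 11, 6, 4, 0.3), motion)
        dn = transition_log_prob(prev_state(e), Ellipse(7.5, 9, 6, 4, 0.3), motion)
        assert up == pytest.approx(dn, abs=1e-12)

    def test_positional_term_is_closed_form_gaussian_at_radius_five(self):
        # sigma_pos = 2, deviation (3, 4): log-density difference from the
        # mode must equal -r^2 / (2 sigma^2) with r = 5
        mm = MotionModel(sigma_pos=2.0)
        e = Ellipse(10, 10, 6, 4, 0.3)
        at_mode = transition_log_prob(prev_state(e), e, mm)
        moved = transition_log_prob(prev_state(e), Ellipse(13, 14, 6, 4, 0.3), mm)
        assert moved - at_mode == pytest.approx(-25.0 / (2 * 4.0), abs=1e-12)


class TestTrajectoryScore:
    def test_singleton_is_birth_death_support_coverage(self, hyp_factory, motion):
        prior = CollectionPrior(log_birth=-3, log_death=-1, log_coverage=2)
        h = hyp_factory(0, 2, 30, 30, support=0.8)
        s = trajectory_log_score(Trajectory(2, (0,)), {0: h}, motion, prior)
        assert s == pytest.approx(-3 - 1 + math.log(0.8) + 2, abs=1e-12)

    def test_stationary_track_scores_transitions_at_their_maximum(self, hyp_factory, motion):
        prior = CollectionPrior()
        hyps = {i: hyp_factory(i, i, 30, 30, support=0.8) for i in range(3)}
        s = trajectory_log_score(Trajectory(0, (0, 1, 2)), hyps, motion, prior)
        e = hyps[0].ellipse
        first = transition_log_prob(
            prev_state(e), e, motion, sigma_pos=motion.sigma_pos * FIRST_STEP_SIGMA_FACTOR
        )
        second = transition_log_prob(prev_state(e), e, motion)
        base = prior.log_birth + prior.log_death + 3 * (math.log(0.8) + prior.log_coverage)
        assert s == pytest.approx(base + first + second, abs=1e-12)

    def test_matches_term_by_term_hand_summation(self, hyp_factory, motion):
        # moving, shape-changing track recomputed by an independent routine
        prior = CollectionPrior(log_birth=-2, log_death=-1, log_coverage=1.5)
        h0 = hyp_factory(0, 0, 30.0, 30.0, a=6.0, b=5.0, theta=0.2, support=0.9)
        h1 = hyp_factory(1, 1, 32.0, 31.0, a=6.3, b=4.8, theta=0.25, support=0.8)
        h2 = hyp_factory(2, 2, 34.5, 31.5, a=6.1, b=4.9, theta=0.22, support=0.85)
        hyps = {h.id: h for h in (h0, h1, h2)}
        s = trajectory_log_score(Trajectory(0, (0, 1, 2)), hyps, motion, prior)

        def norm_lp(d, sig):
            return -0.5 * _LOG_2PI - math.log(sig) - 0.5 * (d / sig) ** 2

        def wrapped_lp(d, sig):
            dens = sum(
                math.exp(-0.5 * (((d + math.pi / 2) % math.pi - math.pi / 2 + k * math.pi) / sig) ** 2)
                for k in range(-3, 4)
            )
            return math.log(dens / (sig * math.sqrt(2 * math.pi)))

        oracle = prior.log_birth + prior.log_death
        for h in (h0, h1, h2):
            oracle += math.log(h.support) + prior.log_coverage
        # step 0 -> 1: zero prior velocity, inflated sigma
        sp = motion.sigma_pos * FIRST_STEP_SIGMA_FACTOR
        oracle += norm_lp(2.0, sp) + norm_lp(1.0, sp) + _LOG_2PI / 2 * 0  # 2-D below
        # rewrite: 2-D gaussian = sum of two 1-D gaussians
        oracle += 0.0
        oracle += norm_lp(math.log(6.3) - math.log(6.0), motion.sigma_shape)
        oracle += norm_lp(math.log(4.8) - math.log(5.0), motion.sigma_shape)
        oracle += wrapped_lp(0.05, motion.sigma_theta)
        # step 1 -> 2: velocity = previous displacement (2, 1)
        oracle += norm_lp(34.5 - 34.0, motion.sigma_pos) + norm_lp(31.5 - 32.0, motion.sigma_pos)
        oracle += norm_lp(math.log(6.1) - math.log(6.3), motion.sigma_shape)
        oracle += norm_lp(math.log(4.9) - math.log(4.8), motion.sigma_shape)
        oracle += wrapped_lp(-0.03, motion.sigma_theta)
        assert s == pytest.approx(oracle, abs=1e-9)

    def test_unknown_hypothesis_id_rejected(self, hyp_factory, motion):
        with pytest.raises(InvalidReferenceError):
            trajectory_log_score(
                Trajectory(0, (0, 99)), {0: hyp_factory(0, 0, 10, 10)}, motion, CollectionPrior()
            )


class TestCollectionScore:
    def test_empty_collection_scores_zero(self, motion):
        assert collection_log_score(TrackCollection(), {}, motion, CollectionPrior()) == 0.0

    def test_hard_exclusion_gives_minus_infinity(self, hyp_factory, motion):
        prior = CollectionPrior(kappa_overlap=math.inf)
        h0 = hyp_factory(0, 0, 30, 30)
        h1 = hyp_factory(1, 0, 30, 30)
        coll = TrackCollection((Trajectory(0, (0,)), Trajectory(0, (1,))))
        s = collection_log_score(coll, {0: h0, 1: h1}, motion, prior)
        assert s == -math.inf

    def test_overlap_penalty_equals_kappa_times_sampled_area(self, hyp_factory, motion):
        kappa = 0.05
        prior = CollectionPrior(kappa_overlap=kappa)
        h0 = hyp_factory(0, 0, 30.0, 30.0, a=8, b=6)
        h1 = hyp_factory(1, 0, 36.0, 30.0, a=8, b=6)
        h1_far = hyp_factory(1, 0, 80.0, 30.0, a=8, b=6)
        overlapping = TrackCollection((Trajectory(0, (0,)), Trajectory(0, (1,))))
        s_near = collection_log_score(overlapping, {0: h0, 1: h1}, motion, prior)
        s_far = collection_log_score(overlapping, {0: h0, 1: h1_far}, motion, prior)
        area = ellipse_overlap_bruteforce(h0.ellipse, h1.ellipse)
        assert area > 0
        assert s_far - s_near == pytest.approx(kappa * area, abs=1e-9)

    def test_duplicated_hypothesis_rejected(self, hyp_factory, motion):
        h0 = hyp_factory(0, 0, 30, 30)
        coll = TrackCollection((Trajectory(0, (0,)), Trajectory(0, (0,))))
        with pytest.raises(InvalidCollectionError):
            collection_log_score(coll, {0: h0}, motion, CollectionPrior())


class TestProposeMove:
    def test_birth_on_empty_collection_creates_singleton(self, hyp_factory):
        hyps = [hyp_factory(0, 0, 30, 30)]
        cand, _, ok = propose_move(TrackCollection(), hyps, "birth", rng_seed=7)
        assert ok and len(cand) == 1 and cand.trajectories[0].hyp_ids == (0,)

    def test_death_then_birth_recovers_the_collection(self, hyp_factory):
        hyps = [hyp_factory(0, 3, 30, 30)]
        start = TrackCollection((Trajectory(3, (0,)),))
        after_death, _, ok = propose_move(start, hyps, "death", rng_seed=1)
        assert ok and len(after_death) == 0
        recovered, _, ok = propose_move(after_death, hyps, "birth", rng_seed=1)
        assert ok and {t.hyp_ids for t in recovered.trajectories} == {(0,)}

    def test_extend_past_the_final_frame_is_flagged_noop(self, hyp_factory):
        # single-frame movie: no adjacent frame to extend into
        hyps = [hyp_factory(0, 0, 30, 30)]
        coll = TrackCollection((Trajectory(0, (0,)),))
        cand, ratio, ok = propose_move(coll, hyps, "extend", rng_seed=0)
        assert not ok and ratio == 0.0
        assert {t.hyp_ids for t in cand.trajectories} == {(0,)}

    def test_inapplicable_death_is_flagged_noop(self, hyp_factory):
        cand, _, ok = propose_move(TrackCollection(), [hyp_factory(0, 0, 30, 30)], "death", 0)
        assert not ok and len(cand) == 0


def score_fn_for(hyps, mm, prior):
    hyps_by_id = {h.id: h for h in hyps}

    def fn(pairs):
        coll = TrackCollection(tuple(Trajectory(t0, ids) for t0, ids in pairs))
        return collection_log_score(coll, hyps_by_id, mm, prior)

    return fn


class TestSamplePosterior:
    def test_no_hypotheses_gives_empty_samples(self, motion, linky_prior):
        samples = sample_posterior([], motion, linky_prior, n_iter=50, seed=0)
        assert all(len(s.collection) == 0 for s in samples)

    def test_two_frame_instance_links_into_one_trajectory(self, hyp_factory, motion, linky_prior):
        # oracle: exhaustive enumeration of all feasible collections
        hyps = [hyp_factory(0, 0, 30, 30), hyp_factory(1, 1, 31, 30)]
        best, scores = map_collection(hyps, motion, linky_prior, score_fn_for(hyps, motion, linky_prior))
        assert best == ((0, (0, 1)),), "enumerated MAP must be the linked pair"
        samples = sample_posterior(hyps, motion, linky_prior, n_iter=4000, seed=11)
        top = max(samples, key=lambda s: s.collection.log_score)
        assert {t.hyp_ids for t in top.collection.trajectories} == {(0, 1)}

    def test_identical_seed_reproduces_the_chain(self, hyp_factory, motion, linky_prior):
        hyps = [hyp_factory(i, i % 3, 30 + i, 30) for i in range(6)]
        s1 = sample_posterior(hyps, motion, linky_prior, n_iter=500, seed=42)
        s2 = sample_posterior(hyps, motion, linky_prior, n_iter=500, seed=42)
        assert [s.collection.log_score for s in s1] == [s.collection.log_score for s in s2]
        assert [s.accepted for s in s1] == [s.accepted for s in s2]


class TestBayesDecision:
    def test_unanimous_samples_reproduce_the_collection(self, hyp_factory):
        coll = TrackCollection((Trajectory(0, (0, 1)),))
        samples = [PosteriorSample(coll, i, True) for i in range(10)]
        decided = bayes_decision(samples, burn_in=0.0)
        assert {t.hyp_ids for t in decided.trajectories} == {(0, 1)}

    def test_minority_link_is_excluded(self):
        linked = TrackCollection((Trajectory(0, (0, 1)),))
        split = TrackCollection((Trajectory(0, (0,)), Trajectory(1, (1,))))
        samples = [PosteriorSample(linked if i < 4 else split, i, True) for i in range(10)]
        decided = bayes_decision(samples, burn_in=0.0)  # link present in 40%
        assert {t.hyp_ids for t in decided.trajectories} == {(0,), (1,)}

    def test_empty_post_burn_in_rejected(self):
        with pytest.raises(InvalidInputError):
            bayes_decision([], burn_in=0.0)

    def test_sharply_peaked_tiny_instance_recovers_the_map(self, hyp_factory, motion):
        prior = CollectionPrior(log_birth=-2.0, log_death=-0.5, log_coverage=2.0)
        hyps = [
            hyp_factory(0, 0, 30.0, 30.0, support=0.9),
            hyp_factory(1, 0, 70.0, 30.0, support=0.1),  # weak decoy
            hyp_factory(2, 1, 31.0, 30.0, support=0.9),
            hyp_factory(3, 2, 32.0, 30.0, support=0.9),
        ]
        best, scores = map_collection(hyps, motion, prior, score_fn_for(hyps, motion, prior))
        assert scores[0] - scores[1] > 2.0
        samples = sample_posterior(hyps, motion, prior, n_iter=20000, seed=5)
        decided = bayes_decision(samples, burn_in=0.3)
        got = tuple(sorted((t.t0, t.hyp_ids) for t in decided.trajectories))
        assert got == best


class TestAverageTrackedCells:
    def test_full_span_trajectories_count_exactly(self):
        coll = TrackCollection(tuple(Trajectory(0, tuple(range(10 * k, 10 * k + 10))) for k in range(3)))
        assert average_tracked_cells(coll, range(10)) == 3.0

    def test_half_span_gives_fractional_average(self):
        coll = TrackCollection((Trajectory(0, tuple(range(10))), Trajectory(5, tuple(range(20, 25)))))
        assert average_tracked_cells(coll, range(10)) == 1.5

    def test_empty_collection_gives_zero(self):
        assert average_tracked_cells(TrackCollection(), range(5)) == 0.0

    def test_empty_frame_range_rejected(self):
        with pytest.raises(InvalidInputError):
            average_tracked_cells(TrackCollection(), [])


class TestModelInvariants:
    def test_decided_collection_is_injective_and_respects_hard_exclusion(self, hyp_factory, motion):
        prior = CollectionPrior(log_birth=-1.0, log_death=-0.5, kappa_overlap=math.inf)
        rng = np.random.default_rng(3)
        hyps = []
        hid = 0
        for f in range(3):
            for k in range(3):
                hyps.append(
                    hyp_factory(hid, f, 20.0 + 25 * k + rng.normal(0, 1), 20.0, support=0.8)
                )
                hid += 1
        model = TrajectoryModel(hyps, motion=motion, prior=prior)
        res = model.fit(n_iter=3000, seed=9)
        ids = res.collection.assigned_ids()
        assert len(ids) == len(set(ids))
        by_frame = {}
        for t in res.collection.trajectories:
            for f, h in t.elements:
                by_frame.setdefault(f, []).append(model.hyps_by_id[h].ellipse)
        for es in by_frame.values():
            for i in range(len(es)):
                for j in range(i + 1, len(es)):
                    assert ellipse_overlap_bruteforce(es[i], es[j]) == 0

    def test_raising_coverage_never_drops_assignments_in_the_map(self, hyp_factory, motion):
        hyps = [
            hyp_factory(0, 0, 30.0, 30.0, support=0.55),
            hyp_factory(1, 1, 33.0, 30.0, support=0.55),
            hyp_factory(2, 2, 80.0, 30.0, support=0.55),
        ]
        sizes = []
        for cov in (0.0, 1.0, 2.0, 3.0):
            prior = CollectionPrior(log_birth=-2, log_death=-1, log_coverage=cov)
            best, _ = map_collection(hyps, motion, prior, score_fn_for(hyps, motion, prior))
            sizes.append(sum(len(ids) for _, ids in best))
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))

    def test_results_dataframe_round_trips_schema(self, hyp_factory, motion, linky_prior):
        hyps = [hyp_factory(i, i, 30.0 + i, 30.0) for i in range(4)]
        res = TrajectoryModel(hyps, motion=motion, prior=linky_prior).fit(n_iter=2000, seed=0)
        df = res.to_dataframe()
        assert list(df.columns) == ["frame", "cell_id", "cx", "cy", "a", "b", "theta"]
        assert res.summary().startswith("Trajectory-collection tracking results")
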
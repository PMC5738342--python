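"""End-to-end glue: movie -> probability maps -> hypotheses -> tracking.

Default stage parameters here are tuned for movie-scale inputs (hundreds of
thousands of pixels per frame): the Gibbs sampler runs a modest per-frame
sweep budget, which is ample for blob detection even though small-frame
statistical analyses use a larger default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .blobs import BlobHypothesis, deduplicate, generate_hypotheses
from .evaluate import EvaluationReport, evaluate_tracking
from .io import ImageStack
from .segmentation import ForegroundMap, MrfParams, segment_frame
from .simulate import GroundTruth, SimConfig, render_phase_contrast, simulate_tracks
from .tracking import CollectionPrior, MotionModel, TrackingResults, TrajectoryModel

__all__ = [
    "DetectParams",
    "MOVIE_MRF_PARAMS",
    "segment_movie",
    "detect_movie",
    "track_movie",
    "run_end_to_end",
]

#: movie-scale MRF inference budget (per-frame sweep counts chosen for
#: hundreds of frames; small-frame analyses use the MrfParams defaults)
MOVIE_MRF_PARAMS = MrfParams(n_burn=50, n_sweeps=150)


@dataclass(frozen=True)
class DetectParams:
    """Hypothesis-generation settings for movie-scale detection."""

    tau: float = 0.5
    min_axis: float = 6.0
    max_axis: float = 80.0
    max_iou: float = 0.6


def segment_movie(stack: ImageStack, mrf: MrfParams = MOVIE_MRF_PARAMS, log=None):
    """Segment every frame of a movie independently."""
    maps = []
    for frame in stack.frames():
        maps.append(segment_frame(frame, mrf))
        if log is not None and frame.time_index % 10 == 0:
            print(f"[segment] frame {frame.time_index}", file=log)
    return maps


def detect_movie(maps: list[ForegroundMap], det: DetectParams = DetectParams()):
    """Generate and deduplicate blob hypotheses over all frames."""
    hyps: list[BlobHypothesis] = []
    next_id = 0
    for m in maps:
        frame_hyps = generate_hypotheses(
            m, tau=det.tau, min_axis=det.min_axis, max_axis=det.max_axis, start_id=next_id
        )
        frame_hyps = deduplicate(frame_hyps, max_iou=det.max_iou)
        if frame_hyps:
            next_id = max(h.id for h in frame_hyps) + 1
        hyps.extend(frame_hyps)
    return hyps


def track_movie(
    hyps: list[BlobHypothesis],
    motion: MotionModel | None = None,
    prior: CollectionPrior | None = None,
    n_iter: int = 30000,
    seed: int = 0,
    thin: int = 10,
    log_every: int | None = None,
) -> TrackingResults:
    """Fit the trajectory model on a movie's hypotheses."""
    model = TrajectoryModel(hyps, motion=motion, prior=prior)
    return model.fit(n_iter=n_iter, seed=seed, thin=thin)


def run_end_to_end(
    sim_cfg: SimConfig,
    seed: int | None = None,
    n_iter: int = 30000,
    mrf: MrfParams = MOVIE_MRF_PARAMS,
    det: DetectParams = DetectParams(),
    log=None,
):
    """simulate -> render -> segment -> detect -> track -> evaluate.

    Returns (gt, results, report).  `seed` overrides the simulator seed and
    also seeds segmentation and the sampler.
    """
    if seed is not None:
        sim_cfg = replace(sim_cfg, seed=seed)
    seed = sim_cfg.seed
    gt = simulate_tracks(sim_cfg)
    stack = render_phase_contrast(gt)
    maps = segment_movie(stack, replace(mrf, seed=seed), log=log)
    hyps = detect_movie(maps, det)
    if log is not None:
        print(f"[detect] {len(hyps)} hypotheses over {len(maps)} frames", file=log)
    results = track_movie(hyps, n_iter=n_iter, seed=seed)
    report = evaluate_tracking(results.collection, results.model.hyps_by_id, gt)
    return gt, results, report
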
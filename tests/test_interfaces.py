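import json

import numpy as np
import pandas as pd
import pytest

from phasetrack._geometry import Ellipse
from phasetrack.blobs import BlobHypothesis
from phasetrack.config import load_config
from phasetrack.evaluate import evaluate_tracking
from phasetrack.exceptions import ConfigurationError, InvalidInputError, ParseError
from phasetrack.io import (
    ImageStack,
    read_stack,
    read_tracks,
    write_stack,
    write_tracks,
)
from phasetrack.simulate import GroundTruth, SimConfig
from phasetrack.tracking import TrackCollection, Trajectory


class TestStackIO:
    def test_uint16_round_trip_is_bit_identical(self, tmp_path, rng):
        data = (rng.random((5, 12, 14)) * 65535).astype(np.uint16)
        p = tmp_path / "movie.tif"
        write_stack(ImageStack(data, 0.65, 300.0), p)
        back = read_stack(p, pixel_size_um=0.65, frame_interval_s=300.0)
        assert back.data.dtype == np.uint16
        assert np.array_equal(back.data, data)

    def test_single_page_becomes_length_one_stack(self, tmp_path, rng):
        data = (rng.random((10, 10)) * 255).astype(np.uint8)
        p = tmp_path / "one.tif"
        write_stack(ImageStack(data[None], 1.0, 1.0), p)
        assert len(read_stack(p)) == 1

    def test_truncated_file_raises_parse_error_with_size(self, tmp_path, rng):
        data = (rng.random((4, 64, 64)) * 65535).astype(np.uint16)
        p = tmp_path / "trunc.tif"
        write_stack(ImageStack(data, 1.0, 1.0), p)
        raw = p.read_bytes()
        p.write_bytes(raw[: len(raw) // 3])
        with pytest.raises(ParseError, match="bytes"):
            read_stack(p)


def two_track_df():
    rows = []
    for f in range(3):
        rows.append((f, 0, 10.0 + f, 10.0, 6.0, 5.0, 0.1))
        rows.append((f, 1, 40.0, 40.0 + f, 7.0, 5.0, 0.2))
    return pd.DataFrame(rows, columns=["frame", "cell_id", "cx", "cy", "a", "b", "theta"])


class TestTrackIO:
    def test_two_track_file_round_trips(self, tmp_path):
        p = tmp_path / "tracks.csv"
        two_track_df().to_csv(p, index=False)
        coll, hyps = read_tracks(p)
        assert len(coll) == 2
        q = tmp_path / "again.csv"
        write_tracks(coll, hyps, q)
        coll2, _ = read_tracks(q)
        assert len(coll2) == 2
        for t1, t2 in zip(coll.trajectories, coll2.trajectories):
            assert t1.t0 == t2.t0 and len(t1) == len(t2)

    def test_gap_in_frames_is_a_validation_error(self, tmp_path):
        df = two_track_df()
        df = df[~((df.cell_id == 0) & (df.frame == 1))]
        p = tmp_path / "gap.csv"
        df.to_csv(p, index=False)
        with pytest.raises(InvalidInputError, match="contiguous"):
            read_tracks(p)

    def test_empty_file_with_header_gives_empty_collection(self, tmp_path):
        p = tmp_path / "empty.csv"
        two_track_df().iloc[0:0].to_csv(p, index=False)
        coll, hyps = read_tracks(p)
        assert len(coll) == 0 and hyps == {}

    def test_missing_column_names_the_column(self, tmp_path):
        df = two_track_df().drop(columns=["theta"])
        p = tmp_path / "nocol.csv"
        df.to_csv(p, index=False)
        with pytest.raises(InvalidInputError, match="theta"):
            read_tracks(p)

    def test_theta_is_wrapped_on_read(self, tmp_path):
        df = two_track_df()
        df.loc[0, "theta"] = 4.0  # > pi
        p = tmp_path / "wrap.csv"
        df.to_csv(p, index=False)
        _, hyps = read_tracks(p)
        assert all(0 <= h.ellipse.theta < np.pi for h in hyps.values())


def gt_from_tracks(tracks, field=(64, 64)):
    n_cells, n_frames = tracks.shape[:2]
    return GroundTruth(
        tracks=tracks,
        elongating=np.zeros(n_cells, dtype=bool),
        junction_totals=np.zeros(n_cells),
        config=SimConfig(n_cells=n_cells, field_size=field, n_frames=n_frames),
    )


def collection_from_tracks(tracks):
    hyps = {}
    trajs = []
    hid = 0
    for c in range(tracks.shape[0]):
        ids = []
        for f in range(tracks.shape[1]):
            cx, cy, a, b, th = tracks[c, f]
            hyps[hid] = BlobHypothesis(hid, f, Ellipse(cx, cy, a, b, th), 1.0)
            ids.append(hid)
            hid += 1
        trajs.append(Trajectory(0, tuple(ids)))
    return TrackCollection(tuple(trajs)), hyps


def make_tracks(n_cells=3, n_frames=10):
    tracks = np.zeros((n_cells, n_frames, 5))
    for c in range(n_cells):
        for f in range(n_frames):
            tracks[c, f] = (15.0 + 18 * c + 0.5 * f, 20.0, 6.0, 5.0, 0.0)
    return tracks


class TestEvaluateTracking:
    def test_perfect_prediction_scores_perfectly(self):
        tracks = make_tracks()
        gt = gt_from_tracks(tracks)
        coll, hyps = collection_from_tracks(tracks)
        rep = evaluate_tracking(coll, hyps, gt)
        assert rep.match_rate == 1.0
        assert rep.id_switches == 0
        assert rep.centre_rmse_px == 0.0

    def test_empty_prediction_scores_zero(self):
        gt = gt_from_tracks(make_tracks())
        rep = evaluate_tracking(TrackCollection(), {}, gt)
        assert rep.match_rate == 0.0

    def test_mid_movie_label_swap_counts_two_switches(self):
        # oracle: hand count on a 3-track, 10-frame constructed case —
        # swapping two tracks' tails at frame 5 flips the matched label once
        # inside each of the two affected predicted tracks
        tracks = make_tracks(3, 10)
        gt = gt_from_tracks(tracks)
        swapped = tracks.copy()
        swapped[0, 5:], swapped[1, 5:] = tracks[1, 5:].copy(), tracks[0, 5:].copy()
        coll, hyps = collection_from_tracks(swapped)
        rep = evaluate_tracking(coll, hyps, gt)
        assert rep.id_switches == 2
        assert rep.match_rate < 1.0  # the minority halves are inconsistent


class TestRunConfig:
    def test_valid_config_round_trip(self, tmp_path):
        p = tmp_path / "run.toml"
        p.write_text(
            "seed = 9\n"
            "[simulate]\nn_cells = 5\nn_frames = 4\n"
            "[motion]\nsigma_pos = 3.0\n"
            "[track]\nn_iter = 500\n"
        )
        cfg = load_config(p)
        assert cfg.seed == 9
        assert cfg.simulate.n_cells == 5
        assert cfg.motion.sigma_pos == 3.0
        assert cfg.track.n_iter == 500

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "bad.toml"
        p.write_text("[motion]\nsigma_position = 3.0\n")
        with pytest.raises(ConfigurationError, match="sigma_position"):
            load_config(p)

    def test_unknown_section_rejected(self, tmp_path):
        p = tmp_path / "bad2.toml"
        p.write_text("[motions]\nsigma_pos = 3.0\n")
        with pytest.raises(ConfigurationError):
            load_config(p)

    def test_invalid_value_rejected(self, tmp_path):
        p = tmp_path / "bad3.toml"
        p.write_text("[motion]\nsigma_pos = -1.0\n")
        with pytest.raises(ConfigurationError):
            load_config(p)


class TestCliPipeline:
    def test_simulate_track_evaluate_round_trip(self, tmp_path):
        from click.testing import CliRunner

        from phasetrack.cli import main

        cfgfile = tmp_path / "run.toml"
        cfgfile.write_text(
            "seed = 2\n"
            "[simulate]\nn_cells = 6\nfield_size = [192, 192]\nn_frames = 6\nseed = 2\n"
            "[track]\nn_iter = 4000\nthin = 4\n"
        )
        runner = CliRunner()
        out = tmp_path / "out"
        r = runner.invoke(
            main, ["simulate", "--config", str(cfgfile), "--out", str(out)],
            catch_exceptions=False,
        )
        assert r.exit_code == 0
        assert (out / "movie.tif").exists()
        assert (out / "junction.tif").exists()
        sidecar = json.loads((out / "sim_config.json").read_text())
        assert sidecar["n_cells"] == 6

        r = runner.invoke(
            main,
            ["segment", "--config", str(cfgfile), "--input", str(out / "movie.tif"),
             "--out", str(out)],
            catch_exceptions=False,
        )
        assert r.exit_code == 0
        r = runner.invoke(
            main,
            ["detect", "--config", str(cfgfile),
             "--probs", str(out / "foreground_probs.tif"), "--out", str(out)],
            catch_exceptions=False,
        )
        assert r.exit_code == 0
        r = runner.invoke(
            main,
            ["track", "--config", str(cfgfile),
             "--hypotheses", str(out / "hypotheses.csv"), "--out", str(out)],
            catch_exceptions=False,
        )
        assert r.exit_code == 0
        r = runner.invoke(
            main,
            ["evaluate", "--config", str(cfgfile), "--tracks", str(out / "tracks.csv"),
             "--ground-truth", str(out / "ground_truth_tracks.csv"), "--out", str(out)],
            catch_exceptions=False,
        )
        assert r.exit_code == 0
        rep = json.loads((out / "evaluation.json").read_text())
        assert rep["match_rate"] > 0.7

        r = runner.invoke(
            main,
            ["morph", "--config", str(cfgfile), "--tracks", str(out / "tracks.csv"),
             "--out", str(out)],
            catch_exceptions=False,
        )
        assert r.exit_code == 0
        per_cell = pd.read_csv(out / "morph_per_cell.csv")
        assert (per_cell.accumulated_um >= per_cell.euclidean_um - 1e-9).all()

    def test_bad_config_exits_with_code_three(self, tmp_path):
        from click.testing import CliRunner

        from phasetrack.cli import main

        bad = tmp_path / "bad.toml"
        bad.write_text("[nonsense]\nx = 1\n")
        r = CliRunner().invoke(main, ["simulate", "--config", str(bad), "--out", str(tmp_path)])
        assert r.exit_code == 3
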
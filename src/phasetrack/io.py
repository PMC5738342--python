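"""Image-stack and track-table I/O.

Multi-page grayscale TIFF in/out (8/16/32-bit; integer round-trips are
bit-identical) and the tracks CSV schema
``frame,cell_id,cx,cy,a,b,theta`` (0-based frames, pixel units, theta in
radians wrapped to [0, pi), floats at 6 significant digits).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile

from ._geometry import Ellipse, wrap_orientation
from .blobs import BlobHypothesis
from .exceptions import InvalidInputError, ParseError, UnsupportedFormatError
from .tracking import TrackCollection, Trajectory

__all__ = [
    "ImageStack",
    "read_stack",
    "write_stack",
    "read_tracks",
    "write_tracks",
    "TRACK_COLUMNS",
]

TRACK_COLUMNS = ["frame", "cell_id", "cx", "cy", "a", "b", "theta"]

HYPOTHESIS_COLUMNS = ["frame", "id", "cx", "cy", "a", "b", "theta", "support"]


@dataclass(frozen=True)
class ImageStack:
    """Calibrated T x H x W intensity movie."""

    data: np.ndarray
    pixel_size_um: float = 1.0
    frame_interval_s: float = 1.0

    def __post_init__(self):
        d = np.asarray(self.data)
        if d.ndim == 2:
            d = d[None, ...]
        if d.ndim != 3:
            raise UnsupportedFormatError(
                f"expected a (T, H, W) grayscale stack, got array of shape {d.shape}"
            )
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise InvalidInputError("calibration values must be > 0")
        object.__setattr__(self, "data", d)

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self):
        return self.data.shape

    def frames(self):
        """Iterate frames as :class:`~phasetrack.segmentation.Frame` objects."""
        from .segmentation import Frame

        for t in range(len(self)):
            yield Frame(
                pixels=self.data[t].astype(np.float64),
                pixel_size=self.pixel_size_um,
                time_index=t,
            )


def read_stack(path, pixel_size_um: float = 1.0, frame_interval_s: float = 1.0) -> ImageStack:
    """Read a multi-page grayscale TIFF as an ImageStack."""
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # tifffile raises assorted errors on corruption
        size = os.path.getsize(path) if os.path.exists(path) else 0
        raise ParseError(
            f"could not parse TIFF {path!r} (file size {size} bytes): {exc}"
        ) from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None, ...]
    if data.ndim != 3:
        raise UnsupportedFormatError(
            f"unsupported TIFF axis layout with shape {data.shape}; "
            "expected single-channel (T, H, W) or (H, W)"
        )
    if data.shape[-1] in (3, 4) and data.ndim == 3 and data.shape[-1] < min(data.shape[:2]):
        raise UnsupportedFormatError(
            f"input looks RGB(A) with shape {data.shape}; only grayscale is supported"
        )
    return ImageStack(data=data, pixel_size_um=pixel_size_um, frame_interval_s=frame_interval_s)


def write_stack(stack: ImageStack, path) -> None:
    """Write an ImageStack as a multi-page TIFF (dtype preserved)."""
    # explicit photometric so 3/4-frame stacks are never stored as RGB planes
    tifffile.imwrite(path, stack.data, photometric="minisblack")


def write_tracks(coll: TrackCollection, hyps_by_id: dict[int, BlobHypothesis], path) -> None:
    """Write a track collection in the tracks CSV schema."""
    rows = []
    for cid, tr in enumerate(coll.trajectories):
        for f, h in tr.elements:
            e = hyps_by_id[h].ellipse
            rows.append((f, cid, e.cx, e.cy, e.a, e.b, wrap_orientation(e.theta)))
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6g")


def read_tracks(path):
    """Read a tracks CSV.

    Returns (collection, hyps_by_id): a TrackCollection view of the file
    plus synthesised hypotheses (support 1.0) carrying the ellipses, so the
    result can be fed to evaluation and morphometrics uniformly.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"could not parse tracks CSV {path!r}: {exc}") from exc
    for col in TRACK_COLUMNS:
        if col not in df.columns:
            raise InvalidInputError(f"tracks CSV is missing required column {col!r}")
    hyps_by_id: dict[int, BlobHypothesis] = {}
    trajectories = []
    next_hid = 0
    for cid, g in df.groupby("cell_id", sort=True):
        g = g.sort_values("frame")
        frames = g["frame"].to_numpy(dtype=int)
        if len(frames) > 1 and not np.array_equal(frames, np.arange(frames[0], frames[-1] + 1)):
            raise InvalidInputError(
                f"cell_id {cid}: frames are not contiguous ({frames.tolist()})"
            )
        if frames.min() < 0:
            raise InvalidInputError("frames must be 0-based and non-negative")
        ids = []
        for _, row in g.iterrows():
            e = Ellipse(
                cx=float(row.cx),
                cy=float(row.cy),
                a=float(row.a),
                b=float(row.b),
                theta=wrap_orientation(float(row.theta)),
            )
            hyps_by_id[next_hid] = BlobHypothesis(
                id=next_hid, frame=int(row.frame), ellipse=e, support=1.0
            )
            ids.append(next_hid)
            next_hid += 1
        trajectories.append(Trajectory(t0=int(frames[0]), hyp_ids=tuple(ids)))
    return TrackCollection(trajectories=tuple(trajectories)), hyps_by_id


def write_hypotheses(hyps: list[BlobHypothesis], path) -> None:
    """Write blob hypotheses as CSV: frame,id,cx,cy,a,b,theta,support."""
    rows = [
        (h.frame, h.id, h.ellipse.cx, h.ellipse.cy, h.ellipse.a, h.ellipse.b, h.ellipse.theta, h.support)
        for h in hyps
    ]
    df = pd.DataFrame(rows, columns=HYPOTHESIS_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6g")


def read_hypotheses(path) -> list[BlobHypothesis]:
    """Read blob hypotheses from the CSV schema written by write_hypotheses."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"could not parse hypotheses CSV {path!r}: {exc}") from exc
    for col in HYPOTHESIS_COLUMNS:
        if col not in df.columns:
            raise InvalidInputError(f"hypotheses CSV is missing required column {col!r}")
    out = []
    for _, row in df.iterrows():
        out.append(
            BlobHypothesis(
                id=int(row.id),
                frame=int(row.frame),
                ellipse=Ellipse(
                    cx=float(row.cx), cy=float(row.cy), a=float(row.a), b=float(row.b),
                    theta=wrap_orientation(float(row.theta)),
                ),
                support=float(row.support),
            )
        )
    return out
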
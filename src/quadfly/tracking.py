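"""Blob detection and track linking for multi-fly video.

Flies appear as small dark blobs on a bright infrared background.  Tracking
deliberately does NOT maintain identity through occlusion: when two flies
intersect, their previously continuous tracks are considered completed and
new, independent tracks are begun once they move apart.  A continuously
labelled track is therefore guaranteed to come from a single fly, which is
what the quadrant-count statistics require; it is the identity guarantee
that matters, not long tracks.

Linking is greedy mutual-nearest-neighbour within a gate distance.  A merge
(two flies intersecting) is declared when either (a) a detection's area
exceeds ``merge_area_factor`` times the running median single-fly area, or
(b) one detection is the only gated candidate of two or more active tracks.
All tracks involved in a merge are terminated and the merged blob is kept
for bookkeeping only -- it contributes no position to any fly track, since
the identity of the flies inside it is unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .geometry import ArenaGeometry

__all__ = [
    "BlobDetection",
    "DetectionParams",
    "LinkParams",
    "Track",
    "TrackSet",
    "detect_blobs",
    "filter_tracks",
    "link_detections",
]


@dataclass(frozen=True)
class BlobDetection:
    """One detected fly candidate: frame index, pixel centroid, area (px^2).

    ``x`` is the column and ``y`` the row of the intensity-weighted
    centroid, both in pixels with the top-left image origin.
    """

    frame: int
    x: float
    y: float
    area: float


@dataclass(frozen=True)
class DetectionParams:
    """Thresholding and size gates for blob detection.

    ``threshold``: intensity below which a pixel is foreground (dark fly);
    None selects it per-frame by Otsu's method on the intensity histogram.
    ``min_area``/``max_area`` bound accepted component areas in px^2.
    """

    threshold: float | None = None
    min_area: int = 3
    max_area: int = 400

    def __post_init__(self) -> None:
        if not (0 < self.min_area <= self.max_area):
            raise ValueError("need 0 < min_area <= max_area")


@dataclass(frozen=True)
class LinkParams:
    """Gating and merge parameters for track linking.

    ``gate_distance_px`` is the largest per-frame displacement accepted as
    the same fly; the default derives from a maximum walking speed of
    ``max_speed_cm_s`` when built via :meth:`for_arena`.
    """

    gate_distance_px: float = 10.0
    merge_area_factor: float = 1.8

    @classmethod
    def for_arena(
        cls,
        arena: ArenaGeometry,
        frame_rate: float,
        max_speed_cm_s: float = 3.0,
        merge_area_factor: float = 1.8,
    ) -> "LinkParams":
        gate = max_speed_cm_s * arena.px_per_cm / frame_rate
        return cls(gate_distance_px=max(gate, 2.0), merge_area_factor=merge_area_factor)


@dataclass
class Track:
    """A contiguous single-fly track.

    Positions are physical cm; frames run ``start_frame`` .. ``start_frame
    + len(xy) - 1`` with no gaps.  A track id never reappears after the
    track terminates.
    """

    id: int
    start_frame: int
    xy: np.ndarray  # (n, 2) cm
    sex: str | None = None

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.xy)

    @property
    def frames(self) -> np.ndarray:
        return self.start_frame + np.arange(len(self.xy))


@dataclass
class TrackSet:
    """A collection of tracks plus the recording context they live in."""

    tracks: list[Track]
    frame_rate: float
    arena: ArenaGeometry
    merged_blobs: list[BlobDetection] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return sum(len(t) for t in self.tracks)

    @property
    def duration(self) -> float:
        """Recording duration in s (last frame + 1 over the frame rate)."""
        if not self.tracks:
            return 0.0
        last = max(t.start_frame + len(t) - 1 for t in self.tracks)
        return (last + 1) / self.frame_rate

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy samples table: track_id, frame, t_s, x_cm, y_cm, sex."""
        if not self.tracks:
            return pd.DataFrame(
                columns=["track_id", "frame", "t_s", "x_cm", "y_cm", "sex"]
            )
        parts = []
        for t in self.tracks:
            frames = t.frames
            parts.append(
                pd.DataFrame(
                    {
                        "track_id": t.id,
                        "frame": frames,
                        "t_s": frames / self.frame_rate,
                        "x_cm": t.xy[:, 0],
                        "y_cm": t.xy[:, 1],
                        "sex": t.sex if t.sex is not None else "unknown",
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, frame_rate: float, arena: ArenaGeometry
    ) -> "TrackSet":
        required = {"track_id", "frame", "x_cm", "y_cm"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
        tracks = []
        for tid, g in df.groupby("track_id", sort=True):
            g = g.sort_values("frame")
            frames = g["frame"].to_numpy()
            if len(frames) > 1 and not np.all(np.diff(frames) == 1):
                raise ValueError(f"track {tid} has non-consecutive frames")
            sex = None
            if "sex" in g.columns:
                s = g["sex"].iloc[0]
                sex = None if s in ("unknown", "", None) else str(s)
            tracks.append(
                Track(
                    id=int(tid),
                    start_frame=int(frames[0]),
                    xy=g[["x_cm", "y_cm"]].to_numpy(),
                    sex=sex,
                )
            )
        return cls(tracks=tracks, frame_rate=frame_rate, arena=arena)


def detect_blobs(
    frame: np.ndarray, params: DetectionParams, frame_index: int = 0
) -> list[BlobDetection]:
    """Detect dark fly blobs in one grayscale frame.

    Connected components of the below-threshold (dark) pixels are filtered
    by area and reported by intensity-weighted centroid, where weight is
    darkness (inverted intensity).
    """
    img = np.asarray(frame)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("frame must be a non-empty 2-D grayscale image")
    thr = params.threshold
    if thr is None:
        if img.min() == img.max():  # uniform frame: nothing to segment
            return []
        thr = threshold_otsu(img)
    mask = img < thr
    if not mask.any():
        return []
    inverted = (float(img.max()) - img.astype(float)) * mask
    out = []
    for region in regionprops(cc_label(mask, connectivity=2), intensity_image=inverted):
        if params.min_area <= region.area <= params.max_area:
            row, col = region.centroid_weighted
            out.append(
                BlobDetection(
                    frame=frame_index, x=float(col), y=float(row), area=float(region.area)
                )
            )
    return out


class _ActiveTrack:
    __slots__ = ("id", "start_frame", "points", "last")

    def __init__(self, tid: int, frame: int, det: BlobDetection):
        self.id = tid
        self.start_frame = frame
        self.points = [(det.x, det.y)]
        self.last = det


def link_detections(
    detections_by_frame: list[list[BlobDetection]],
    params: LinkParams,
    arena: ArenaGeometry,
    frame_rate: float,
) -> TrackSet:
    """Link per-frame detections into continuous single-fly tracks.

    ``detections_by_frame[i]`` holds the detections of frame ``i`` (the
    list is ordered by frame; detections carrying a different ``frame``
    attribute than their slot raise).  See the module docstring for the
    assignment and merge rules.  Track ids increase in order of creation.
    """
    for i, dets in enumerate(detections_by_frame):
        for d in dets:
            if d.frame != i:
                raise ValueError(
                    f"detection frame {d.frame} out of order (expected {i})"
                )

    finished: list[Track] = []
    merged: list[BlobDetection] = []
    active: list[_ActiveTrack] = []
    area_history: list[float] = []
    next_id = 0

    def close(tr: _ActiveTrack) -> None:
        xy_px = np.asarray(tr.points)
        x_cm, y_cm = arena.px_to_cm(xy_px[:, 1], xy_px[:, 0])
        finished.append(
            Track(id=tr.id, start_frame=tr.start_frame, xy=np.column_stack([x_cm, y_cm]))
        )

    for frame_idx, dets in enumerate(detections_by_frame):
        n_act, n_det = len(active), len(dets)
        assigned_det: set[int] = set()
        matched_tracks: set[int] = set()
        merge_dets: set[int] = set()

        if n_det:
            median_area = float(np.median(area_history)) if area_history else None
            # area-based merge flag
            for j, d in enumerate(dets):
                if (
                    median_area is not None
                    and d.area > params.merge_area_factor * median_area
                ):
                    merge_dets.add(j)

        if n_act and n_det:
            tp = np.array([t.last.x for t in active]), np.array(
                [t.last.y for t in active]
            )
            dp = np.array([d.x for d in dets]), np.array([d.y for d in dets])
            dist = np.hypot(
                tp[0][:, None] - dp[0][None, :], tp[1][:, None] - dp[1][None, :]
            )
            gated = dist <= params.gate_distance_px

            # two-tracks-one-candidate merge flag
            sole = {}
            for i in range(n_act):
                js = np.nonzero(gated[i])[0]
                if len(js) == 1:
                    sole.setdefault(int(js[0]), []).append(i)
            for j, tracks_i in sole.items():
                if len(tracks_i) >= 2:
                    merge_dets.add(j)

            # terminate every track gated to a merge blob
            merge_victims = set()
            for j in merge_dets:
                merge_victims.update(np.nonzero(gated[:, j])[0].tolist())

            # greedy mutual nearest neighbour on the remainder
            cand = dist.copy()
            cand[~gated] = np.inf
            for j in merge_dets:
                cand[:, j] = np.inf
            for i in merge_victims:
                cand[i, :] = np.inf
            while np.isfinite(cand).any():
                i, j = np.unravel_index(np.argmin(cand), cand.shape)
                active[i].points.append((dets[j].x, dets[j].y))
                active[i].last = dets[j]
                matched_tracks.add(i)
                assigned_det.add(int(j))
                area_history.append(dets[j].area)
                cand[i, :] = np.inf
                cand[:, j] = np.inf
            matched_tracks |= set()  # victims handled below
            for i in merge_victims:
                matched_tracks.discard(i)

        # close unmatched / merge-terminated tracks
        survivors = []
        for i, tr in enumerate(active):
            if i in matched_tracks:
                survivors.append(tr)
            else:
                close(tr)
        active = survivors

        # record merged blobs (bookkeeping only)
        for j in sorted(merge_dets):
            merged.append(dets[j])

        # open new tracks for unassigned, non-merge detections
        for j, d in enumerate(dets):
            if j in assigned_det or j in merge_dets:
                continue
            active.append(_ActiveTrack(next_id, frame_idx, d))
            area_history.append(d.area)
            next_id += 1

    for tr in active:
        close(tr)
    finished.sort(key=lambda t: t.id)
    return TrackSet(
        tracks=finished, frame_rate=frame_rate, arena=arena, merged_blobs=merged
    )


def filter_tracks(ts: TrackSet, min_length_frames: int) -> TrackSet:
    """Drop tracks shorter than ``min_length_frames``; survivors unchanged."""
    if min_length_frames < 1:
        raise ValueError("min_length_frames must be >= 1")
    return TrackSet(
        tracks=[t for t in ts.tracks if len(t) >= min_length_frames],
        frame_rate=ts.frame_rate,
        arena=ts.arena,
        merged_blobs=list(ts.merged_blobs),
    )
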
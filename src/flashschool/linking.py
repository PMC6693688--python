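"""Frame-to-frame linking of detections into per-fish tracks.

Linking is globally greedy by distance (a Crocker–Grier-style nearest-match
rule without global optimisation): at each frame, the closest (open track,
detection) pair within the allowed radius is matched first, each track and
detection used at most once. Unmatched detections open new tracks; tracks
unseen for more than ``max_gap`` frames are closed. Because only flashing
fish are detectable, ``max_gap`` can be raised to bridge off-phases when the
goal is flash kinetics rather than strict per-flash tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidConfigError

__all__ = ["LinkConfig", "Track", "link_frame", "build_tracks", "tracks_to_dataframe"]


@dataclass
class LinkConfig:
    max_radius: float  # px per frame of elapsed gap
    max_gap: int = 0
    min_track_length: int = 2

    def __post_init__(self) -> None:
        if not self.max_radius > 0:
            raise InvalidConfigError("max_radius must be > 0")
        if self.max_gap < 0:
            raise InvalidConfigError("max_gap must be >= 0")
        if self.min_track_length < 1:
            raise InvalidConfigError("min_track_length must be >= 1")


@dataclass
class Track:
    """One fish's linked detections."""

    track_id: int
    frames: list[int] = field(default_factory=list)
    rows: list[float] = field(default_factory=list)
    cols: list[float] = field(default_factory=list)
    areas: list[int] = field(default_factory=list)
    peaks: list[float] = field(default_factory=list)

    def append(self, frame: int, row: float, col: float, area: int, peak: float) -> None:
        if self.frames and frame <= self.frames[-1]:
            raise InvalidConfigError("track frames must be strictly increasing")
        self.frames.append(int(frame))
        self.rows.append(float(row))
        self.cols.append(float(col))
        self.areas.append(int(area))
        self.peaks.append(float(peak))

    @property
    def last_frame(self) -> int:
        return self.frames[-1]

    @property
    def last_position(self) -> np.ndarray:
        return np.array([self.rows[-1], self.cols[-1]])

    def __len__(self) -> int:
        return len(self.frames)


def link_frame(
    open_tracks: list[Track],
    detections: pd.DataFrame,
    frame: int,
    config: LinkConfig,
) -> list[Track]:
    """Greedily match ``detections`` (all from ``frame``) to ``open_tracks``.

    A track last seen at frame t0 may move at most max_radius·(frame − t0),
    i.e. max_radius per elapsed frame. Returns newly created tracks;
    matched tracks are extended in place.
    """
    new_tracks: list[Track] = []
    det = detections.reset_index(drop=True)
    if len(open_tracks) and len(det):
        track_pos = np.array([t.last_position for t in open_tracks])
        det_pos = det[["row", "col"]].to_numpy(dtype=float)
        dist = np.linalg.norm(track_pos[:, None, :] - det_pos[None, :, :], axis=2)
        allowed = np.array(
            [config.max_radius * (frame - t.last_frame) for t in open_tracks]
        )
        dist = np.where(dist <= allowed[:, None], dist, np.inf)
        used_tracks = np.zeros(len(open_tracks), dtype=bool)
        used_dets = np.zeros(len(det), dtype=bool)
        while True:
            i, j = np.unravel_index(np.argmin(dist), dist.shape)
            if not np.isfinite(dist[i, j]):
                break
            row = det.iloc[j]
            open_tracks[i].append(frame, row["row"], row["col"], row["area"], row["peak"])
            used_tracks[i] = True
            used_dets[j] = True
            dist[i, :] = np.inf
            dist[:, j] = np.inf
    else:
        used_dets = np.zeros(len(det), dtype=bool)
    for j in np.flatnonzero(~used_dets):
        row = det.iloc[j]
        t = Track(track_id=-1)  # id assigned by build_tracks
        t.append(frame, row["row"], row["col"], row["area"], row["peak"])
        new_tracks.append(t)
    return new_tracks


def build_tracks(detections: pd.DataFrame, config: LinkConfig) -> list[Track]:
    """Link a full detection table (sorted or not) into tracks.

    Deterministic for a fixed input; tracks shorter than
    ``min_track_length`` are dropped.
    """
    cols = {"frame", "row", "col", "area", "peak"}
    if not cols.issubset(detections.columns):
        raise InvalidConfigError(f"detections must have columns {sorted(cols)}")
    if detections.empty:
        return []
    detections = detections.sort_values("frame")
    open_tracks: list[Track] = []
    closed: list[Track] = []
    next_id = 0
    for frame, det in detections.groupby("frame"):
        frame = int(frame)
        still_open = []
        for t in open_tracks:
            # gap = frames skipped since last sample
            if frame - t.last_frame - 1 > config.max_gap:
                closed.append(t)
            else:
                still_open.append(t)
        open_tracks = still_open
        for t in link_frame(open_tracks, det, frame, config):
            t.track_id = next_id
            next_id += 1
            open_tracks.append(t)
    closed.extend(open_tracks)
    kept = [t for t in closed if len(t) >= config.min_track_length]
    kept.sort(key=lambda t: (t.frames[0], t.track_id))
    for new_id, t in enumerate(kept):
        t.track_id = new_id
    return kept


def tracks_to_dataframe(tracks: list[Track]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for k in range(len(t)):
            rows.append((t.track_id, t.frames[k], t.rows[k], t.cols[k], t.areas[k], t.peaks[k]))
    return pd.DataFrame(rows, columns=["track_id", "frame", "row", "col", "area", "peak"])
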
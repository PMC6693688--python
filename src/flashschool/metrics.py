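"""School-synchrony statistics.

``mSync`` is the polarization order parameter of collective motion: the
magnitude of the mean velocity divided by the mean speed, 0 for an
unpolarised shoal and 1 for an ideally polarised school. The direction
correlation quantifies how well the school aligns with motivated leader
fish. Both are dimension-agnostic (2-D velocities from video tracks, 3-D
from the model).

Also here: a random-motion null model for mSync and a Wilcoxon rank-sum
test with an exact small-sample branch (enumeration over rank splits) and a
tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidConfigError, UndefinedValueError
from .simulate import SchoolTrajectory

__all__ = [
    "msync",
    "kinematics_series",
    "track_velocities",
    "direction_correlation",
    "direction_correlation_series",
    "random_motion_null",
    "RankSumResult",
    "rank_sum_test",
]


def msync(velocities: np.ndarray) -> float:
    """|mean velocity| / mean speed for one frame's velocity vectors.

    Accepts an (n, d) array for any d >= 1. Raises if every speed is zero
    (the metric is undefined for a school at rest).
    """
    v = np.atleast_2d(np.asarray(velocities, dtype=float))
    speeds = np.linalg.norm(v, axis=1)
    mean_speed = speeds.mean()
    if mean_speed == 0:
        raise UndefinedValueError("mSync undefined: all speeds are zero")
    return float(np.linalg.norm(v.mean(axis=0)) / mean_speed)


def track_velocities(tracks: pd.DataFrame, fps: float) -> pd.DataFrame:
    """Forward-difference velocities (px/s) from linked track centroids.

    Expects columns track_id, frame, row, col. A fish contributes a velocity
    at frame n only if it is also tracked at frame n+1.
    """
    rows = []
    for tid, grp in tracks.sort_values("frame").groupby("track_id"):
        f = grp["frame"].to_numpy()
        p = grp[["row", "col"]].to_numpy(dtype=float)
        consec = np.diff(f) == 1
        v = (p[1:] - p[:-1]) * fps
        rows.append(
            pd.DataFrame(
                {
                    "track_id": tid,
                    "frame": f[:-1][consec],
                    "vrow": v[consec, 0],
                    "vcol": v[consec, 1],
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["track_id", "frame", "vrow", "vcol"])
    return pd.concat(rows, ignore_index=True)


def kinematics_series(
    trajectory: SchoolTrajectory | pd.DataFrame, fps: float | None = None
) -> pd.DataFrame:
    """Per-frame mean speed and mSync.

    For a :class:`SchoolTrajectory` the stored velocities are used; for a
    track table (track_id, frame, row, col) velocities are finite-differenced
    at ``fps``. Frames with no moving fish get NaN mSync and are counted with
    ``n_fish`` contributing fish.
    """
    if isinstance(trajectory, SchoolTrajectory):
        T = trajectory.n_frames
        if T < 2:
            raise InvalidConfigError("trajectory must have >= 2 frames")
        records = []
        for n in range(T):
            v = trajectory.velocities[n]
            speeds = np.linalg.norm(v, axis=1)
            mean_speed = float(speeds.mean())
            val = msync(v) if mean_speed > 0 else np.nan
            records.append((n, mean_speed, val, v.shape[0]))
        return pd.DataFrame(records, columns=["frame", "mean_speed", "msync", "n_fish"])

    if fps is None:
        raise InvalidConfigError("fps is required for track tables")
    vel = track_velocities(trajectory, fps)
    if vel.empty:
        raise InvalidConfigError("no linked velocities in track table")
    records = []
    for n, grp in vel.groupby("frame"):
        v = grp[["vrow", "vcol"]].to_numpy()
        speeds = np.linalg.norm(v, axis=1)
        mean_speed = float(speeds.mean())
        val = msync(v) if mean_speed > 0 else np.nan
        records.append((n, mean_speed, val, len(grp)))
    return pd.DataFrame(records, columns=["frame", "mean_speed", "msync", "n_fish"])


def direction_correlation(velocities: np.ndarray, v_leader: np.ndarray) -> float:
    """Σ⟨v_L, v_i⟩ / (|v_L| Σ|v_i|): alignment of the school with a leader.

    The value lies in [−1, 1]; fish anti-aligned with the leader contribute
    negative terms, so the metric can go negative. Invariant to rescaling of
    v_L.
    """
    v = np.atleast_2d(np.asarray(velocities, dtype=float))
    vL = np.asarray(v_leader, dtype=float)
    nL = np.linalg.norm(vL)
    total_speed = np.linalg.norm(v, axis=1).sum()
    if nL == 0 or total_speed == 0:
        raise UndefinedValueError("direction correlation undefined for zero-magnitude input")
    return float((v @ vL).sum() / (nL * total_speed))


def direction_correlation_series(
    trajectory: SchoolTrajectory, leader_ids: np.ndarray
) -> pd.DataFrame:
    """Per-frame direction correlation of the non-leader fish against the
    leaders' mean velocity (the leaders' average when there are several)."""
    leaders = np.asarray(leader_ids, dtype=int)
    if leaders.size == 0:
        raise InvalidConfigError("leader_ids must be non-empty")
    others = np.setdiff1d(np.arange(trajectory.n_agents), leaders)
    records = []
    for n in range(trajectory.n_frames):
        vL = trajectory.velocities[n, leaders].mean(axis=0)
        v = trajectory.velocities[n, others]
        try:
            val = direction_correlation(v, vL)
        except UndefinedValueError:
            val = np.nan
        records.append((n, val))
    return pd.DataFrame(records, columns=["frame", "direction_correlation"])


def random_motion_null(
    speed_samples: np.ndarray,
    n_fish: int,
    n_frames: int,
    seed: int = 0,
    dim: int = 3,
    dt: float = 1.0 / 30.0,
) -> SchoolTrajectory:
    """Null model for mSync: every fish-frame gets an independent uniformly
    random direction and a speed resampled from ``speed_samples``. Frame-wise
    mSync concentrates near 0 at rate ~ n_fish^(−1/2)."""
    speed_samples = np.asarray(speed_samples, dtype=float)
    if speed_samples.size == 0:
        raise InvalidConfigError("speed_samples must be non-empty")
    if dim not in (2, 3):
        raise InvalidConfigError("dim must be 2 or 3")
    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(n_frames, n_fish, dim))
    norms = np.linalg.norm(dirs, axis=2, keepdims=True)
    norms[norms == 0] = 1.0
    dirs /= norms
    speeds = rng.choice(speed_samples, size=(n_frames, n_fish))
    vel = np.zeros((n_frames, n_fish, 3))
    vel[:, :, :dim] = dirs * speeds[:, :, None]
    pos = np.zeros_like(vel)
    pos[1:] = np.cumsum(vel[:-1] * dt, axis=0)
    shape = (n_frames, n_fish)
    return SchoolTrajectory(
        positions=pos,
        velocities=vel,
        flashing=np.ones(shape, dtype=bool),
        dark=np.zeros(shape, dtype=bool),
        motivated=np.zeros(shape, dtype=bool),
        dt=dt,
    )


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank-sum (midranks) of the smaller sample
    p_value: float
    method: str  # "exact" or "normal-approximation"


def rank_sum_test(sample_a, sample_b) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    The statistic is the midrank sum of the smaller sample. When both
    samples have n <= 8 the null is enumerated exactly over all rank splits;
    otherwise a normal approximation with tie-corrected variance and a
    continuity correction is used.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidConfigError("both samples must be non-empty")
    if a.size > b.size:
        a, b = b, a
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1, n2 = a.size, b.size
    N = n1 + n2
    w_obs = float(ranks[:n1].sum())
    mu = n1 * (N + 1) / 2.0

    if n1 <= 8 and n2 <= 8:
        dev = abs(w_obs - mu)
        hits = 0
        for idx in combinations(range(N), n1):
            w = ranks[list(idx)].sum()
            if abs(w - mu) >= dev - 1e-9:
                hits += 1
        p = hits / comb(N, n1)
        return RankSumResult(statistic=w_obs, p_value=min(1.0, p), method="exact")

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (N * (N - 1)))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var == 0:
        return RankSumResult(statistic=w_obs, p_value=1.0, method="normal-approximation")
    diff = w_obs - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return RankSumResult(statistic=w_obs, p_value=p, method="normal-approximation")
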
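"""3-D agent-based model of a bioluminescent fish school.

Each simulated fish carries a position ``r``, velocity ``v`` and acceleration
``a`` in an unbounded 3-D space measured in body lengths. Motion is driven by
three social forces — cohesion, alignment and separation — plus internal
friction and speed-control forces, each with a scalar weight. Every social
force has its own region of vision (a sphere with blind cones fore and/or
aft), and, crucially for flashlight fish, a neighbour only contributes to a
flash-gated force while it is flashing: a non-flashing fish is invisible.

Flashing is controlled by two parameters. ``P`` is the per-frame probability
that a (non-dark) fish flashes; in nature P ≈ 0.5 since the duty cycle is
about 50%. ``D`` is the probability that a fish is "dark" — assigned a
uniform draw R at initialisation, a fish is dark while R < D and never
flashes. A square-wave flash mode with configurable on/off durations is also
provided.

Integration is synchronous explicit Euler: every fish is updated from the
previous frame's state, ``a = f_tot`` (unit mass), ``v ← clamp(v + a·dt)``,
``r ← r + v·dt``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateGeometryError,
    InvalidConfigError,
    NumericFailureError,
)

__all__ = [
    "VisionRegion",
    "SimConfig",
    "AgentState",
    "SchoolTrajectory",
    "SchoolSimulator",
    "visible_neighbors",
    "cohesion_force",
    "alignment_force",
    "separation_force",
    "internal_forces",
    "init_school",
    "run_simulation",
]


@dataclass(frozen=True)
class VisionRegion:
    """Spherical vision region with blind cones.

    ``blind_behind_deg`` / ``blind_front_deg`` are *full* apex angles of the
    excluded cones centred on −v and +v respectively. A fish at rest has no
    heading, so no blind cone is applied to it that frame.
    """

    radius: float
    blind_behind_deg: float = 0.0
    blind_front_deg: float = 0.0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise InvalidConfigError(f"vision radius must be > 0, got {self.radius}")
        for ang in (self.blind_behind_deg, self.blind_front_deg):
            if not (0 <= ang < 360):
                raise InvalidConfigError(f"blind-cone angle must be in [0, 360), got {ang}")


# Default regions: cohesion reaches furthest and excludes a 90° cone behind;
# separation is short range and excludes 60° behind; alignment (lateral-line
# mediated) covers the flanks only, excluding 60° cones fore and aft, at an
# intermediate range.
DEFAULT_COHESION_REGION = VisionRegion(radius=10.0, blind_behind_deg=90.0)
DEFAULT_ALIGNMENT_REGION = VisionRegion(radius=3.0, blind_behind_deg=60.0, blind_front_deg=60.0)
DEFAULT_SEPARATION_REGION = VisionRegion(radius=1.0, blind_behind_deg=60.0)


@dataclass
class SimConfig:
    """Full parameterisation of a school simulation.

    Weights default to the field-calibrated values w_c=7, w_a=6, w_s=9 with
    internal weights w_f=1.05 (friction) and w_v=5 (speed control). Distances
    are in body lengths, time in seconds; dt defaults to 1/30 s to mirror
    30 fps recordings. v_max is the hard speed cap; v_cruise the preferred
    speed regulated by the speed-control force (default 0.8·v_max).
    """

    n_fish: int = 100
    w_c: float = 7.0
    w_a: float = 6.0
    w_s: float = 9.0
    w_f: float = 1.05
    w_v: float = 5.0
    v_max: float = 2.0
    v_cruise: float | None = None
    dt: float = 1.0 / 30.0
    P: float = 0.5
    D: float = 0.0
    cohesion_region: VisionRegion = DEFAULT_COHESION_REGION
    alignment_region: VisionRegion = DEFAULT_ALIGNMENT_REGION
    separation_region: VisionRegion = DEFAULT_SEPARATION_REGION
    init_half_width: float = 10.0
    flash_mode: str = "bernoulli"
    flash_on_s: float = 0.166
    flash_off_s: float = 0.168
    flash_gates_all_forces: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.v_cruise is None:
            self.v_cruise = 0.8 * self.v_max
        if self.n_fish < 1:
            raise InvalidConfigError(f"n_fish must be >= 1, got {self.n_fish}")
        for name in ("w_c", "w_a", "w_s", "w_f", "w_v"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        if not (0.0 <= self.P <= 1.0):
            raise InvalidConfigError(f"P must be in [0, 1], got {self.P}")
        if not (0.0 <= self.D <= 1.0):
            raise InvalidConfigError(f"D must be in [0, 1], got {self.D}")
        if not self.dt > 0:
            raise InvalidConfigError("dt must be > 0")
        if not self.v_max > 0:
            raise InvalidConfigError("v_max must be > 0")
        if self.flash_mode not in ("bernoulli", "square_wave"):
            raise InvalidConfigError(f"unknown flash_mode {self.flash_mode!r}")
        if self.flash_mode == "square_wave" and not (self.flash_on_s > 0 and self.flash_off_s > 0):
            raise InvalidConfigError("square-wave on/off durations must be > 0")

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("cohesion_region", "alignment_region", "separation_region"):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = VisionRegion(**raw[key])
        return cls(**raw)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


@dataclass
class AgentState:
    """One simulated fish (single-agent view used by the force functions)."""

    position: np.ndarray
    velocity: np.ndarray
    acceleration: np.ndarray = field(default_factory=lambda: np.zeros(3))
    is_dark: bool = False
    is_flashing: bool = False
    is_motivated: bool = False
    motivated_direction: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.acceleration = np.asarray(self.acceleration, dtype=float)


@dataclass
class SchoolTrajectory:
    """Per-frame state of every agent: the common schema for model output and
    for tracked (real or synthetic) video once lifted to velocities."""

    positions: np.ndarray  # (T, n, 3)
    velocities: np.ndarray  # (T, n, 3)
    flashing: np.ndarray  # (T, n) bool
    dark: np.ndarray  # (T, n) bool
    motivated: np.ndarray  # (T, n) bool
    dt: float

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_agents(self) -> int:
        return self.positions.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        T, n, _ = self.positions.shape
        frames = np.repeat(np.arange(T), n)
        agents = np.tile(np.arange(n), T)
        pos = self.positions.reshape(-1, 3)
        vel = self.velocities.reshape(-1, 3)
        return pd.DataFrame(
            {
                "frame": frames,
                "agent_id": agents,
                "x": pos[:, 0],
                "y": pos[:, 1],
                "z": pos[:, 2],
                "vx": vel[:, 0],
                "vy": vel[:, 1],
                "vz": vel[:, 2],
                "flashing": self.flashing.reshape(-1).astype(int),
                "dark": self.dark.reshape(-1).astype(int),
                "motivated": self.motivated.reshape(-1).astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, dt: float) -> "SchoolTrajectory":
        df = df.sort_values(["frame", "agent_id"])
        T = df["frame"].nunique()
        n = df["agent_id"].nunique()
        if len(df) != T * n:
            raise InvalidConfigError("trajectory table must have a constant agent count per frame")
        shape = (T, n)
        return cls(
            positions=df[["x", "y", "z"]].to_numpy().reshape(T, n, 3),
            velocities=df[["vx", "vy", "vz"]].to_numpy().reshape(T, n, 3),
            flashing=df["flashing"].to_numpy().reshape(shape).astype(bool),
            dark=df["dark"].to_numpy().reshape(shape).astype(bool),
            motivated=df["motivated"].to_numpy().reshape(shape).astype(bool),
            dt=dt,
        )

    @classmethod
    def from_csv(cls, path, dt: float) -> "SchoolTrajectory":
        return cls.from_dataframe(pd.read_csv(path), dt=dt)


def _unit(vec: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(vec)
    if norm == 0:
        return np.zeros_like(vec)
    return vec / norm


def visible_neighbors(
    focal: AgentState,
    school: Sequence[AgentState],
    region: VisionRegion,
    flash_gated: bool = True,
) -> list[AgentState]:
    """Neighbours of ``focal`` inside ``region``, excluding blind cones and,
    when ``flash_gated``, excluding non-flashing (invisible) fish.

    A focal fish at rest has no heading, so the blind cones are skipped.
    """
    speed = np.linalg.norm(focal.velocity)
    heading = focal.velocity / speed if speed > 0 else None
    cos_behind = np.cos(np.deg2rad(region.blind_behind_deg / 2.0))
    cos_front = np.cos(np.deg2rad(region.blind_front_deg / 2.0))
    out: list[AgentState] = []
    for other in school:
        if other is focal:
            continue
        if flash_gated and not other.is_flashing:
            continue
        d = other.position - focal.position
        dist = np.linalg.norm(d)
        if dist > region.radius:
            continue
        if heading is not None and dist > 0:
            cos_bearing = float(d @ heading) / dist
            if region.blind_behind_deg > 0 and cos_bearing < -cos_behind:
                continue
            if region.blind_front_deg > 0 and cos_bearing > cos_front:
                continue
        out.append(other)
    return out


def cohesion_force(focal: AgentState, visible: Sequence[AgentState], v_max: float) -> np.ndarray:
    """Steer toward the centroid of visible fish: unit(s_c)·v_max − v with
    s_c the centroid of visible positions relative to the focal fish.

    Empty neighbourhood or a zero s-vector contributes the zero vector.
    """
    if len(visible) == 0:
        return np.zeros(3)
    centroid = np.mean([a.position for a in visible], axis=0)
    s_c = centroid - focal.position
    if np.linalg.norm(s_c) == 0:
        return np.zeros(3)
    return _unit(s_c) * v_max - focal.velocity


def alignment_force(focal: AgentState, visible: Sequence[AgentState], v_max: float) -> np.ndarray:
    """Steer toward the mean heading of visible fish: unit(s_a)·v_max − v
    with s_a the mean of visible velocities."""
    if len(visible) == 0:
        return np.zeros(3)
    s_a = np.mean([a.velocity for a in visible], axis=0)
    if np.linalg.norm(s_a) == 0:
        return np.zeros(3)
    return _unit(s_a) * v_max - focal.velocity


def separation_force(focal: AgentState, visible: Sequence[AgentState], v_max: float) -> np.ndarray:
    """Steer away from close fish: s_s is the mean of (r − r_k)/|r − r_k|²,
    so nearer neighbours repel harder; force is unit(s_s)·v_max − v."""
    if len(visible) == 0:
        return np.zeros(3)
    terms = []
    for other in visible:
        d = focal.position - other.position
        dist2 = float(d @ d)
        if dist2 == 0:
            raise DegenerateGeometryError("separation undefined: coincident fish")
        terms.append(d / dist2)
    s_s = np.mean(terms, axis=0)
    if np.linalg.norm(s_s) == 0:
        return np.zeros(3)
    return _unit(s_s) * v_max - focal.velocity


def internal_forces(focal: AgentState, config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Pre-weight friction (linear drag −v) and speed control
    (unit(v)·(v_cruise − |v|); zero at rest)."""
    friction = -focal.velocity
    speed = np.linalg.norm(focal.velocity)
    if speed == 0:
        speed_control = np.zeros(3)
    else:
        speed_control = (focal.velocity / speed) * (config.v_cruise - speed)
    return friction, speed_control


class SchoolSimulator:
    """Vectorised engine for the school model.

    Holds the full state as arrays and advances it with synchronous Euler
    steps; all randomness comes from one generator seeded by the config, with
    per-agent draws in fixed agent order.
    """

    def __init__(self, config: SimConfig):
        self.config = config
        n = config.n_fish
        self.rng = np.random.default_rng(config.seed)
        self.frame = 0
        hw = config.init_half_width
        self.positions = self.rng.uniform(-hw, hw, size=(n, 3))
        self.velocities = np.zeros((n, 3))
        self.accelerations = np.zeros((n, 3))
        # Dark assignment: one uniform draw per fish at init; a fish is dark
        # while its draw is below the current D (constant D => fixed flag).
        self._dark_draw = self.rng.random(n)
        self.D = config.D
        self.P = config.P
        period = config.flash_on_s + config.flash_off_s
        self._period_frames = max(1, int(round(period / config.dt)))
        self._phase_frames = self.rng.integers(0, self._period_frames, size=n)
        self.motivated = np.zeros(n, dtype=bool)
        self.motivated_velocity = np.zeros((n, 3))
        self.flashing = self._draw_flashing(self.frame)

    # -- state views ---------------------------------------------------
    @property
    def n_fish(self) -> int:
        return self.config.n_fish

    @property
    def dark(self) -> np.ndarray:
        return self._dark_draw < self.D

    def agent_states(self) -> list[AgentState]:
        dark = self.dark
        return [
            AgentState(
                position=self.positions[i].copy(),
                velocity=self.velocities[i].copy(),
                acceleration=self.accelerations[i].copy(),
                is_dark=bool(dark[i]),
                is_flashing=bool(self.flashing[i]),
                is_motivated=bool(self.motivated[i]),
                motivated_direction=(
                    _unit(self.motivated_velocity[i]) if self.motivated[i] else None
                ),
            )
            for i in range(self.n_fish)
        ]

    # -- flashing ------------------------------------------------------
    def _draw_flashing(self, frame: int) -> np.ndarray:
        cfg = self.config
        if cfg.flash_mode == "bernoulli":
            draws = self.rng.random(self.n_fish)
            flashing = draws < self.P
        else:  # square_wave: deterministic per-agent phase schedule
            t_on_frames = cfg.flash_on_s / cfg.dt
            phase = (frame + self._phase_frames) % self._period_frames
            flashing = phase < t_on_frames
        return flashing & ~self.dark

    # -- forces (vectorised) --------------------------------------------
    def _region_mask(
        self,
        dist: np.ndarray,
        cos_bearing: np.ndarray,
        moving: np.ndarray,
        region: VisionRegion,
        gated: bool,
    ) -> np.ndarray:
        mask = dist <= region.radius
        np.fill_diagonal(mask, False)
        if gated:
            mask &= self.flashing[None, :]
        # blind cones apply only to moving focal fish at nonzero range
        if region.blind_behind_deg > 0:
            cb = np.cos(np.deg2rad(region.blind_behind_deg / 2.0))
            mask &= ~(moving[:, None] & (cos_bearing < -cb))
        if region.blind_front_deg > 0:
            cf = np.cos(np.deg2rad(region.blind_front_deg / 2.0))
            mask &= ~(moving[:, None] & (cos_bearing > cf))
        return mask

    def _social_force(self, s_vec: np.ndarray, counts: np.ndarray) -> np.ndarray:
        """unit(s)·v_max − v where defined, else zero."""
        norms = np.linalg.norm(s_vec, axis=1)
        ok = (counts > 0) & (norms > 0)
        force = np.zeros_like(s_vec)
        force[ok] = (
            s_vec[ok] / norms[ok, None] * self.config.v_max - self.velocities[ok]
        )
        return force

    def compute_forces(self) -> dict[str, np.ndarray]:
        """Per-agent force components (pre-weight) from the current state."""
        cfg = self.config
        R, V = self.positions, self.velocities
        n = self.n_fish
        diff = R[None, :, :] - R[:, None, :]  # diff[i, j] = r_j - r_i
        dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        speeds = np.linalg.norm(V, axis=1)
        moving = speeds > 0
        heading = np.zeros_like(V)
        heading[moving] = V[moving] / speeds[moving, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            cos_bearing = np.einsum("ijk,ik->ij", diff, heading) / dist
        cos_bearing = np.nan_to_num(cos_bearing)

        gate_lateral = cfg.flash_gates_all_forces
        m_c = self._region_mask(dist, cos_bearing, moving, cfg.cohesion_region, True)
        m_a = self._region_mask(dist, cos_bearing, moving, cfg.alignment_region, gate_lateral)
        m_s = self._region_mask(dist, cos_bearing, moving, cfg.separation_region, gate_lateral)

        c_c = m_c.sum(axis=1)
        c_a = m_a.sum(axis=1)
        c_s = m_s.sum(axis=1)

        with np.errstate(invalid="ignore"):
            s_c = m_c @ R / np.maximum(c_c, 1)[:, None] - R  # centroid - focal
            s_a = m_a @ V / np.maximum(c_a, 1)[:, None]
        if np.any(m_s & (dist == 0)):
            raise DegenerateGeometryError("separation undefined: coincident fish")
        inv2 = np.zeros_like(dist)
        nz = m_s & (dist > 0)
        inv2[nz] = 1.0 / dist[nz] ** 2
        # sum_j (r_i - r_j)/|r_i - r_j|^2 = r_i * sum_j w_ij - W @ R
        s_s = (R * inv2.sum(axis=1)[:, None] - inv2 @ R) / np.maximum(c_s, 1)[:, None]

        friction = -V
        speed_control = np.zeros_like(V)
        speed_control[moving] = heading[moving] * (cfg.v_cruise - speeds[moving])[:, None]

        return {
            "cohesion": self._social_force(s_c, c_c),
            "alignment": self._social_force(s_a, c_a),
            "separation": self._social_force(s_s, c_s),
            "friction": friction,
            "speed_control": speed_control,
        }

    # -- dynamics --------------------------------------------------------
    def step(self) -> None:
        """Advance one frame: forces from the previous frame only, Euler
        update with a hard speed clamp, then redraw flashing flags."""
        cfg = self.config
        f = self.compute_forces()
        total = (
            cfg.w_c * f["cohesion"]
            + cfg.w_a * f["alignment"]
            + cfg.w_s * f["separation"]
            + cfg.w_f * f["friction"]
            + cfg.w_v * f["speed_control"]
        )
        self.accelerations = total  # unit mass: a = f_tot
        v_new = self.velocities + total * cfg.dt
        speeds = np.linalg.norm(v_new, axis=1)
        over = speeds > cfg.v_max
        v_new[over] *= (cfg.v_max / speeds[over])[:, None]
        if np.any(self.motivated):
            v_new[self.motivated] = self.motivated_velocity[self.motivated]
        self.velocities = v_new
        self.positions = self.positions + v_new * cfg.dt
        if not (np.isfinite(self.positions).all() and np.isfinite(self.velocities).all()):
            raise NumericFailureError("simulation state became non-finite")
        self.frame += 1
        self.flashing = self._draw_flashing(self.frame)

    def set_motivated(
        self,
        agent_ids: Sequence[int],
        direction: Sequence[float],
        speed_factor: float = 1.5,
    ) -> None:
        """Flag agents as motivated leaders: from now on they move straight
        along ``direction`` at min(speed_factor·v_cruise, v_max), ignoring
        social forces. Leaders must not be dark — they lead by being seen."""
        ids = np.asarray(agent_ids, dtype=int)
        if ids.size == 0:
            raise InvalidConfigError("agent_ids must be non-empty")
        if np.any((ids < 0) | (ids >= self.n_fish)):
            raise InvalidConfigError("unknown agent id in agent_ids")
        if np.any(self.dark[ids]):
            raise InvalidConfigError("a dark fish cannot be a motivated leader")
        u = _unit(np.asarray(direction, dtype=float))
        if np.linalg.norm(u) == 0:
            raise InvalidConfigError("motivated direction must be nonzero")
        speed = min(speed_factor * self.config.v_cruise, self.config.v_max)
        self.motivated[ids] = True
        self.motivated_velocity[ids] = u * speed
        self.velocities[ids] = u * speed

    def set_dark_fraction(self, D: float) -> None:
        """Change D mid-run; agents keep their init draw R, so darkness is
        re-evaluated monotonically (dark iff R < D)."""
        if not (0.0 <= D <= 1.0):
            raise InvalidConfigError("D must be in [0, 1]")
        self.D = D

    def snapshot(self) -> tuple[np.ndarray, ...]:
        return (
            self.positions.copy(),
            self.velocities.copy(),
            self.flashing.copy(),
            self.dark.copy(),
            self.motivated.copy(),
        )

    def run(
        self,
        n_frames: int,
        interventions: Iterable[tuple[int, Callable[["SchoolSimulator"], None]]] = (),
    ) -> SchoolTrajectory:
        """Advance ``n_frames`` steps, recording the initial state as frame 0.

        ``interventions`` is a sequence of (frame, callable) pairs; each
        callable receives the simulator just before stepping out of that
        frame (e.g. ``lambda sim: sim.set_motivated([0], (1, 0, 0))``).
        """
        if n_frames < 1:
            raise InvalidConfigError("n_frames must be >= 1")
        sched: dict[int, list[Callable[[SchoolSimulator], None]]] = {}
        for frame, fn in interventions:
            sched.setdefault(int(frame), []).append(fn)
        frames = [self.snapshot()]
        for _ in range(n_frames):
            for fn in sched.get(self.frame, ()):
                fn(self)
            self.step()
            frames.append(self.snapshot())
        pos, vel, fl, dk, mo = (np.stack(arrs) for arrs in zip(*frames))
        return SchoolTrajectory(
            positions=pos, velocities=vel, flashing=fl, dark=dk, motivated=mo,
            dt=self.config.dt,
        )


def init_school(config: SimConfig) -> SchoolSimulator:
    """Place n_fish at rest uniformly inside a cube of half-width
    ``init_half_width`` centred on the origin, assign dark draws, and return
    the ready simulator (reproducible under the config seed)."""
    return SchoolSimulator(config)


def run_simulation(
    config: SimConfig,
    n_frames: int,
    interventions: Iterable[tuple[int, Callable[[SchoolSimulator], None]]] = (),
) -> SchoolTrajectory:
    """Initialise and run a school for ``n_frames`` steps; bitwise
    reproducible for a fixed (config, seed, interventions)."""
    return init_school(config).run(n_frames, interventions)
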
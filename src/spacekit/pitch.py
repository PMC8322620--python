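"""Pitch geometry, grids, tracking/event data model and readers/writers.

Coordinate convention: the pitch is 105 x 68 m, centered at the origin, so
x spans [-52.5, 52.5] and y spans [-34, 34].  The team under analysis is
assumed to attack toward +x; flip coordinates per half upstream if needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Pitch",
    "Grid",
    "PlayerState",
    "TrackingFrame",
    "TrackingSequence",
    "PassEvent",
    "ShotEvent",
    "Possession",
    "FormatError",
    "DataError",
    "AlignmentError",
    "read_tracking",
    "write_tracking",
    "read_events",
    "write_events",
    "group_possessions",
    "align",
]

TRACKING_COLUMNS = ["frame", "t", "agent_id", "team", "role", "x", "y"]
EVENT_COLUMNS = [
    "event_id", "type", "t", "team", "player_id", "receiver_id",
    "t_receive", "x", "y", "x_dest", "y_dest", "outcome",
]

BALL_ID = "ball"


class FormatError(ValueError):
    """Malformed input file (missing columns, bad header)."""


class DataError(ValueError):
    """Well-formed file with invalid content (bounds, monotonicity)."""


class AlignmentError(ValueError):
    """Event cannot be matched to a tracking frame."""


@dataclass(frozen=True)
class Pitch:
    """The playing surface: 105 x 68 m, origin at the center."""

    length: float = 105.0
    width: float = 68.0

    @property
    def x_range(self) -> tuple[float, float]:
        return (-self.length / 2.0, self.length / 2.0)

    @property
    def y_range(self) -> tuple[float, float]:
        return (-self.width / 2.0, self.width / 2.0)

    @property
    def goal_center_home(self) -> np.ndarray:
        """Goal defended by the home side (negative x)."""
        return np.array([-self.length / 2.0, 0.0])

    @property
    def goal_center_away(self) -> np.ndarray:
        return np.array([self.length / 2.0, 0.0])

    @property
    def corners(self) -> np.ndarray:
        hx, hy = self.length / 2.0, self.width / 2.0
        return np.array([[-hx, -hy], [hx, -hy], [hx, hy], [-hx, hy]])

    def goal_center(self, attack_direction: int = 1) -> np.ndarray:
        """Center of the attacked goal for a team attacking toward
        ``attack_direction`` (+1 or -1 along x)."""
        return np.array([attack_direction * self.length / 2.0, 0.0])

    def far_corner(self, attack_direction: int = 1) -> np.ndarray:
        """Corner diagonally opposite the attacked goal (the farthest
        point on the pitch from the goal center)."""
        return np.array([-attack_direction * self.length / 2.0, self.width / 2.0])

    def contains(self, p, tol: float = 1e-9) -> bool:
        p = np.asarray(p, dtype=float)
        return bool(
            abs(p[..., 0]).max() <= self.length / 2.0 + tol
            and abs(p[..., 1]).max() <= self.width / 2.0 + tol
        )


@dataclass(frozen=True)
class Grid:
    """Regular grid of node positions covering the pitch.

    Nodes sit at cell centers and are ordered row-major: the node with flat
    index ``k`` has ``iy, ix = divmod(k, n_x)``, i.e. x varies fastest and
    rows advance from y = -34 toward y = +34.
    """

    n_x: int
    n_y: int
    pitch: Pitch = field(default_factory=Pitch)

    @classmethod
    def from_spacing(cls, spacing: float, pitch: Pitch | None = None) -> "Grid":
        """Grid with (approximately) the requested node spacing in meters.
        ``spacing=0.5`` gives the 50 cm analysis grid (210 x 136 nodes)."""
        pitch = pitch or Pitch()
        return cls(
            n_x=int(round(pitch.length / spacing)),
            n_y=int(round(pitch.width / spacing)),
            pitch=pitch,
        )

    @property
    def spacing(self) -> tuple[float, float]:
        return (self.pitch.length / self.n_x, self.pitch.width / self.n_y)

    @property
    def xs(self) -> np.ndarray:
        dx = self.pitch.length / self.n_x
        return -self.pitch.length / 2.0 + dx * (np.arange(self.n_x) + 0.5)

    @property
    def ys(self) -> np.ndarray:
        dy = self.pitch.width / self.n_y
        return -self.pitch.width / 2.0 + dy * (np.arange(self.n_y) + 0.5)

    @property
    def nodes(self) -> np.ndarray:
        """(n_x * n_y, 2) array of node positions, row-major."""
        xx, yy = np.meshgrid(self.xs, self.ys)
        return np.column_stack([xx.ravel(), yy.ravel()])

    @property
    def n_nodes(self) -> int:
        return self.n_x * self.n_y

    def reshape(self, values: np.ndarray) -> np.ndarray:
        """Flat node values -> (n_y, n_x) array for plotting."""
        return np.asarray(values).reshape(self.n_y, self.n_x)


@dataclass
class PlayerState:
    """Kinematic state of one player at one instant.

    The velocity is the backward finite difference over the window delta:
    v_t = (p_t - p_{t-delta}) / delta; speed is in km/h; the heading theta
    is atan2 of the displacement, with the convention theta = 0 for a
    stationary player.
    """

    player_id: str
    team_id: str
    p_t: np.ndarray
    p_tdelta: np.ndarray
    delta: float = 0.2
    role: str = "field"

    def __post_init__(self):
        self.p_t = np.asarray(self.p_t, dtype=float)
        self.p_tdelta = np.asarray(self.p_tdelta, dtype=float)

    @property
    def v_t(self) -> np.ndarray:
        return (self.p_t - self.p_tdelta) / self.delta

    @property
    def speed(self) -> float:
        """Speed in km/h."""
        return 3.6 * float(np.linalg.norm(self.v_t))

    @property
    def theta(self) -> float:
        d = self.p_t - self.p_tdelta
        if d[0] == 0.0 and d[1] == 0.0:
            return 0.0
        return math.atan2(d[1], d[0])

    @property
    def is_goalkeeper(self) -> bool:
        return self.role == "goalkeeper"


@dataclass
class TrackingFrame:
    """Positions of all players plus the ball at one timestamp."""

    t: float
    players: list[PlayerState]
    ball: np.ndarray

    def __post_init__(self):
        self.ball = np.asarray(self.ball, dtype=float)

    def team(self, team_id: str, include_goalkeeper: bool = True) -> list[PlayerState]:
        return [
            s for s in self.players
            if s.team_id == team_id and (include_goalkeeper or not s.is_goalkeeper)
        ]

    @property
    def team_ids(self) -> list[str]:
        seen: list[str] = []
        for s in self.players:
            if s.team_id not in seen:
                seen.append(s.team_id)
        return seen

    def state(self, player_id: str) -> PlayerState:
        for s in self.players:
            if s.player_id == player_id:
                return s
        raise KeyError(player_id)


class TrackingSequence:
    """A time-ordered collection of tracking frames.

    Internally a tidy DataFrame with columns frame, t, agent_id, team,
    role, x, y (one row per agent per frame, ball included with
    team='ball').
    """

    def __init__(self, df: pd.DataFrame, frame_rate: float = 25.0):
        missing = [c for c in TRACKING_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"tracking data missing columns: {missing}")
        self.df = df[TRACKING_COLUMNS].copy()
        self.df["agent_id"] = self.df["agent_id"].astype(str)
        self.frame_rate = float(frame_rate)
        self.df.sort_values(["frame", "team", "agent_id"], inplace=True, kind="mergesort")
        self.df.reset_index(drop=True, inplace=True)
        self._times = np.sort(self.df["t"].unique())
        if len(self._times) > 1 and np.any(np.diff(self._times) <= 0):
            raise DataError("non-monotone timestamps")
        self._by_frame = {t: g for t, g in self.df.groupby("t", sort=True)}

    # -- basic accessors ---------------------------------------------------
    @property
    def times(self) -> np.ndarray:
        return self._times

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def t_start(self) -> float:
        return float(self._times[0])

    @property
    def t_end(self) -> float:
        return float(self._times[-1])

    def player_ids(self) -> list[str]:
        mask = self.df["team"] != BALL_ID
        return sorted(self.df.loc[mask, "agent_id"].unique())

    def nearest_time(self, t: float) -> float:
        """Time of the frame nearest to ``t``; equidistant ties go to the
        later frame."""
        i = int(np.searchsorted(self._times, t))
        if i == 0:
            return float(self._times[0])
        if i >= len(self._times):
            return float(self._times[-1])
        before, after = self._times[i - 1], self._times[i]
        return float(after) if (t - before) >= (after - t) else float(before)

    def positions(self, t: float) -> pd.DataFrame:
        try:
            return self._by_frame[t]
        except KeyError:
            raise KeyError(f"no frame at t={t}")

    def ball_position(self, t: float) -> np.ndarray:
        g = self.positions(t)
        row = g[g["team"] == BALL_ID]
        if row.empty:
            raise DataError(f"no ball row at t={t}")
        return row[["x", "y"]].to_numpy(dtype=float)[0]

    # -- derived state -----------------------------------------------------
    def velocity_state(self, player_id: str, t: float, delta: float = 0.2) -> PlayerState:
        """Kinematic state of a player at time t using the position
        ``delta`` seconds earlier for the finite-difference velocity."""
        player_id = str(player_id)
        t = self.nearest_time(t)
        t_prev = self.nearest_time(t - delta)
        if t - delta < self.t_start - 0.5 * self.dt:
            raise DataError(f"t - delta = {t - delta:.3f} precedes first frame")
        g_now = self.positions(t)
        row_now = g_now[g_now["agent_id"] == player_id]
        if row_now.empty:
            raise DataError(f"player {player_id} not tracked at t={t}")
        g_prev = self.positions(t_prev)
        row_prev = g_prev[g_prev["agent_id"] == player_id]
        if row_prev.empty:
            raise DataError(f"player {player_id} not tracked at t={t_prev}")
        return PlayerState(
            player_id=player_id,
            team_id=str(row_now["team"].iloc[0]),
            p_t=row_now[["x", "y"]].to_numpy(dtype=float)[0],
            p_tdelta=row_prev[["x", "y"]].to_numpy(dtype=float)[0],
            delta=t - t_prev if t != t_prev else delta,
            role=str(row_now["role"].iloc[0]),
        )

    def frame_at(self, t: float, delta: float = 0.2) -> TrackingFrame:
        """Full frame (all player states + ball) at the frame nearest t.

        Velocities use the frame ``delta`` seconds earlier; at the start of
        the sequence players are treated as stationary.
        """
        t = self.nearest_time(t)
        g = self.positions(t)
        use_prev = (t - delta) >= self.t_start - 0.5 * self.dt
        t_prev = self.nearest_time(t - delta) if use_prev else t
        g_prev = self.positions(t_prev) if use_prev else g
        prev_pos = {
            r.agent_id: np.array([r.x, r.y])
            for r in g_prev.itertuples()
        }
        states = []
        ball = None
        for r in g.itertuples():
            p = np.array([r.x, r.y])
            if r.team == BALL_ID:
                ball = p
                continue
            states.append(PlayerState(
                player_id=str(r.agent_id),
                team_id=str(r.team),
                p_t=p,
                p_tdelta=prev_pos.get(r.agent_id, p) if use_prev else p,
                delta=(t - t_prev) if t != t_prev else delta,
                role=str(r.role),
            ))
        if ball is None:
            raise DataError(f"no ball row at t={t}")
        return TrackingFrame(t=t, players=states, ball=ball)

    def __len__(self) -> int:
        return len(self._times)


@dataclass
class PassEvent:
    event_id: str
    t_p: float
    t_r: float
    team: str
    passer_id: str
    receiver_id: str | None
    origin: np.ndarray
    destination: np.ndarray
    completed: bool = True

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.destination = np.asarray(self.destination, dtype=float)
        if self.completed and self.t_r <= self.t_p:
            raise DataError(f"pass {self.event_id}: t_r must exceed t_p")

    @property
    def type(self) -> str:
        return "pass"

    @property
    def t(self) -> float:
        return self.t_p


@dataclass
class ShotEvent:
    event_id: str
    t: float
    team: str
    player_id: str
    position: np.ndarray
    on_target: bool = True

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)

    @property
    def type(self) -> str:
        return "shot"


@dataclass
class Possession:
    """An uninterrupted run of passes by one team, optionally closed by a
    shot.  Successful iff it ends with a shot by the possessing team.
    Possessions with fewer than three passes are retained but flagged."""

    possession_id: int
    team_id: str
    passes: list[PassEvent]
    shot: ShotEvent | None = None
    min_passes: int = 3

    @property
    def n_p(self) -> int:
        return len(self.passes)

    @property
    def pass_timestamps(self) -> list[float]:
        return [p.t_p for p in self.passes]

    @property
    def success(self) -> bool:
        return self.shot is not None and self.shot.team == self.team_id

    @property
    def short(self) -> bool:
        return self.n_p < self.min_passes


# ---------------------------------------------------------------------------
# readers / writers

_FLOAT_FMT = "%.3f"


def read_tracking(path, pitch: Pitch | None = None) -> TrackingSequence:
    """Read a tracking CSV (header ``frame,t,agent_id,team,role,x,y``).

    The frame rate may be overridden with a ``# frame_rate: <hz>`` comment
    on the first line; default 25 Hz.  Positions outside the pitch and
    non-monotone timestamps are hard errors.
    """
    pitch = pitch or Pitch()
    frame_rate = 25.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "frame_rate" in first:
                frame_rate = float(first.split(":", 1)[1])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    missing = [c for c in TRACKING_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    frames_without_ball = set(df["frame"].unique()) - set(
        df.loc[df["team"] == BALL_ID, "frame"].unique()
    )
    if frames_without_ball:
        raise FormatError(
            f"{path}: frames without a ball row: {sorted(frames_without_ball)[:5]}"
        )
    hx, hy = pitch.length / 2.0, pitch.width / 2.0
    bad = df[(df["x"].abs() > hx + 1e-9) | (df["y"].abs() > hy + 1e-9)]
    if not bad.empty:
        i = bad.index[0]
        raise DataError(
            f"{path}: position out of pitch bounds at row {i} "
            f"(agent {bad.loc[i, 'agent_id']}, x={bad.loc[i, 'x']}, y={bad.loc[i, 'y']})"
        )
    per_frame_t = df.groupby("frame", sort=True)["t"].first()
    if len(per_frame_t) > 1 and np.any(np.diff(per_frame_t.to_numpy()) <= 0):
        raise DataError(f"{path}: non-monotone timestamps")
    return TrackingSequence(df, frame_rate=frame_rate)


def write_tracking(seq: TrackingSequence, path) -> None:
    """Write the canonical tracking CSV (sorted rows, fixed float format).

    ``write_tracking(read_tracking(f))`` is idempotent byte-for-byte.
    """
    with open(path, "w", newline="") as fh:
        if seq.frame_rate != 25.0:
            fh.write(f"# frame_rate: {seq.frame_rate}\n")
        seq.df.to_csv(fh, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def read_events(path) -> list[PassEvent | ShotEvent]:
    """Read an events CSV (pass/shot rows, time-sorted)."""
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    events: list[PassEvent | ShotEvent] = []
    for r in df.sort_values("t", kind="mergesort").itertuples():
        if r.type == "pass":
            completed = str(r.outcome).lower() in {"complete", "completed", "success", "1", "true"}
            receiver = None if pd.isna(r.receiver_id) else str(r.receiver_id)
            if completed and receiver is None:
                raise DataError(f"{path}: completed pass {r.event_id} lacks a receiver")
            events.append(PassEvent(
                event_id=str(r.event_id), t_p=float(r.t),
                t_r=float(r.t_receive) if not pd.isna(r.t_receive) else float(r.t),
                team=str(r.team), passer_id=str(r.player_id), receiver_id=receiver,
                origin=(r.x, r.y), destination=(r.x_dest, r.y_dest),
                completed=completed,
            ))
        elif r.type == "shot":
            events.append(ShotEvent(
                event_id=str(r.event_id), t=float(r.t), team=str(r.team),
                player_id=str(r.player_id), position=(r.x, r.y),
                on_target=str(r.outcome).lower() in {"on_target", "goal", "1", "true"},
            ))
        else:
            raise FormatError(f"{path}: unknown event type {r.type!r}")
    return events


def write_events(events, path) -> None:
    rows = []
    for e in events:
        if e.type == "pass":
            rows.append({
                "event_id": e.event_id, "type": "pass", "t": e.t_p, "team": e.team,
                "player_id": e.passer_id, "receiver_id": e.receiver_id,
                "t_receive": e.t_r, "x": e.origin[0], "y": e.origin[1],
                "x_dest": e.destination[0], "y_dest": e.destination[1],
                "outcome": "complete" if e.completed else "incomplete",
            })
        else:
            rows.append({
                "event_id": e.event_id, "type": "shot", "t": e.t, "team": e.team,
                "player_id": e.player_id, "receiver_id": "",
                "t_receive": "", "x": e.position[0], "y": e.position[1],
                "x_dest": "", "y_dest": "",
                "outcome": "on_target" if e.on_target else "off_target",
            })
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(
        path, index=False, float_format=_FLOAT_FMT, lineterminator="\n"
    )


def group_possessions(events, min_passes: int = 3) -> list[Possession]:
    """Segment a time-sorted event list into possessions.

    A possession is a maximal run of consecutive passes by one team; it is
    closed by a shot (attached if taken by the possessing team) or by a
    pass of the other team.  Shots with no preceding pass open a degenerate
    possession with n_p = 0.
    """
    possessions: list[Possession] = []
    current: list[PassEvent] = []
    team: str | None = None

    def flush(shot: ShotEvent | None = None):
        nonlocal current, team
        if current or shot is not None:
            possessions.append(Possession(
                possession_id=len(possessions),
                team_id=team if team is not None else (shot.team if shot else ""),
                passes=current, shot=shot, min_passes=min_passes,
            ))
        current, team = [], None

    for e in events:
        if e.type == "pass":
            if team is not None and e.team != team:
                flush()
            team = e.team
            current.append(e)
        elif e.type == "shot":
            if team is None:
                team = e.team
            flush(shot=e)
    flush()
    return possessions


def align(tracking: TrackingSequence, events, max_gap: float = 0.1) -> dict[str, float]:
    """Map each event to its nearest tracking frame time.

    Returns ``{event_id: frame_time}``.  Equidistant ties go to the later
    frame.  An event farther than ``max_gap`` seconds from every frame
    raises :class:`AlignmentError` naming the event.
    """
    out: dict[str, float] = {}
    for e in events:
        t = e.t
        ft = tracking.nearest_time(t)
        if abs(ft - t) > max_gap:
            raise AlignmentError(
                f"event {e.event_id} at t={t:.3f}s is {abs(ft - t):.3f}s from the "
                f"nearest frame (max {max_gap}s)"
            )
        out[e.event_id] = ft
    return out
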
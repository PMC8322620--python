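"""Pitch control, observed defensive influence, the learned value surface
and pitch value.

Pitch control squashes the difference of the two teams' summed player
influences through tanh, giving a field in [-1, 1] (+1: the attacking team
has full control).  Defensive influence (DI) is the capped sum of the
defenders' influences; a small feed-forward network learns DI as a
function of (node, ball) so it generalizes to unseen situations, and
pitch value scales that learned surface by proximity to the attacked goal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import r2_score
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .movement import HORIZONS
from .passtime import PassTimeModel, predict_horizon
from .pitch import Grid, Pitch, Possession, TrackingFrame, TrackingSequence

log = logging.getLogger(__name__)

__all__ = [
    "ControlField",
    "ValueField",
    "DIModel",
    "player_horizons",
    "team_influence",
    "pitch_control",
    "pitch_control_at",
    "final_pass_pc",
    "observed_di",
    "build_di_dataset",
    "fit_di_model",
    "goal_distance_scale",
    "pitch_value",
]


@dataclass
class ControlField:
    """tanh-squashed team-influence difference on a grid; values in [-1, 1],
    +1 meaning full control by the attacking team."""

    grid: Grid
    values: np.ndarray
    t: float
    attacking_team: str


@dataclass
class ValueField:
    """Pitch value PV in [0, 1] on a grid: the learned defensive-influence
    surface scaled by proximity to the attacked goal."""

    grid: Grid
    values: np.ndarray
    ball: np.ndarray
    goal: np.ndarray
    far_corner: np.ndarray


def player_horizons(
    frame: TrackingFrame,
    pass_time_model: PassTimeModel | None,
    default: float = 1.0,
) -> dict[str, float]:
    """Per-player movement horizon from the player's distance to the ball
    through the pass-time model; the ball carrier (nearest player to the
    ball) gets the smallest horizon in T."""
    out: dict[str, float] = {}
    dists = {s.player_id: float(np.linalg.norm(s.p_t - frame.ball)) for s in frame.players}
    carrier = min(dists, key=dists.get) if dists else None
    for s in frame.players:
        if s.player_id == carrier:
            out[s.player_id] = float(HORIZONS[0])
        elif pass_time_model is not None:
            out[s.player_id] = predict_horizon(pass_time_model, dists[s.player_id])
        else:
            out[s.player_id] = default
    return out


def team_influence(
    frame: TrackingFrame,
    team_id: str,
    backend,
    points: np.ndarray,
    horizons: dict[str, float] | None = None,
    include_goalkeeper: bool = True,
    default_horizon: float = 1.0,
) -> np.ndarray:
    """Sum of the team's player influences at the query points."""
    points = np.atleast_2d(points)
    total = np.zeros(len(points))
    for s in frame.team(team_id, include_goalkeeper=include_goalkeeper):
        h = (horizons or {}).get(s.player_id, default_horizon)
        total += backend.influence(s, frame.ball, h, points)
    return total


def pitch_control_at(
    frame: TrackingFrame,
    backend,
    points: np.ndarray,
    pass_time_model: PassTimeModel | None = None,
    attacking_team: str = "A",
) -> np.ndarray:
    """PC(p) = tanh(sum_A PI_a(p) - sum_B PI_b(p)) at arbitrary points."""
    points = np.atleast_2d(points)
    horizons = player_horizons(frame, pass_time_model)
    teams = frame.team_ids
    defending = [t for t in teams if t != attacking_team]
    total = team_influence(frame, attacking_team, backend, points, horizons)
    for t in defending:
        total -= team_influence(frame, t, backend, points, horizons)
    return np.tanh(total)


def pitch_control(
    frame: TrackingFrame,
    backend,
    grid: Grid,
    pass_time_model: PassTimeModel | None = None,
    attacking_team: str = "A",
) -> ControlField:
    """Pitch control field on a grid (see :func:`pitch_control_at`)."""
    values = pitch_control_at(frame, backend, grid.nodes, pass_time_model, attacking_team)
    return ControlField(grid=grid, values=values, t=frame.t, attacking_team=attacking_team)


def final_pass_pc(
    possessions: list[Possession],
    tracking: TrackingSequence,
    backend,
    pass_time_model: PassTimeModel | None = None,
    pitch: Pitch | None = None,
) -> np.ndarray:
    """Attacking-team pitch control at the destination of the final pass of
    each successful possession with at least three passes.

    Returns one PC scalar per qualifying possession; the share above zero
    is the headline summary.  Destinations outside the pitch skip the
    possession with a log entry.
    """
    pitch = pitch or Pitch()
    out = []
    for pos in possessions:
        if not pos.success or pos.n_p < pos.min_passes:
            continue
        final = pos.passes[-1]
        if not pitch.contains(final.destination):
            log.warning("possession %d: final-pass destination outside pitch; skipped",
                        pos.possession_id)
            continue
        frame = tracking.frame_at(final.t_p)
        pc = pitch_control_at(
            frame, backend, final.destination[None, :],
            pass_time_model, attacking_team=pos.team_id,
        )
        out.append(float(pc[0]))
    return np.asarray(out)


def observed_di(
    frame: TrackingFrame,
    defending_team: str,
    grid: Grid,
    backend,
    horizons: dict[str, float] | None = None,
    default_horizon: float = 1.0,
) -> np.ndarray:
    """Observed defensive influence DI(p) = min(sum of defender PI, 1) on
    the grid; goalkeepers are excluded."""
    total = team_influence(
        frame, defending_team, backend, grid.nodes,
        horizons=horizons, include_goalkeeper=False,
        default_horizon=default_horizon,
    )
    return np.minimum(total, 1.0)


@dataclass
class DIModel:
    """Feed-forward approximator of the defensive-influence surface.

    Features are rows (x_node, y_node, x_ball, y_ball); the default
    architecture is two hidden layers of 64 units trained with Adam on the
    mean squared error.  Outputs are clipped to [0, 1] at inference.
    """

    pipeline: Pipeline = field(repr=False)
    hidden_layer_sizes: tuple[int, ...]
    train_mse: float
    val_mse: float
    val_r2: float
    n_train: int
    final_loss: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != 4:
            raise ValueError("feature matrix must have 4 columns (x, y, x_ball, y_ball)")
        return np.clip(self.pipeline.predict(X), 0.0, 1.0)

    def surface(self, ball: np.ndarray, grid: Grid) -> np.ndarray:
        nodes = grid.nodes
        X = np.column_stack([nodes, np.tile(np.asarray(ball, dtype=float), (len(nodes), 1))])
        return self.predict(X)


def build_di_dataset(
    frames: list[TrackingFrame],
    grid: Grid,
    backend,
    defending_team: str = "B",
    default_horizon: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack (x_node, y_node, x_ball, y_ball) -> observed DI rows over all
    frames and grid nodes."""
    nodes = grid.nodes
    X_list, y_list = [], []
    for fr in frames:
        di = observed_di(fr, defending_team, grid, backend,
                         default_horizon=default_horizon)
        X_list.append(np.column_stack([nodes, np.tile(fr.ball, (len(nodes), 1))]))
        y_list.append(di)
    return np.vstack(X_list), np.concatenate(y_list)


def fit_di_model(
    X: np.ndarray,
    y: np.ndarray,
    hidden_layer_sizes: tuple[int, ...] = (64, 64),
    alpha: float = 1e-4,
    max_iter: int = 300,
    seed: int = 0,
    val_fraction: float = 0.2,
) -> DIModel:
    """Train the DI network on an 80/20 split of the rows.

    sklearn's MLPRegressor (Adam, MSE loss) with L2 regularization stands
    behind this surface; training is single-threaded and deterministic for
    a fixed seed.  Non-finite losses raise with diagnostics.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(X)
    perm = rng.permutation(n)
    n_val = int(round(val_fraction * n))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("mlp", MLPRegressor(
            hidden_layer_sizes=hidden_layer_sizes,
            activation="relu", solver="adam", alpha=alpha,
            max_iter=max_iter, random_state=seed, tol=1e-5,
        )),
    ])
    pipe.fit(X[tr_idx], y[tr_idx])
    mlp: MLPRegressor = pipe.named_steps["mlp"]
    if not np.isfinite(mlp.loss_):
        raise RuntimeError(
            f"DI training diverged: loss={mlp.loss_}, n_iter={mlp.n_iter_}"
        )
    pred_tr = np.clip(pipe.predict(X[tr_idx]), 0.0, 1.0)
    pred_va = np.clip(pipe.predict(X[val_idx]), 0.0, 1.0)
    return DIModel(
        pipeline=pipe,
        hidden_layer_sizes=tuple(hidden_layer_sizes),
        train_mse=float(np.mean((pred_tr - y[tr_idx]) ** 2)),
        val_mse=float(np.mean((pred_va - y[val_idx]) ** 2)),
        val_r2=float(r2_score(y[val_idx], pred_va)),
        n_train=len(tr_idx),
        final_loss=float(mlp.loss_),
    )


def goal_distance_scale(
    points: np.ndarray,
    attack_direction: int = 1,
    pitch: Pitch | None = None,
) -> np.ndarray:
    """The goal-proximity factor 1 - |p - p_g| / |p_c - p_g| in [0, 1].

    p_g is the attacked goal center and p_c the diagonally opposite
    corner, so the denominator is the longest possible distance to the
    goal: the factor is 1 at the goal center and 0 at the far corner.
    """
    pitch = pitch or Pitch()
    goal = pitch.goal_center(attack_direction)
    corner = pitch.far_corner(attack_direction)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    denom = float(np.linalg.norm(corner - goal))
    return 1.0 - np.linalg.norm(pts - goal, axis=1) / denom


def pitch_value(
    di_model,
    ball: np.ndarray,
    grid: Grid,
    attack_direction: int = 1,
    pitch: Pitch | None = None,
) -> ValueField:
    """PV(p) = (1 - |p - p_g| / |p_c - p_g|) * fn(ball, p), clipped to [0, 1].

    ``di_model`` is anything with a ``predict((n, 4)) -> DI`` method.
    """
    pitch = pitch or Pitch()
    goal = pitch.goal_center(attack_direction)
    corner = pitch.far_corner(attack_direction)
    nodes = grid.nodes
    scale = goal_distance_scale(nodes, attack_direction, pitch)
    X = np.column_stack([nodes, np.tile(np.asarray(ball, dtype=float), (len(nodes), 1))])
    di = np.asarray(di_model.predict(X))
    values = np.clip(scale * di, 0.0, 1.0)
    return ValueField(grid=grid, values=values, ball=np.asarray(ball, dtype=float),
                      goal=goal, far_corner=corner)
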
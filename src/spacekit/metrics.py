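"""Space quality, possession outcome features, and space generation.

Space quality SQ is the node-wise product of pitch control and pitch
value: high where a team controls valuable ground.  Possession features
average exponentially distance-weighted SQ around each pass origin and
destination and feed a linear-SVM outcome classifier.  Space generation
SG credits a player with the pitch-value-weighted influence surplus they
hold over every other player at pass moments, split into receiver
(SG_rec) and passer (SG_pas) aggregates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .control import ControlField, ValueField, pitch_value, player_horizons
from .pitch import Grid, PassEvent, Possession, TrackingFrame

log = logging.getLogger(__name__)

__all__ = [
    "QualityField",
    "PossessionFeatures",
    "SGReport",
    "space_quality",
    "possession_features",
    "outcome_experiment",
    "space_generation",
    "aggregate_sg",
    "pass_network",
]


@dataclass
class QualityField:
    """SQ = PC * PV node-wise; |SQ| <= PV <= 1."""

    grid: Grid
    values: np.ndarray
    t: float


def space_quality(control: ControlField, value: ValueField) -> QualityField:
    """Node-wise product of a control field and a value field (same grid)."""
    if control.grid != value.grid:
        raise ValueError("control and value fields live on different grids")
    return QualityField(grid=control.grid, values=control.values * value.values,
                        t=control.t)


@dataclass
class PossessionFeatures:
    """Distance-weighted average space quality around pass origins (x_o)
    and destinations (x_d) for one possession."""

    possession_id: int
    x_o: float
    x_d: float
    lambda_o: float
    lambda_d: float
    n_p: int


def _decayed_sum(sq: np.ndarray, nodes: np.ndarray, anchor: np.ndarray,
                 lam: float) -> float:
    dist = np.linalg.norm(nodes - np.asarray(anchor, dtype=float), axis=1)
    return float(np.sum(sq * np.exp(-lam * dist)))


def possession_features(
    possession: Possession,
    quality_fields: dict[float, QualityField],
    lambda_o: float,
    lambda_d: float,
) -> PossessionFeatures:
    """Per-possession features: for each pass timestamp, sum SQ over the
    grid weighted by exp(-lambda * distance) to the pass origin
    (destination), then average over the possession's passes.

    ``quality_fields`` maps each pass timestamp t_p to the SQ field at
    that instant; a missing timestamp is an error naming it.
    """
    missing = [p.t_p for p in possession.passes if p.t_p not in quality_fields]
    if missing:
        raise KeyError(f"missing SQ fields for pass timestamps {missing}")
    if possession.n_p == 0:
        raise ValueError("possession has no passes")
    xo = xd = 0.0
    for p in possession.passes:
        q = quality_fields[p.t_p]
        nodes = q.grid.nodes
        xo += _decayed_sum(q.values, nodes, p.origin, lambda_o)
        xd += _decayed_sum(q.values, nodes, p.destination, lambda_d)
    n = possession.n_p
    return PossessionFeatures(
        possession_id=possession.possession_id,
        x_o=xo / n, x_d=xd / n,
        lambda_o=lambda_o, lambda_d=lambda_d, n_p=n,
    )


def outcome_experiment(
    features: np.ndarray,
    labels: np.ndarray,
    n_repeats: int = 100,
    seed: int = 0,
    test_fraction: float = 0.2,
) -> np.ndarray:
    """Repeated random-split linear-SVM evaluation of possession outcome.

    Each repeat standardizes the features on a fresh 80% training draw,
    fits a linear SVM, and scores ROC AUC on the held-out 20%; splits that
    land a single class in either part are redrawn (logged).  Returns the
    per-repeat AUC array.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels).astype(int)
    if X.shape[0] != len(y):
        raise ValueError("features and labels disagree in length")
    rng = np.random.default_rng(seed)
    n = len(y)
    n_test = max(int(round(test_fraction * n)), 1)
    aucs = np.empty(n_repeats)
    for rep in range(n_repeats):
        for attempt in range(100):
            perm = rng.permutation(n)
            te, tr = perm[:n_test], perm[n_test:]
            if len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2:
                break
            log.info("repeat %d: single-class split redrawn", rep)
        else:
            raise RuntimeError("could not draw a two-class split")
        scaler = StandardScaler().fit(X[tr])
        clf = LinearSVC(dual=True, random_state=int(rng.integers(2**31 - 1)))
        clf.fit(scaler.transform(X[tr]), y[tr])
        scores = clf.decision_function(scaler.transform(X[te]))
        aucs[rep] = roc_auc_score(y[te], scores)
    return aucs


def space_generation(
    frame: TrackingFrame,
    player_id: str,
    backend,
    di_model,
    grid: Grid,
    pass_time_model=None,
    attack_direction: int = 1,
    value_field: ValueField | None = None,
) -> float:
    """Space generation of one player at one instant.

    Per-player space quality is SQ_i(p) = PI_i(p) * PV(p); the player's SG
    is the sum over grid nodes of their SQ surplus over every other player
    (both teams), floored at zero:

        SG_i = sum_p sum_{j != i} max(SQ_i(p) - SQ_j(p), 0)

    ``di_model`` is any object with ``predict((n, 4)) -> DI``; pass a
    precomputed ``value_field`` to amortize PV across players.
    """
    pi, order = _influence_matrix(frame, backend, grid, pass_time_model)
    if player_id not in order:
        raise KeyError(f"player {player_id} not in frame")
    if value_field is None:
        value_field = pitch_value(di_model, frame.ball, grid, attack_direction,
                                  pitch=grid.pitch)
    sq = pi * value_field.values[None, :]
    i = order.index(player_id)
    diff = sq[i][None, :] - sq
    diff = np.delete(diff, i, axis=0)
    return float(np.maximum(diff, 0.0).sum())


def _influence_matrix(frame, backend, grid, pass_time_model):
    horizons = player_horizons(frame, pass_time_model)
    order = [s.player_id for s in frame.players]
    pi = np.vstack([
        backend.influence(s, frame.ball, horizons[s.player_id], grid.nodes)
        for s in frame.players
    ])
    return pi, order


@dataclass
class SGReport:
    """Per-player space-generation aggregates.

    SG_rec averages, over passes a player received, the receiver's SG at
    pass initiation; SG_pas credits the same quantity to the passer;
    SG_total is their sum.  Players involved in fewer than 30 passes are
    flagged, and per-90-minute totals are included for comparability.
    """

    player_id: str
    sg_rec: float
    sg_pas: float
    n_received: int
    n_passed: int
    minutes: float
    min_involvements: int = 30
    per_pass_rec: list[float] = field(default_factory=list)
    per_pass_pas: list[float] = field(default_factory=list)

    @property
    def sg_total(self) -> float:
        return self.sg_rec + self.sg_pas

    @property
    def involvements(self) -> int:
        return self.n_received + self.n_passed

    @property
    def flagged(self) -> bool:
        return self.involvements < self.min_involvements

    @property
    def sg_rec_per90(self) -> float:
        return sum(self.per_pass_rec) * 90.0 / self.minutes if self.minutes > 0 else float("nan")

    @property
    def sg_pas_per90(self) -> float:
        return sum(self.per_pass_pas) * 90.0 / self.minutes if self.minutes > 0 else float("nan")

    @property
    def sg_total_per90(self) -> float:
        return self.sg_rec_per90 + self.sg_pas_per90


def aggregate_sg(
    events: list[PassEvent],
    sg_values: dict[str, float],
    minutes: float,
    min_involvements: int = 30,
) -> dict[str, SGReport]:
    """Aggregate per-pass receiver SG into per-player reports.

    ``sg_values`` maps pass event ids to the receiver's SG at t_p.  Events
    without an SG value are ignored; players with zero involvements do not
    appear.
    """
    rec: dict[str, list[float]] = {}
    pas: dict[str, list[float]] = {}
    for e in events:
        if not isinstance(e, PassEvent) or e.event_id not in sg_values:
            continue
        v = float(sg_values[e.event_id])
        if e.receiver_id is not None:
            rec.setdefault(str(e.receiver_id), []).append(v)
        pas.setdefault(str(e.passer_id), []).append(v)
    reports: dict[str, SGReport] = {}
    for pid in sorted(set(rec) | set(pas)):
        r, p = rec.get(pid, []), pas.get(pid, [])
        reports[pid] = SGReport(
            player_id=pid,
            sg_rec=float(np.mean(r)) if r else 0.0,
            sg_pas=float(np.mean(p)) if p else 0.0,
            n_received=len(r), n_passed=len(p),
            minutes=minutes, min_involvements=min_involvements,
            per_pass_rec=r, per_pass_pas=p,
        )
    return reports


def pass_network(
    team_events: list[PassEvent],
    sg_values: dict[str, float],
    focus_player: str,
) -> tuple[pd.DataFrame, list[dict]]:
    """Passes into one player, grouped by passer.

    Returns a table keyed by passer (pass count, mean receiver SG) plus the
    per-pass records (origin, destination, SG) for rendering arrows.  An
    absent focus player yields an empty table with a warning.
    """
    focus_player = str(focus_player)
    per_pass = []
    for e in team_events:
        if not isinstance(e, PassEvent) or str(e.receiver_id) != focus_player:
            continue
        if e.event_id not in sg_values:
            continue
        per_pass.append({
            "event_id": e.event_id, "passer_id": str(e.passer_id),
            "receiver_id": focus_player, "t_p": e.t_p,
            "x": float(e.origin[0]), "y": float(e.origin[1]),
            "x_dest": float(e.destination[0]), "y_dest": float(e.destination[1]),
            "sg": float(sg_values[e.event_id]),
        })
    if not per_pass:
        log.warning("no passes to focus player %s", focus_player)
        return (
            pd.DataFrame(columns=["passer_id", "n_passes", "mean_sg"]),
            [],
        )
    df = pd.DataFrame(per_pass)
    table = (
        df.groupby("passer_id")
        .agg(n_passes=("sg", "size"), mean_sg=("sg", "mean"))
        .reset_index()
        .sort_values("n_passes", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    return table, per_pass
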
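"""Data-driven per-player movement models.

A movement model summarizes where a player can get to: every historical
trajectory triplet (p_{t-delta}, p_t, p_{t+Delta}) is mapped into a local
frame in which the initial movement points along +x, and the endpoints are
pooled per (initial-speed bin, horizon Delta) and smoothed with a Gaussian
kernel density estimate.  Normalizing the density by its value at the main
mode (found by mean shift) yields the player influence PI in [0, 1].
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from .pitch import PlayerState, TrackingSequence

log = logging.getLogger(__name__)

__all__ = [
    "HORIZONS",
    "VELOCITY_BINS",
    "speed_bin",
    "snap_horizon",
    "Triplet",
    "TransformedEndpoint",
    "extract_triplets",
    "transform_triplet",
    "MovementCell",
    "MovementModel",
    "fit_movement_model",
    "player_influence",
    "InfluenceField",
    "DataDrivenInfluence",
    "mean_shift",
    "endpoint_hull",
]

#: Horizon set T = {0.2, 0.4, ..., 5.0} s (passes complete within 5 s).
HORIZONS: np.ndarray = np.round(0.2 * np.arange(1, 26), 10)

#: Initial-speed bins in km/h: [lo, hi) ranges partitioning [0, inf).
VELOCITY_BINS: dict[str, tuple[float, float]] = {
    "standing": (0.0, 1.0),
    "walking": (1.0, 7.0),
    "jogging": (7.0, 14.0),
    "running": (14.0, 20.0),
    "sprinting": (20.0, math.inf),
}

BIN_NAMES = list(VELOCITY_BINS)


def speed_bin(speed_kmh: float) -> str:
    """Name of the velocity bin containing ``speed_kmh``."""
    if speed_kmh < 0:
        raise ValueError("speed must be nonnegative")
    for name, (lo, hi) in VELOCITY_BINS.items():
        if lo <= speed_kmh < hi:
            return name
    return "sprinting"


def snap_horizon(delta: float) -> float:
    """Snap a continuous horizon to the nearest element of T, ties upward,
    clipped to [0.2, 5.0]."""
    k = int(math.floor(delta / 0.2 + 0.5 + 1e-9))
    k = min(max(k, 1), len(HORIZONS))
    return float(HORIZONS[k - 1])


@dataclass(frozen=True)
class Triplet:
    """(past, current, future) positions of one player."""

    p_tdelta: np.ndarray
    p_t: np.ndarray
    p_tDelta: np.ndarray
    delta: float
    Delta: float

    @property
    def speed(self) -> float:
        """Initial speed over [t - delta, t], km/h."""
        return 3.6 * float(
            np.linalg.norm(np.asarray(self.p_t) - np.asarray(self.p_tdelta))
        ) / self.delta


@dataclass(frozen=True)
class TransformedEndpoint:
    """Triplet endpoint in the player-local frame (initial movement
    along +x): endpoint = (d cos(theta), d sin(theta))."""

    x: float
    y: float
    d: float
    theta: float

    @property
    def point(self) -> np.ndarray:
        return np.array([self.x, self.y])


def extract_triplets(
    sequence: TrackingSequence,
    player_id: str,
    delta: float = 0.2,
    horizons=HORIZONS,
    stride: int = 1,
) -> list[Triplet]:
    """All triplets of one player, one per (t, Delta) with t - delta and
    t + Delta inside the sequence; t advances in steps of ``stride`` frames.
    """
    player_id = str(player_id)
    df = sequence.df
    rows = df[df["agent_id"] == player_id].sort_values("t", kind="mergesort")
    if rows.empty:
        warnings.warn(f"player {player_id} not present in sequence")
        return []
    t = rows["t"].to_numpy(dtype=float)
    pos = rows[["x", "y"]].to_numpy(dtype=float)
    dt = sequence.dt
    k_delta = int(round(delta / dt))
    out: list[Triplet] = []
    n = len(t)
    for Delta in np.atleast_1d(horizons):
        k_D = int(round(Delta / dt))
        first, last = k_delta, n - 1 - k_D
        if last < first:
            continue
        for i in range(first, last + 1, stride):
            out.append(Triplet(
                p_tdelta=pos[i - k_delta], p_t=pos[i], p_tDelta=pos[i + k_D],
                delta=round(k_delta * dt, 10), Delta=round(k_D * dt, 10),
            ))
    if not out:
        warnings.warn(f"sequence too short to extract triplets for {player_id}")
    return out


def _heading(p_from: np.ndarray, p_to: np.ndarray) -> float:
    d = np.asarray(p_to, dtype=float) - np.asarray(p_from, dtype=float)
    if d[0] == 0.0 and d[1] == 0.0:
        return 0.0
    return math.atan2(d[1], d[0])


def transform_triplet(triplet: Triplet) -> TransformedEndpoint:
    """Map the endpoint into the local frame where the initial movement
    lies along +x.

    The endpoint angle is measured relative to the heading
    (theta = angle of p_t -> p_tDelta minus angle of p_{t-delta} -> p_t),
    an orientation-preserving rotation; a stationary start (standing
    convention) applies no rotation.  The output is invariant under rigid
    motions of the three input points.
    """
    d = float(np.linalg.norm(np.asarray(triplet.p_tDelta) - np.asarray(triplet.p_t)))
    heading = _heading(triplet.p_tdelta, triplet.p_t)
    theta = _heading(triplet.p_t, triplet.p_tDelta) - heading
    # wrap to (-pi, pi] for a tidy angle; cos/sin are insensitive
    theta = math.atan2(math.sin(theta), math.cos(theta))
    return TransformedEndpoint(x=d * math.cos(theta), y=d * math.sin(theta), d=d, theta=theta)


def mean_shift(
    points: np.ndarray,
    cov: np.ndarray,
    init: np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> np.ndarray:
    """Gaussian mean-shift mode seeking with kernel covariance ``cov``.

    Iterates the weighted mean until the shift is below ``tol`` meters;
    converges to a local maximum of the Gaussian KDE with that kernel.
    """
    points = np.asarray(points, dtype=float)
    m = np.asarray(init, dtype=float).copy()
    prec = np.linalg.inv(cov)
    for _ in range(max_iter):
        diff = points - m
        w = np.exp(-0.5 * np.einsum("ij,jk,ik->i", diff, prec, diff))
        s = w.sum()
        if s <= 0:
            break
        new = (w[:, None] * points).sum(axis=0) / s
        if np.linalg.norm(new - m) < tol:
            return new
        m = new
    return m


@dataclass
class MovementCell:
    """Fitted endpoint density for one (velocity bin, horizon) cell."""

    bin_name: str
    horizon: float
    endpoints: np.ndarray
    kde: gaussian_kde = field(repr=False)
    mode: np.ndarray = field(default=None)
    peak_density: float = 0.0

    @property
    def n(self) -> int:
        return len(self.endpoints)

    def density(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self.kde(pts.T)


@dataclass
class MovementModel:
    """Per-player endpoint densities over (velocity bin, horizon) cells."""

    player_id: str
    cells: dict[tuple[str, float], MovementCell]
    min_count: int = 50
    counts: dict[tuple[str, float], int] = field(default_factory=dict)

    def available(self, bin_name: str, horizon: float) -> bool:
        return (bin_name, snap_horizon(horizon)) in self.cells

    def cell(self, bin_name: str, horizon: float) -> MovementCell:
        key = (bin_name, snap_horizon(horizon))
        if key in self.cells:
            return self.cells[key]
        # fall back to the nearest available horizon in the same bin
        horizons = sorted(h for (b, h) in self.cells if b == bin_name)
        if not horizons:
            raise KeyError(f"no fitted cell in bin {bin_name!r}")
        nearest = min(horizons, key=lambda h: (abs(h - key[1]), -h))
        log.info("cell %s unavailable; falling back to horizon %.1f", key, nearest)
        return self.cells[(bin_name, nearest)]

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        """Store as <path>.json (schema) + <path>.npz (endpoint arrays)."""
        meta = {
            "schema_version": 1,
            "player_id": self.player_id,
            "min_count": self.min_count,
            "cells": [
                {
                    "bin": b, "horizon": h, "n": c.n,
                    "mode": [float(c.mode[0]), float(c.mode[1])],
                    "peak_density": float(c.peak_density),
                    "bandwidth_factor": float(c.kde.factor),
                }
                for (b, h), c in sorted(self.cells.items())
            ],
        }
        with open(f"{path}.json", "w") as fh:
            json.dump(meta, fh, indent=1)
        arrays = {
            f"{b}_{h:.1f}": c.endpoints for (b, h), c in self.cells.items()
        }
        np.savez(f"{path}.npz", **arrays)

    @classmethod
    def load(cls, path) -> "MovementModel":
        with open(f"{path}.json") as fh:
            meta = json.load(fh)
        arrays = np.load(f"{path}.npz")
        cells = {}
        for rec in meta["cells"]:
            key = (rec["bin"], float(rec["horizon"]))
            endpoints = arrays[f"{rec['bin']}_{rec['horizon']:.1f}"]
            kde = gaussian_kde(endpoints.T)
            cells[key] = MovementCell(
                bin_name=rec["bin"], horizon=float(rec["horizon"]),
                endpoints=endpoints, kde=kde,
                mode=np.array(rec["mode"]), peak_density=rec["peak_density"],
            )
        return cls(player_id=meta["player_id"], cells=cells, min_count=meta["min_count"])


def fit_movement_model(
    triplets: list[Triplet],
    player_id: str,
    min_count: int = 50,
    bw_method=None,
    mode_tol: float = 1e-4,
) -> MovementModel:
    """Fit per-(bin, horizon) Gaussian KDEs to transformed triplet endpoints.

    Bandwidths use Scott's rule unless ``bw_method`` overrides.  The main
    mode of each cell is found by mean shift (kernel = the KDE kernel,
    tolerance 1e-4 m, max 500 iterations) started from the sample mean and
    from the highest-density endpoint, keeping the better optimum; the
    stored peak density therefore dominates the density at every endpoint.
    Cells with fewer than ``min_count`` endpoints are left unavailable.
    """
    groups: dict[tuple[str, float], list[np.ndarray]] = {}
    for tr in triplets:
        key = (speed_bin(tr.speed), snap_horizon(tr.Delta))
        groups.setdefault(key, []).append(transform_triplet(tr).point)
    cells: dict[tuple[str, float], MovementCell] = {}
    counts = {k: len(v) for k, v in groups.items()}
    for key, pts in groups.items():
        if len(pts) < min_count:
            continue
        endpoints = np.asarray(pts)
        spreads = endpoints.std(axis=0)
        if np.any(spreads <= 1e-12):
            # degenerate cloud (e.g. perfectly straight synthetic walk);
            # jitter-free KDE is singular, mark unavailable
            log.warning("cell %s has a degenerate endpoint cloud; skipped", key)
            continue
        kde = gaussian_kde(endpoints.T, bw_method=bw_method)
        dens_at_points = kde(endpoints.T)
        starts = [endpoints.mean(axis=0), endpoints[int(np.argmax(dens_at_points))]]
        candidates = [
            mean_shift(endpoints, kde.covariance, s, tol=mode_tol) for s in starts
        ]
        dens = [float(kde(c[:, None])[0]) for c in candidates]
        best = int(np.argmax(dens))
        mode, peak = candidates[best], dens[best]
        peak = max(peak, float(dens_at_points.max()))
        cells[key] = MovementCell(
            bin_name=key[0], horizon=key[1], endpoints=endpoints,
            kde=kde, mode=candidates[best], peak_density=peak,
        )
    return MovementModel(player_id=player_id, cells=cells, min_count=min_count, counts=counts)


def _local_frame(state: PlayerState, points: np.ndarray) -> np.ndarray:
    """Map global query points into the player-local frame (player at the
    origin, heading along +x)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float)) - state.p_t
    th = state.theta
    c, s = math.cos(th), math.sin(th)
    rot = np.array([[c, s], [-s, c]])  # rotation by -theta
    return pts @ rot.T


def player_influence(
    model: MovementModel,
    state: PlayerState,
    horizon: float,
    points: np.ndarray,
) -> np.ndarray:
    """Normalized player influence PI in [0, 1] at the query points.

    PI(p) = density(p in local frame) / density(main mode); the value at
    the mode is exactly 1.
    """
    cell = model.cell(speed_bin(state.speed), horizon)
    local = _local_frame(state, points)
    dens = cell.density(local)
    return np.clip(dens / cell.peak_density, 0.0, 1.0)


@dataclass
class InfluenceField:
    """Scalar PI surface on a grid for one player at one instant."""

    grid: object
    values: np.ndarray
    player_id: str
    t: float


class DataDrivenInfluence:
    """Influence backend backed by fitted movement models.

    Players without a model fall back to the supplied backend (typically
    the Gaussian baseline), logged once per player.
    """

    name = "datadriven"

    def __init__(self, models: dict[str, MovementModel], fallback=None):
        self.models = {str(k): v for k, v in models.items()}
        self.fallback = fallback
        self._warned: set[str] = set()

    def influence(self, state: PlayerState, ball: np.ndarray,
                  horizon: float, points: np.ndarray) -> np.ndarray:
        model = self.models.get(str(state.player_id))
        if model is None:
            if self.fallback is None:
                raise KeyError(f"no movement model for player {state.player_id}")
            if state.player_id not in self._warned:
                log.info("player %s has no movement model; using fallback backend",
                         state.player_id)
                self._warned.add(state.player_id)
            return self.fallback.influence(state, ball, horizon, points)
        return player_influence(model, state, horizon, points)

    def influence_field(self, state, ball, horizon, grid, t=0.0) -> InfluenceField:
        return InfluenceField(
            grid=grid,
            values=self.influence(state, ball, horizon, grid.nodes),
            player_id=state.player_id, t=t,
        )


def endpoint_hull(endpoints: np.ndarray) -> np.ndarray:
    """Convex hull of an endpoint cloud (vertices in order).  Utility for
    inspecting reachable sets; not part of the headline pipeline."""
    from scipy.spatial import ConvexHull

    endpoints = np.asarray(endpoints, dtype=float)
    hull = ConvexHull(endpoints)
    return endpoints[hull.vertices]
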
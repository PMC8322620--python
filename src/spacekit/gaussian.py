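"""Bivariate-Gaussian player influence (the Fernandez–Bornn baseline).

A player's influence is a bivariate normal density centered ahead of the
player (mu = p + 0.5 s * v), elongated along the heading according to
speed, and sized by a ball-distance-dependent radius r(d) in [4, 10] m.
Normalizing by the density at the mode gives an influence surface in
(0, 1], drop-in compatible with the data-driven movement backend.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .pitch import PlayerState

log = logging.getLogger(__name__)

__all__ = [
    "radius_from_ball",
    "gaussian_params",
    "gaussian_pi",
    "GaussianParams",
    "GaussianInfluence",
]

#: Default maximum player speed (m/s) used to scale the covariance.
V_MAX_DEFAULT = 13.0

#: Floor for the scaling-matrix entries (m); keeps Sigma non-singular at
#: full speed.
V_EPS = 1e-6

_R_MIN, _R_MAX = 4.0, 10.0
_R_MID, _R_SCALE = 15.0, 3.0
_S0 = 1.0 / (1.0 + math.exp(_R_MID / _R_SCALE))  # logistic((0-mid)/scale)


def radius_from_ball(d) -> np.ndarray | float:
    """Influence radius r(d) in meters from the player–ball distance.

    A rescaled logistic in d: exactly 4 m at the ball, saturating to 10 m
    far from it (within 1e-3 by d = 60 m), monotone nondecreasing.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance to ball must be nonnegative")
    s = 1.0 / (1.0 + np.exp(-(d - _R_MID) / _R_SCALE))
    r = _R_MIN + (_R_MAX - _R_MIN) * (s - _S0) / (1.0 - _S0)
    r = np.clip(r, _R_MIN, _R_MAX)
    return float(r) if r.ndim == 0 else r


@dataclass
class GaussianParams:
    """Parameters of one player's Gaussian influence at one instant."""

    mu: np.ndarray
    Sigma: np.ndarray
    R: np.ndarray
    V: np.ndarray
    theta: float
    r: float
    v_max: float

    @property
    def Sigma_inv(self) -> np.ndarray:
        return np.linalg.inv(self.Sigma)


def gaussian_params(
    state: PlayerState,
    ball: np.ndarray,
    v_max: float = V_MAX_DEFAULT,
    radius_fn=radius_from_ball,
) -> GaussianParams:
    """Build the Gaussian influence parameters for one player state.

    mu = p + 0.5 s * v.  Sigma = R V V R^-1 with R the rotation by the
    heading and V diagonal with entries (r + r*(|v|/v_max)^2)/2 and
    (r - r*(|v|/v_max)^2)/2, floored at a small epsilon so Sigma stays
    positive definite when |v| = v_max.  Speeds above v_max are clipped.
    """
    if v_max <= 0:
        raise ValueError("v_max must be positive")
    v = state.v_t
    speed = float(np.linalg.norm(v))
    if speed > v_max:
        log.info("player %s speed %.2f m/s clipped to v_max=%.2f",
                 state.player_id, speed, v_max)
        v = v * (v_max / speed)
        speed = v_max
    r = radius_fn(float(np.linalg.norm(state.p_t - np.asarray(ball, dtype=float))))
    ratio2 = (speed / v_max) ** 2
    v1 = (r + r * ratio2) / 2.0
    v2 = (r - r * ratio2) / 2.0
    V = np.diag([max(v1, V_EPS), max(v2, V_EPS)])
    th = state.theta
    c, s = math.cos(th), math.sin(th)
    R = np.array([[c, -s], [s, c]])
    Sigma = R @ V @ V @ R.T  # R^-1 = R^T for a rotation
    mu = state.p_t + 0.5 * v
    return GaussianParams(mu=mu, Sigma=Sigma, R=R, V=V, theta=th, r=float(r), v_max=v_max)


def gaussian_pi(params: GaussianParams, points: np.ndarray) -> np.ndarray:
    """Mode-normalized influence f(p)/f(mu) = exp(-0.5 (p-mu)^T Sigma^-1 (p-mu))."""
    pts = np.atleast_2d(np.asarray(points, dtype=float)) - params.mu
    prec = params.Sigma_inv
    q = np.einsum("ij,jk,ik->i", pts, prec, pts)
    return np.exp(-0.5 * q)


class GaussianInfluence:
    """Influence backend for the Gaussian baseline (ignores the horizon)."""

    name = "gaussian"

    def __init__(self, v_max: float = V_MAX_DEFAULT, radius_fn=radius_from_ball):
        self.v_max = v_max
        self.radius_fn = radius_fn

    def influence(self, state: PlayerState, ball: np.ndarray,
                  horizon: float, points: np.ndarray) -> np.ndarray:
        params = gaussian_params(state, ball, v_max=self.v_max, radius_fn=self.radius_fn)
        return gaussian_pi(params, points)
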
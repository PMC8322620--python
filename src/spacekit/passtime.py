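"""Pass-distance -> available-time regression.

The time a receiver has to move before the ball arrives is bounded by the
pass duration Delta = t_r - t_p, learned as a function of the passer to
receiver distance d at pass initiation.  A Yeo-Johnson power transform of
d followed by ordinary least squares is fitted on 80% of the passes; the
transform exponent lambda is a hyperparameter selected by mean squared
error on the held-out 20%.  Predictions are snapped to the discrete
horizon set T = {0.2, ..., 5.0} s.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import yeojohnson
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import PowerTransformer

from .movement import HORIZONS, snap_horizon
from .pitch import PassEvent, TrackingSequence

log = logging.getLogger(__name__)

__all__ = ["PassTimeModel", "build_pass_dataset", "fit_pass_time", "predict_horizon"]

#: Candidate Yeo-Johnson exponents tried alongside the MLE-fitted value.
LAMBDA_GRID = (-1.0, -0.5, 0.0, 0.5, 1.0, 1.5, 2.0)


@dataclass
class PassTimeModel:
    """Fitted distance -> pass-duration model (Yeo-Johnson + OLS).

    The transformed predictor is standardized with the training mean and
    standard deviation before the least-squares line, so the stored slope
    refers to the standardized scale.
    """

    lmbda: float
    intercept: float
    slope: float
    z_mean: float
    z_std: float
    train_mse: float
    val_mse: float
    n: int

    def predict_raw(self, d) -> np.ndarray:
        """Unclipped, unsnapped predicted duration in seconds."""
        d = np.atleast_1d(np.asarray(d, dtype=float))
        z = (yeojohnson(d, lmbda=self.lmbda) - self.z_mean) / self.z_std
        return self.intercept + self.slope * z

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "lambda": self.lmbda, "intercept": self.intercept,
                "slope": self.slope, "z_mean": self.z_mean, "z_std": self.z_std,
                "train_mse": self.train_mse, "val_mse": self.val_mse, "n": self.n,
            }, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PassTimeModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(lmbda=d["lambda"], intercept=d["intercept"], slope=d["slope"],
                   z_mean=d["z_mean"], z_std=d["z_std"], train_mse=d["train_mse"],
                   val_mse=d["val_mse"], n=d["n"])


def build_pass_dataset(
    events,
    tracking: TrackingSequence,
    max_duration: float = float(HORIZONS[-1]),
) -> np.ndarray:
    """(d, Delta) pairs from completed passes.

    d is the Euclidean passer-receiver distance at the frame aligned with
    t_p; Delta = t_r - t_p.  Pairs with Delta above ``max_duration`` are
    dropped (passes complete within 5 s) and counted in the log; passes
    whose receiver is untracked at t_p are skipped with a warning.
    """
    pairs = []
    n_long = 0
    for e in events:
        if not isinstance(e, PassEvent) or not e.completed:
            continue
        duration = e.t_r - e.t_p
        if duration > max_duration:
            n_long += 1
            continue
        t = tracking.nearest_time(e.t_p)
        g = tracking.positions(t)
        passer = g[g["agent_id"] == str(e.passer_id)]
        receiver = g[g["agent_id"] == str(e.receiver_id)]
        if passer.empty or receiver.empty:
            log.warning("pass %s: passer or receiver untracked at t=%.2f; skipped",
                        e.event_id, t)
            continue
        d = float(np.linalg.norm(
            passer[["x", "y"]].to_numpy(dtype=float)[0]
            - receiver[["x", "y"]].to_numpy(dtype=float)[0]
        ))
        pairs.append((d, duration))
    if n_long:
        log.info("dropped %d passes with duration > %.1f s", n_long, max_duration)
    return np.asarray(pairs, dtype=float)


def _ols_1d(z: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    zm, ym = z.mean(), y.mean()
    slope = float(np.sum((z - zm) * (y - ym)) / np.sum((z - zm) ** 2))
    return float(ym - slope * zm), slope


def fit_pass_time(pairs: np.ndarray, split_seed: int = 0) -> PassTimeModel:
    """Fit the Yeo-Johnson + OLS duration model on an 80/20 split.

    The power transform applies to the predictor d only.  Its exponent is
    selected by validation MSE among the MLE-fitted value and a fixed
    candidate grid (an identity transform, lambda = 1, is always among the
    candidates, so a genuinely linear relation is recovered unbiased).
    """
    pairs = np.asarray(pairs, dtype=float)
    if len(pairs) < 100:
        raise ValueError(f"need at least 100 pairs, got {len(pairs)}")
    d, y = pairs[:, 0], pairs[:, 1]
    if np.std(d) <= 1e-12:
        raise ValueError("degenerate predictor: distance has no variance")
    d_tr, d_va, y_tr, y_va = train_test_split(
        d, y, test_size=0.2, random_state=split_seed
    )
    mle = PowerTransformer(method="yeo-johnson", standardize=False)
    mle.fit(d_tr[:, None])
    candidates = sorted(set(LAMBDA_GRID) | {round(float(mle.lambdas_[0]), 6)})
    best = None
    for lam in candidates:
        z_tr = yeojohnson(d_tr, lmbda=lam)
        z_mean, z_std = float(z_tr.mean()), float(z_tr.std())
        if z_std <= 1e-12:
            continue
        zs_tr = (z_tr - z_mean) / z_std
        intercept, slope = _ols_1d(zs_tr, y_tr)
        zs_va = (yeojohnson(d_va, lmbda=lam) - z_mean) / z_std
        val_mse = float(np.mean((intercept + slope * zs_va - y_va) ** 2))
        train_mse = float(np.mean((intercept + slope * zs_tr - y_tr) ** 2))
        if best is None or val_mse < best.val_mse:
            best = PassTimeModel(
                lmbda=float(lam), intercept=intercept, slope=slope,
                z_mean=z_mean, z_std=z_std,
                train_mse=train_mse, val_mse=val_mse, n=len(pairs),
            )
    assert best is not None
    log.info("pass-time model: lambda=%.3f val MSE=%.5f", best.lmbda, best.val_mse)
    return best


def predict_horizon(model: PassTimeModel, d: float) -> float:
    """Predicted movement horizon snapped to the nearest element of T
    (ties upward), clipped to [0.2, 5.0] s."""
    raw = float(model.predict_raw(d)[0])
    return snap_horizon(raw)
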
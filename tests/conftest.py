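import numpy as np
import pytest

import spacekit as sk
from spacekit.pitch import PlayerState, TrackingFrame


@pytest.fixture(scope="session")
def corpus():
    """Stratified triplet corpus for an 8 m/s player (shared, read-only)."""
    return sk.simulate_triplet_corpus(sk.KinematicProfile(max_speed=8.0), 5000, seed=3)


@pytest.fixture(scope="session")
def movement_model(corpus):
    return sk.fit_movement_model(corpus.triplets, "P")


@pytest.fixture(scope="session")
def short_match():
    cfg = sk.ScenarioConfig(seed=1, duration=60.0)
    seq, events = sk.simulate_match(cfg)
    return cfg, seq, events


def random_frame(rng, n_per_team=5, ball=None):
    """A hand-built frame with moving players on both teams."""
    players = []
    for i in range(2 * n_per_team):
        p = rng.uniform([-45, -30], [45, 30])
        q = p - rng.normal(0, 0.4, 2)
        players.append(PlayerState(
            f"P{i}", "A" if i < n_per_team else "B", p_t=p, p_tdelta=q))
    if ball is None:
        ball = rng.uniform([-40, -25], [40, 25])
    return TrackingFrame(t=0.0, players=players, ball=np.asarray(ball, dtype=float))
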
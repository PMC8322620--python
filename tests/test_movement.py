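"""Movement models: triplet extraction, local-frame transform, KDE cells,
mean-shift modes and normalized player influence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spacekit as sk
from spacekit.movement import (
    HORIZONS,
    MovementCell,
    Triplet,
    mean_shift,
    snap_horizon,
    speed_bin,
    transform_triplet,
)
from spacekit.pitch import PlayerState
from scipy.stats import gaussian_kde


def make_walk_sequence(v=(1.5, 0.0), duration=10.0, dt=0.04):
    """Constant-velocity single-player sequence."""
    import pandas as pd

    n = int(round(duration / dt)) + 1
    rows = []
    for k in range(n):
        t = round(k * dt, 6)
        rows.append((k, t, "P", "A", "field", v[0] * t, v[1] * t))
        rows.append((k, t, "ball", "ball", "ball", 0.0, 0.0))
    df = pd.DataFrame(rows, columns=["frame", "t", "agent_id", "team", "role", "x", "y"])
    return sk.TrackingSequence(df)


class TestBinsAndHorizons:
    @pytest.mark.parametrize("speed,name", [
        (0.0, "standing"), (0.99, "standing"), (1.0, "walking"), (6.99, "walking"),
        (7.0, "jogging"), (13.99, "jogging"), (14.0, "running"), (19.99, "running"),
        (20.0, "sprinting"), (35.0, "sprinting"),
    ])
    def test_bin_boundaries(self, speed, name):
        assert speed_bin(speed) == name

    @pytest.mark.parametrize("raw,expected", [
        (0.33, 0.4), (0.30, 0.4), (7.0, 5.0), (0.05, 0.2), (1.0, 1.0), (4.9, 5.0),
    ])
    def test_snap(self, raw, expected):
        assert snap_horizon(raw) == expected

    @given(st.floats(min_value=0.0, max_value=10.0))
    @settings(derandomize=True, max_examples=50)
    def test_snap_always_in_horizon_set(self, raw):
        assert snap_horizon(raw) in set(float(h) for h in HORIZONS)


class TestExtractTriplets:
    def test_boundary_arithmetic(self):
        seq = make_walk_sequence(duration=10.0)
        triplets = sk.extract_triplets(seq, "P", horizons=[5.0])
        ts = [5.0]  # Delta = 5 -> t in [0.2, 5.0]
        assert len(triplets) == int(round((10.0 - 0.2 - 5.0) / 0.04)) + 1

    def test_count_matches_enumeration_oracle(self):
        seq = make_walk_sequence(duration=3.0)
        horizons = [0.2, 1.0, 2.0]
        triplets = sk.extract_triplets(seq, "P", horizons=horizons)
        n_frames = len(seq)
        expected = 0
        for D in horizons:  # brute-force count of valid (t, Delta) pairs
            kD, kd = int(round(D / 0.04)), 5
            expected += sum(1 for i in range(n_frames) if i - kd >= 0 and i + kD <= n_frames - 1)
        assert len(triplets) == expected

    def test_constant_walk_endpoints_on_axis(self):
        seq = make_walk_sequence(v=(1.5, 0.0))
        for tr in sk.extract_triplets(seq, "P", horizons=[2.0], stride=10):
            ep = transform_triplet(tr)
            assert ep.point == pytest.approx([1.5 * 2.0, 0.0], abs=1e-9)


class TestTransform:
    def test_collinear(self):
        tr = Triplet((0.0, 0.0), (1.0, 0.0), (3.0, 0.0), 0.2, 1.0)
        assert transform_triplet(tr).point == pytest.approx([2.0, 0.0])

    def test_left_turn_keeps_orientation(self):
        # moving +y, endpoint 90 degrees to the left -> local (0, 1)
        tr = Triplet((0.0, 0.0), (0.0, 1.0), (-1.0, 1.0), 0.2, 1.0)
        ep = transform_triplet(tr)
        assert ep.d == pytest.approx(1.0)
        assert ep.point == pytest.approx([0.0, 1.0], abs=1e-12)

    @given(st.floats(min_value=-math.pi, max_value=math.pi),
           st.floats(min_value=-20, max_value=20),
           st.floats(min_value=-20, max_value=20))
    @settings(derandomize=True, max_examples=50)
    def test_rigid_motion_invariance(self, angle, tx, ty):
        pts = np.array([[0.0, 0.0], [1.0, 0.5], [3.0, -1.0]])
        c, s = math.cos(angle), math.sin(angle)
        R = np.array([[c, -s], [s, c]])
        moved = pts @ R.T + np.array([tx, ty])
        ep1 = transform_triplet(Triplet(pts[0], pts[1], pts[2], 0.2, 1.0))
        ep2 = transform_triplet(Triplet(moved[0], moved[1], moved[2], 0.2, 1.0))
        assert ep1.point == pytest.approx(ep2.point, abs=1e-9)

    def test_standing_convention_no_rotation(self):
        tr = Triplet((2.0, 3.0), (2.0, 3.0), (2.0, 4.0), 0.2, 1.0)
        assert transform_triplet(tr).point == pytest.approx([0.0, 1.0])


class TestFitAndModes:
    def test_planted_gaussian_density_integrates_to_one(self):
        rng = np.random.default_rng(0)
        pts = rng.normal([2.0, 0.0], 1.0, size=(5000, 2))
        kde = gaussian_kde(pts.T)
        xs = np.linspace(-10, 10, 201)
        xx, yy = np.meshgrid(xs, xs)
        dens = kde(np.vstack([xx.ravel(), yy.ravel()]))
        integral = dens.sum() * (xs[1] - xs[0]) ** 2
        assert 0.98 <= integral <= 1.02

    def test_fit_determinism(self, corpus):
        m1 = sk.fit_movement_model(corpus.triplets[:3000], "P")
        m2 = sk.fit_movement_model(corpus.triplets[:3000], "P")
        assert set(m1.cells) == set(m2.cells)
        for k in m1.cells:
            assert np.array_equal(m1.cells[k].mode, m2.cells[k].mode)
            assert m1.cells[k].kde.factor == m2.cells[k].kde.factor

    def test_bimodal_mode_matches_grid_argmax_oracle(self):
        rng = np.random.default_rng(1)
        heavy = rng.normal([3.0, 0.0], 0.8, size=(1400, 2))
        light = rng.normal([-3.0, 0.0], 0.8, size=(600, 2))
        pts = np.vstack([heavy, light])
        kde = gaussian_kde(pts.T)
        mode = mean_shift(pts, kde.covariance, pts.mean(axis=0))
        # independent oracle: density argmax on a 1 cm grid
        xs = np.arange(-6.0, 6.0, 0.01)
        ys = np.arange(-1.5, 1.5, 0.01)
        xx, yy = np.meshgrid(xs, ys)
        dens = kde(np.vstack([xx.ravel(), yy.ravel()]))
        best = np.unravel_index(np.argmax(dens.reshape(yy.shape)), yy.shape)
        oracle = np.array([xs[best[1]], ys[best[0]]])
        assert np.linalg.norm(mode - oracle) <= 0.3
        assert abs(oracle[0] - 3.0) < 1.0  # heavy component wins

    def test_min_count_leaves_cells_unavailable(self, corpus):
        model = sk.fit_movement_model(corpus.triplets[:300], "P", min_count=10**6)
        assert len(model.cells) == 0

    def test_mode_density_dominates_endpoints(self, movement_model):
        for cell in list(movement_model.cells.values())[::25]:
            assert cell.peak_density >= cell.density(cell.endpoints).max() - 1e-12


class TestPlayerInfluence:
    @pytest.fixture()
    def state(self):
        # jogging along +y at 10.8 km/h
        return PlayerState("P", "A", p_t=[5.0, 5.0], p_tdelta=[5.0, 4.4], delta=0.2)

    def test_pi_is_one_at_mode(self, movement_model, state):
        cell = movement_model.cell(speed_bin(state.speed), 1.0)
        th = state.theta
        R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        global_mode = state.p_t + R @ cell.mode
        pi = sk.player_influence(movement_model, state, 1.0, global_mode[None, :])
        assert pi[0] == pytest.approx(1.0, abs=1e-9)

    def test_far_point_negligible(self, movement_model, state):
        pi = sk.player_influence(movement_model, state, 0.2, np.array([[5.0 + 60.0, 5.0]]))
        assert pi[0] < 1e-6

    def test_pi_in_unit_interval(self, movement_model, state):
        rng = np.random.default_rng(3)
        pts = rng.uniform([-52, -33], [52, 33], size=(500, 2))
        for h in (0.2, 1.0, 3.0, 5.0):
            pi = sk.player_influence(movement_model, state, h, pts)
            assert np.all(pi >= 0.0) and np.all(pi <= 1.0)

    def test_matches_independent_transform_oracle(self, movement_model, state):
        """Duplicate-path check: rotate/translate queries by hand, then
        evaluate the cell density ratio directly."""
        rng = np.random.default_rng(4)
        pts = rng.uniform([-10, -10], [20, 20], size=(100, 2))
        h = 1.0
        pi = sk.player_influence(movement_model, state, h, pts)
        cell = movement_model.cell(speed_bin(state.speed), h)
        th = state.theta
        Rinv = np.array([[math.cos(-th), -math.sin(-th)], [math.sin(-th), math.cos(-th)]])
        local = (pts - state.p_t) @ Rinv.T
        oracle = np.clip(cell.kde(local.T) / cell.peak_density, 0.0, 1.0)
        assert np.max(np.abs(pi - oracle)) < 1e-10

    def test_unavailable_cell_falls_back_to_nearest_horizon(self, corpus):
        model = sk.fit_movement_model(
            [t for t in corpus.triplets if t.Delta in (0.4, 0.6)], "P")
        state = PlayerState("P", "A", p_t=[0, 0], p_tdelta=[-0.6, 0], delta=0.2)
        b = speed_bin(state.speed)
        assert not model.available(b, 5.0)
        cell = model.cell(b, 5.0)
        assert cell.horizon in (0.4, 0.6)


class TestReachabilityAndSpread:
    def test_endpoints_bounded_by_speed_cap(self, corpus):
        per = {}
        for tr in corpus.triplets:
            per.setdefault((speed_bin(tr.speed), tr.Delta), []).append(
                transform_triplet(tr).d)
        assert per
        for (b, D), ds in per.items():
            assert np.quantile(ds, 0.99) <= 1.05 * 8.0 * D, (b, D)

    def test_mean_endpoint_distance_monotone_in_horizon(self, corpus):
        per = {}
        for tr in corpus.triplets:
            per.setdefault((speed_bin(tr.speed), tr.Delta), []).append(
                transform_triplet(tr).d)
        for b in sk.VELOCITY_BINS:
            hs = sorted(h for (bb, h) in per if bb == b)
            means = [np.mean(per[(b, h)]) for h in hs]
            for m1, m2 in zip(means, means[1:]):
                assert m2 >= m1 * 0.95

    def test_rigid_motion_leaves_model_unchanged(self):
        seq = make_walk_sequence(v=(1.2, 0.9), duration=8.0)
        triplets = sk.extract_triplets(seq, "P", horizons=[1.0], stride=3)
        eps1 = [transform_triplet(t).point for t in triplets]
        ang = 0.7
        c, s = math.cos(ang), math.sin(ang)
        R = np.array([[c, -s], [s, c]])
        rotated = [Triplet(R @ np.asarray(t.p_tdelta) + 3.0,
                           R @ np.asarray(t.p_t) + 3.0,
                           R @ np.asarray(t.p_tDelta) + 3.0, t.delta, t.Delta)
                   for t in triplets]
        eps2 = [transform_triplet(t).point for t in rotated]
        assert np.allclose(eps1, eps2, atol=1e-9)


class TestPersistence:
    def test_save_load_roundtrip(self, movement_model, tmp_path):
        movement_model.save(tmp_path / "m")
        loaded = sk.MovementModel.load(tmp_path / "m")
        assert set(loaded.cells) == set(movement_model.cells)
        key = next(iter(loaded.cells))
        pts = np.array([[0.5, 0.5], [2.0, -1.0]])
        assert np.allclose(loaded.cells[key].density(pts),
                           movement_model.cells[key].density(pts))
        assert np.allclose(loaded.cells[key].mode, movement_model.cells[key].mode)
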
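"""Space quality, possession features, outcome classifier and space
generation."""

import numpy as np
import pytest

import spacekit as sk
from spacekit.control import ControlField, ValueField, pitch_value
from spacekit.metrics import (
    QualityField,
    _influence_matrix,
    outcome_experiment,
    pass_network,
    possession_features,
    space_generation,
    space_quality,
)
from spacekit.pitch import PassEvent, PlayerState, Possession, TrackingFrame
from conftest import random_frame


class ConstDI:
    def __init__(self, value=1.0):
        self.value = value

    def predict(self, X):
        return np.full(len(X), self.value)


def make_fields(grid, pc_vals, pv_vals, t=0.0):
    pc = ControlField(grid=grid, values=np.asarray(pc_vals, dtype=float),
                      t=t, attacking_team="A")
    pv = ValueField(grid=grid, values=np.asarray(pv_vals, dtype=float),
                    ball=np.zeros(2), goal=np.array([52.5, 0.0]),
                    far_corner=np.array([-52.5, 34.0]))
    return pc, pv


@pytest.fixture(scope="module")
def grid():
    return sk.Grid.from_spacing(4.0)


class TestSpaceQuality:
    def test_zero_control_absorbs(self, grid):
        pc, pv = make_fields(grid, np.zeros(grid.n_nodes), np.ones(grid.n_nodes))
        assert np.all(space_quality(pc, pv).values == 0.0)

    def test_pointwise_product(self, grid):
        pc, pv = make_fields(grid, np.full(grid.n_nodes, 0.57),
                             np.full(grid.n_nodes, 0.5))
        assert space_quality(pc, pv).values[0] == pytest.approx(0.285)

    def test_bounded_by_factors(self, grid):
        rng = np.random.default_rng(0)
        pc, pv = make_fields(grid, rng.uniform(-1, 1, grid.n_nodes),
                             rng.uniform(0, 1, grid.n_nodes))
        sq = space_quality(pc, pv).values
        assert np.all(np.abs(sq) <= np.minimum(np.abs(pc.values), pv.values) + 1e-12)

    def test_grid_mismatch_rejected(self, grid):
        other = sk.Grid.from_spacing(5.0)
        pc, _ = make_fields(grid, np.zeros(grid.n_nodes), np.zeros(grid.n_nodes))
        _, pv = make_fields(other, np.zeros(other.n_nodes), np.zeros(other.n_nodes))
        with pytest.raises(ValueError):
            space_quality(pc, pv)


def possession_with_fields(grid, sq_values, n_passes=2, origin=(0.0, 0.0),
                           dest=(10.0, 0.0)):
    passes = [
        PassEvent(event_id=f"e{i}", t_p=float(i), t_r=float(i) + 0.8, team="A",
                  passer_id="A1", receiver_id="A2", origin=origin, destination=dest)
        for i in range(n_passes)
    ]
    poss = Possession(possession_id=0, team_id="A", passes=passes)
    fields = {p.t_p: QualityField(grid=grid, values=np.asarray(sq_values, dtype=float),
                                  t=p.t_p) for p in passes}
    return poss, fields


class TestPossessionFeatures:
    def test_constant_sq_no_decay_sums_nodes(self, grid):
        c = 0.3
        poss, fields = possession_with_fields(grid, np.full(grid.n_nodes, c))
        f = possession_features(poss, fields, lambda_o=0.0, lambda_d=0.0)
        assert f.x_o == pytest.approx(c * grid.n_nodes)
        assert f.x_d == pytest.approx(c * grid.n_nodes)

    def test_large_decay_isolates_nearest_node(self, grid):
        dest = np.array([10.0, 0.0])
        i_near = int(np.argmin(np.linalg.norm(grid.nodes - dest, axis=1)))
        vals = np.zeros(grid.n_nodes)
        vals[i_near] = 1.0
        poss, fields = possession_with_fields(grid, vals, dest=tuple(dest))
        f = possession_features(poss, fields, lambda_o=10.0, lambda_d=10.0)
        d_near = np.linalg.norm(grid.nodes[i_near] - dest)
        assert f.x_d == pytest.approx(np.exp(-10.0 * d_near), rel=1e-9)

    def test_matches_naive_loop_oracle(self, grid):
        rng = np.random.default_rng(1)
        vals = rng.uniform(-0.5, 0.5, grid.n_nodes)
        poss, fields = possession_with_fields(grid, vals, n_passes=3)
        lam_o, lam_d = 0.2, 0.5
        f = possession_features(poss, fields, lam_o, lam_d)
        xo = xd = 0.0
        for p in poss.passes:
            for node, v in zip(grid.nodes, fields[p.t_p].values):
                xo += v * np.exp(-lam_o * np.linalg.norm(node - np.asarray(p.origin)))
                xd += v * np.exp(-lam_d * np.linalg.norm(node - np.asarray(p.destination)))
        assert f.x_o == pytest.approx(xo / poss.n_p, rel=1e-9)
        assert f.x_d == pytest.approx(xd / poss.n_p, rel=1e-9)

    def test_features_shrink_with_lambda(self, grid):
        poss, fields = possession_with_fields(grid, np.full(grid.n_nodes, 0.4))
        lams = [0.0, 0.05, 0.2, 1.0, 5.0]
        xs = [possession_features(poss, fields, lam, lam).x_o for lam in lams]
        assert all(b <= a for a, b in zip(xs, xs[1:]))

    def test_missing_field_is_error(self, grid):
        poss, fields = possession_with_fields(grid, np.zeros(grid.n_nodes))
        del fields[poss.passes[0].t_p]
        with pytest.raises(KeyError):
            possession_features(poss, fields, 0.1, 0.1)


class TestOutcomeExperiment:
    def test_null_labels_auc_near_half(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(800, 2))
        y = rng.random(800) < 0.2
        aucs = outcome_experiment(X, y, n_repeats=50, seed=1)
        assert 0.42 <= aucs.mean() <= 0.58

    def test_planted_signal_detected(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(800, 2))
        p = 1.0 / (1.0 + np.exp(-(-2.0 + 3.0 * X[:, 1])))
        y = rng.random(800) < p
        aucs = outcome_experiment(X, y, n_repeats=50, seed=1)
        assert aucs.mean() >= 0.65

    def test_same_seed_identical_sequence(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(300, 2))
        y = rng.random(300) < 0.3
        a1 = outcome_experiment(X, y, n_repeats=10, seed=7)
        a2 = outcome_experiment(X, y, n_repeats=10, seed=7)
        assert np.array_equal(a1, a2)


@pytest.fixture(scope="module")
def small_grid():
    return sk.Grid.from_spacing(6.0)


class TestSpaceGeneration:

    def test_lone_player_zero(self, small_grid):
        st = PlayerState("P", "A", p_t=[0.0, 0.0], p_tdelta=[0.0, 0.0])
        fr = TrackingFrame(t=0.0, players=[st], ball=np.zeros(2))
        sg = space_generation(fr, "P", sk.GaussianInfluence(), ConstDI(), small_grid)
        assert sg == 0.0

    def test_identical_twins_cancel(self, small_grid):
        sts = [PlayerState(p, "A", p_t=[5.0, 5.0], p_tdelta=[4.8, 5.0])
               for p in ("P", "Q")]
        fr = TrackingFrame(t=0.0, players=sts, ball=np.zeros(2))
        for pid in ("P", "Q"):
            sg = space_generation(fr, pid, sk.GaussianInfluence(), ConstDI(), small_grid)
            assert sg == pytest.approx(0.0, abs=1e-12)

    def test_matches_triple_loop_oracle(self, small_grid):
        rng = np.random.default_rng(4)
        fr = random_frame(rng, n_per_team=3)  # 6 players (5 rivals)
        backend = sk.GaussianInfluence()
        di = ConstDI(0.8)
        target = fr.players[0].player_id
        got = space_generation(fr, target, backend, di, small_grid)
        pi, order = _influence_matrix(fr, backend, small_grid, None)
        vf = pitch_value(di, fr.ball, small_grid, 1, pitch=small_grid.pitch)
        i = order.index(target)
        oracle = 0.0
        for k, node in enumerate(small_grid.nodes):  # naive sum over (p, j)
            for j in range(len(order)):
                if j == i:
                    continue
                diff = pi[i, k] * vf.values[k] - pi[j, k] * vf.values[k]
                oracle += max(diff, 0.0)
        assert got == pytest.approx(oracle, abs=1e-12)

    def test_nonnegative_and_rival_relabeling_invariant(self, small_grid):
        rng = np.random.default_rng(5)
        fr = random_frame(rng, n_per_team=4)
        backend = sk.GaussianInfluence()
        sg1 = space_generation(fr, fr.players[0].player_id, backend, ConstDI(), small_grid)
        assert sg1 >= 0.0
        for s in fr.players[1:]:
            s.player_id = "X" + s.player_id
        sg2 = space_generation(fr, fr.players[0].player_id, backend, ConstDI(), small_grid)
        assert sg2 == sg1


class TestAggregation:
    def make_events(self):
        evs = []
        # A2 receives 3 passes with SG 1, 2, 3 (passer A1)
        for i, sgv in enumerate([1.0, 2.0, 3.0]):
            evs.append(PassEvent(f"r{i}", float(i), i + 0.5, "A", "A1", "A2",
                                 (0, 0), (5, 0)))
        sg = {"r0": 1.0, "r1": 2.0, "r2": 3.0}
        return evs, sg

    def test_receiver_mean(self):
        evs, sg = self.make_events()
        rep = sk.aggregate_sg(evs, sg, minutes=90.0)
        assert rep["A2"].sg_rec == pytest.approx(2.0)
        assert rep["A2"].n_received == 3
        assert rep["A1"].sg_pas == pytest.approx(2.0)
        assert rep["A2"].sg_total == rep["A2"].sg_rec + rep["A2"].sg_pas

    def test_below_threshold_flagged_not_dropped(self):
        evs, sg = self.make_events()
        rep = sk.aggregate_sg(evs, sg, minutes=90.0, min_involvements=30)
        assert rep["A2"].flagged and rep["A2"].involvements == 3
        rep2 = sk.aggregate_sg(evs, sg, minutes=90.0, min_involvements=2)
        assert not rep2["A2"].flagged

    def test_per90_scaling(self):
        evs, sg = self.make_events()
        rep = sk.aggregate_sg(evs, sg, minutes=45.0)
        assert rep["A2"].sg_rec_per90 == pytest.approx(sum(sg.values()) * 2.0)


class TestPassNetwork:
    def make_events(self):
        evs = [PassEvent(f"e{i}", float(i), i + 0.5, "A", "13", "6", (0, 0), (5, 0))
               for i in range(10)]
        evs.append(PassEvent("x0", 20.0, 20.5, "A", "11", "6", (0, 0), (5, 0)))
        sg = {e.event_id: float(i) for i, e in enumerate(evs)}
        return evs, sg

    def test_edge_counts(self):
        evs, sg = self.make_events()
        table, per_pass = pass_network(evs, sg, focus_player="6")
        row = table[table["passer_id"] == "13"].iloc[0]
        assert row["n_passes"] == 10
        assert len(per_pass) == 11

    def test_table_means_match_per_pass_list(self):
        evs, sg = self.make_events()
        table, per_pass = pass_network(evs, sg, focus_player="6")
        for _, row in table.iterrows():
            vals = [p["sg"] for p in per_pass if p["passer_id"] == row["passer_id"]]
            assert row["mean_sg"] == pytest.approx(np.mean(vals))

    def test_absent_focus_player_empty(self):
        evs, sg = self.make_events()
        table, per_pass = pass_network(evs, sg, focus_player="99")
        assert table.empty and per_pass == []
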
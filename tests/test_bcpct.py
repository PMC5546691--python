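import numpy as np
import pandas as pd
import pytest

from bcflux import (
    AdjacencyModel,
    BCPercentModel,
    NeighborRole,
    OTUTable,
    SampleKey,
    SimConfig,
    ValidationError,
    bc_decompose,
    bcpct_timeseries,
    build_neighbor_set,
    interaction_network,
    simulate_system,
)
from conftest import make_table

ADJ3 = AdjacencyModel.fully_connected(["A", "S", "W"])


def keys(spec):
    """Build SampleKeys from 'A0 S0 W0 A1 ...' shorthand."""
    return {SampleKey(s[0], int(s[1:])) for s in spec.split()}


class TestBuildNeighborSet:
    def test_interior_point_has_five_neighbors(self):
        avail = keys("A0 S0 W0 A1 S1 W1")
        slots = build_neighbor_set(SampleKey("A", 1), avail, ADJ3)
        assert len(slots) == 5
        roles = sorted(s.role.value for s in slots)
        assert roles.count("inner") == 1
        assert roles.count("spatial_current") == 2
        assert roles.count("spatial_previous") == 2
        inner = next(s for s in slots if s.role is NeighborRole.INNER)
        assert inner.key == SampleKey("A", 0)

    def test_earliest_time_point_has_spatial_current_only(self):
        avail = keys("A0 S0 W0 A1 S1 W1")
        slots = build_neighbor_set(SampleKey("A", 0), avail, ADJ3)
        assert len(slots) == 2
        assert {s.role for s in slots} == {NeighborRole.SPATIAL_CURRENT}
        assert {s.key.compartment for s in slots} == {"S", "W"}

    def test_previous_means_previous_sampled_time(self):
        # irregular day grid: previous of day 11 is day 7, not day 10
        avail = keys("A2 A7 A11 S2 S7 S11 W2 W7 W11")
        slots = build_neighbor_set(SampleKey("A", 11), avail, ADJ3)
        inner = next(s for s in slots if s.role is NeighborRole.INNER)
        assert inner.key.time_index == 7

    def test_nearest_earlier_policy_fills_missing_current(self):
        # S has no sample at t=2; its latest earlier sample (t=1) fills in
        avail = keys("A0 S0 W0 A1 S1 W1 A2 W2")
        slots = build_neighbor_set(SampleKey("A", 2), avail, ADJ3)
        s_cur = next(
            s for s in slots
            if s.role is NeighborRole.SPATIAL_CURRENT and s.key.compartment == "S"
        )
        assert s_cur.key.time_index == 1
        assert s_cur.lag == 1
        s_prev = next(
            s for s in slots
            if s.role is NeighborRole.SPATIAL_PREVIOUS and s.key.compartment == "S"
        )
        assert s_prev.key.time_index == 0  # slides back behind the substitute

    def test_drop_slot_policy_omits_missing_current(self):
        avail = keys("A0 S0 W0 A1 S1 W1 A2 W2")
        slots = build_neighbor_set(
            SampleKey("A", 2), avail, ADJ3, policy="drop-slot"
        )
        s_slots = [s for s in slots if s.key.compartment == "S"]
        assert len(s_slots) == 1
        assert s_slots[0].role is NeighborRole.SPATIAL_PREVIOUS
        assert s_slots[0].key.time_index == 1

    def test_focal_must_be_available(self):
        with pytest.raises(ValidationError, match="not among"):
            build_neighbor_set(SampleKey("A", 5), keys("A0"), ADJ3)

    def test_adjacency_restricts_spatial_slots(self):
        adj = AdjacencyModel.from_pairs(["A", "S", "W"], [("A", "S")])
        avail = keys("A0 S0 W0 A1 S1 W1")
        slots = build_neighbor_set(SampleKey("A", 1), avail, adj)
        assert {s.key.compartment for s in slots} == {"A", "S"}
        assert len(slots) == 3


class TestBCDecompose:
    def test_equal_similarities_give_uniform_budget(self):
        # identical communities everywhere: all five BC = 1 -> 20% each
        col = [5, 3, 2]
        table = make_table(
            {f"{c}{t}": col for c in "ASW" for t in (0, 1)},
            {f"{c}{t}": (c, t) for c in "ASW" for t in (0, 1)},
        )
        d = bc_decompose(SampleKey("A", 1), table, ADJ3)
        assert d.defined and not d.boundary
        for _, bc, pct in d.terms:
            assert bc == pytest.approx(1.0)
            assert pct == pytest.approx(20.0)
        assert d.inner_pct == pytest.approx(20.0)
        assert d.external_pct["S"] == pytest.approx(40.0)

    def test_only_inner_nonzero_gives_hundred(self):
        a = [5, 5, 0, 0]
        other = [0, 0, 3, 3]
        table = make_table(
            {
                "A0": a, "A1": a,
                "S0": other, "S1": other,
                "W0": other, "W1": other,
            },
            {f"{c}{t}": (c, t) for c in "ASW" for t in (0, 1)},
        )
        d = bc_decompose(SampleKey("A", 1), table, ADJ3)
        assert d.inner_pct == pytest.approx(100.0)
        assert d.total_external_pct == pytest.approx(0.0)

    def test_hand_normalized_budget(self):
        """BC values (inner .4, S-cur .3, S-prev .2, W-cur .06, W-prev .04)
        must yield inner 40%, external S 50%, external W 10%."""
        # construct samples whose abundance-mode BC against A1 hits the targets:
        # disjoint designated blocks shared only with A1 at the right mass.
        # A1 spreads mass over blocks b_inner..b_wprev plus its own block.
        def vec(shared_block, shared_mass):
            v = np.zeros(12)
            v[shared_block] = shared_mass * 100
            v[11] = (1 - shared_mass) * 100  # private filler OTU
            return v.astype(int).tolist()

        a1 = np.zeros(12)
        a1[0], a1[1], a1[2], a1[3], a1[4] = 40, 30, 20, 6, 4
        table = make_table(
            {
                "A1": a1.astype(int).tolist(),
                "A0": vec(0, 0.40),
                "S1": vec(1, 0.30),
                "S0": vec(2, 0.20),
                "W1": vec(3, 0.06),
                "W0": vec(4, 0.04),
            },
            {
                "A1": ("A", 1), "A0": ("A", 0), "S1": ("S", 1),
                "S0": ("S", 0), "W1": ("W", 1), "W0": ("W", 0),
            },
        )
        d = bc_decompose(SampleKey("A", 1), table, ADJ3)
        assert d.inner_pct == pytest.approx(40.0, abs=1e-9)
        assert d.external_pct["S"] == pytest.approx(50.0, abs=1e-9)
        assert d.external_pct["W"] == pytest.approx(10.0, abs=1e-9)

    def test_budget_conservation(self):
        truth = simulate_system(SimConfig(n_otus=80, depth=1500, n_times=4, seed=0))
        for d in bcpct_timeseries(truth.table, ADJ3):
            if d.defined:
                assert d.inner_pct + sum(d.external_pct.values()) == pytest.approx(
                    100.0, abs=1e-6
                )

    def test_percentages_invariant_to_bc_rescaling(self):
        # scaling every sample's counts by a constant leaves percentages fixed
        truth = simulate_system(SimConfig(n_otus=40, depth=900, n_times=3, seed=5))
        t1 = truth.table
        t2 = OTUTable(t1.counts * 7, t1.metadata)
        for da, db in zip(bcpct_timeseries(t1, ADJ3), bcpct_timeseries(t2, ADJ3)):
            if da.defined:
                assert da.inner_pct == pytest.approx(db.inner_pct, abs=1e-9)

    def test_zero_budget_is_undefined_not_uniform(self):
        # focal shares nothing with any neighbor
        table = make_table(
            {
                "A1": [0, 0, 9], "A0": [5, 0, 0],
                "S1": [5, 0, 0], "S0": [5, 0, 0],
                "W1": [0, 5, 0], "W0": [0, 5, 0],
            },
            {f"{c}{t}": (c, t) for c in "ASW" for t in (0, 1)},
        )
        d = bc_decompose(SampleKey("A", 1), table, ADJ3)
        assert not d.defined
        assert d.inner_pct is None

    def test_all_zero_focal_rejected(self):
        table = make_table(
            {"A1": [0, 0], "A0": [5, 0], "S1": [5, 0], "S0": [1, 1],
             "W0": [1, 1], "W1": [1, 1]},
            {f"{c}{t}": (c, t) for c in "ASW" for t in (0, 1)},
        )
        with pytest.raises(ValidationError, match="zero total"):
            bc_decompose(SampleKey("A", 1), table, ADJ3)


class TestTimeseriesAndNetwork:
    def test_static_system_uniform_over_neighbor_count(self):
        col = [4, 4, 2]
        table = make_table(
            {f"{c}{t}": col for c in "ASW" for t in range(3)},
            {f"{c}{t}": (c, t) for c in "ASW" for t in range(3)},
        )
        decomps = bcpct_timeseries(table, ADJ3)
        assert len(decomps) == 9
        for d in decomps:
            for _, _, pct in d.terms:
                assert pct == pytest.approx(100.0 / d.n_neighbors)

    def test_boundary_flagged_first_time_point(self):
        truth = simulate_system(SimConfig(n_otus=40, depth=800, n_times=3, seed=1))
        for d in bcpct_timeseries(truth.table, ADJ3):
            assert d.boundary == (d.focal.time_index == 0)

    def test_zero_migration_disjoint_pools(self):
        cfg = SimConfig(
            n_otus=90, depth=2000, n_times=5, migration={}, init_overlap=0.0,
            seed=3,
        )
        res = BCPercentModel(simulate_system(cfg).table).fit()
        for d in res.decompositions:
            if d.focal.time_index == 0 or not d.defined:
                continue
            assert d.inner_pct == pytest.approx(100.0)
            assert d.total_external_pct == pytest.approx(0.0)

    def test_missing_time_point_leaves_others_unaffected(self):
        rng = np.random.default_rng(0)
        cols = {
            f"{c}{t}": (rng.integers(1, 30, 5)).tolist()
            for c in "ASW" for t in range(3)
        }
        meta = {sid: (sid[0], int(sid[1:])) for sid in cols}
        full = make_table(cols, meta)
        gappy_cols = {k: v for k, v in cols.items() if k not in ("S1", "S2")}
        gappy = make_table(gappy_cols, {k: meta[k] for k in gappy_cols})
        d_full = bc_decompose(SampleKey("W", 2), full, ADJ3)
        d_gap = bc_decompose(SampleKey("W", 2), gappy, ADJ3)
        # W2's A-slots are identical; only the S slots differ
        full_a = {s.key: pct for s, _, pct in d_full.terms if s.key.compartment == "A"}
        gap_a_bc = {s.key: bc for s, bc, _ in d_gap.terms if s.key.compartment == "A"}
        full_a_bc = {s.key: bc for s, bc, _ in d_full.terms if s.key.compartment == "A"}
        assert gap_a_bc == full_a_bc
        s_cur = next(
            s for s, _, _ in d_gap.terms
            if s.key.compartment == "S" and s.role is NeighborRole.SPATIAL_CURRENT
        )
        assert s_cur.key.time_index == 0 and s_cur.lag == 2

    def test_single_window_network_equals_point_values(self):
        truth = simulate_system(SimConfig(n_otus=50, depth=1000, n_times=4, seed=8))
        decomps = bcpct_timeseries(truth.table, ADJ3)
        net = interaction_network(decomps, [(2, 2)])[0]
        d_a2 = next(
            d for d in decomps
            if d.focal == SampleKey("A", 2)
        )
        assert net.nodes["A"] == pytest.approx(d_a2.inner_pct)
        assert net.edges[("S", "A")] == pytest.approx(d_a2.external_pct["S"])

    def test_network_conserves_budget(self):
        truth = simulate_system(SimConfig(n_otus=50, depth=1000, n_times=5, seed=4))
        decomps = bcpct_timeseries(truth.table, ADJ3)
        net = interaction_network(decomps, [(1, 4)])[0]
        for target, inner in net.nodes.items():
            incoming = sum(w for (s, t), w in net.edges.items() if t == target)
            assert inner + incoming == pytest.approx(100.0, abs=1e-6)

    def test_empty_window_rejected(self):
        truth = simulate_system(SimConfig(n_otus=30, depth=500, n_times=3, seed=4))
        decomps = bcpct_timeseries(truth.table, ADJ3)
        with pytest.raises(ValidationError, match="window"):
            interaction_network(decomps, [(99, 100)])


@pytest.fixture(scope="module")
def results():
    truth = simulate_system(SimConfig(n_otus=60, depth=1200, n_times=5, seed=6))
    return BCPercentModel(truth.table).fit()


class TestModelResults:
    def test_trajectory_is_long_format(self, results):
        traj = results.trajectory
        assert {"compartment", "time_index", "role", "source", "pct"} <= set(
            traj.columns
        )
        # defined decompositions sum to 100 per focal sample
        sums = (
            traj[traj["defined"]]
            .groupby(["compartment", "time_index"])["pct"]
            .sum()
        )
        assert np.allclose(sums, 100.0, atol=1e-6)

    def test_inner_series_shape(self, results):
        inner = results.inner_series()
        assert list(inner.index) == ["A", "S", "W"]
        assert set(inner.columns) <= set(range(5))

    def test_summary_mentions_key_facts(self, results):
        text = results.summary()
        assert "Inner BC%" in text
        assert "S -> A" in text

    def test_default_windows_are_first_and_last(self, results):
        nets = results.interaction_network()
        assert nets[0].window == (0, 0)
        assert nets[1].window == (4, 4)

    def test_from_dataframes_constructor(self, toy_table):
        meta = pd.DataFrame(
            [
                {"sample_id": s, "compartment": k.compartment, "time_index": k.time_index}
                for s, k in toy_table.metadata.items()
            ]
        )
        model = BCPercentModel.from_dataframes(toy_table.counts, meta)
        res = model.fit()
        assert len(res.decompositions) > 0

    def test_plot_smoke(self, results):
        import matplotlib

        matplotlib.use("Agg")
        fig = results.plot_stacked("A")
        assert fig is not None

    def test_replicates_rejected(self):
        df = pd.DataFrame({"x": [1], "y": [2]}, index=["o1"])
        meta = {"x": SampleKey("A", 0, "r1"), "y": SampleKey("A", 0, "r2")}
        with pytest.raises(ValidationError, match="replicate"):
            BCPercentModel(OTUTable(df, meta), adjacency=ADJ3).fit()
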
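import numpy as np
import pytest

from rpsmeta.dynamics import (
    IntegrationError,
    MetaState,
    Rates,
    integrate,
    integrate_single_habitat,
    lv_invariant,
    migration_term,
    reaction_term,
    read_trajectory_csv,
    rhs,
    write_trajectory_csv,
)
from rpsmeta.equilibria import network_equilibrium
from rpsmeta.graphs import complete_graph, path_graph


def paper_initial(n=3):
    init = np.full((3, n), 0.1)
    init[0, 2] = 0.2
    return MetaState(init)


class TestRates:
    @pytest.mark.parametrize("bad", [0.0, -1.0, np.inf, np.nan])
    def test_nonpositive_rates_rejected(self, bad):
        with pytest.raises(ValueError):
            Rates(bad, 1.0, 1.0)

    def test_cycled_rotates_the_triple(self):
        assert Rates(1.0, 2.0, 3.0).cycled().as_tuple() == (2.0, 3.0, 1.0)


class TestReactionTerm:
    @pytest.mark.parametrize(
        "state, rates, expected",
        [
            ((1 / 3, 1 / 3, 1 / 3), Rates(), (0.0, 0.0, 0.0)),
            ((1.0, 0.0, 0.0), Rates(2.0, 0.5, 3.0), (0.0, 0.0, 0.0)),
            # direct substitution: a=b=c=1, (0.4, 0.2, 0.4)
            ((0.4, 0.2, 0.4), Rates(), (-0.08, 0.0, 0.08)),
        ],
    )
    def test_known_values(self, state, rates, expected):
        assert reaction_term(state, rates) == pytest.approx(expected, abs=1e-15)

    def test_components_cancel_exactly(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            s = rng.uniform(0, 1, 3)
            r = Rates(*rng.uniform(0.1, 3, 3))
            assert reaction_term(s, r).sum() == pytest.approx(0.0, abs=1e-15)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            reaction_term((-0.1, 0.5, 0.6), Rates())


class TestMigrationTerm:
    def test_degree_proportional_state_is_stationary(self):
        g = path_graph(3)
        share = g.degrees / g.degrees.sum()
        state = MetaState(np.outer([0.5, 0.3, 0.2], share))
        assert np.abs(migration_term(state, g)).max() == pytest.approx(0.0, abs=1e-16)

    def test_uniform_state_stationary_on_complete_graph(self):
        g = complete_graph(3)
        state = MetaState(np.full((3, 3), 1 / 9))
        assert np.abs(migration_term(state, g)).max() == pytest.approx(0.0, abs=1e-15)

    def test_single_occupied_leaf_on_path3(self):
        # node 2 (degree 1) empties into the center at unit rate
        g = path_graph(3)
        state = MetaState(np.array([[0.0, 1.0, 0.0], [0] * 3, [0] * 3], float))
        out = migration_term(state, g)
        assert out[0] == pytest.approx([1.0, -1.0, 0.0], abs=1e-15)
        assert np.abs(out[1:]).max() == 0.0

    def test_conserves_each_species_exactly(self):
        rng = np.random.default_rng(11)
        g = path_graph(5)
        state = MetaState(rng.uniform(0, 1, (3, 5)))
        sums = migration_term(state, g).sum(axis=1)
        assert np.abs(sums).max() == pytest.approx(0.0, abs=1e-14)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            migration_term(MetaState(np.full((3, 4), 1 / 12)), path_graph(3))


class TestRhs:
    def test_vanishes_at_network_equilibrium(self, path3, unit_rates):
        eq = network_equilibrium(path3, unit_rates)
        assert np.abs(rhs(0.0, eq, path3, unit_rates)).max() < 1e-15

    def test_reduces_to_reaction_on_synchronized_complete_graph(self, triangle):
        rates = Rates(1.2, 0.9, 1.4)
        node = np.array([0.15, 0.1, 0.08])
        state = MetaState(np.tile(node[:, None], 3) / (3 * node.sum()) * node.sum())
        full = rhs(0.0, state, triangle, rates)
        per_node = reaction_term(state.rho[:, 0], rates)
        for i in range(3):
            assert full[:, i] == pytest.approx(per_node, abs=1e-15)

    def test_total_derivative_sums_to_zero(self, path3):
        rng = np.random.default_rng(3)
        state = MetaState(rng.uniform(0, 1, (3, 3)))
        assert rhs(0.0, state, path3, Rates(1.3, 0.8, 1.1)).sum() == pytest.approx(0.0, abs=1e-14)


class TestIntegrate:
    def test_equilibrium_start_stays_constant(self, path3, unit_rates):
        eq = network_equilibrium(path3, unit_rates)
        tr = integrate(eq, path3, unit_rates, t_end=50.0, n_points=201)
        assert np.abs(tr.states - eq.rho).max() < 1e-10

    def test_conservation_and_positivity(self, triangle, unit_rates):
        tr = integrate(paper_initial(), triangle, unit_rates, t_end=200.0, n_points=1001)
        total = tr.total_density()
        assert np.abs(total - 1.0).max() < 1e-9
        assert tr.states.min() > 0.0

    def test_cyclic_relabeling_symmetry(self, path3):
        # R->S->P->R with rates (a,b,c)->(b,c,a) permutes the trajectory
        rates = Rates(1.3, 0.7, 1.1)
        rng = np.random.default_rng(5)
        init = rng.uniform(0.05, 0.15, (3, 3))
        init /= init.sum()
        perm = [1, 2, 0]
        tr1 = integrate(MetaState(init), path3, rates, t_end=60.0, n_points=301)
        tr2 = integrate(MetaState(init[perm]), path3, rates.cycled(), t_end=60.0, n_points=301)
        assert np.abs(tr2.states - tr1.states[:, perm, :]).max() < 1e-8

    def test_unnormalized_initial_rejected(self, triangle, unit_rates):
        bad = MetaState(np.full((3, 3), 0.2))
        with pytest.raises(ValueError, match="sums to"):
            integrate(bad, triangle, unit_rates, t_end=10.0)

    def test_negative_initial_rejected(self, triangle, unit_rates):
        arr = np.full((3, 3), 1 / 9)
        arr[0, 0] = -0.01
        arr[1, 0] = 2 / 9 + 0.01
        with pytest.raises(ValueError, match="negative"):
            integrate(MetaState(arr), triangle, unit_rates, t_end=10.0)


class TestLvInvariant:
    def test_symmetric_equilibrium_value(self):
        assert lv_invariant((1 / 3, 1 / 3, 1 / 3), Rates()) == pytest.approx(3 * np.log(1 / 3))

    def test_zero_density_rejected(self):
        with pytest.raises(ValueError):
            lv_invariant((0.0, 0.5, 0.5), Rates())

    def test_conserved_on_single_habitat_run(self):
        rates = Rates(0.8, 1.0, 1.0)
        tr = integrate_single_habitat((0.4, 0.2, 0.4), rates, t_end=500.0, n_points=2001)
        v = np.array([lv_invariant(s[:, 0], rates) for s in tr.states])
        assert np.abs(v - v[0]).max() < 1e-6

    def test_conserved_per_node_on_synchronized_attractor(self, fig2a_result, unit_rates):
        # on the homogeneous graph the late-time dynamics reduce to a
        # rescaled single-habitat system, so per-node V is constant too
        tr = fig2a_result.trajectory
        half = len(tr.times) // 2
        v = np.array([lv_invariant(s[:, 0], unit_rates) for s in tr.states[half:]])
        assert np.abs(v - v[0]).max() < 1e-5


class TestTrajectoryIO:
    def test_csv_round_trip(self, tmp_path, path3, unit_rates):
        tr = integrate(paper_initial(), path3, unit_rates, t_end=5.0, n_points=41)
        p = tmp_path / "traj.csv"
        write_trajectory_csv(tr, p)
        back = read_trajectory_csv(p, rates=unit_rates, graph=path3)
        assert np.abs(back.times - tr.times).max() < 1e-9
        assert np.abs(back.states - tr.states).max() < 1e-9

    def test_series_uses_one_based_nodes(self, fig2b_result):
        tr = fig2b_result.trajectory
        assert tr.series("R", 1)[0] == pytest.approx(0.4)
        with pytest.raises(ValueError):
            tr.series("R", 2)
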
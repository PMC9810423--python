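import numpy as np
import pytest

import growthctl as g
from growthctl.biculture import (
    classify_outcome,
    resolve_pair_strategy,
    tabulate_outcomes,
)
from growthctl.model import GrowthMode
from growthctl.strategies import GreedyPlaneStrategy, PurePairStrategy


@pytest.fixture(scope="module")
def joint_config():
    return g.default_config(K=30, T=90, N_initial=3)


@pytest.fixture(scope="module")
def anticipative30(joint_config):
    return g.build_anticipative_tensor(joint_config, keep_gains=True)


@pytest.fixture(scope="module")
def joint_opt30(joint_config):
    return g.solve_biculture_optimal(joint_config)


class TestCompetitorRates:
    def test_zero_net_growth_at_joint_capacity(self, small_config):
        K = small_config.K
        beta, delta = g.competitor_rates(
            PurePairStrategy(GrowthMode.AGGRESSIVE), K - 20, 20, small_config
        )
        assert beta == pytest.approx(delta)

    def test_greedy_competitor_goes_defensive_above_K(self, small_config):
        K = small_config.K
        beta, _ = g.competitor_rates(
            GreedyPlaneStrategy(small_config), K - 10, 11, small_config
        )
        assert beta == small_config.rates_def.beta

    def test_reduces_to_monoculture_when_alone(self, small_config):
        for mode in GrowthMode:
            mono = g.effective_rates(mode, 23, small_config)
            bi = g.competitor_rates(PurePairStrategy(mode), 0, 23, small_config)
            assert bi == pytest.approx(mono)

    def test_out_of_range_joint_state_rejected(self, small_config):
        with pytest.raises(ValueError):
            g.competitor_rates(
                PurePairStrategy(GrowthMode.DEFENSIVE),
                small_config.n_top + 1,
                0,
                small_config,
            )


class TestAnticipativeTensor:
    def test_absent_competitor_slice_is_the_monoculture_map(
        self, joint_config, anticipative30
    ):
        cmap = g.solve_bellman(joint_config)
        assert np.array_equal(anticipative30.modes[:, :, 0], cmap.modes)

    def test_gain_boundary_is_focal_size_for_every_competitor(
        self, joint_config, anticipative30
    ):
        n = joint_config.n_states
        assert np.array_equal(
            anticipative30.gains[-1],
            np.broadcast_to(np.arange(n, dtype=float)[:, None], (n, n)),
        )

    def test_saturated_competitor_forces_terminal_defensive(
        self, joint_config, anticipative30
    ):
        """With the competitor at or above K the community exceeds
        capacity for any Na >= 1, so the terminal slice is defensive."""
        K = joint_config.K
        terminal = anticipative30.modes[-1]
        assert np.all(terminal[2:, K:] == GrowthMode.DEFENSIVE)


class TestGreedyPlane:
    def test_switch_at_community_capacity_and_symmetry(self, small_config):
        plane = g.greedy_plane(small_config)
        K = small_config.K
        assert plane[K, 0] == GrowthMode.AGGRESSIVE
        assert plane[K, 1] == GrowthMode.DEFENSIVE
        assert np.array_equal(plane, plane.T)

    def test_equals_tensor_terminal_slice_where_resolved(
        self, joint_config, anticipative30
    ):
        """The greedy plane is the tensor's last controlled slice; the
        comparison skips the focal-extinct column (defensive by the
        tie-break convention), community density exactly K (where the
        two gains tie up to rounding) and Na = 1, where the absorbing
        floor truncates losses and genuinely rewards the high-variance
        aggressive mode even above capacity."""
        plane = g.greedy_plane(joint_config)
        terminal = anticipative30.modes[-1]
        n = joint_config.n_states
        total = np.arange(n)[:, None] + np.arange(n)[None, :]
        resolved = (total != joint_config.K) & (np.arange(n)[:, None] > 1)
        assert np.array_equal(terminal[resolved], plane[resolved])


class TestJointOptimal:
    def test_reduces_to_monoculture_map_without_competitor(self, joint_config, joint_opt30):
        cmap = g.solve_bellman(joint_config)
        assert np.array_equal(joint_opt30.modes[:, :, 0], cmap.modes)

    def test_gain_boundary(self, joint_config, joint_opt30):
        n = joint_config.n_states
        assert np.array_equal(
            joint_opt30.gains[-1],
            np.broadcast_to(np.arange(n, dtype=float)[:, None], (n, n)),
        )

    def test_memory_budget_guard(self):
        with pytest.raises(g.JointStateSpaceError):
            g.solve_biculture_optimal(g.default_config(K=500, T=10))

    def test_solver_gain_matches_exact_propagation(
        self, joint_config, joint_opt30
    ):
        greedy = GreedyPlaneStrategy(joint_config)
        e = g.expected_final_focal(
            (3, 3), joint_opt30.strategy(), greedy, joint_config
        )
        assert e == pytest.approx(joint_opt30.gains[0, 3, 3], abs=1e-8)

    def test_dominates_anticipative_and_greedy_against_greedy(
        self, joint_config, joint_opt30, anticipative30
    ):
        """Exact joint propagation: the joint-state optimum is an upper
        bound among strategies of (Na, Nc, t), and strictly improves on
        the frozen-competitor (anticipative) tensor."""
        greedy = GreedyPlaneStrategy(joint_config)
        e_opt = g.expected_final_focal(
            (3, 3), joint_opt30.strategy(), greedy, joint_config
        )
        e_ant = g.expected_final_focal(
            (3, 3), anticipative30.strategy(), greedy, joint_config
        )
        e_gre = g.expected_final_focal((3, 3), greedy, greedy, joint_config)
        assert e_opt >= e_ant - 1e-9
        assert e_opt >= e_gre - 1e-9
        assert e_opt > e_ant + 0.01

    def test_preemptive_defensive_switch_below_capacity(
        self, joint_config, joint_opt30, anticipative30
    ):
        """Against a live competitor the joint optimum abandons the
        aggressive mode at community densities strictly below K, earlier
        than the frozen-competitor tensor does."""
        K = joint_config.K
        t = joint_config.T // 2

        def switch_density(modes_slice, c):
            col = modes_slice[5:, c]  # skip the low-density lag band
            idx = np.nonzero(col == GrowthMode.DEFENSIVE)[0]
            return idx[0] + 5 + c if idx.size else None

        pairs = []
        for c in range(1, K):
            so = switch_density(joint_opt30.modes[t], c)
            sa = switch_density(anticipative30.modes[t], c)
            if so is not None and sa is not None:
                pairs.append((so, sa))
        so, sa = np.array(pairs).T
        assert so.min() < K
        assert np.median(so) < np.median(sa)


class TestCompetitions:
    def test_outcome_classification(self):
        assert classify_outcome([5, 0]) == "focal_win"
        assert classify_outcome([0, 5]) == "focal_loss"
        assert classify_outcome([0, 0]) == "all_extinct"
        assert classify_outcome([3, 3]) == "coexist"

    def test_absent_competitor_gives_monoculture_outcome(self, small_config):
        proto = g.TransferProtocol(cycle_length=60, n_cycles=2, fraction=0.2)
        out = g.simulate_competition(
            GreedyPlaneStrategy(small_config),
            PurePairStrategy(GrowthMode.AGGRESSIVE),
            proto,
            small_config,
            seed=0,
            initial=(10, 0),
        )
        assert out.label == "focal_win"
        assert out.final_sizes[1] == 0

    def test_identical_strategies_win_and_lose_equally_often(self):
        """Symmetry: same strategy and initial sizes on both sides, so
        the win/loss split among decided runs is Binomial(1/2); assert
        inside the 99% interval over 2000 runs."""
        cfg = g.default_config(K=100)
        proto = g.TransferProtocol(
            cycle_length=60, n_cycles=4, rule="fixed_founders", founders=10
        )
        strat = PurePairStrategy(GrowthMode.AGGRESSIVE)
        labels = g.simulate_competition_batch(
            strat, strat, proto, cfg, 2000, seed=13, initial=(10, 10)
        )
        wins = int(np.sum(labels == "focal_win"))
        losses = int(np.sum(labels == "focal_loss"))
        decided = wins + losses
        assert decided > 100
        assert abs(wins - decided / 2) < 2.58 * np.sqrt(decided * 0.25) + 1

    def test_sweep_fractions_sum_to_one(self, small_config):
        proto = g.TransferProtocol(
            cycle_length=30, n_cycles=2, rule="fixed_founders", founders=5
        )
        table = g.sweep_cycle_lengths(
            ("aggressive", "defensive"), [20, 40], 200, proto, small_config, seed=3
        )
        sums = table[["win", "loss", "coexist", "all_extinct"]].sum(axis=1)
        assert np.allclose(sums, 1.0)
        assert list(table["T"]) == [20, 40]

    def test_tabulate_outcomes(self):
        labels = np.array(["focal_win", "focal_win", "coexist", "focal_loss"])
        tab = tabulate_outcomes(labels)
        assert tab["focal_win"] == 0.5
        assert tab["n_sims"] == 4

    def test_resolve_pair_strategy_names_and_cache(self, tiny_config):
        cache = {}
        for name in ("defensive", "aggressive", "greedy", "anticipative"):
            strat = resolve_pair_strategy(name, tiny_config, cache)
            assert strat.name == name
        again = resolve_pair_strategy("anticipative", tiny_config, cache)
        assert again.tensor is next(iter(cache.values()))
        with pytest.raises(ValueError):
            resolve_pair_strategy("bogus", tiny_config)
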
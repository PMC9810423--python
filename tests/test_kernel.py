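import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import skellam as scipy_skellam

import growthctl as g
from growthctl.kernel import MASS_TOL
from growthctl.strategies import PureStrategy

from conftest import skellam_oracle, skellam_oracle_lower_tail


class TestSkellamPmf:
    @pytest.mark.parametrize(
        "mu1, mu2",
        [(0.3, 0.1), (2.0, 1.0), (5.0, 5.0), (40.0, 25.0), (93.75, 56.25)],
    )
    def test_matches_poisson_convolution_oracle(self, mu1, mu2):
        for k in range(-30, 31, 5):
            assert g.skellam_pmf(mu1, mu2, k) == pytest.approx(
                skellam_oracle(mu1, mu2, k), abs=1e-12
            )

    def test_matches_scipy(self):
        ks = np.arange(-20, 21)
        assert np.allclose(
            g.skellam_pmf(3.5, 1.2, ks), scipy_skellam.pmf(ks, 3.5, 1.2), atol=1e-13
        )

    def test_no_deaths_reduces_to_poisson(self):
        from scipy.stats import poisson

        assert g.skellam_pmf(2.5, 0.0, 3) == pytest.approx(poisson.pmf(3, 2.5))
        assert g.skellam_pmf(2.5, 0.0, -1) == 0.0

    def test_equal_intensities_give_symmetry(self):
        for k in (1, 4, 9):
            assert g.skellam_pmf(3.0, 3.0, k) == pytest.approx(
                g.skellam_pmf(3.0, 3.0, -k), rel=1e-12
            )

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            g.skellam_pmf(-1.0, 2.0, 0)

    @settings(derandomize=True, max_examples=60)
    @given(
        mu1=st.floats(0.0, 120.0),
        mu2=st.floats(0.0, 160.0),
        k=st.integers(-40, 40),
    )
    def test_pmf_is_probability_mass(self, mu1, mu2, k):
        p = g.skellam_pmf(mu1, mu2, k)
        assert 0.0 <= p <= 1.0


class TestTransitionRow:
    def test_extinct_source_is_point_mass(self, tiny_config):
        for mode in g.GrowthMode:
            row = g.transition_row(0, mode, tiny_config)
            assert row.probs[0] == 1.0
            assert row.probs[1:].sum() == 0.0

    @pytest.mark.parametrize("N", [1, 5, 10, 15])
    @pytest.mark.parametrize("mode", list(g.GrowthMode))
    def test_rows_are_normalized(self, tiny_config, N, mode):
        row = g.transition_row(N, mode, tiny_config)
        assert abs(row.probs.sum() - 1.0) < MASS_TOL
        assert np.all(row.probs >= 0)

    def test_interior_matches_skellam_oracle(self, tiny_config):
        N, mode = 8, g.GrowthMode.AGGRESSIVE
        beta, delta = g.effective_rates(mode, N, tiny_config)
        row = g.transition_row(N, mode, tiny_config)
        for dest in range(1, tiny_config.n_top):
            assert row.probs[dest] == pytest.approx(
                skellam_oracle(N * beta, N * delta, dest - N), abs=1e-13
            )

    def test_absorbed_mass_is_skellam_lower_tail(self):
        """From N=10 under the aggressive mode all outcomes <= 0 land in
        the extinction state; that mass equals P(increment <= -10)."""
        cfg = g.default_config()
        N = 10
        beta, delta = g.effective_rates(g.GrowthMode.AGGRESSIVE, N, cfg)
        row = g.transition_row(N, g.GrowthMode.AGGRESSIVE, cfg)
        assert row.probs[0] == pytest.approx(
            skellam_oracle_lower_tail(N * beta, N * delta, -N), abs=1e-13
        )

    def test_top_state_lumps_upper_tail(self, tiny_config):
        N = tiny_config.n_top
        row = g.transition_row(N, g.GrowthMode.AGGRESSIVE, tiny_config)
        assert abs(row.probs.sum() - 1.0) < MASS_TOL
        assert row.probs[-1] > 0  # staying-or-overshooting mass is lumped

    def test_out_of_range_source_rejected(self, tiny_config):
        with pytest.raises(ValueError):
            g.transition_row(tiny_config.n_top + 1, g.GrowthMode.DEFENSIVE, tiny_config)

    def test_matrix_rows_match_single_rows(self, tiny_config):
        for mode in g.GrowthMode:
            W = g.transition_matrix(mode, tiny_config)
            assert np.abs(W.sum(axis=1) - 1.0).max() < MASS_TOL
            for N in (0, 3, 11):
                row = g.transition_row(N, mode, tiny_config)
                assert np.allclose(W[N], row.probs, atol=1e-14)


class TestPropagate:
    def test_single_step_equals_transition_row(self, tiny_config):
        strat = PureStrategy(g.GrowthMode.AGGRESSIVE)
        dist = g.PopulationDistribution.point_mass(6, tiny_config)
        out = g.propagate(dist, strat, tiny_config, 1)
        row = g.transition_row(6, g.GrowthMode.AGGRESSIVE, tiny_config)
        assert np.allclose(out.probs, row.probs, atol=1e-14)
        assert out.t == 1

    def test_mass_conserved_over_many_steps(self, small_config):
        strat = g.greedy_strategy(small_config)
        dist = g.PopulationDistribution.point_mass(
            small_config.N_initial, small_config
        )
        out = g.propagate(dist, strat, small_config, 200)
        assert abs(out.probs.sum() - 1.0) < MASS_TOL

    def test_equals_matrix_power_on_small_instance(self):
        """Propagation under a strategy is the repeated vector-matrix
        product with the strategy-induced transition matrix."""
        cfg = g.default_config(K=20, T=30, N_initial=4)
        strat = g.greedy_strategy(cfg)
        modes = strat.mode_vector(0, cfg.n_states)
        W_def = g.transition_matrix(g.GrowthMode.DEFENSIVE, cfg)
        W_aggr = g.transition_matrix(g.GrowthMode.AGGRESSIVE, cfg)
        W = np.where(modes[:, None] == 1, W_aggr, W_def)
        p = np.zeros(cfg.n_states)
        p[4] = 1.0
        for _ in range(25):
            p = p @ W
        out = g.propagate(
            g.PopulationDistribution.point_mass(4, cfg), strat, cfg, 25
        )
        assert np.allclose(out.probs, p, atol=1e-12)


class TestSummarize:
    def test_point_mass(self, tiny_config):
        dist = g.PopulationDistribution.point_mass(12, tiny_config)
        s = g.summarize(dist)
        assert (s.median, s.variance, s.extinction_probability) == (12, 0.0, 0.0)
        assert s.mean == 12.0

    def test_median_is_smallest_state_reaching_half(self):
        probs = np.zeros(10)
        probs[1:5] = 0.25
        assert g.summarize(g.PopulationDistribution(probs)).median == 2

    def test_defensive_mode_reduces_extinction_risk(self, paper_config):
        """Propagating both pure strategies from a small inoculum: the
        defensive mode's longer lifetime suppresses extinctions."""
        finals = {}
        for mode in g.GrowthMode:
            dist = g.PopulationDistribution.point_mass(10, paper_config)
            out = g.propagate(dist, PureStrategy(mode), paper_config, 400)
            finals[mode] = g.summarize(out).extinction_probability
        assert (
            finals[g.GrowthMode.DEFENSIVE] < finals[g.GrowthMode.AGGRESSIVE]
        )
        assert finals[g.GrowthMode.AGGRESSIVE] > 1e-4


def test_monte_carlo_total_variation_shrinks_with_replicates(small_config):
    """Empirical histograms converge to the exactly propagated law."""
    from growthctl.simulate import _step_sizes

    cfg = small_config
    strat = g.greedy_strategy(cfg)
    exact = g.propagate(
        g.PopulationDistribution.point_mass(cfg.N_initial, cfg), strat, cfg, 40
    )
    tvs = []
    for R in (500, 50_000):
        rng = np.random.default_rng(5)
        sizes = np.full(R, cfg.N_initial, dtype=np.int64)
        for t in range(40):
            modes = strat.mode_at(t, sizes).astype(np.int8)
            sizes = _step_sizes(sizes, modes, sizes, cfg, rng).astype(np.int64)
        emp = np.bincount(sizes, minlength=cfg.n_states) / R
        tvs.append(0.5 * np.abs(emp - exact.probs).sum())
    assert tvs[1] < tvs[0]
    assert tvs[1] < 0.05
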
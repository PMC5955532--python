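"""The stochastic occupation engine: placement, heating, deposition."""

import numpy as np
import pytest

from pyrolith.grid import make_rectangle, parse_area_file
from pyrolith.simulate import (
    NEAR_RADIUS,
    FirePlacement,
    LithicPlacement,
    ScatterKernel,
    SimulationConfig,
    _footprint,
    choose_scatter_centroid,
    deposit_scatter,
    expected_heated_pct_random,
    fire_schedule,
    heat_underlying,
    heated_percentage,
    place_fires,
    run_experiment,
    valid_fire_anchors,
    LayerState,
)


def make_state(grid, n_occupations=30):
    return LayerState(grid, n_occupations)


class TestFireSchedule:
    def test_no_skip_all_fire_bearing(self):
        assert fire_schedule(30, 0) == [True] * 30

    def test_every_third_occupation(self):
        flags = fire_schedule(30, 2)
        assert sum(flags) == 10
        assert [i for i, f in enumerate(flags, start=1) if f][:3] == [1, 4, 7]

    def test_skip_five_gives_five_fire_occupations(self):
        assert sum(fire_schedule(30, 5)) == 5  # ceil(30 / 6)

    @pytest.mark.parametrize("n,skip", [(1, 0), (7, 3), (100, 99)])
    def test_first_occupation_always_fire_bearing(self, n, skip):
        assert fire_schedule(n, skip)[0] is True


class TestPlaceFires:
    def test_single_cell_grid_forces_anchor(self, rng):
        grid = make_rectangle(1, 1)
        cfg = SimulationConfig(grid=grid, n_occupations=5)
        state = make_state(grid, 5)
        for _ in range(5):
            (fp,) = place_fires(state, cfg, 0, rng)
            assert fp.anchor == (0, 0)

    def test_random_placement_is_uniform(self, square7, rng):
        cfg = SimulationConfig(grid=square7, n_occupations=1)
        state = make_state(square7, 1)
        n_draws = 20_000
        counts = np.zeros(49)
        idx = {rc: i for i, rc in enumerate(state.coords)}
        for _ in range(n_draws):
            (fp,) = place_fires(state, cfg, 0, rng)
            counts[idx[fp.anchor]] += 1
        p = 1 / 49
        se = np.sqrt(n_draws * p * (1 - p))
        assert np.all(np.abs(counts - n_draws * p) < 3.5 * se)

    def test_near_previous_stays_in_neighbourhood(self, square7, rng):
        cfg = SimulationConfig(
            grid=square7, n_occupations=10, fire_placement=FirePlacement.FNP
        )
        state = run_experiment(cfg, rng)
        anchors = [rec.hearths[0].anchor for rec in state.records]
        for prev, cur in zip(anchors, anchors[1:]):
            assert max(abs(prev[0] - cur[0]), abs(prev[1] - cur[1])) <= NEAR_RADIUS

    def test_size4_anchors_keep_block_on_floor(self, rng):
        grid = parse_area_file("IIW\nIIW\nIII")
        anchors = valid_fire_anchors(grid, 4)
        assert anchors == [(0, 0), (1, 0)]
        cfg = SimulationConfig(grid=grid, n_occupations=3, fire_size=4)
        state = make_state(grid, 3)
        for _ in range(20):
            (fp,) = place_fires(state, cfg, 0, rng)
            assert all(grid.is_interior(r, c) for r, c in fp.cells)
            assert len(set(fp.cells)) == 4

    def test_size4_impossible_on_single_row(self):
        with pytest.raises(ValueError, match="no valid anchor"):
            SimulationConfig(grid=make_rectangle(1, 8), n_occupations=5, fire_size=4)


class TestHeatUnderlying:
    def setup_cohort(self, grid, cell, occ, count):
        state = make_state(grid, 10)
        state.unheated[state.cell_index[cell], occ] = count
        return state

    def test_zero_tb_heats_everything_below(self, square7, rng):
        state = self.setup_cohort(square7, (3, 3), 0, 100)
        heat_underlying(state, _footprint((3, 3), 1, 5), 5, tb_pct=0.0, rng=rng)
        ci = state.cell_index[(3, 3)]
        assert state.heated[ci, 0] == 100 and state.unheated[ci, 0] == 0

    def test_full_tb_heats_nothing(self, square7, rng):
        state = self.setup_cohort(square7, (3, 3), 0, 100)
        heat_underlying(state, _footprint((3, 3), 1, 5), 5, tb_pct=100.0, rng=rng)
        assert state.total_heated == 0

    def test_half_tb_binomial_at_gap_one_zero_at_gap_two(self, square7):
        rng = np.random.default_rng(99)
        heated = []
        for _ in range(300):
            state = self.setup_cohort(square7, (3, 3), 4, 100)
            heat_underlying(state, _footprint((3, 3), 1, 5), 5, tb_pct=50.0, rng=rng)
            heated.append(state.total_heated)
        mean = np.mean(heated)
        # binomial(100, 0.5): SE of the mean over 300 trials is ~0.29
        assert abs(mean - 50.0) < 3 * 5.0 / np.sqrt(300)
        state = self.setup_cohort(square7, (3, 3), 3, 100)
        heat_underlying(state, _footprint((3, 3), 1, 5), 5, tb_pct=50.0, rng=rng)
        assert state.total_heated == 0  # gap 2 at TB 50 -> p = 0

    def test_window_floor_at_gap_100_over_tb(self, square7, rng):
        # TB 5 -> gaps >= 20 can no longer heat
        state = self.setup_cohort(square7, (3, 3), 0, 100)
        heat_underlying(state, _footprint((3, 3), 1, 9), 9, tb_pct=5.0, rng=rng)
        assert 0 < state.total_heated  # gap 9: p = 0.55
        state = LayerState(square7, 30)
        state.unheated[state.cell_index[(3, 3)], 0] = 100
        heat_underlying(state, _footprint((3, 3), 1, 25), 25, tb_pct=5.0, rng=rng)
        assert state.total_heated == 0

    def test_current_occupation_cohort_untouched(self, square7, rng):
        state = self.setup_cohort(square7, (3, 3), 5, 100)
        heat_underlying(state, _footprint((3, 3), 1, 5), 5, tb_pct=0.0, rng=rng)
        assert state.total_heated == 0


class TestChooseScatterCentroid:
    def test_single_cell_grid(self, rng):
        grid = make_rectangle(1, 1)
        cfg = SimulationConfig(grid=grid, n_occupations=1)
        state = make_state(grid, 1)
        assert choose_scatter_centroid(state, cfg, 0, [], rng) == (0, 0)

    def test_near_fire_stays_in_neighbourhood(self, rng):
        grid = make_rectangle(9, 9)
        cfg = SimulationConfig(
            grid=grid, n_occupations=1, lithic_placement=LithicPlacement.LSNF
        )
        state = make_state(grid, 1)
        hearth = _footprint((4, 4), 1, 0)
        for _ in range(200):
            r, c = choose_scatter_centroid(state, cfg, 0, [hearth], rng)
            assert max(abs(r - 4), abs(c - 4)) <= NEAR_RADIUS

    def test_no_fires_falls_back_to_random_uniform(self, rng):
        grid = make_rectangle(10, 10)
        cfg = SimulationConfig(
            grid=grid, n_occupations=1, lithic_placement=LithicPlacement.LSNF
        )
        state = make_state(grid, 1)
        n_draws = 20_000
        counts = np.zeros(100)
        idx = {rc: i for i, rc in enumerate(state.coords)}
        for _ in range(n_draws):
            counts[idx[choose_scatter_centroid(state, cfg, 0, [], rng)]] += 1
        p = 1 / 100
        se = np.sqrt(n_draws * p * (1 - p))
        assert np.all(np.abs(counts - n_draws * p) < 3.5 * se)


class TestDepositScatter:
    def test_open_neighbourhood_exact_kernel_counts(self, square7, rng):
        cfg = SimulationConfig(grid=square7, n_occupations=1, introduced_pct=0.0)
        state = make_state(square7, 1)
        deposit_scatter(state, cfg, 0, (3, 3), [], rng)
        counts = sorted(state.unheated[:, 0][state.unheated[:, 0] > 0], reverse=True)
        assert counts == [60, 8, 8, 8, 8, 2, 2, 2, 2]

    def test_fire_bearing_largest_remainder_split(self, square7, rng):
        cfg = SimulationConfig(grid=square7, n_occupations=1, introduced_pct=1.0)
        state = make_state(square7, 1)
        hearth = _footprint((1, 1), 1, 0)
        deposit_scatter(state, cfg, 0, (3, 3), [hearth], rng)
        assert state.heated[state.cell_index[(1, 1)], 0] == 1
        counts = sorted(state.unheated[:, 0][state.unheated[:, 0] > 0], reverse=True)
        assert counts == [59, 8, 8, 8, 8, 2, 2, 2, 2]

    def test_corner_centroid_renormalises(self, rng):
        grid = parse_area_file("IWW\nWWW")
        cfg = SimulationConfig(
            grid=grid,
            n_occupations=1,
            fires_per_occupation=0,
            introduced_pct=0.0,
        )
        state = make_state(grid, 1)
        deposit_scatter(state, cfg, 0, (0, 0), [], rng)
        assert state.unheated[state.cell_index[(0, 0)], 0] == 100

    @pytest.mark.parametrize(
        "mode", [LithicPlacement.LR, LithicPlacement.LU, LithicPlacement.LSR]
    )
    def test_conservation_per_scatter(self, square7, rng, mode):
        cfg = SimulationConfig(
            grid=square7, n_occupations=1, lithic_placement=mode, introduced_pct=0.0
        )
        state = make_state(square7, 1)
        centroid = (3, 3) if mode is LithicPlacement.LSR else None
        deposit_scatter(state, cfg, 0, centroid, [], rng)
        assert state.total_lithics == 100

    def test_uniform_mode_spreads_evenly(self, rng):
        grid = make_rectangle(4, 4)
        cfg = SimulationConfig(
            grid=grid,
            n_occupations=1,
            lithic_placement=LithicPlacement.LU,
            introduced_pct=0.0,
            lithics_per_scatter=35,
        )
        state = make_state(grid, 1)
        deposit_scatter(state, cfg, 0, None, [], rng)
        col = state.unheated[:, 0]
        assert set(col.tolist()) == {2, 3} and col.sum() == 35

    def test_custom_kernel_weights(self, square7, rng):
        cfg = SimulationConfig(
            grid=square7,
            n_occupations=1,
            introduced_pct=0.0,
            kernel=ScatterKernel(center=100.0, orthogonal=0.0, diagonal=0.0),
        )
        state = make_state(square7, 1)
        deposit_scatter(state, cfg, 0, (3, 3), [], rng)
        assert state.unheated[state.cell_index[(3, 3)], 0] == 100

    def test_bad_kernel_rejected(self):
        with pytest.raises(ValueError, match="sum to 100"):
            ScatterKernel(center=70.0, orthogonal=8.0, diagonal=2.0)


class TestRunExperiment:
    def test_no_fires_no_heated(self, base_config, rng):
        state = run_experiment(base_config.with_(fires_per_occupation=0), rng)
        assert state.total_heated == 0
        assert heated_percentage(state) == 0.0

    def test_single_occupation_heats_only_introduced(self, base_config, rng):
        state = run_experiment(base_config.with_(n_occupations=1), rng)
        assert state.total_heated == 4  # 1 % of 4 x 100, nothing buried yet

    @pytest.mark.parametrize(
        "mode",
        [
            LithicPlacement.LSR,
            LithicPlacement.LSNF,
            LithicPlacement.LR,
            LithicPlacement.LU,
        ],
    )
    def test_conservation_of_total_lithics(self, base_config, rng, mode):
        state = run_experiment(base_config.with_(lithic_placement=mode), rng)
        assert state.total_lithics == 30 * 4 * 100

    def test_heated_counts_never_decrease(self, base_config):
        """Re-run with snapshots: cumulative heated is monotone in time."""
        rng = np.random.default_rng(5)
        cfg = base_config.with_(tb_pct=10.0)
        state = LayerState(cfg.grid, cfg.n_occupations)
        from pyrolith.simulate import OccupationRecord, fire_schedule as fs

        schedule = fs(cfg.n_occupations, cfg.skip)
        totals = []
        for occ in range(cfg.n_occupations):
            hearths = []
            if schedule[occ]:
                hearths = place_fires(state, cfg, occ, rng)
                for fp in hearths:
                    heat_underlying(state, fp, occ, cfg.tb_pct, rng)
            for _ in range(cfg.scatters_per_occupation):
                centroid = choose_scatter_centroid(state, cfg, occ, hearths, rng)
                deposit_scatter(state, cfg, occ, centroid, hearths, rng)
            state.records.append(
                OccupationRecord(occ, bool(hearths), hearths, [])
            )
            totals.append(state.total_heated)
        assert totals == sorted(totals)

    def test_full_tb_leaves_only_introduced(self, base_config, rng):
        state = run_experiment(base_config.with_(tb_pct=100.0), rng)
        assert heated_percentage(state) == pytest.approx(1.0)  # 1 % introduced

    def test_full_tb_with_skip_scales_introduced_share(self, base_config, rng):
        state = run_experiment(base_config.with_(tb_pct=100.0, skip=2), rng)
        # introduced only in the 10 fire-bearing of 30 occupations
        assert heated_percentage(state) == pytest.approx(1.0 * 10 / 30)

    def test_same_rng_seed_reproduces_state(self, base_config):
        s1 = run_experiment(base_config, np.random.default_rng(42))
        s2 = run_experiment(base_config, np.random.default_rng(42))
        assert np.array_equal(s1.unheated, s2.unheated)
        assert np.array_equal(s1.heated, s2.heated)
        assert [r.hearths for r in s1.records] == [r.hearths for r in s2.records]

    def test_assemblage_table_conserves_counts(self, base_config, rng):
        state = run_experiment(base_config, rng)
        table = state.assemblage_table()
        assert int(table[["unheated", "heated"]].to_numpy().sum()) == 12000

    def test_empty_layer_percentage_undefined(self, square7):
        with pytest.raises(ValueError, match="no lithics"):
            heated_percentage(LayerState(square7, 3))


class TestClosedFormOracle:
    def test_reduces_to_coupon_collector_at_tb0(self):
        # at TB 0 with no introduced lithics the expectation is
        # 1 - (1/m) sum_j (1 - 1/N)^j  (independent derivation)
        N, m = 49, 30
        expected = 100 * (1 - sum((1 - 1 / N) ** j for j in range(m)) / m)
        got = expected_heated_pct_random(N, m, tb_pct=0.0, introduced_pct=0.0)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_introduced_only_at_full_tb(self):
        got = expected_heated_pct_random(80, 30, tb_pct=100.0, introduced_pct=1.0)
        assert got == pytest.approx(1.0)
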
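import numpy as np
import pytest

from hopfstrat.fitting import (
    GridSimBank,
    MonteCarloRecord,
    build_parameter_grid,
    detect_modes,
    monte_carlo_fit,
    published_grid,
    simulate_grid,
)
from hopfstrat.oscillator import ModelParameters, SimulationConfig
from hopfstrat.signals import FCMatrix

from conftest import random_connectome
from hopfstrat.oscillator import draw_intrinsic_frequencies


def _sym_fc(n, rng):
    x = rng.standard_normal((n, n))
    m = (x + x.T) / 2
    np.fill_diagonal(m, 0.0)
    return FCMatrix(m, "fisher_z")


def _bank_from_grid(grid, n_regions=6, seed=0, met=None, syn=None):
    rng = np.random.default_rng(seed)
    points = grid.points()
    fcs = [_sym_fc(n_regions, rng) for _ in points]
    met = np.arange(len(points), dtype=float) if met is None else np.asarray(met)
    syn = np.linspace(0.1, 0.9, len(points)) if syn is None else np.asarray(syn)
    return GridSimBank(grid, points, fcs, syn, met)


def _noisy(fc, rng, sd=0.1, sid=None):
    n = fc.n_regions
    iu = np.triu_indices(n, 1)
    noise = np.zeros((n, n))
    noise[iu] = rng.normal(0, sd, iu[0].size)
    return FCMatrix(fc.values + noise + noise.T, "fisher_z",
                    {"subject_id": sid} if sid else {})


class TestParameterGrid:
    def test_published_ranges_cardinality(self):
        grid = published_grid()
        av = grid.axis_values
        assert [av[k].size for k in ("A", "G", "F", "M")] == [41, 10, 11, 14]
        assert len(grid) == 63_140

    def test_m_axis_stops_short_of_upper_bound(self):
        vals = build_parameter_grid((0, 0, 1), (0, 0, 1), (0, 0, 1),
                                    (0.10, 0.50, 0.03)).axis_values["M"]
        assert vals.size == 14
        assert vals[-1] == pytest.approx(0.49)

    def test_degenerate_ranges(self):
        grid = build_parameter_grid((0.1, 0.1, 1), (0.2, 0.2, 1),
                                    (0.3, 0.3, 1), (0.4, 0.4, 1))
        assert len(grid) == 1
        assert grid.points()[0].as_tuple() == (0.1, 0.2, 0.3, 0.4)

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ValueError):
            build_parameter_grid((0, 1, 0), (0, 0, 1), (0, 0, 1), (0, 0, 1)).points()

    def test_lexicographic_enumeration(self):
        grid = build_parameter_grid((0, 0.1, 0.1), (0, 0.1, 0.1),
                                    (0, 0, 1), (0, 0, 1))
        pts = [p.as_tuple() for p in grid.points()]
        assert pts == sorted(pts)


class TestMonteCarloFit:
    def test_single_point_bank_always_selected(self):
        grid = build_parameter_grid((0.1, 0.1, 1), (0.2, 0.2, 1),
                                    (0.3, 0.3, 1), (0.4, 0.4, 1))
        bank = _bank_from_grid(grid)
        rng = np.random.default_rng(1)
        fcs = [_noisy(bank.fcs[0], rng, sid=f"s{i}") for i in range(10)]
        records = monte_carlo_fit(bank, fcs, iters_per_threshold=20, seed=3)
        assert len(records) == 60
        assert all(r.best_params == bank.points[0] for r in records)
        assert all(-1.0 <= r.best_similarity <= 1.0 for r in records)

    def test_exact_match_cohort_selects_entry_with_similarity_one(self):
        grid = build_parameter_grid((0.0, 0.1, 0.1), (0.2, 0.2, 1),
                                    (0.3, 0.3, 1), (0.4, 0.4, 1))
        bank = _bank_from_grid(grid)
        fcs = [FCMatrix(bank.fcs[1].values.copy(), "fisher_z",
                        {"subject_id": f"s{i}"}) for i in range(8)]
        records = monte_carlo_fit(bank, fcs, iters_per_threshold=10, seed=4)
        assert all(r.best_params == bank.points[1] for r in records)
        assert all(r.best_similarity == pytest.approx(1.0) for r in records)

    def test_draw_size_rounds_half_up(self):
        grid = build_parameter_grid((0.1, 0.1, 1), (0.2, 0.2, 1),
                                    (0.3, 0.3, 1), (0.4, 0.4, 1))
        bank = _bank_from_grid(grid)
        rng = np.random.default_rng(5)
        fcs = [_noisy(bank.fcs[0], rng, sid=f"s{i:02d}") for i in range(42)]
        records = monte_carlo_fit(bank, fcs, thresholds=(0.3,),
                                  iters_per_threshold=3, seed=6)
        assert all(len(r.selected_subjects) == 13 for r in records)  # 0.3*42 -> 13

    def test_subject_order_invariance(self):
        grid = build_parameter_grid((0.0, 0.1, 0.1), (0.2, 0.2, 1),
                                    (0.3, 0.3, 1), (0.4, 0.4, 1))
        bank = _bank_from_grid(grid, seed=7)
        rng = np.random.default_rng(8)
        fcs = [_noisy(bank.fcs[i % 2], rng, sid=f"s{i:02d}") for i in range(12)]
        rec_a = monte_carlo_fit(bank, fcs, iters_per_threshold=10, seed=9)
        rec_b = monte_carlo_fit(bank, fcs[::-1], iters_per_threshold=10, seed=9)
        assert [r.best_params for r in rec_a] == [r.best_params for r in rec_b]
        assert [r.selected_subjects for r in rec_a] == [r.selected_subjects for r in rec_b]

    def test_mixed_cohort_selects_multiple_points(self):
        # resampling a two-subtype cohort must spread over >= 2 grid points
        grid = build_parameter_grid((0.0, 0.1, 0.1), (0.2, 0.2, 1),
                                    (0.3, 0.3, 1), (0.4, 0.4, 1))
        bank = _bank_from_grid(grid, seed=10)
        rng = np.random.default_rng(11)
        fcs = [_noisy(bank.fcs[i % 2], rng, sd=0.05, sid=f"s{i:02d}")
               for i in range(20)]
        records = monte_carlo_fit(bank, fcs, thresholds=(0.3,),
                                  iters_per_threshold=100, seed=12)
        assert len({r.best_params for r in records}) >= 2

    def test_too_small_draw_rejected(self):
        grid = build_parameter_grid((0.1, 0.1, 1), (0.2, 0.2, 1),
                                    (0.3, 0.3, 1), (0.4, 0.4, 1))
        bank = _bank_from_grid(grid)
        rng = np.random.default_rng(13)
        fcs = [_noisy(bank.fcs[0], rng, sid=f"s{i}") for i in range(4)]
        with pytest.raises(ValueError, match="at least 2"):
            monte_carlo_fit(bank, fcs, thresholds=(0.1,), iters_per_threshold=1)


class TestDetectModes:
    def _two_point_setup(self):
        grid = build_parameter_grid((-0.09, 0.02, 0.11), (0.01, 0.035, 0.025),
                                    (0.4, 0.7, 0.3), (0.46, 0.49, 0.03))
        bank = _bank_from_grid(grid, seed=14)
        p_lo = bank.points[0]     # smallest A
        p_hi = bank.points[-1]    # largest A
        return grid, bank, p_lo, p_hi

    def _records(self, params_list):
        return [MonteCarloRecord(i, 0.5, ["a", "b"], p, 0.5)
                for i, p in enumerate(params_list)]

    def test_even_split_recovers_both_points(self):
        _, bank, p_lo, p_hi = self._two_point_setup()
        records = self._records([p_lo] * 750 + [p_hi] * 750)
        sol = detect_modes(records, bank)
        assert {sol.params_dep1, sol.params_dep2} == {p_lo, p_hi}
        assert sol.mode_counts == {"DEP1": 750, "DEP2": 750}

    def test_label_rule_smaller_bifurcation_parameter_is_dep1(self):
        _, bank, p_lo, p_hi = self._two_point_setup()
        sol = detect_modes(self._records([p_lo] * 10 + [p_hi] * 10), bank)
        assert sol.params_dep1.A < sol.params_dep2.A

    def test_unimodal_records_rejected(self):
        _, bank, p_lo, _ = self._two_point_setup()
        with pytest.raises(ValueError, match="unimodal"):
            detect_modes(self._records([p_lo] * 100), bank)

    def test_record_order_invariance(self):
        _, bank, p_lo, p_hi = self._two_point_setup()
        mixed = [p_lo, p_hi] * 50 + [p_lo] * 7
        a = detect_modes(self._records(mixed), bank)
        b = detect_modes(self._records(mixed[::-1]), bank)
        assert (a.params_dep1, a.params_dep2) == (b.params_dep1, b.params_dep2)

    def test_representative_is_cluster_majority_point(self):
        grid = build_parameter_grid((-0.09, 0.02, 0.11), (0.01, 0.035, 0.025),
                                    (0.4, 0.7, 0.3), (0.46, 0.49, 0.03))
        bank = _bank_from_grid(grid, seed=15)
        near_lo = [p for p in bank.points if p.A == -0.09]
        near_hi = [p for p in bank.points if p.A == 0.02]
        records = self._records(
            [near_lo[0]] * 60 + [near_lo[1]] * 10 + [near_hi[3]] * 50 + [near_hi[2]] * 5
        )
        sol = detect_modes(records, bank)
        assert sol.params_dep1 == near_lo[0]
        assert sol.params_dep2 == near_hi[3]


class TestSimulateGrid:
    def test_single_point_bank(self, conn12, omega12, short_config):
        grid = build_parameter_grid((0.02, 0.02, 1), (0.02, 0.02, 1),
                                    (0.5, 0.5, 1), (0.3, 0.3, 1))
        bank = simulate_grid(grid, conn12, omega12, short_config)
        assert len(bank) == 1
        assert bank.fcs[0].space == "fisher_z"

    def test_regimes_differ_across_bifurcation(self, conn12, omega12, short_config):
        grid = build_parameter_grid((-0.1, 0.1, 0.2), (0.0, 0.0, 1),
                                    (1.0, 1.0, 1), (0.0, 0.0, 1))
        bank = simulate_grid(grid, conn12, omega12, short_config)
        iu = np.triu_indices(12, 1)
        var_focus = bank.fcs[0].values[iu].var()
        var_cycle = bank.fcs[1].values[iu].var()
        assert var_cycle > var_focus  # limit cycle makes extreme correlations

    def test_reproducible_and_cached(self, conn12, omega12, short_config, tmp_path):
        grid = build_parameter_grid((0.0, 0.02, 0.02), (0.02, 0.02, 1),
                                    (0.5, 0.5, 1), (0.3, 0.3, 1))
        a = simulate_grid(grid, conn12, omega12, short_config, cache_dir=tmp_path)
        b = simulate_grid(grid, conn12, omega12, short_config, cache_dir=tmp_path)
        c = simulate_grid(grid, conn12, omega12, short_config)
        for bank in (b, c):
            for i in range(len(a)):
                assert np.allclose(a.fcs[i].values, bank.fcs[i].values)
            assert np.allclose(a.metastability, bank.metastability)
        assert list(tmp_path.glob("gridbank_*.npz"))

    def test_worker_count_does_not_change_results(self, conn12, omega12, short_config):
        grid = build_parameter_grid((0.0, 0.02, 0.02), (0.02, 0.02, 1),
                                    (0.5, 0.5, 1), (0.3, 0.3, 1))
        a = simulate_grid(grid, conn12, omega12, short_config, n_workers=1)
        b = simulate_grid(grid, conn12, omega12, short_config, n_workers=2)
        for i in range(len(a)):
            assert np.array_equal(a.fcs[i].values, b.fcs[i].values)
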
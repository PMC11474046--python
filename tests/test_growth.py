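"""Growth-rate estimators, smoothing, alignment, and population summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import caulogrowth as cg
from caulogrowth.growth import (
    align_cell_cycle,
    average_growth_rate,
    bin_by_g1,
    bin_by_quantiles,
    compute_profile,
    exp_fit_residuals,
    instantaneous_growth_rate,
    population_mean_curve,
    smooth_area,
    tempogram,
)
from conftest import make_exponential_track


class TestSmoothArea:
    def test_constant_series_unchanged(self):
        a = np.full(20, 3.7)
        np.testing.assert_allclose(smooth_area(a), a)

    def test_linear_series_unchanged(self):
        a = 1.0 + 0.1 * np.arange(30)
        np.testing.assert_allclose(smooth_area(a), a)  # symmetric windows on a line

    def test_shrinking_boundary_windows_hand_computed(self):
        out = smooth_area([1.0, 2.0, 4.0, 8.0], window=2)
        np.testing.assert_allclose(out, [1.0, 7.0 / 3.0, 14.0 / 3.0, 8.0])

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_area([1.0, 2.0], window=0)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0.5, 10.0), min_size=2, max_size=40), st.integers(1, 15))
    def test_length_preserved_and_bounded(self, areas, window):
        out = smooth_area(areas, window)
        assert len(out) == len(areas)
        assert out.min() >= min(areas) - 1e-12 and out.max() <= max(areas) + 1e-12


class TestInstantaneousRate:
    def test_geometric_series_constant_rate(self):
        a = 2.0 * 1.1 ** np.arange(10)
        np.testing.assert_allclose(instantaneous_growth_rate(a, 1.0), 0.1)

    def test_constant_series_zero_rate(self):
        np.testing.assert_allclose(instantaneous_growth_rate(np.ones(8), 1.5), 0.0)

    def test_exponential_closed_form(self):
        mu, dt = 0.006, 1.5
        a = np.exp(mu * dt * np.arange(50))
        expected = (np.exp(mu * dt) - 1) / dt  # ~0.006027 per min
        np.testing.assert_allclose(instantaneous_growth_rate(a, dt), expected)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_growth_rate([1.0, -1.0], 1.5)


class TestAverageGrowthRate:
    def test_no_growth_is_zero(self):
        assert average_growth_rate(1.0, 1.0, 30.0) == 0.0

    def test_doubling_closed_form(self):
        assert average_growth_rate(2.0, 4.0, 60.0) == pytest.approx(np.log(2) / 60)

    def test_noiseless_synthetic_round_trip(self):
        p = cg.SimParams(seed=6, dip_depth=0.0, area_noise_cv=0.0, rate_cv=0.0)
        truth, _ = cg.simulate_lineage(p, 1, 1)
        cell = truth[0]
        lam = average_growth_rate(
            cell.birth_area_true,
            cell.area_true_at(cell.division_time, p),
            cell.division_time - cell.birth_time_cyto,
        )
        assert lam == pytest.approx(0.006, abs=1e-9)

    def test_invalid_inputs_rejected(self):
        for args in [(0.0, 1.0, 1.0), (1.0, 0.0, 1.0), (1.0, 1.0, 0.0)]:
            with pytest.raises(ValueError):
                average_growth_rate(*args)


class TestExpFitResiduals:
    def test_exact_exponential_scores_zero(self):
        t = 1.5 * np.arange(60)
        a = 1.3 * np.exp(0.007 * t)
        assert exp_fit_residuals(a, t) < 1e-10

    def test_linear_trajectory_scores_positive(self):
        t = np.arange(40.0)
        assert exp_fit_residuals(1.0 + 0.05 * t, t) > 1e-4

    def test_dipped_cells_score_higher_than_exponential(self):
        """Cells with a G1 growth-rate dip deviate more from a single exponential."""
        p_dip = cg.SimParams(seed=7, dip_depth=0.4, area_noise_cv=0.0, rate_cv=0.0,
                             g1_mean_swarmer=40.0, g1_dispersion=0.0)
        p_exp = cg.SimParams(seed=7, dip_depth=0.0, area_noise_cv=0.0, rate_cv=0.0)
        dip, _ = cg.simulate_lineage(p_dip, 2, 3)
        exp_, _ = cg.simulate_lineage(p_exp, 2, 3)
        score_dip = np.median([
            exp_fit_residuals(c.areas_true, c.frame_times)
            for c in dip if c.progeny_type == "swarmer"
        ])
        score_exp = np.median([
            exp_fit_residuals(c.areas_true, c.frame_times)
            for c in exp_ if c.progeny_type == "swarmer"
        ])
        assert score_dip > score_exp

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            exp_fit_residuals([1.0, 2.0], [0.0, 1.0])
        with pytest.raises(ValueError):
            exp_fit_residuals([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])


class TestEstimatorConsistency:
    def test_three_estimators_agree_on_exponential(self):
        """Average rate, log-corrected mean step rate, and log-fit slope agree."""
        mu, dt = 0.008, 1.5
        t = dt * np.arange(100)
        a = 0.9 * np.exp(mu * t)
        lam = average_growth_rate(a[0], a[-1], t[-1] - t[0])
        step = instantaneous_growth_rate(a, dt).mean()
        lam_step = np.log1p(step * dt) / dt
        slope = np.polyfit(t, np.log(a), 1)[0]
        assert lam == pytest.approx(mu, rel=1e-9)
        assert lam_step == pytest.approx(mu, rel=1e-9)
        assert slope == pytest.approx(mu, rel=1e-9)


class TestAlignCellCycle:
    def test_constant_rate_fills_bins_with_constant(self):
        t = np.linspace(0.75, 119.25, 80)
        out = align_cell_cycle(np.full(80, 0.004), t, 0.0, 120.0, n_bins=30)
        filled = out[~np.isnan(out)]
        assert filled.size > 0
        np.testing.assert_allclose(filled, 0.004)

    def test_first_step_maps_into_first_unit_interval(self):
        t = np.array([0.75, 2.25])
        out = align_cell_cycle([1.0, 2.0], t, 0.0, 150.0, n_bins=30)
        assert not np.isnan(out[0])

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        rates = rng.normal(0.005, 0.001, 60)
        t = 1.5 * np.arange(60) + 0.75
        base = align_cell_cycle(rates, t, 0.0, 90.0, n_bins=20)
        for scale in (2.0, 0.4, 17.0):
            scaled = align_cell_cycle(rates, t * scale, 0.0, 90.0 * scale, n_bins=20)
            np.testing.assert_allclose(scaled, base, equal_nan=True)

    def test_zero_length_cycle_rejected(self):
        with pytest.raises(ValueError):
            align_cell_cycle([1.0], [0.5], 10.0, 10.0)

    def test_trough_position_recovered_on_noiseless_cell(self):
        """argmin of the binned curve sits within one bin of the true G1 end."""
        p = cg.SimParams(seed=9, area_noise_cv=0.0, rate_cv=0.0,
                         g1_mean_swarmer=40.0, g1_dispersion=0.0,
                         interdivision_sd=0.0)
        truth, table = cg.simulate_lineage(p, 2, 1)
        from caulogrowth.lineage import BirthDefinition, assign_birth, link_generations

        tracks = link_generations(table.to_dict("records"))
        tmap = {c.cell_id: c for c in truth}
        sw = [cid for cid, tr in tracks.items()
              if tr.daughter_ids and tmap[cid].progeny_type == "swarmer"]
        for cid in sw:
            assign_birth(tracks[cid], BirthDefinition.CYTOKINESIS)
            prof = compute_profile(tracks[cid])
            cc_true = tmap[cid].g1_duration_true / (
                tmap[cid].division_time - tmap[cid].birth_time_cyto
            )
            true_bin = min(int(cc_true * 30), 29)
            assert abs(int(np.nanargmin(prof.aligned)) - true_bin) <= 1


class TestPopulationMeanCurve:
    def test_identical_cells_have_zero_width_ci(self):
        vec = np.linspace(0.004, 0.006, 30)
        pop = population_mean_curve([vec] * 5, n_boot=100, seed=0)
        np.testing.assert_allclose(pop.ci_low, vec)
        np.testing.assert_allclose(pop.ci_high, vec)
        np.testing.assert_allclose(pop.boot_se, 0.0, atol=1e-15)

    def test_ci_brackets_mean_and_is_deterministic(self):
        rng = np.random.default_rng(1)
        vecs = rng.normal(0.005, 0.001, size=(40, 30))
        pop1 = population_mean_curve(vecs, n_boot=300, seed=7)
        pop2 = population_mean_curve(vecs, n_boot=300, seed=7)
        assert np.all(pop1.ci_low <= pop1.mean_rate + 1e-12)
        assert np.all(pop1.mean_rate <= pop1.ci_high + 1e-12)
        np.testing.assert_array_equal(pop1.ci_low, pop2.ci_low)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            population_mean_curve([np.ones(10)], n_boot=10)


class TestTempogram:
    def test_rows_sorted_by_interdivision_time(self):
        vecs = [np.full(5, v) for v in (1.0, 2.0, 3.0)]
        mat, order = tempogram(vecs, [50.0, 30.0, 40.0])
        np.testing.assert_array_equal(order, [1, 2, 0])
        np.testing.assert_allclose(mat[:, 0], [2.0, 3.0, 1.0])
        assert mat.shape == (3, 5)

    def test_long_g1_rows_slower_in_early_midcycle(self):
        """Long-G1 rows stay slow well into the cycle while short-G1 rows have
        already recovered: compare the window between one sixth and one half
        of the cycle, where the fixed-depth dip separates the groups."""
        p = cg.SimParams(seed=10, area_noise_cv=0.0, rate_cv=0.0, interdivision_sd=0.0)
        n_bins = 30
        vecs = []
        for g1 in (10.0, 20.0, 40.0, 60.0):
            t = np.arange(0, 120.0, 1.5)
            rates = cg.growth_rate_profile(t, p, g1)
            vecs.append(align_cell_cycle(rates, t + 0.75, 0.0, 120.0, n_bins))
        window = slice(n_bins // 6, n_bins // 2)
        means = [np.nanmean(v[window]) for v in vecs]
        assert max(means[2], means[3]) < min(means[0], means[1])
        assert means[1] < means[0]
        # and the deepest point of every row approaches the dip trough
        for v in vecs:
            assert np.nanmin(v) == pytest.approx(0.006 * 0.6, rel=0.1)


class TestBinByG1:
    def test_interval_assignment_with_printed_edges(self):
        groups, excluded = bin_by_g1([10.0, 40.0, 25.0], [(4.5, 19.5), (33.0, 90.0)])
        assert groups == [[0], [1]]
        assert excluded == [2]

    def test_final_edge_inclusive(self):
        groups, excluded = bin_by_g1([19.5, 90.0], [(4.5, 19.5), (33.0, 90.0)])
        assert groups == [[], [1]]  # 19.5 excluded (hi-exclusive), 90 kept (final edge)
        assert excluded == [0]

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError):
            bin_by_g1([1.0], [(0.0, 10.0), (5.0, 20.0)])

    def test_empty_input_gives_empty_groups(self):
        groups, excluded = bin_by_g1([], [(0.0, 10.0)])
        assert groups == [[]] and excluded == []

    def test_quantile_split_near_equal_sizes(self):
        rng = np.random.default_rng(2)
        groups = bin_by_quantiles(rng.gamma(4, 10, size=100), 3)
        sizes = sorted(len(g) for g in groups)
        assert sizes[-1] - sizes[0] <= 1
        assert sum(sizes) == 100


class TestMonotonicity:
    def test_deeper_dip_lowers_trough_and_average(self):
        p = cg.SimParams()
        t = np.arange(0, 120.0, 1.5)
        curves = {}
        for d in (0.2, 0.5):
            pd = cg.SimParams(dip_depth=d)
            rates = cg.growth_rate_profile(t, pd, 40.0)
            curves[d] = (rates.min(), rates.mean())
        assert curves[0.5][0] < curves[0.2][0]
        assert curves[0.5][1] < curves[0.2][1]

    def test_longer_g1_lowers_average_rate(self):
        p = cg.SimParams(dip_depth=0.4)
        t = np.arange(0, 120.0, 1.5)
        means = [cg.growth_rate_profile(t, p, g1).mean() for g1 in (10.0, 30.0, 60.0)]
        assert means[0] > means[1] > means[2]


def test_compute_profile_on_synthetic_track():
    track = make_exponential_track(mu=0.008, n=100)
    from caulogrowth.lineage import BirthDefinition, assign_birth

    assign_birth(track, BirthDefinition.CYTOKINESIS)
    prof = compute_profile(track)
    assert prof.avg_rate == pytest.approx(0.008, rel=1e-9)
    assert prof.residual_score < 1e-10
    assert len(prof.inst_rate) == 99
    assert np.all(np.isfinite(prof.aligned))
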
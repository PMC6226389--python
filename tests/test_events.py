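"""Event extraction, shape statistics, lifetime models and conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hpwhmm.events import (
    RAYLEIGH_SKEWNESS,
    attach_shapes,
    conservation_clustering,
    correlate,
    exponential_mixture_sample,
    extract_events,
    fit_exponential_mixture,
    heterogeneity_tests,
    lifetime_table,
    local_diffusivity,
    mark_repeats,
    qq_r_squared,
    shannon_diversity,
    shape_statistics,
    threshold_states,
    uncertain_fraction,
)
from hpwhmm.model import Trajectory
from hpwhmm.simulate import SimulationConfig, simulate

DT = 2e-4


def _times(n, dt=DT):
    return dt * np.arange(n)


class TestThresholdStates:
    def test_simple_thresholding(self):
        out = threshold_states([0.1, 0.9, 0.95, 0.2])
        assert out.tolist() == [0, 1, 1, 0]

    def test_ties_classified_free(self):
        assert not threshold_states([0.5, 0.5, 0.5]).any()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            threshold_states([0.2, 1.4])

    def test_uncertain_fraction_summary(self):
        probs = [0.05, 0.3, 0.5, 0.7, 0.95]
        assert uncertain_fraction(probs) == pytest.approx(3 / 5)


class TestExtractEvents:
    def test_enumerated_example(self):
        binary = np.array([0, 1, 1, 0, 0, 1])
        conf, free = extract_events(binary, _times(7))
        assert len(conf) == 2 and len(free) == 2
        first, second = conf
        assert (first.start, first.end) == (1, 2)
        assert not first.touches_boundary
        assert (second.start, second.end) == (5, 5)
        assert second.touches_boundary
        assert first.lifetime == pytest.approx(2 * DT)

    def test_all_ones_single_boundary_event(self):
        conf, free = extract_events(np.ones(9, dtype=int), _times(10))
        assert len(conf) == 1 and len(free) == 0
        assert conf[0].touches_boundary
        assert conf[0].lifetime == pytest.approx(9 * DT)

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.integers(0, 1), min_size=1, max_size=60))
    def test_count_identity_and_partition(self, bits):
        # event count = number of 0->1 transitions plus starting-state unit,
        # and confinement + free frames partition all increments
        binary = np.array(bits)
        conf, free = extract_events(binary, _times(binary.size + 1))
        rises = int(np.sum((binary[1:] == 1) & (binary[:-1] == 0)))
        assert len(conf) == rises + int(binary[0] == 1)
        n_frames = sum(e.n_frames for e in conf) + sum(
            e.n_frames for e in free
        )
        assert n_frames == binary.size
        # lifetimes (boundary included) sum to the trajectory duration
        total = sum(e.lifetime for e in conf) + sum(e.lifetime for e in free)
        assert total == pytest.approx(binary.size * DT)


class TestLifetimeTable:
    def test_boundary_exclusion(self):
        binary = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        conf, _ = extract_events(binary, _times(9))
        assert len(conf) == 3
        kept = lifetime_table(conf, exclude_boundary=True)
        assert kept.size == 1  # first and last touch the boundary
        assert kept[0] == pytest.approx(3 * DT)

    def test_fifty_frame_event_sits_exactly_at_the_cut(self):
        # 50 confined frames at dt = 2e-4 s: lifetime exactly 0.01 s (kept)
        rng = np.random.default_rng(99)
        binary = np.zeros(100, dtype=int)
        binary[25:75] = 1
        conf, _ = extract_events(
            binary,
            _times(101),
            positions=rng.standard_normal((101, 2)) * 0.01,
            centers=np.zeros((100, 2)),
        )
        assert conf[0].lifetime == pytest.approx(0.01)
        shaped = attach_shapes(conf, min_lifetime=0.01)
        assert len(shaped) == 1  # "at least 0.01 s" keeps the exact cut
        assert lifetime_table(conf).size == 1

    def test_empty_input(self):
        assert lifetime_table([]).size == 0


class TestShapeStatistics:
    def test_degenerate_ring(self):
        theta = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        r = 0.012
        pos = r * np.column_stack([np.cos(theta), np.sin(theta)])
        s = shape_statistics(pos, np.zeros(2))
        assert s.mean_radius == pytest.approx(r)
        assert s.radial_sd == pytest.approx(0.0, abs=1e-15)
        assert s.radial_skewness == 0.0
        assert s.degenerate

    def test_gaussian_cloud_reaches_rayleigh_skewness(self):
        # isotropic 2D Gaussian occupation: radial skew -> 0.63
        rng = np.random.default_rng(8)
        pos = rng.standard_normal((10**6, 2)) * 0.009
        s = shape_statistics(pos, np.zeros(2))
        assert s.radial_skewness == pytest.approx(RAYLEIGH_SKEWNESS, abs=0.01)
        assert s.radial_skewness == pytest.approx(0.63, abs=0.01)

    def test_five_point_hand_oracle(self):
        # scalar-by-scalar spreadsheet computation
        pos = np.array(
            [[0.0, 0.0], [0.03, 0.04], [0.06, 0.08], [0.0, 0.05], [0.05, 0.0]]
        )
        center = np.array([0.0, 0.0])
        radii = [0.0, 0.05, 0.1, 0.05, 0.05]
        mean_r = sum(radii) / 5  # 0.05
        var_r = sum((r - mean_r) ** 2 for r in radii) / 5  # 0.001
        skew = (sum((r - mean_r) ** 3 for r in radii) / 5) / var_r**1.5
        s = shape_statistics(pos, center)
        assert s.mean_radius == pytest.approx(mean_r)
        assert s.radial_sd == pytest.approx(np.sqrt(var_r))
        assert s.radial_skewness == pytest.approx(skew)
        assert s.mean_median_distance == pytest.approx(0.0, abs=1e-15)

    def test_rotation_and_translation_invariance(self):
        rng = np.random.default_rng(9)
        pos = rng.standard_normal((40, 2)) * 0.01
        center = np.array([0.002, -0.001])
        base = shape_statistics(pos, center)
        phi = 0.7
        rot = np.array(
            [[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]]
        )
        shift = np.array([1.2, -3.4])
        moved = shape_statistics(pos @ rot.T + shift, rot @ center + shift)
        assert moved.mean_radius == pytest.approx(base.mean_radius)
        assert moved.radial_skewness == pytest.approx(base.radial_skewness)
        assert moved.radial_sd == pytest.approx(base.radial_sd)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            shape_statistics(np.zeros((1, 2)), np.zeros(2))


def _event_at(x_nm, t0=0.0):
    """Minimal confined event whose mean center sits at (x_nm, 0) nm."""
    conf, _ = extract_events(
        np.ones(2, dtype=int),
        t0 + _times(3),
        positions=np.zeros((3, 2)),
        centers=np.full((2, 2), [x_nm * 1e-3, 0.0]),
    )
    return conf[0]


class TestMarkRepeats:
    def test_nearby_centers_flagged(self):
        events = [_event_at(0.0), _event_at(10.0)]
        out = mark_repeats(events)
        assert not out[0].is_repeat
        assert out[1].is_repeat

    def test_distant_centers_not_flagged(self):
        out = mark_repeats([_event_at(0.0), _event_at(40.0)])
        assert not any(e.is_repeat for e in out)

    def test_any_earlier_event_rule(self):
        # A(0), B(25), C(50): B repeats A; C repeats B though 50 nm from A
        out = mark_repeats([_event_at(0.0), _event_at(25.0), _event_at(50.0)])
        assert [e.is_repeat for e in out] == [False, True, True]


class TestExponentialMixture:
    def test_single_component_closed_form(self):
        rng = np.random.default_rng(10)
        x = rng.exponential(0.02, size=500)
        means, weights, ll = fit_exponential_mixture(x, 1)
        assert means[0] == pytest.approx(x.mean(), rel=1e-12)
        assert weights[0] == 1.0

    def test_recovers_reference_mixture(self):
        # (mu1, mu2, w) = (0.004 s, 0.1 s, 0.8/0.2) from 1e4 samples
        rng = np.random.default_rng(11)
        x = exponential_mixture_sample(
            np.array([0.004, 0.1]), np.array([0.8, 0.2]), 10_000, rng
        )
        means, weights, _ = fit_exponential_mixture(x, 2, seed=1)
        assert means[0] == pytest.approx(0.004, rel=0.1)
        assert means[1] == pytest.approx(0.1, rel=0.1)
        assert weights[0] == pytest.approx(0.8, rel=0.1)

    def test_nesting_on_single_component_data(self):
        rng = np.random.default_rng(12)
        x = rng.exponential(0.05, size=2000)
        m1, w1, ll1 = fit_exponential_mixture(x, 1)
        m2, w2, ll2 = fit_exponential_mixture(x, 2, seed=2)
        assert ll2 >= ll1 - 1e-6
        # components nearly equal or one weight collapses
        assert (abs(m2[0] - m2[1]) < 0.25 * m1[0]) or w2.min() < 0.05

    def test_em_loglik_monotone(self):
        # monotonicity surfaces as: more iterations never lower the best ll
        rng = np.random.default_rng(13)
        x = exponential_mixture_sample(
            np.array([0.01, 0.2]), np.array([0.5, 0.5]), 2000, rng
        )
        _, _, ll_short = fit_exponential_mixture(x, 2, max_iter=3, seed=3)
        _, _, ll_long = fit_exponential_mixture(x, 2, max_iter=2000, seed=3)
        assert ll_long >= ll_short - 1e-9

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential_mixture(np.array([0.1, -0.2] * 10), 2)
        with pytest.raises(ValueError):
            fit_exponential_mixture(np.full(5, 0.1), 1)


class TestQQRSquared:
    def test_self_consistency(self):
        rng = np.random.default_rng(14)
        x = rng.exponential(0.024, size=10_000)
        assert qq_r_squared(x, stats.expon(scale=0.024)) > 0.95

    def test_mixture_data_ranks_true_model_above_single_exponential(self):
        rng = np.random.default_rng(15)
        x = exponential_mixture_sample(
            np.array([0.004, 0.1]), np.array([0.8, 0.2]), 5000, rng
        )
        ref = exponential_mixture_sample(
            np.array([0.004, 0.1]), np.array([0.8, 0.2]), 10_000, rng
        )
        r2_mix = qq_r_squared(x, ref)
        r2_single = qq_r_squared(x, stats.expon(scale=x.mean()))
        assert r2_mix > 0.9
        assert r2_single < r2_mix - 0.2

    def test_perfect_line_through_quartiles(self):
        x = np.linspace(0.0, 1.0, 100)

        class Identity:
            def ppf(self, p):
                return np.asarray(p)

        # order statistics equal the plotting positions: R^2 = 1 exactly
        assert qq_r_squared(x, Identity()) == pytest.approx(1.0, abs=1e-2)

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError):
            qq_r_squared(np.full(20, 0.5), stats.expon())


class TestHeterogeneity:
    def test_null_calibration(self):
        # identical group distributions: ~5% rejections at the 5% level
        rng = np.random.default_rng(16)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            values = rng.exponential(1.0, size=60)
            groups = np.repeat(np.arange(6), 10)
            p = heterogeneity_tests(values, groups)["kruskal_p"]
            rejections += p < 0.05
        rate = rejections / n_rep
        assert 0.02 < rate < 0.09

    def test_power_grows_with_shift(self):
        rng = np.random.default_rng(17)
        values = np.concatenate(
            [rng.normal(0, 1, 50), rng.normal(3, 1, 50)]
        )
        groups = np.repeat([0, 1], 50)
        out = heterogeneity_tests(values, groups)
        assert out["anova_p"] < 1e-6
        assert out["kruskal_p"] < 1e-6

    def test_hand_computed_three_group_anova(self):
        # textbook one-way ANOVA arithmetic
        g1, g2, g3 = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [4.0, 5.0, 6.0]
        grand = np.mean(g1 + g2 + g3)  # 10/3... computed below
        means = [np.mean(g) for g in (g1, g2, g3)]
        ss_between = 3 * sum((m - grand) ** 2 for m in means)
        ss_within = sum(
            (x - m) ** 2 for g, m in zip((g1, g2, g3), means) for x in g
        )
        f = (ss_between / 2) / (ss_within / 6)
        p_expected = stats.f.sf(f, 2, 6)
        out = heterogeneity_tests(
            np.array(g1 + g2 + g3), np.repeat([0, 1, 2], 3)
        )
        assert out["anova_p"] == pytest.approx(p_expected, rel=1e-9)

    def test_insufficient_groups_reported_not_raised(self):
        out = heterogeneity_tests(np.array([1.0, 2.0]), np.array([0, 0]))
        assert out["insufficient_groups"]


class TestConservationClustering:
    def test_perfectly_clustered_trajectories_give_zero_diversity(self):
        # each trajectory's events share one value: one cluster each, H = 0
        values = np.repeat([0.0, 10.0, 20.0], 10)
        ids = np.repeat(["a", "b", "c"], 10)
        out = conservation_clustering(
            values, ids, n_clusters_range=[3], n_restarts=5, seed=0
        )
        assert out[3] == pytest.approx(0.0, abs=1e-12)

    def test_random_assignment_approaches_log_k(self):
        # uninformative statistic: per-trajectory H -> log k
        rng = np.random.default_rng(18)
        n_traj, per_traj, k = 20, 200, 4
        values = rng.standard_normal(n_traj * per_traj)
        ids = np.repeat(np.arange(n_traj), per_traj)
        out = conservation_clustering(
            values, ids, n_clusters_range=[k], n_restarts=3, seed=1
        )
        per_traj_h = out[k] / n_traj
        assert per_traj_h > 0.8 * np.log(k)
        assert per_traj_h <= np.log(k) + 1e-9

    def test_conserved_statistic_scores_below_uninformative_one(self):
        rng = np.random.default_rng(19)
        n_traj, per_traj = 12, 8
        traj_mean = rng.uniform(10, 40, size=n_traj)
        radius = np.repeat(traj_mean, per_traj) + rng.normal(
            0, 1.0, n_traj * per_traj
        )
        noise = rng.standard_normal(n_traj * per_traj)
        ids = np.repeat(np.arange(n_traj), per_traj)
        h_radius = conservation_clustering(
            radius, ids, n_clusters_range=[5], n_restarts=20, seed=2
        )[5]
        h_noise = conservation_clustering(
            noise, ids, n_clusters_range=[5], n_restarts=20, seed=2
        )[5]
        assert h_radius < h_noise

    def test_diversity_nondecreasing_in_k_for_random_labels(self):
        rng = np.random.default_rng(20)
        values = rng.standard_normal(400)
        ids = np.repeat(np.arange(10), 40)
        out = conservation_clustering(
            values, ids, n_clusters_range=[2, 4, 8], n_restarts=5, seed=3
        )
        assert out[2] <= out[4] <= out[8]

    def test_more_clusters_than_events_rejected(self):
        with pytest.raises(ValueError):
            conservation_clustering(
                np.arange(3.0), np.zeros(3), n_clusters_range=[5]
            )

    def test_shannon_diversity_point_mass_and_uniform(self):
        assert shannon_diversity(np.zeros(10)) == 0.0
        assert shannon_diversity(np.arange(8)) == pytest.approx(np.log(8))


class TestLocalDiffusivity:
    def test_unbiased_on_pure_brownian_motion(self):
        rng = np.random.default_rng(21)
        n = 10_001
        positions = np.cumsum(
            np.sqrt(2 * 0.5 * DT) * rng.standard_normal((n, 2)), axis=0
        )
        traj = Trajectory(times=_times(n), positions=positions)
        est = local_diffusivity(traj, window=100)
        se = 0.5 * np.sqrt(2 / (2 * (n - 1)))
        assert abs(np.nanmean(est) - 0.5) < 3 * se

    def test_frozen_particle_gives_zero(self):
        traj = Trajectory(times=_times(300), positions=np.zeros((300, 2)))
        est = local_diffusivity(traj, window=50)
        assert np.allclose(est, 0.0)

    def test_level_shift_inside_confinement_events(self):
        traj, hidden = simulate(SimulationConfig(seed=22))
        est = local_diffusivity(traj, window=100)
        conf, free = hidden.z == 1, hidden.z == 0
        # estimate drops inside confinement: clear separation of means
        assert np.nanmean(est[conf]) < 0.8 * np.nanmean(est[free])

    def test_nonuniform_steps_skipped_with_warning(self):
        times = np.concatenate([_times(50), 50 * DT + 0.5 + _times(50)])
        rng = np.random.default_rng(23)
        traj = Trajectory(
            times=times, positions=rng.standard_normal((100, 2)) * 0.01
        )
        with pytest.warns(UserWarning):
            est = local_diffusivity(traj, window=10)
        assert np.isnan(est).any()
        assert np.isfinite(est).any()


class TestCorrelate:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, p = correlate(x, x)
        assert r == pytest.approx(1.0)

    def test_independent_pairs_near_zero(self):
        rng = np.random.default_rng(24)
        r, _ = correlate(rng.standard_normal(10_000), rng.standard_normal(10_000))
        assert abs(r) < 0.05

    def test_five_pair_hand_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        xm, ym = x.mean(), y.mean()
        r_hand = np.sum((x - xm) * (y - ym)) / np.sqrt(
            np.sum((x - xm) ** 2) * np.sum((y - ym) ** 2)
        )
        r, p = correlate(x, y)
        assert r == pytest.approx(r_hand, rel=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            correlate(np.ones(5), np.arange(5.0))
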
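import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import photonpath as pp
from photonpath.enhancement import GROUPS, round_half_up
from photonpath.errors import CorruptInputError, InsufficientStatesError, MissingGroupError
from photonpath.reconstruct import StatePath


def path_from_states(states, dt, t0=0.0):
    times = t0 + np.concatenate(([0.0], np.cumsum(dt)))
    segs = []
    start = 0
    for i in range(1, len(states)):
        if states[i] != states[start]:
            segs.append((times[start], times[i], int(states[start])))
            start = i
    segs.append((times[start], times[-1], int(states[start])))
    return StatePath(states=np.asarray(states), log_likelihood=0.0, segments=tuple(segs))


def two_segment_series(mean_dt1, n1, mean_dt0, n0):
    """State-1 segment then state-0 segment, each with exact mean dt."""
    dt = np.concatenate([np.full(n1, mean_dt1), np.full(n0, mean_dt0)])
    states = np.concatenate([np.ones(n1, dtype=int), np.zeros(n0, dtype=int)])
    return pp.InterphotonSeries(dt=dt), path_from_states(states, dt)


class TestSummarizeStates:
    def test_worked_example_count_rates(self):
        # printed mean interphoton times give the printed count rates
        series, path = two_segment_series(6.154e-4, 9768, 1.541e-3, 6552)
        s0, s1 = pp.summarize_states(path, series, n_states=2)
        assert round(s1.count_rate) == 1625
        assert round(s0.count_rate) == 649

    def test_single_state_mean_equals_global_mean(self):
        rng = np.random.default_rng(1)
        dt = rng.exponential(1e-3, 500)
        series = pp.InterphotonSeries(dt=dt)
        path = path_from_states(np.zeros(500, dtype=int), dt)
        (s0,) = pp.summarize_states(path, series, n_states=1)
        assert s0.mean_interphoton_time == pytest.approx(dt.mean())

    def test_unoccupied_state_is_null(self):
        series, path = two_segment_series(1e-3, 10, 2e-3, 10)
        summaries = pp.summarize_states(path, series, n_states=3)
        assert summaries[2].n_intervals == 0
        assert summaries[2].count_rate is None

    def test_misaligned_lengths_rejected(self):
        series, path = two_segment_series(1e-3, 10, 2e-3, 10)
        short = pp.InterphotonSeries(dt=series.dt[:-1])
        with pytest.raises(CorruptInputError):
            pp.summarize_states(path, short)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 5000), n=st.integers(5, 300), n_states=st.integers(2, 3))
    def test_reciprocal_identity_and_conservation(self, seed, n, n_states):
        rng = np.random.default_rng(seed)
        dt = rng.exponential(1e-3, n)
        states = rng.integers(0, n_states, n)
        series = pp.InterphotonSeries(dt=dt)
        path = path_from_states(states, dt)
        summaries = pp.summarize_states(path, series, n_states=n_states)
        assert sum(s.n_intervals for s in summaries) == n
        for s in summaries:
            if s.n_intervals:
                assert abs(s.count_rate * s.mean_interphoton_time - 1.0) < 1e-9


class TestComputeIntensities:
    def test_worked_example_intensity(self):
        series, path = two_segment_series(6.154e-4, 9768, 1.541e-3, 6552)
        summaries = pp.summarize_states(path, series, n_states=2)
        res = pp.compute_intensities(summaries)
        assert round(res.intensities[1]) == 976

    def test_equal_rates_give_zero(self):
        dt = np.concatenate([np.full(10, 1e-3), np.full(10, 5e-4), np.full(10, 5e-4)])
        states = np.repeat([0, 1, 2], 10)
        series = pp.InterphotonSeries(dt=dt)
        res = pp.compute_intensities(
            pp.summarize_states(path_from_states(states, dt), series, n_states=3)
        )
        assert res.intensities[2] == pytest.approx(0.0)

    def test_single_occupied_state_rejected(self):
        dt = np.full(20, 1e-3)
        series = pp.InterphotonSeries(dt=dt)
        path = path_from_states(np.zeros(20, dtype=int), dt)
        with pytest.raises(InsufficientStatesError):
            pp.compute_intensities(pp.summarize_states(path, series, n_states=2))

    def test_negative_intensity_flagged_not_clamped(self):
        # state 1 slower than state 0: ordering violated upstream
        dt = np.concatenate([np.full(10, 2e-3), np.full(10, 1e-3)])
        states = np.concatenate([np.ones(10, dtype=int), np.zeros(10, dtype=int)])
        series = pp.InterphotonSeries(dt=dt)
        res = pp.compute_intensities(
            pp.summarize_states(path_from_states(states, dt), series, n_states=2)
        )
        assert res.flagged_negative
        assert res.intensities[1] < 0

    def test_blink_intensities_match_configured_rates(self, blink_sim):
        traj, _ = blink_sim
        path, model = pp.reconstruct(traj, n_states=3)
        series = pp.compute_interphoton_times(traj)
        res = pp.compute_intensities(pp.summarize_states(path, series, n_states=3))
        assert res.intensities[1] == pytest.approx(2500.0 - 650.0, rel=0.10)
        assert res.intensities[2] == pytest.approx(6000.0 - 2500.0, rel=0.15)


def intensity(mol, substrate, n_states, vals):
    return pp.IntensityResult(
        molecule_id=mol, substrate=substrate, n_states=n_states, intensities=vals
    )


class TestAggregateEnhancement:
    def cohort(self):
        res = []
        for i in range(6):
            res.append(intensity(f"g2_{i}", "glass", 2, {1: 900.0 + 10 * i}))
        for i in range(4):
            res.append(intensity(f"g3_{i}", "glass", 3, {1: 800.0, 2: 1500.0 + i}))
        for i in range(5):
            res.append(intensity(f"z2_{i}", "ZMW", 2, {1: 1800.0 + i}))
        for i in range(3):
            res.append(intensity(f"z3_{i}", "ZMW", 3, {1: 1700.0, 2: 3000.0 + i}))
        return res

    def test_group_sizes_are_consistent(self):
        # the pattern of the published table (63 = 33 + 30) holds by
        # construction for any cohort
        enh = pp.aggregate_enhancement(self.cohort())
        for side, n2, n3 in ((enh.glass, 6, 4), (enh.zmw, 5, 3)):
            assert side["two_state_I1"].n == n2
            assert side["all_I1"].n == n2 + n3
            assert side["three_state_I2"].n == n3
            assert side["pooled_I1_I2"].n == side["all_I1"].n + side["three_state_I2"].n

    def test_identical_lists_give_unit_ef(self):
        res = [intensity(f"g{i}", "glass", 2, {1: v}) for i, v in enumerate([800.0, 1000.0])]
        res += [intensity(f"z{i}", "ZMW", 2, {1: v}) for i, v in enumerate([800.0, 1000.0])]
        enh = pp.aggregate_enhancement(res)
        assert enh.ef["two_state_I1"] == pytest.approx(1.0)
        assert enh.ef_rounded["two_state_I1"] == 1.0

    def test_published_cohort_means_reproduce_ef_column(self):
        means = {
            "two_state_I1": (3086.0, 3566.0),
            "all_I1": (2572.0, 4105.0),
            "three_state_I2": (3934.0, 7224.0),
            "pooled_I1_I2": (3011.0, 4844.0),
        }
        efs = pp.enhancement_from_means(means)
        assert [efs[g][1] for g in GROUPS] == [1.2, 1.6, 1.8, 1.6]

    def test_outlier_rule_excludes_bright_glass_only(self):
        res = self.cohort()
        res.append(intensity("g_hot", "glass", 2, {1: 20_000.0}))
        res.append(intensity("z_hot", "ZMW", 2, {1: 20_000.0}))
        enh = pp.aggregate_enhancement(res, outlier_threshold=16_000.0)
        assert enh.excluded_ids == ("g_hot",)
        assert enh.glass["two_state_I1"].n == 6  # hot molecule dropped
        assert enh.zmw["two_state_I1"].n == 6  # ZMW side untouched

    def test_one_sided_group_is_an_error(self):
        res = [intensity("g", "glass", 3, {1: 800.0, 2: 1500.0}),
               intensity("z", "ZMW", 2, {1: 1800.0})]
        with pytest.raises(MissingGroupError):
            pp.aggregate_enhancement(res)

    def test_absent_distribution_is_omitted(self):
        res = [intensity("g", "glass", 2, {1: 800.0}),
               intensity("z", "ZMW", 2, {1: 1800.0})]
        enh = pp.aggregate_enhancement(res)
        assert "three_state_I2" not in enh.ef
        assert set(enh.ef) == {"two_state_I1", "all_I1", "pooled_I1_I2"}


def test_round_half_up_boundaries():
    assert round_half_up(1.15, 1) == 1.2
    assert round_half_up(1.55, 1) == 1.6
    assert round_half_up(1.8361, 1) == 1.8


class TestBinTrajectory:
    def test_uniform_photons(self):
        t = (np.arange(100) + 0.5) / 100.0
        binned = pp.bin_trajectory(pp.PhotonTrajectory(arrival_times=t), bin_width=0.1)
        assert binned.counts.sum() == 100
        assert np.all(binned.counts[:10] == 10)

    def test_empty_trajectory(self):
        binned = pp.bin_trajectory(pp.PhotonTrajectory(arrival_times=np.empty(0)))
        assert binned.counts.size == 0

    def test_worked_example_step_heights(self, worked_example_sim):
        # binned trace steps from ~162 to ~65 counts per 100 ms at the bleach
        traj, truth = worked_example_sim
        path, _ = pp.reconstruct(traj, n_states=2)
        binned = pp.bin_trajectory(traj, path, bin_width=0.1)
        boundary = truth.segments[0][1]
        centers = (binned.bin_edges[:-1] + binned.bin_edges[1:]) / 2
        on = binned.counts[centers < boundary - 0.1]
        off = binned.counts[centers > boundary + 0.1]
        assert on.mean() == pytest.approx(162.5, rel=0.07)
        assert off.mean() == pytest.approx(64.9, rel=0.07)
        # overlay tracks the same two levels
        assert binned.overlay is not None
        assert binned.overlay.max() == pytest.approx(162.5, rel=0.07)
        assert binned.overlay.min() == pytest.approx(64.9, rel=0.07)

    def test_conservation_with_any_width(self, worked_example_sim):
        traj, _ = worked_example_sim
        for width in (0.05, 0.1, 0.7):
            assert pp.bin_trajectory(traj, bin_width=width).counts.sum() == len(traj)
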
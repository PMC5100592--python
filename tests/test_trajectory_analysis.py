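import numpy as np
import pytest

from minicircle.trajectory_analysis import (
    KIND_BOOL,
    KIND_DISTANCE,
    KIND_ENERGY,
    BasePairTrajectory,
    OpenCallConfig,
    UndefinedStatisticError,
    antipodal_enhancement,
    antipodal_permutation_null,
    breathing_events,
    call_open,
    circular_separation,
    classify_defects,
    denaturation_probability,
    mutual_denaturation_map,
    replicate_error_bars,
    twist_deviation_series,
)
from minicircle.sidd_model import JointProfile


def bool_traj(matrix, dt_ns=0.1, **aux):
    return BasePairTrajectory(
        values=np.asarray(matrix, dtype=bool), dt_ns=dt_ns, kind=KIND_BOOL, **aux
    )


class TestCallOpen:
    def test_distance_threshold_is_strict(self):
        traj = BasePairTrajectory(
            values=np.array([[4.0, 5.2, 3.9, 4.0001]]), dt_ns=1.0, kind=KIND_DISTANCE
        )
        assert call_open(traj).tolist() == [[False, True, False, True]]

    def test_energy_threshold(self):
        # less negative than -3.03e-21 J means the bond is effectively lost
        traj = BasePairTrajectory(
            values=np.array([[-3.0e-21, -3.1e-21]]), dt_ns=1.0, kind=KIND_ENERGY
        )
        assert call_open(traj).tolist() == [[True, False]]

    def test_monotone_in_threshold(self):
        vals = np.linspace(0, 8, 50).reshape(10, 5)
        traj = BasePairTrajectory(values=vals, dt_ns=1.0, kind=KIND_DISTANCE)
        loose = call_open(traj, OpenCallConfig(distance_threshold_A=3.0))
        tight = call_open(traj, OpenCallConfig(distance_threshold_A=5.0))
        assert (tight <= loose).all()

    def test_negative_distances_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            BasePairTrajectory(
                values=np.array([[-1.0]]), dt_ns=1.0, kind=KIND_DISTANCE
            )


class TestBreathingEvents:
    def test_sub_window_episode_counts_once(self):
        m = np.array([[0], [1], [1], [0]], dtype=bool)
        stats = breathing_events(m, dt_ns=0.4)
        assert stats.total == 1 and stats.per_bp.tolist() == [1]

    def test_episode_longer_than_window_not_breathing(self):
        m = np.array([[0], [1], [1], [1], [0]], dtype=bool)
        assert breathing_events(m, dt_ns=0.4).total == 0  # 1.2 ns > 1 ns

    def test_boundary_duration_exactly_one_ns_counts(self):
        m = np.array([[0], [1], [1], [0]], dtype=bool)
        assert breathing_events(m, dt_ns=0.5).total == 1  # duration == 1 ns

    def test_episodes_touching_ends_excluded(self):
        m = np.array([[1], [0], [0], [1]], dtype=bool)
        assert breathing_events(m, dt_ns=0.1).total == 0

    def test_closed_padding_invariance(self):
        rng = np.random.default_rng(0)
        m = rng.random((40, 6)) < 0.3
        pad = np.zeros((5, 6), dtype=bool)
        base = breathing_events(np.vstack([pad, m, pad]), dt_ns=0.2)
        more = breathing_events(np.vstack([pad, pad, m, pad, pad, pad]), dt_ns=0.2)
        assert base.per_bp.tolist() == more.per_bp.tolist()

    def test_per_bp_counts_sum_to_total(self):
        rng = np.random.default_rng(1)
        m = rng.random((60, 9)) < 0.4
        stats = breathing_events(m, dt_ns=0.2)
        assert stats.total == int(stats.per_bp.sum())

    def test_unresolvable_frame_spacing_rejected(self):
        with pytest.raises(ValueError, match="frame spacing"):
            breathing_events(np.zeros((4, 1), dtype=bool), dt_ns=2.0)


class TestDenaturationProbability:
    def test_all_closed(self):
        assert denaturation_probability(np.zeros((5, 4), dtype=bool)).tolist() == [0] * 4

    def test_open_fraction(self):
        m = np.zeros((100, 2), dtype=bool)
        m[:25, 0] = True
        assert denaturation_probability(m)[0] == pytest.approx(0.25)

    def test_pooling_is_frame_weighted(self):
        a = np.ones((30, 3), dtype=bool)
        b = np.zeros((10, 3), dtype=bool)
        pooled = denaturation_probability([a, b])
        assert np.allclose(pooled, 0.75)

    def test_replicate_error_bars(self):
        a = np.ones((10, 2), dtype=bool)
        b = np.zeros((10, 2), dtype=bool)
        assert np.allclose(replicate_error_bars([a, b]), np.std([1.0, 0.0], ddof=1))


class TestMutualDenaturationMap:
    def test_always_co_open_gives_log_one(self):
        m = np.ones((10, 3), dtype=bool)
        joint = mutual_denaturation_map(m)
        assert np.allclose(joint.log_p, 0.0)

    def test_never_co_open_gives_sentinel(self):
        m = np.zeros((10, 2), dtype=bool)
        m[:, 0] = True
        joint = mutual_denaturation_map(m)
        assert np.isnan(joint.log_p[0, 1]) and np.isnan(joint.log_p[1, 0])
        assert np.isnan(joint.log_p[1, 1])  # bp 2 never opens at all

    def test_diagonal_is_single_site_fraction(self):
        rng = np.random.default_rng(2)
        m = rng.random((200, 5)) < 0.5
        joint = mutual_denaturation_map(m)
        frac = m.mean(axis=0)
        assert np.allclose(np.exp(np.diag(joint.log_p)), frac)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        m = rng.random((50, 8)) < 0.3
        lp = mutual_denaturation_map(m).log_p
        assert np.allclose(lp, lp.T, equal_nan=True)


class TestAntipodalEnhancement:
    def test_constant_map_gives_zero(self):
        lp = np.zeros((20, 20)) - 2.0
        assert antipodal_enhancement(JointProfile(log_p=lp), 2) == pytest.approx(0.0)

    def test_recovers_imposed_band_offset(self):
        n = 24
        sep = circular_separation(n)
        lp = np.full((n, n), -5.0)
        band = (sep > 0) & (np.abs(sep - n / 2) <= 2)
        lp[band] += 1.5
        assert antipodal_enhancement(JointProfile(log_p=lp), 2) == pytest.approx(1.5)

    def test_empty_band_raises_undefined(self):
        n = 12
        sep = circular_separation(n)
        lp = np.full((n, n), np.nan)
        lp[(sep > 0) & (sep < 3)] = -1.0  # only near-diagonal sampled
        with pytest.raises(UndefinedStatisticError):
            antipodal_enhancement(JointProfile(log_p=lp), 1)

    def test_coupled_signal_beats_permutation_null(self):
        """Frames where antipodal partners co-open yield a significant excess."""
        rng = np.random.default_rng(4)
        n, frames = 20, 400
        m = np.zeros((frames, n), dtype=bool)
        for f in range(frames):
            i = rng.integers(0, n)
            m[f, i] = True
            if rng.random() < 0.8:
                m[f, (i + n // 2) % n] = True  # antipodal partner
            if rng.random() < 0.3:
                m[f, rng.integers(0, n)] = True
        stat = antipodal_enhancement(mutual_denaturation_map(m), 1)
        null = antipodal_permutation_null(m, 1, n_permutations=100, rng=rng)
        assert stat > np.quantile(null, 0.95)


class TestClassifyDefects:
    def make_traj(self, open_matrix, dt_ns=1.0, **aux):
        return bool_traj(open_matrix, dt_ns=dt_ns, **aux)

    def test_persistent_multi_bp_opening_is_bubble(self, recwarn):
        m = np.zeros((20, 10), dtype=bool)
        m[2:17, 3:6] = True  # 3 bp open for 15 frames at 1 ns
        calls = classify_defects(self.make_traj(m))
        kinds = [c.kind for c in calls]
        assert kinds == ["bubble"]
        assert calls[0].span == (4, 3)
        assert calls[0].persistent

    def test_persistent_single_bp_is_type_two_kink(self):
        m = np.zeros((20, 8), dtype=bool)
        m[1:16, 2] = True
        with pytest.warns(UserWarning):
            calls = classify_defects(self.make_traj(m))
        assert [c.kind for c in calls] == ["kink_II"]

    def test_short_multi_bp_opening_is_wrinkle(self):
        m = np.zeros((20, 8), dtype=bool)
        m[5:8, 2:4] = True  # 2 bp for 3 ns: transient
        with pytest.warns(UserWarning):
            calls = classify_defects(self.make_traj(m))
        assert [c.kind for c in calls] == ["wrinkle"]

    def test_sub_ns_single_bp_is_breathing(self):
        m = np.zeros((30, 6), dtype=bool)
        m[10, 1] = True
        with pytest.warns(UserWarning):
            calls = classify_defects(self.make_traj(m, dt_ns=0.5))
        assert [c.kind for c in calls] == ["breathing"]

    def test_stacking_break_with_intact_pairing_is_type_one_kink(self):
        m = np.zeros((20, 8), dtype=bool)
        stack = np.zeros((20, 8), dtype=bool)
        stack[2:18, 4] = True  # step 5 loses stacking, no pairing broken
        with pytest.warns(UserWarning):  # still no registry channel
            calls = classify_defects(self.make_traj(m, stacking_broken=stack))
        assert [c.kind for c in calls] == ["kink_I"]

    def test_sustained_register_shift_is_slip(self):
        m = np.zeros((20, 8), dtype=bool)
        reg = np.zeros((20, 8), dtype=int)
        reg[3:19, 5] = 1
        stack = np.zeros((20, 8), dtype=bool)
        calls = classify_defects(
            self.make_traj(m, registry_shift=reg, stacking_broken=stack)
        )
        assert [c.kind for c in calls] == ["slip"]

    def test_missing_channels_warn_and_skip(self):
        m = np.zeros((5, 4), dtype=bool)
        with pytest.warns(UserWarning, match="stacking"):
            classify_defects(self.make_traj(m))

    def test_wrap_around_bubble_span(self):
        m = np.zeros((20, 10), dtype=bool)
        m[2:17, 9] = True
        m[2:17, 0] = True  # contiguous across the circular seam
        with pytest.warns(UserWarning):
            calls = classify_defects(self.make_traj(m))
        assert [c.kind for c in calls] == ["bubble"]
        assert calls[0].span == (10, 2)


class TestTwistDeviation:
    def test_all_at_reference_is_zero(self):
        twists = np.full((5, 12), 34.3)
        assert np.allclose(twist_deviation_series(twists, 34.3), 0.0)

    def test_uniform_offset(self):
        twists = np.full((4, 6), 35.3)
        assert np.allclose(twist_deviation_series(twists, 34.3), 1.0)

    def test_relaxation_trend_recovered(self):
        frames, steps = 50, 10
        decay = np.exp(-np.arange(frames) / 12.0)
        twists = 34.3 - 3.0 * decay[:, None] * np.ones((1, steps))
        series = twist_deviation_series(twists, np.full(steps, 34.3))
        assert series[0] == pytest.approx(-3.0)
        assert np.all(np.diff(series) > 0)  # monotone relaxation toward zero
        assert abs(series[-1]) < 0.1

    def test_reference_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            twist_deviation_series(np.zeros((3, 5)), np.zeros(4))
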
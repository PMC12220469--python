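import numpy as np
import pytest

import iseq
from iseq.behaviour_maps import (TrajectorySet, YMazeMask, classify_licks,
                                 gini_slice, location_vector,
                                 trajectory_distance)
from iseq.io_preproc import SessionRecord
from iseq.postprocess import SpikeIntensity


def _session_from_licks(lick_times, reward_times, T=400, frame_rate=1.0):
    lick = np.zeros(T, dtype=bool)
    reward = np.zeros(T, dtype=bool)
    lick[lick_times] = True
    reward[reward_times] = True
    return SessionRecord(x=np.zeros(T), y=np.zeros(T),
                         in_zone=np.zeros(T, bool), lick=lick, reward=reward,
                         frame_rate=frame_rate)


class TestClassifyLicks:
    def test_rewarded_lick_always_success(self):
        # second lick rewarded only 2 s after the first
        s = _session_from_licks([100, 102], [102])
        succ, fail = classify_licks(s, refractory_s=10)
        assert 102 in succ

    def test_close_unrewarded_lick_not_counted_but_resets_clock(self):
        # licks at 100, 105, 114: the 105 lick is within 10 s (ignored) but
        # resets the clock, so the 114 lick (9 s later) is also ignored
        s = _session_from_licks([100, 105, 114], [])
        succ, fail = classify_licks(s, refractory_s=10)
        assert succ == [] and fail == [100]

    def test_distant_unrewarded_lick_is_failure(self):
        s = _session_from_licks([100, 112], [])
        _, fail = classify_licks(s, refractory_s=10)
        assert fail == [100, 112]

    def test_reward_without_lick_rejected(self):
        s = _session_from_licks([10], [10])
        s.reward[20] = True
        with pytest.raises(ValueError, match="frame 20"):
            classify_licks(s)


class TestMask:
    def test_block_count_and_symmetry(self):
        m = YMazeMask()
        assert m.n_blocks == 190
        perm = m.mirror_y_permutation()
        assert (perm[perm] == np.arange(190)).all()      # involution

    def test_off_mask_position_rejected(self):
        m = YMazeMask()
        with pytest.raises(ValueError):
            m.block_of(0.5, 0.5)


class TestLocationVector:
    def test_constant_field_gives_constant_map(self, toy_session):
        session, _ = toy_session
        T = session.n_frames
        S = SpikeIntensity(np.full((1, T), 0.7), frame_rate=5.0)
        lv = location_vector(S, session, L=3, smooth=True)
        vals = lv.values[0][~np.isnan(lv.values[0])]
        np.testing.assert_allclose(vals, 0.7, atol=1e-9)

    def test_zero_shift_matches_direct_average(self, toy_session):
        session, _ = toy_session
        T = session.n_frames
        rng = np.random.default_rng(0)
        S = SpikeIntensity(rng.uniform(size=(1, T)), frame_rate=5.0)
        mask = YMazeMask()
        lv = location_vector(S, session, mask=mask, L=1, smooth=False)
        blocks = mask.blocks_of(session.x, session.y)
        b = blocks[0]
        expect = S.values[0, blocks == b].mean()
        assert lv.values[0, 0, b] == pytest.approx(expect)

    def test_bump_locked_to_block_concentrates_mass(self, toy_session):
        session, H = toy_session
        # sequence 0 fires 5 frames before zone entry in the fixture
        S = iseq.spike_intensity(H, frame_rate=5.0)
        lv = location_vector(S, session, L=10, smooth=True)
        mask = lv.mask
        zone = set(mask.zone_blocks("upper")) | set(mask.zone_blocks("lower"))
        m5 = np.nan_to_num(lv.values[0, 5], nan=-np.inf)
        # mass at lag 5 should sit in or next to the zone
        bx, by = mask.cells[int(np.argmax(m5))]
        near = min(abs(bx - mask.cells[z][0]) + abs(by - mask.cells[z][1])
                   for z in zone)
        assert near <= 3

    def test_mismatched_lengths_rejected(self, toy_session):
        session, _ = toy_session
        S = SpikeIntensity(np.zeros((1, 10)), frame_rate=5.0)
        with pytest.raises(ValueError):
            location_vector(S, session, L=2)


class TestGini:
    def _brute(self, x, N):
        x = np.asarray(x, float)
        total = x.sum()
        acc = sum(abs(a - b) for a in x for b in x)
        return acc / (2 * N * total)

    def test_single_block_is_maximal(self):
        x = np.zeros(190)
        x[17] = 5.0
        g = gini_slice(x)
        assert g == pytest.approx(self._brute(x, 190))
        assert g == pytest.approx(189 / 190)
        assert g > 0.99

    def test_uniform_is_zero(self):
        assert gini_slice(np.full(190, 0.3)) == pytest.approx(0.0, abs=1e-12)

    def test_two_equal_blocks_brute_force(self):
        x = np.zeros(190)
        x[[3, 100]] = 2.5
        g = gini_slice(x)
        assert g == pytest.approx(188 / 190)
        assert g == pytest.approx(self._brute(x, 190))

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(size=190)
        assert gini_slice(13.7 * x) == pytest.approx(gini_slice(x))

    def test_all_zero_slice_is_zero(self):
        assert gini_slice(np.zeros(190)) == 0.0

    def test_block_relabeling_equivariance(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(size=190)
        perm = rng.permutation(190)
        assert gini_slice(x[perm]) == pytest.approx(gini_slice(x))


class TestTrajectoryDistance:
    def test_identical_sets_zero(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=(4, 6, 2))
        ts = TrajectorySet(w)
        assert trajectory_distance(ts, ts, "euclidean") == pytest.approx(0.0)
        assert trajectory_distance(ts, ts, "mahalanobis") == pytest.approx(0.0, abs=1e-6)

    def test_hand_arithmetic_example(self):
        # 2 frames, d=1: mean S = (1, 3), mean F = (0, 1), Var = 4 per frame
        S = TrajectorySet(np.array([[[1.0], [3.0]]]))
        r2 = np.sqrt(2.0)
        F = TrajectorySet(np.array([[[-r2], [1 - r2]], [[r2], [1 + r2]]]))
        assert trajectory_distance(S, F, "euclidean") == pytest.approx(1.5)
        assert trajectory_distance(S, F, "mahalanobis") == pytest.approx(0.75, rel=1e-6)

    def test_unit_variance_matches_euclidean(self):
        rng = np.random.default_rng(1)
        S = TrajectorySet(rng.normal(size=(3, 5, 1)) + 4)
        h = np.sqrt(0.5)
        base = rng.normal(size=(1, 5, 1))
        F = TrajectorySet(np.concatenate([base - h, base + h], axis=0))  # var 1
        de = trajectory_distance(S, F, "euclidean")
        dm = trajectory_distance(S, F, "mahalanobis")
        assert dm == pytest.approx(de, rel=1e-5)

    def test_pooled_covariance_formula(self):
        rng = np.random.default_rng(2)
        S = TrajectorySet(rng.normal(size=(5, 3, 2)))
        F = TrajectorySet(rng.normal(size=(7, 3, 2)) + 1)
        got = trajectory_distance(S, F, "mahalanobis", covariance="pooled", ridge=0)
        m, n = 5, 7
        total = 0.0
        for t in range(3):
            d = S.windows[:, t].mean(0) - F.windows[:, t].mean(0)
            Sig = ((m - 1) * np.cov(S.windows[:, t], rowvar=False)
                   + (n - 1) * np.cov(F.windows[:, t], rowvar=False)) / (m + n - 2)
            total += np.sqrt(d @ np.linalg.solve(Sig, d))
        assert got == pytest.approx(total / 3)

    def test_singular_covariance_without_ridge_raises(self):
        S = TrajectorySet(np.ones((2, 2, 2)))
        F = TrajectorySet(np.zeros((3, 2, 2)))   # zero variance -> singular
        with pytest.raises(np.linalg.LinAlgError):
            trajectory_distance(S, F, "mahalanobis", ridge=0.0)
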
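"""Tests for spatial binning, smoothing, the shuffle null, place fields,
spatial information and field properties."""

import numpy as np
import pytest

from fosplace import tuning
from fosplace.tuning import (
    bin_activity,
    detect_place_fields,
    field_properties,
    shuffle_block_permutation,
    smooth_circular,
    spatial_information,
)


def frame_loop_oracle(activity, session, eligible, n_bins=40, thr=5.0):
    """Direct per-frame accumulation of occupancy and binned means."""
    bw = session.track_length / n_bins
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    for f in range(session.n_frames):
        if session.trial_id[f] in eligible and session.speed[f] > thr:
            b = min(int(session.position[f] // bw), n_bins - 1)
            sums[b] += activity[f]
            counts[b] += 1
    mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    occ = counts / counts.sum()
    return mean, occ


class TestBinActivity:
    def test_constant_activity_gives_constant_bins(self, small_session):
        _, d = small_session
        act = np.full(d.session.n_frames, 2.5)
        b = bin_activity(act, d.session)
        visited = b.counts > 0
        assert np.allclose(b.mean[0, visited], 2.5)
        assert b.occupancy.sum() == pytest.approx(1.0)

    def test_point_activity_lands_in_expected_bin(self, small_session):
        _, d = small_session
        act = np.where(
            np.abs(d.session.position - 7.0) < 0.5, 1.0, 0.0
        )  # activity only near 7 cm -> bin 1
        b = bin_activity(act, d.session)
        hot = np.nansum(np.where(np.isfinite(b.mean[0]), b.mean[0], 0) > 0)
        assert b.mean[0, 1] > 0
        assert hot == 1

    def test_matches_frame_loop_oracle(self, small_session, rng):
        _, d = small_session
        act = rng.random(d.session.n_frames)
        elig = d.session.eligible_trials()
        b = bin_activity(act, d.session, elig)
        mean, occ = frame_loop_oracle(act, d.session, set(elig))
        assert np.allclose(b.occupancy, occ)
        assert np.allclose(b.mean[0], mean, equal_nan=True)

    def test_no_running_frames_raises(self, small_session):
        _, d = small_session
        import dataclasses

        slow = dataclasses.replace(d.session, speed=np.zeros(d.session.n_frames))
        with pytest.raises(ValueError):
            bin_activity(np.ones(d.session.n_frames), slow)


class TestSmoothCircular:
    def test_constant_vector_unchanged(self):
        assert np.allclose(smooth_circular(np.full(40, 3.0)), 3.0)

    def test_impulse_gives_wrapped_kernel(self):
        v = np.zeros(40)
        v[0] = 1.0
        s = smooth_circular(v)
        assert s.sum() == pytest.approx(1.0)
        assert s[39] == pytest.approx(s[1])  # circular symmetry around bin 0
        assert s[0] == s.max()

    def test_nan_bins_bridged(self):
        v = np.full(40, 2.0)
        v[10] = np.nan
        s = smooth_circular(v)
        assert np.all(np.isfinite(s))
        assert s[10] == pytest.approx(2.0)


class TestBlockPermutation:
    @pytest.mark.parametrize("n_frames", [120, 121, 125])
    def test_structure_matches_index_arithmetic(self, n_frames, rng):
        perm = shuffle_block_permutation(n_frames, rng)
        # it is a permutation
        assert np.array_equal(np.sort(perm), np.arange(n_frames))
        # it decomposes into exactly 6 maximal circularly-contiguous chunks
        # whose sizes differ by at most one frame
        breaks = np.flatnonzero(np.diff(perm) % n_frames != 1) + 1
        chunks = np.split(perm, breaks)
        # merge chunks that are circularly contiguous across the shift seam
        sizes = sorted(len(c) for c in chunks)
        assert len(chunks) <= 7  # 6 blocks, one possibly split by the wrap
        merged = []
        for c in chunks:
            if merged and (c[0] - merged[-1][-1]) % n_frames == 1:
                merged[-1] = np.r_[merged[-1], c]
            else:
                merged.append(c)
        assert sum(len(c) for c in merged) == n_frames

    def test_too_few_frames(self, rng):
        with pytest.raises(ValueError):
            shuffle_block_permutation(5, rng)


class TestSpatialInformation:
    def test_flat_tuning_zero_bits(self):
        p = np.full(40, 1 / 40)
        assert spatial_information(np.full(40, 3.0), p) == pytest.approx(0.0)

    def test_two_bin_worked_case_is_one_bit(self):
        H = spatial_information(np.array([2.0, 0.0]), np.array([0.5, 0.5]))
        assert H == pytest.approx(1.0)

    @pytest.mark.parametrize("c", [0.5, 2.0, 7.3])
    def test_linear_scaling_in_amplitude(self, c, rng):
        a = rng.random(40)
        p = rng.random(40)
        p /= p.sum()
        H1 = spatial_information(a, p)
        Hc = spatial_information(c * a, p)
        assert Hc == pytest.approx(c * H1)

    def test_silent_cell_zero(self):
        p = np.full(40, 1 / 40)
        assert spatial_information(np.zeros(40), p) == 0.0


class TestPlaceFields:
    def test_two_bins_not_enough(self):
        sm = np.zeros(40)
        null = np.full(40, 0.5)
        sm[[5, 6]] = 1.0
        assert detect_place_fields(sm, null) == []

    def test_all_bins_significant_single_wrapped_field(self):
        assert detect_place_fields(np.ones(40), np.zeros(40)) == [(0, 40)]

    def test_run_wrapping_the_origin(self):
        sm = np.zeros(40)
        null = np.full(40, 0.5)
        sm[[38, 39, 0, 1]] = 1.0
        assert detect_place_fields(sm, null) == [(38, 4)]

    def test_ties_are_not_significant(self):
        sm = np.full(40, 0.5)
        null = np.full(40, 0.5)
        assert detect_place_fields(sm, null) == []


class TestShuffleNull:
    def test_single_shuffle_percentile_is_that_shuffle(self, small_session, rng):
        """With one shuffle, the percentile curve equals the curve obtained
        by replaying the same permutation by hand."""
        _, d = small_session
        act = rng.random(d.session.n_frames)
        b = bin_activity(act, d.session)
        null, sh = tuning.shuffle_null(b, n_shuffles=1, seed=1)
        # replay: same rng stream, same permutation, direct binning
        perm = shuffle_block_permutation(b.bin_of_frame.size, np.random.default_rng(1))
        bins_s = b.bin_of_frame[perm]
        mean = np.full(40, np.nan)
        for i in range(40):
            sel = bins_s == i
            if sel.any():
                mean[i] = b.activity[0][sel].mean()
        expected = smooth_circular(mean)
        assert np.allclose(null[0], expected, equal_nan=True)
        assert sh[0, 0] == pytest.approx(
            spatial_information(np.where(np.isfinite(mean), mean, 0), b.occupancy)
        )

    def test_null_is_calibrated_for_position_independent_cells(self, small_session):
        _, d = small_session
        rngl = np.random.default_rng(9)
        acts = rngl.random((30, d.session.n_frames))
        b = bin_activity(acts, d.session)
        sm = smooth_circular(b.mean)
        null, _ = tuning.shuffle_null(b, n_shuffles=300, seed=2, observed=sm)
        with np.errstate(invalid="ignore"):
            frac = np.nanmean((sm > null).astype(float))
        assert frac < 0.03  # nominal exceedance is 1 percent per bin

    def test_recovery_of_planted_tuning(self, tuned_session):
        cfg, d = tuned_session
        from fosplace import signals

        sig = np.zeros_like(d.dff)
        for c in range(cfg.n_cells):
            sig[c] = signals.detect_significant_transients(d.dff[c]).dff
        tun = tuning.analyze_tuning(sig, d.session, n_shuffles=500, seed=0)
        assert tun.is_place_cell.mean() > 0.9
        # detected peaks near the true field centres
        bw = cfg.bin_width_cm
        hits = 0
        checked = 0
        for c in np.flatnonzero(tun.is_place_cell):
            true_bin = int(d.truth.field_center_cm[c] // bw)
            fb = tuning.field_bins(tun.fields[c], cfg.n_bins)
            peak = int(fb[np.argmax(tun.smoothed[c][fb])])
            dist = min(abs(peak - true_bin), 40 - abs(peak - true_bin))
            checked += 1
            hits += dist <= 2
        assert checked > 0 and hits / checked > 0.9


class TestFieldProperties:
    def _binned(self, per_trial, mean=None):
        nt, nb = per_trial.shape
        return tuning.BinnedActivity(
            per_trial=per_trial[None],
            mean=(per_trial.mean(axis=0) if mean is None else mean)[None],
            occupancy=np.full(nb, 1 / nb),
            counts=np.ones(nb, int),
            trial_ids=np.arange(nt),
            frame_index=np.arange(nt * nb),
            bin_of_frame=np.tile(np.arange(nb), nt),
            trial_of_frame=np.repeat(np.arange(nt), nb),
            activity=per_trial.reshape(1, -1),
            bin_width=5.0,
        )

    def test_identical_trials_give_unit_correlation(self):
        row = np.r_[np.zeros(10), [1.0, 2, 1.0], np.zeros(27)]
        b = self._binned(np.tile(row, (4, 1)))
        sig = (b.activity[0] > 0)
        p = field_properties(0, b, [(10, 3)], sig)
        assert p["trial_to_trial_corr"] == pytest.approx(1.0)
        assert p["fraction_active"] == 1.0

    def test_zero_outfield_activity_full_selectivity(self):
        row = np.r_[np.zeros(10), [1.0, 2, 1.0], np.zeros(27)]
        b = self._binned(np.tile(row, (3, 1)))
        p = field_properties(0, b, [(10, 3)], b.activity[0] > 0)
        assert p["selectivity"] == pytest.approx(1.0)

    def test_hand_computed_three_trial_matrix(self):
        t0 = np.r_[[1.0, 2, 3], np.zeros(37)]
        t1 = np.r_[[3.0, 2, 1], np.zeros(37)]
        t2 = np.r_[[1.0, 2, 3], np.zeros(37)]
        pt = np.vstack([t0, t1, t2])
        b = self._binned(pt)
        p = field_properties(0, b, [(0, 3)], b.activity[0] > 0)
        r01 = np.corrcoef(t0, t1)[0, 1]
        r02 = np.corrcoef(t0, t2)[0, 1]
        r12 = np.corrcoef(t1, t2)[0, 1]
        assert p["trial_to_trial_corr"] == pytest.approx((r01 + r02 + r12) / 3)
        assert p["field_widths_cm"] == [15.0]

    def test_cell_without_field_raises(self):
        b = self._binned(np.ones((3, 40)))
        with pytest.raises(ValueError):
            field_properties(0, b, [], b.activity[0] > 0)
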
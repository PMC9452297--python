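"""Tests for dF/F baselining and significant-transient detection."""

import numpy as np
import pytest

from fosplace import signals
from fosplace.signals import (
    DEFAULT_THRESHOLDS,
    compute_dff,
    detect_significant_transients,
    transient_stats,
)


def oracle_sliding_percentile(raw, frame_rate, window_s=60.0, q=30.0):
    """Literal frame-by-frame truncated-window percentile baseline."""
    n = raw.size
    half = int(round(window_s * frame_rate)) // 2
    base = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        base[i] = np.percentile(raw[lo:hi], q)
    return (raw - base) / base


def oracle_detect_mask(x, thresholds=DEFAULT_THRESHOLDS, fpr=0.001):
    """Exhaustive run-enumeration oracle applying the rules literally."""

    def runs(cond):
        out, start = [], None
        for i, c in enumerate(cond):
            if c and start is None:
                start = i
            elif not c and start is not None:
                out.append((start, i))
                start = None
        if start is not None:
            out.append((start, len(cond)))
        return out

    z = (x - np.median(x)) / x.std()
    mask = np.zeros(x.size, bool)
    for t in thresholds:
        pos = runs(z > t)
        neg = runs(z < -t)
        for s, e in pos:
            n = e - s
            n_pos = sum(1 for a, b in pos if b - a >= n)
            n_neg = sum(1 for a, b in neg if b - a >= n)
            if n_neg / n_pos < fpr:
                mask[s:e] = True
    # merge runs separated by a gap of < 2 frames
    r = runs(mask)
    for (s1, e1), (s2, e2) in zip(r, r[1:]):
        if s2 - e1 < 2:
            mask[e1:s2] = True
    # drop runs shorter than 2 frames
    for s, e in runs(mask):
        if e - s < 2:
            mask[s:e] = False
    return mask


class TestComputeDff:
    def test_constant_trace_is_zero(self):
        out = compute_dff(np.full(3000, 7.5), frame_rate=30.0)
        assert np.allclose(out, 0.0)

    def test_isolated_doubling_gives_one(self):
        raw = np.full(4000, 3.0)
        raw[2000] = 6.0  # single frame at twice the baseline
        out = compute_dff(raw, frame_rate=30.0)
        assert out[2000] == pytest.approx(1.0)

    def test_matches_sliding_window_oracle_on_step_trace(self):
        raw = np.r_[np.full(1200, 2.0), np.full(1400, 5.0), np.full(900, 3.0)]
        raw += 0.01 * np.sin(np.arange(raw.size))
        out = compute_dff(raw, frame_rate=30.0)
        exp = oracle_sliding_percentile(raw, 30.0)
        assert np.allclose(out, exp)

    def test_rejects_nonpositive_baseline_and_short_trace(self):
        with pytest.raises(ValueError):
            compute_dff(np.zeros(3000), 30.0)
        with pytest.raises(ValueError):
            compute_dff(np.ones(100), 30.0)


class TestDetector:
    def test_symmetric_trace_yields_nothing(self):
        # positive and negative run counts are equal at every length, so
        # FPR >= 1 for every candidate
        bump = np.r_[np.zeros(50), np.full(10, 5.0), np.zeros(50)]
        x = np.r_[bump, -bump, bump, -bump]
        tr = detect_significant_transients(x)
        assert tr.n_transients == 0
        assert np.all(tr.dff == 0)

    def test_clean_plateau_detected(self):
        rngl = np.random.default_rng(1)
        x = 0.01 * rngl.standard_normal(2000)
        x[1000:1010] += 5.0 * x.std() * 50  # far above any threshold
        tr = detect_significant_transients(x)
        assert tr.n_transients >= 1
        assert tr.mask[1000:1010].all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        rngl = np.random.default_rng(seed)
        x = rngl.standard_normal(2000)
        # inject a few decaying events so some transients are real
        for f in rngl.integers(0, 1900, 4):
            x[f : f + 30] += 5.0 * np.exp(-np.arange(30) / 10)
        tr = detect_significant_transients(x)
        assert np.array_equal(tr.mask, oracle_detect_mask(x))

    @pytest.mark.parametrize("gain,offset", [(3.7, 0.0), (0.2, 5.0), (10.0, -2.0)])
    def test_affine_invariance(self, gain, offset):
        rngl = np.random.default_rng(3)
        x = rngl.standard_normal(1500)
        x[700:720] += 6.0
        a = detect_significant_transients(x)
        b = detect_significant_transients(gain * x + offset)
        assert np.array_equal(a.mask, b.mask)

    def test_min_duration_and_merge_rules(self):
        rngl = np.random.default_rng(4)
        x = 0.01 * rngl.standard_normal(1000)
        sd = x.std()
        x[500:510] += 50 * sd
        x[511:520] += 50 * sd  # 1-frame gap: must merge into one transient
        tr = detect_significant_transients(x)
        spans = tr.transients[["start_frame", "end_frame"]].to_numpy()
        assert any(s <= 500 and e >= 520 for s, e in spans)
        # every retained transient lasts >= 2 frames
        assert (tr.transients["duration_frames"] >= 2).all()

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            detect_significant_transients(np.ones(100))

    def test_retained_transients_satisfy_fpr_bound_post_hoc(self):
        """Every acceptance recorded by the detector re-verifies FPR < 0.001
        when run counts are recomputed from scratch."""
        rngl = np.random.default_rng(11)
        x = rngl.standard_normal(5000)
        for f in rngl.integers(0, 4900, 6):
            x[f : f + 40] += 4.0 * np.exp(-np.arange(40) / 12)
        tr = detect_significant_transients(x)
        z = tr.standardized
        for acc in tr.acceptances:
            for t, n, _ in acc:
                pos = signals.find_runs(z > t)
                neg = signals.find_runs(z < -t)
                n_pos = int(np.sum(pos[:, 1] - pos[:, 0] >= n))
                n_neg = int(np.sum(neg[:, 1] - neg[:, 0] >= n)) if len(neg) else 0
                assert n_neg / n_pos < 0.001

    def test_sensitivity_on_low_noise_events(self):
        from fosplace.synthetic import GroupSpec, SimConfig, generate_session

        cfg = SimConfig(
            n_cells=10, n_trials=12, noise_sd=0.02,
            groups={"g": GroupSpec(1.0, reliability_p=1.0, tuned_fraction=1.0)},
        )
        d = generate_session(cfg, 5)
        recovered = total = 0
        for c in range(cfg.n_cells):
            tr = detect_significant_transients(d.dff[c])
            truth = d.truth.event_mask[c]
            recovered += int((tr.mask & truth).sum())
            total += int(truth.sum())
        assert total > 0
        assert recovered / total >= 0.99


class TestTransientStats:
    def test_empty_trace_stats(self):
        rngl = np.random.default_rng(0)
        tr = detect_significant_transients(rngl.standard_normal(1000))
        if tr.n_transients == 0:
            st = transient_stats(tr, 30.0)
            assert st["empty"] and st["alpha"] == 0 and st["transients_per_second"] == 0

    def test_hand_summed_single_transient(self):
        # one 3-frame transient of constant dF/F = 1 at 30 Hz
        import pandas as pd
        from fosplace.signals import TransientTrace

        dff = np.zeros(300)
        dff[100:103] = 1.0
        mask = dff > 0
        t = pd.DataFrame(
            dict(start_frame=[100], end_frame=[103], duration_frames=[3],
                 peak_dff=[1.0], sum_dff=[3.0])
        )
        st = transient_stats(TransientTrace(dff, mask, t), 30.0)
        assert st["mean_duration_s"] == pytest.approx(0.1)
        assert st["mean_integral"] == pytest.approx(0.1)
        assert st["alpha"] == pytest.approx(0.1)

    def test_duplicating_transients_doubles_rate_not_mean(self):
        import pandas as pd
        from fosplace.signals import TransientTrace

        def make(k):
            dff = np.zeros(600)
            rows = []
            for i in range(k):
                s = 100 + 50 * i
                dff[s : s + 3] = 1.0
                rows.append(dict(start_frame=s, end_frame=s + 3,
                                 duration_frames=3, peak_dff=1.0, sum_dff=3.0))
            return TransientTrace(dff, dff > 0, pd.DataFrame(rows))

        a, b = transient_stats(make(1), 30.0), transient_stats(make(2), 30.0)
        assert b["transients_per_second"] == pytest.approx(2 * a["transients_per_second"])
        assert b["mean_integral"] == pytest.approx(a["mean_integral"])
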
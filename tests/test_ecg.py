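"""Tachogram pipeline: R-peak detection, interpolation, outlier repair,
subject centering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiosleep.config import EPOCH_SAMPLES, EcgConfig
from cardiosleep.ecg import (
    BeatSeries, EPOCH_GRID_S, IhrEpoch, center_subject, detect_r_peaks,
    fill_nan_gaps, flag_outliers, make_ihr_epoch, preprocess_ecg,
)
from cardiosleep.errors import EmptyRecordingError, ParameterError

FS = 256.0


def pulse_train(beat_times, fs=FS, duration=30.0, noise_sd=0.0, seed=0):
    """Synthetic ECG of Gaussian QRS pulses at known beat times."""
    n = int(duration * fs)
    t = np.arange(n) / fs
    x = np.zeros(n)
    for tb in beat_times:
        x += np.exp(-0.5 * ((t - tb) / 0.012) ** 2)
    if noise_sd:
        x += np.random.default_rng(seed).normal(0, noise_sd, n)
    return x


class TestDetector:
    def test_clean_1hz_pulses_found_at_centers(self):
        truth = np.arange(0.5, 30.0, 1.0)
        beats = detect_r_peaks(pulse_train(truth), FS)
        assert len(beats) == 30
        assert np.max(np.abs(beats.beat_times_s - truth)) <= 1.0 / FS

    def test_all_zero_segment_gives_empty_series(self):
        assert len(detect_r_peaks(np.zeros(int(30 * FS)), FS)) == 0

    def test_noisy_pulses_mostly_recovered(self):
        # unit pulses + noise with sd 0.1 (20 dB peak SNR)
        truth = np.arange(0.5, 30.0, 1.0)
        beats = detect_r_peaks(pulse_train(truth, noise_sd=0.1, seed=7), FS)
        dist = np.abs(truth[:, None] - beats.beat_times_s[None, :]).min(axis=1)
        assert np.sum(dist < 0.05) >= 28

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ParameterError):
            detect_r_peaks(np.zeros(100), 0.0)

    def test_beat_times_must_be_ordered(self):
        with pytest.raises(ParameterError):
            BeatSeries(np.array([1.0, 0.5]))


class TestIhrEpoch:
    def test_fewer_than_15_beats_discarded(self):
        beats = BeatSeries(np.linspace(0.5, 29.5, 14))
        assert not make_ihr_epoch(beats).valid

    def test_uniform_rhythm_is_fixed_point(self):
        beats = BeatSeries(np.arange(0.5, 30.0, 1.0))
        e = make_ihr_epoch(beats)
        assert e.valid
        np.testing.assert_allclose(e.values, 60.0, atol=1e-9)

    def test_alternating_ibis_stay_within_rate_range(self):
        # IBIs alternating 0.8/1.0 s: rates 75 and 60 bpm; PCHIP is
        # shape-preserving so the interpolant never overshoots
        times = [0.2]
        for i in range(32):
            times.append(times[-1] + (0.8 if i % 2 == 0 else 1.0))
        beats = BeatSeries(np.array([t for t in times if t < 30.0]))
        e = make_ihr_epoch(beats)
        assert e.valid
        assert e.values.min() >= 60.0 - 1e-9
        assert e.values.max() <= 75.0 + 1e-9

    def test_border_shift_rule(self):
        # first beat time <- t1 - mean(ibi2, ibi3); with irregular borders the
        # interpolant anchors at the shifted time, checked via the oracle below
        t = np.array([0.1, 1.4, 2.2, 3.3] + list(np.arange(4.3, 29.0, 1.0)))
        e = make_ihr_epoch(BeatSeries(t))
        assert e.valid

    def test_pchip_matches_independent_hermite_oracle(self, rng):
        # brute-force Fritsch-Carlson derivatives + manual cubic Hermite
        ibis = rng.uniform(0.7, 1.3, size=28)
        t = np.concatenate([[0.3], 0.3 + np.cumsum(ibis)])
        t = t[t < 30.0]
        e = make_ihr_epoch(BeatSeries(t))
        assert e.valid

        tt = t.copy()
        ibi = np.diff(tt)
        y = np.empty_like(tt)
        y[1:] = 60.0 / ibi
        y[0] = y[1]
        tt[0] = tt[1] - 0.5 * (ibi[1] + ibi[2])
        tt[-1] = tt[-2] + 0.5 * (ibi[-2] + ibi[-3])
        h = np.diff(tt)
        delta = np.diff(y) / h
        d = np.zeros_like(y)
        for i in range(1, len(y) - 1):
            if delta[i - 1] * delta[i] <= 0:
                d[i] = 0.0
            else:
                w1 = 2 * h[i] + h[i - 1]
                w2 = h[i] + 2 * h[i - 1]
                d[i] = (w1 + w2) / (w1 / delta[i - 1] + w2 / delta[i])

        def edge(h0, h1, d0, d1):
            val = ((2 * h0 + h1) * d0 - h0 * d1) / (h0 + h1)
            if np.sign(val) != np.sign(d0):
                return 0.0
            if np.sign(d0) != np.sign(d1) and abs(val) > 3 * abs(d0):
                return 3 * d0
            return val

        d[0] = edge(h[0], h[1], delta[0], delta[1])
        d[-1] = edge(h[-1], h[-2], delta[-1], delta[-2])

        grid = EPOCH_GRID_S
        inside = (grid >= tt[0]) & (grid <= tt[-1])
        expected = np.empty(inside.sum())
        for j, g in enumerate(grid[inside]):
            i = np.searchsorted(tt, g, side="right") - 1
            i = min(i, len(tt) - 2)
            s = (g - tt[i]) / h[i]
            h00 = 2 * s**3 - 3 * s**2 + 1
            h10 = s**3 - 2 * s**2 + s
            h01 = -2 * s**3 + 3 * s**2
            h11 = s**3 - s**2
            expected[j] = (h00 * y[i] + h10 * h[i] * d[i]
                           + h01 * y[i + 1] + h11 * h[i] * d[i + 1])
        np.testing.assert_allclose(e.values[inside], expected, rtol=1e-9)


class TestOutliers:
    def test_constant_epoch_unflagged(self):
        e = flag_outliers(IhrEpoch(values=np.full(120, 60.0), valid=True))
        assert not e.nan_mask.any()

    def test_physiological_bounds(self):
        v = np.full(120, 60.0)
        v[5] = 39.0
        v[7] = 181.0
        e = flag_outliers(IhrEpoch(values=v, valid=True))
        assert e.nan_mask[5] and e.nan_mask[7]
        assert e.nan_mask.sum() == 2

    def test_median_band_rule_inside_physiological_range(self):
        v = np.full(120, 100.0)
        v[3] = 121.0  # inside 40-180 but > median + 20
        e = flag_outliers(IhrEpoch(values=v, valid=True))
        assert e.nan_mask[3]

    def test_three_sd_rule_can_be_tighter_than_band(self):
        v = 60.0 + np.resize([1.0, -1.0], 120)  # SD = 1
        v[10] = 64.5  # within +/-20 of the median but beyond 3 SD
        e = flag_outliers(IhrEpoch(values=v, valid=True))
        assert e.nan_mask[10]
        assert e.nan_mask.sum() == 1

    def test_statistics_use_preflag_samples(self):
        # an extreme value inflates the pre-flag SD used for all samples
        v = np.full(120, 60.0)
        v[0] = 500.0
        e = flag_outliers(IhrEpoch(values=v, valid=True))
        assert e.nan_mask[0] and e.nan_mask.sum() == 1


class TestGapFill:
    def test_ten_sample_gap_filled_by_mirroring(self):
        v = np.arange(120, dtype=float) + 50.0
        v[40:50] = np.nan
        e = fill_nan_gaps(IhrEpoch(values=v, valid=True))
        assert e.valid
        np.testing.assert_array_equal(e.values[40:50], (np.arange(30, 40) + 50.0)[::-1])
        assert not np.isnan(e.values).any()

    def test_eleven_sample_gap_invalidates(self):
        v = np.full(120, 70.0)
        v[40:51] = np.nan
        assert not fill_nan_gaps(IhrEpoch(values=v, valid=True)).valid

    def test_gap_at_epoch_start_invalidates(self):
        v = np.full(120, 70.0)
        v[0:3] = np.nan
        assert not fill_nan_gaps(IhrEpoch(values=v, valid=True)).valid

    def test_no_gap_is_identity(self):
        v = np.linspace(55, 80, 120)
        e = fill_nan_gaps(IhrEpoch(values=v, valid=True))
        np.testing.assert_array_equal(e.values, v)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_extra_flags_never_resurrect_an_invalid_epoch(self, seed):
        r = np.random.default_rng(seed)
        v = r.normal(60, 5, 120)
        mask = r.random(120) < 0.2
        v1 = v.copy()
        v1[mask] = np.nan
        e1 = fill_nan_gaps(IhrEpoch(values=v1, valid=True))
        extra = mask | (r.random(120) < 0.2)
        v2 = v.copy()
        v2[extra] = np.nan
        e2 = fill_nan_gaps(IhrEpoch(values=v2, valid=True))
        if not e1.valid:
            assert not e2.valid
        if e2.valid:
            assert not np.isnan(e2.values).any()


class TestCentering:
    def test_constant_recording_centers_to_zero(self):
        epochs = [IhrEpoch(values=np.full(120, 72.0), valid=True) for _ in range(4)]
        out = center_subject(epochs)
        for e in out:
            np.testing.assert_array_equal(e.values, 0.0)

    def test_pooled_median_is_zero_after_centering(self, rng):
        epochs = [IhrEpoch(values=rng.normal(65, 8, 120), valid=True)
                  for _ in range(9)]
        epochs.append(IhrEpoch(valid=False))
        out = center_subject(epochs)
        pooled = np.concatenate([e.values for e in out if e.valid])
        assert abs(np.median(pooled)) < 1e-12

    def test_baseline_shift_removed_between_subjects(self, rng):
        shape = rng.normal(0, 3, (5, 120))
        a = [IhrEpoch(values=60.0 + s, valid=True) for s in shape]
        b = [IhrEpoch(values=90.0 + s, valid=True) for s in shape]
        out_a, out_b = center_subject(a), center_subject(b)
        for ea, eb in zip(out_a, out_b):
            np.testing.assert_allclose(ea.values, eb.values, atol=1e-12)

    def test_zero_valid_epochs_raises(self):
        with pytest.raises(EmptyRecordingError):
            center_subject([IhrEpoch(valid=False)])


def test_pipeline_is_deterministic(rng):
    truth = np.cumsum(rng.uniform(0.8, 1.1, 100))
    truth = truth[truth < 60.0]
    x = np.concatenate([pulse_train(truth[truth < 30]),
                        pulse_train(truth[truth >= 30] - 30.0)])
    out1 = preprocess_ecg(x, FS, 2)
    out2 = preprocess_ecg(x.copy(), FS, 2)
    for e1, e2 in zip(out1, out2):
        assert e1.valid == e2.valid
        np.testing.assert_array_equal(e1.values, e2.values)


def test_valid_epochs_always_complete(rng):
    # every valid epoch leaving the pipeline has 120 finite samples
    truth = np.cumsum(rng.uniform(0.5, 1.6, 130))
    truth = truth[truth < 90.0]
    segs = [pulse_train(truth[(truth >= 30 * i) & (truth < 30 * (i + 1))] - 30 * i,
                        noise_sd=0.05, seed=i) for i in range(3)]
    out = preprocess_ecg(np.concatenate(segs), FS, 3)
    assert len(out) == 3
    for e in out:
        assert e.values.shape == (EPOCH_SAMPLES,)
        if e.valid:
            assert np.isfinite(e.values).all()
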
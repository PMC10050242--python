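import numpy as np
import pytest
from scipy.signal import welch

from winbci.core_io import EEGRecording, RunConfig
from winbci.preprocess import (
    bandpass_5_40,
    blink_threshold_signal,
    channel_weight,
    detect_blinks,
    preprocess_recording,
    regression_component,
    rejection_mask,
    remove_blinks,
    standardize_channel,
    z_sum,
)

FS = 128.0


def tone(freq, seconds=10.0, fs=FS, amp=1.0):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def band_power(x, fs, lo, hi):
    f, p = welch(x, fs, nperseg=min(len(x), 512))
    sel = (f >= lo) & (f <= hi)
    return np.trapezoid(p[sel], f[sel])


class TestRegressionComponent:
    def test_passband_4hz_preserved(self):
        x = tone(4.0)
        y = regression_component(x, FS)
        core = slice(256, -256)          # skip filter edge transients
        ratio = np.abs(y[core]).max() / np.abs(x[core]).max()
        assert 0.9 <= ratio <= 1.01

    def test_stopband_20hz_attenuated(self):
        x = tone(20.0)
        y = regression_component(x, FS)
        core = slice(256, -256)
        rms = lambda v: np.sqrt((v**2).mean())
        assert rms(y[core]) < 0.1 * rms(x[core])

    def test_dc_rejected(self):
        y = regression_component(np.full(2000, 5.0), FS)
        assert np.abs(y).max() < 1e-6

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError, match="band"):
            regression_component(np.zeros(100), 14.0)


class TestBlinkThresholdSignal:
    def test_non_negative_everywhere(self, rng):
        x = regression_component(rng.normal(size=4000), FS)
        assert (blink_threshold_signal(x, FS) >= 0).all()

    def test_constant_offset_invariant(self, rng):
        x = regression_component(rng.normal(size=4000), FS)
        a = blink_threshold_signal(x, FS)
        b = blink_threshold_signal(x + 100.0, FS)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            blink_threshold_signal(np.ones(100), FS)

    def test_argmax_inside_injected_blink(self):
        from winbci.synthetic import blink_pulse

        x = np.zeros(int(20 * FS))
        pulse = blink_pulse(FS, 300.0, 150.0)
        i0 = int(10 * FS)
        x[i0:i0 + len(pulse)] += pulse
        x += 0.5 * np.sin(2 * np.pi * 3.0 * np.arange(len(x)) / FS)
        regr = regression_component(x, FS)
        thres = blink_threshold_signal(regr, FS)
        peak_t = np.argmax(thres) / FS
        assert 10.0 - 0.1 <= peak_t <= 10.0 + 0.3 + 0.1


class TestDetectBlinks:
    def test_all_zero_gives_empty(self):
        assert detect_blinks(np.zeros(1000), FS) == []

    def test_two_separated_pulses_two_intervals(self):
        thres = np.full(int(30 * FS), 0.01)
        for t0 in (5.0, 20.0):
            i = int(t0 * FS)
            thres[i:i + 26] = 10.0
        out = detect_blinks(thres, FS, k=5.0, pad_s=0.1)
        assert len(out) == 2
        for (s, e), t0 in zip(out, (5.0, 20.0)):
            assert s <= t0 and e >= t0 + 26 / FS

    def test_overlapping_pads_merge(self):
        thres = np.full(int(10 * FS), 0.01)
        thres[640:655] = 10.0
        thres[660:675] = 10.0
        out = detect_blinks(thres, FS, k=5.0, pad_s=0.2)
        assert len(out) == 1

    def test_coverage_of_true_blinks(self, subject):
        rec, gt = subject
        _, corr = remove_blinks(rec)
        assert gt.blink_intervals, "fixture should contain blinks"
        covered = 0
        for s, e in gt.blink_intervals:
            mid = 0.5 * (s + e)
            if any(a <= mid <= b for a, b in corr.blink_intervals):
                covered += 1
        assert covered / len(gt.blink_intervals) >= 0.9


class TestChannelWeight:
    def test_identity(self, rng):
        x = rng.normal(size=500)
        assert channel_weight(x, x) == pytest.approx(1.0)

    def test_scaling(self, rng):
        x = rng.normal(size=500)
        assert channel_weight(2 * x, x) == pytest.approx(2.0)

    def test_hand_computed(self):
        assert channel_weight([1.0, -2.0, 3.0], [2.0, 2.0, 2.0]) == pytest.approx(1.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            channel_weight([1.0, 2.0], [0.0, 0.0])


class TestRemoveBlinks:
    def test_constructed_channel_residual_small(self):
        """A channel that is exactly w * regression component inside a blink
        interval is nearly cancelled there.

        The reference is built band-limited (an in-band tone burst) so the
        amplitude-ratio weight estimate is unbiased.
        """
        n = int(60 * FS)
        rng = np.random.default_rng(5)
        t = np.arange(n) / FS
        burst = np.exp(-0.5 * ((t - 30.0) / 0.1) ** 2)
        afz_src = 150.0 * burst * np.sin(2 * np.pi * 3.5 * t)
        af3 = afz_src + rng.normal(0, 1.0, n)
        af4 = afz_src + rng.normal(0, 1.0, n)
        regr = regression_component(afz_src, FS)
        w = 0.7
        target = w * regr
        other = np.zeros(n)
        rec = EEGRecording(
            np.vstack([af3, af4, target, other]), FS,
            ["AF3", "AF4", "F7", "O1"],
        )
        out, corr = remove_blinks(rec)
        hit = [iv for iv in corr.blink_intervals if iv[0] <= 30.0 <= iv[1]]
        assert len(hit) == 1, "the burst at t=30 s must be detected"
        s, e = hit[0]
        sl = slice(int(s * FS), int(e * FS))
        before = np.sqrt((target[sl] ** 2).mean())
        after = np.sqrt((out.channel("F7")[sl] ** 2).mean())
        assert after < 0.05 * before
        assert corr.weights["F7"] == pytest.approx(0.7, abs=0.05)

    def test_no_blinks_identity(self):
        rng = np.random.default_rng(0)
        rec = EEGRecording(rng.normal(0, 1, (4, 4000)), FS,
                           ["AF3", "AF4", "O1", "O2"])
        cfg = RunConfig(blink_k=1e9)      # nothing crosses the threshold
        out, corr = remove_blinks(rec, cfg)
        assert corr.blink_intervals == []
        np.testing.assert_array_equal(out.samples, rec.samples)

    def test_untouched_outside_intervals(self, subject):
        rec, _ = subject
        out, corr = remove_blinks(rec)
        inside = np.zeros(rec.n_samples, dtype=bool)
        for s, e in corr.blink_intervals:
            inside[int(s * FS):int(np.ceil(e * FS))] = True
        np.testing.assert_array_equal(out.samples[:, ~inside],
                                      rec.samples[:, ~inside])

    def test_frontal_cleanup_spares_occipital_alpha(self, subject):
        """Blink power (1-7 Hz) drops sharply on AF3 inside true blink
        intervals while O1 alpha power is nearly unchanged."""
        rec, gt = subject
        out, _ = remove_blinks(rec)
        inside = np.zeros(rec.n_samples, dtype=bool)
        for s, e in gt.blink_intervals:
            inside[int(s * FS):int(np.ceil(e * FS))] = True
        af3_before = rec.channel("AF3")
        af3_after = out.channel("AF3")
        bp = lambda x: band_power(x, FS, 1.0, 7.0)
        assert bp(af3_after[inside]) < 0.2 * bp(af3_before[inside])
        alpha = lambda x: band_power(x, FS, 8.0, 12.0)
        a_before = alpha(rec.channel("O1"))
        a_after = alpha(out.channel("O1"))
        assert abs(a_after - a_before) <= 0.05 * a_before

    def test_missing_reference_channel(self):
        rec = EEGRecording(np.zeros((2, 100)), FS, ["O1", "O2"])
        with pytest.raises(ValueError, match="AF3"):
            remove_blinks(rec)


class TestBandpass:
    def test_10hz_preserved(self):
        rec = EEGRecording(tone(10.0)[None, :], FS, ["O1"])
        out = bandpass_5_40(rec)
        core = slice(256, -256)
        ratio = np.abs(out.samples[0][core]).max() / np.abs(rec.samples[0][core]).max()
        assert abs(ratio - 1.0) < 0.1

    @pytest.mark.parametrize("freq", [1.0, 60.0])
    def test_stopband(self, freq):
        rec = EEGRecording(tone(freq)[None, :], FS, ["O1"])
        out = bandpass_5_40(rec)
        rms = lambda x: np.sqrt((x**2).mean())
        assert rms(out.samples[0]) < 0.1 * rms(rec.samples[0])

    def test_low_fs_warns_or_errors(self):
        rec = EEGRecording(np.random.default_rng(0).normal(size=(1, 4000)),
                           64.0, ["O1"])
        with pytest.warns(UserWarning, match="Nyquist"):
            bandpass_5_40(rec)
        rec2 = EEGRecording(np.zeros((1, 100)), 10.0, ["O1"])
        with pytest.raises(ValueError):
            bandpass_5_40(rec2)


class TestStandardize:
    def test_arithmetic_population_sigma(self):
        out = standardize_channel(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out, [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_zero_mean_unit_var(self, rng):
        out = standardize_channel(rng.normal(3, 7, 10_000))
        assert abs(out.mean()) < 1e-12
        assert abs(out.std() - 1.0) < 1e-12

    def test_affine_invariance(self, rng):
        x = rng.normal(size=1000)
        np.testing.assert_allclose(standardize_channel(3.2 * x + 11.0),
                                   standardize_channel(x), atol=1e-9)

    def test_constant_channel_named(self):
        with pytest.raises(ValueError, match="P7"):
            standardize_channel(np.ones(10), "P7")


class TestZSum:
    def test_identical_channels_scale_sqrt_c(self, rng):
        z = rng.normal(size=1000)
        out = z_sum(np.vstack([z, z, z, z]))
        np.testing.assert_allclose(out, 2.0 * z)

    def test_opposite_channels_cancel(self, rng):
        z = rng.normal(size=1000)
        np.testing.assert_allclose(z_sum(np.vstack([z, -z])), 0.0, atol=1e-12)

    def test_independent_channels_unit_variance(self, rng):
        z = rng.standard_normal((8, 100_000))
        assert abs(z_sum(z).var() - 1.0) < 0.05

    def test_montage_order_invariant(self, rng):
        z = rng.standard_normal((6, 500))
        perm = rng.permutation(6)
        np.testing.assert_allclose(z_sum(z), z_sum(z[perm]), atol=1e-12)


class TestRejectionMask:
    def test_hand_computed_threshold(self):
        m = rejection_mask(np.array([0.0, 0.0, 0.0, 0.0, 10.0]))
        assert m.mu_sum == pytest.approx(2.0)
        assert m.sigma_sum == pytest.approx(4.0)
        assert m.th_rej == pytest.approx(14.0)
        assert m.kept.all()

    def test_gaussian_tail_fraction(self):
        rng = np.random.default_rng(7)
        zs = rng.standard_normal(1_000_000)
        m = rejection_mask(zs, fs=1.0, pad_s=0.0)
        frac = 1.0 - m.kept.mean()
        assert frac == pytest.approx(0.00135, abs=0.0005)

    def test_shift_invariant(self, rng):
        zs = rng.standard_normal(10_000)
        np.testing.assert_array_equal(rejection_mask(zs).kept,
                                      rejection_mask(zs + 42.0).kept)

    def test_padding_dilates(self):
        zs = np.zeros(1000)
        zs[500] = 100.0
        zs += np.random.default_rng(0).normal(0, 0.1, 1000)
        no_pad = rejection_mask(zs, fs=100.0, pad_s=0.0)
        pad = rejection_mask(zs, fs=100.0, pad_s=0.05)
        assert (~pad.kept).sum() >= (~no_pad.kept).sum() + 8

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            rejection_mask(np.ones(100))


class TestPreprocessRecording:
    def test_clean_recording_keeps_samples(self, small_synth_cfg):
        """Without artifact bursts almost everything survives: >= 99% of
        samples before padding; the 0.1 s dilation around each threshold
        crossing costs a further few percent (the mu + 3 sigma threshold
        flags ~0.1-0.3% of samples of any stationary signal by
        construction, and padding widens each crossing by ~25 samples)."""
        from dataclasses import replace

        from winbci.synthetic import generate_subject

        cfg = replace(small_synth_cfg, burst_rate_per_min=0.0)
        rec, _ = generate_subject(cfg, 0)
        _, mask_nopad, _ = preprocess_recording(
            rec, RunConfig(reject_pad_s=0.0))
        assert mask_nopad.kept_fraction >= 0.99
        _, mask, _ = preprocess_recording(rec)
        assert mask.kept_fraction >= 0.93

    def test_burst_samples_rejected(self, subject):
        rec, gt = subject
        assert gt.artifact_intervals, "fixture should contain bursts"
        _, mask, _ = preprocess_recording(rec)
        hits = 0
        for s, e in gt.artifact_intervals:
            sl = slice(int(s * rec.fs), int(e * rec.fs))
            if (~mask.kept[sl]).any():
                hits += 1
        assert hits / len(gt.artifact_intervals) >= 0.8

    def test_threshold_identity(self, subject):
        rec, _ = subject
        _, mask, _ = preprocess_recording(rec)
        assert mask.th_rej == pytest.approx(mask.mu_sum + 3 * mask.sigma_sum)
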
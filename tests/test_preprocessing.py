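"""Filtering, leak removal, rejection, baseline, binning, vectorization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from caneeg.epochs import EpochsSet
from caneeg.preprocessing import (
    bandpass_filter,
    baseline_correct,
    bin_epochs,
    bin_starts,
    decoding_stream,
    erp_stream,
    reject_by_amplitude,
    remove_trigger_leak,
    vectorize_features,
)

SFREQ = 512.0
CHANNELS = ["F3", "F4", "T3", "T4", "Cz", "P3", "P4"]


def make_epochs(data, channels=None, t0=-150.0, labels=None):
    data = np.asarray(data, dtype=np.float64)
    n_trials, n_ch, n_samp = data.shape
    channels = channels or CHANNELS[:n_ch]
    labels = labels if labels is not None else np.array(["S"] * n_trials, dtype=object)
    times = t0 + np.arange(n_samp) * (1000.0 / SFREQ)
    return EpochsSet(data, times, SFREQ, channels, labels)


class TestBandpass:
    def test_dc_removed(self):
        ep = make_epochs(np.full((2, 2, 441), 7.0))
        out = bandpass_filter(ep, 2.0, 40.0)
        interior = slice(50, -50)
        assert np.abs(out.data[:, :, interior]).max() < 0.05

    def test_passband_sinusoid_preserved(self):
        t = np.arange(441) / SFREQ
        sine = 3.0 * np.sin(2 * np.pi * 10.0 * t)
        ep = make_epochs(sine[None, None, :])
        out = bandpass_filter(ep, 2.0, 40.0)
        interior = out.data[0, 0, 80:-80]
        amp = (interior.max() - interior.min()) / 2.0
        assert abs(amp - 3.0) / 3.0 < 0.05

    def test_stopband_attenuated_20db(self):
        t = np.arange(441) / SFREQ
        sine = 3.0 * np.sin(2 * np.pi * 100.0 * t)
        ep = make_epochs(sine[None, None, :])
        out = bandpass_filter(ep, 2.0, 25.0)
        amp = np.abs(out.data[0, 0, 80:-80]).max()
        assert amp < 3.0 * 10 ** (-20 / 20)

    def test_zero_phase_keeps_pulse_peak(self):
        x = np.zeros((1, 1, 441))
        x[0, 0, 220] = 1.0
        blur = np.exp(-0.5 * ((np.arange(441) - 220) / 10.0) ** 2)
        ep = make_epochs(blur[None, None, :])
        out = bandpass_filter(ep, 2.0, 40.0)
        assert abs(int(np.argmax(out.data[0, 0])) - 220) <= 1

    def test_band_outside_nyquist_rejected(self):
        ep = make_epochs(np.zeros((1, 1, 441)))
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(ep, 2.0, 300.0)


class TestTriggerLeak:
    def test_pure_leak_removed(self):
        leak = ((np.arange(256) > 77) & (np.arange(256) < 200)).astype(float)
        ep = make_epochs(3.0 * np.tile(leak, (2, 3, 1)))
        out = remove_trigger_leak(ep, leak)
        assert np.abs(out.data).max() < 1e-9

    def test_orthogonal_signal_untouched(self):
        """Normal-equations oracle: with a zero-mean signal orthogonal to
        the regressor, subtracting the GLM projection returns the signal."""
        rng = np.random.default_rng(0)
        leak = ((np.arange(256) >= 77) & (np.arange(256) < 200)).astype(float)
        raw = rng.standard_normal(256)
        # orthogonalize against [1, leak] so the projection is exactly zero
        design = np.column_stack([np.ones(256), leak])
        signal = raw - design @ np.linalg.lstsq(design, raw, rcond=None)[0]
        ep = make_epochs((signal + 2.5 * leak)[None, None, :])
        out = remove_trigger_leak(ep, leak)
        assert np.abs(out.data[0, 0] - signal).max() < 1e-6

    @given(st.integers(0, 2**31 - 1))
    def test_residual_orthogonal_to_regressor(self, seed):
        rng = np.random.default_rng(seed)
        leak = rng.standard_normal(128)
        ep = make_epochs(rng.standard_normal((2, 2, 128)))
        out = remove_trigger_leak(ep, leak)
        inner = np.tensordot(out.data, leak, axes=([2], [0]))
        assert np.abs(inner).max() < 1e-6 * np.abs(ep.data).max() * 128

    def test_zero_regressor_warns_noop(self):
        ep = make_epochs(np.random.default_rng(1).standard_normal((1, 1, 64)))
        with pytest.warns(UserWarning, match="all-zero"):
            out = remove_trigger_leak(ep, np.zeros(64))
        np.testing.assert_array_equal(out.data, ep.data)


class TestRejection:
    def test_quiet_trials_kept(self):
        ep = make_epochs(np.zeros((5, 3, 256)))
        out = reject_by_amplitude(ep, 100.0, (-150.0, 350.0))
        assert out.kept.all()

    def test_spike_inside_window_flags_exactly_that_trial(self):
        data = np.zeros((4, 3, 256))
        times = -150.0 + np.arange(256) * (1000.0 / SFREQ)
        spike_at = np.argmin(np.abs(times - 100.0))
        data[2, 1, spike_at] = 150.0
        out = reject_by_amplitude(make_epochs(data), 100.0, (-150.0, 350.0))
        assert list(out.kept) == [True, True, False, True]
        assert "F4" in out.reject_reason[2]
        # kept trials unmodified, rejected trial only flagged
        np.testing.assert_array_equal(out.data, data)

    def test_spike_outside_window_ignored(self):
        data = np.zeros((4, 3, 512))
        t0 = -300.0
        times = t0 + np.arange(512) * (1000.0 / SFREQ)
        data[2, 1, np.argmin(np.abs(times - (-200.0)))] = 150.0
        ep = make_epochs(data, t0=t0)
        out = reject_by_amplitude(ep, 100.0, (-150.0, 350.0))
        assert out.kept.all()

    def test_empty_window_rejected(self):
        ep = make_epochs(np.zeros((1, 1, 64)))
        with pytest.raises(ValueError, match="window"):
            reject_by_amplitude(ep, 100.0, (400.0, 500.0))


class TestBaseline:
    def test_constant_trace_zeroed_and_step_shifted(self):
        times = -150.0 + np.arange(256) * (1000.0 / SFREQ)
        data = np.where(times < 0, 5.0, 12.0)[None, None, :]
        out = baseline_correct(make_epochs(data), (-150.0, 0.0))
        pre = out.data[0, 0, times < 0]
        post = out.data[0, 0, times >= 0]
        np.testing.assert_allclose(pre, 0.0, atol=1e-12)
        np.testing.assert_allclose(post, 7.0, atol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        ep = make_epochs(rng.standard_normal((3, 2, 256)))
        once = baseline_correct(ep)
        twice = baseline_correct(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-12)


class TestBinningAndVectorization:
    def test_860ms_epoch_gives_43_bins_and_301_features(self):
        n = int(np.ceil(860.0 * SFREQ / 1000.0))  # 441
        ep = make_epochs(np.zeros((2, 7, n)))
        binned = bin_epochs(ep, 20.0)
        assert binned.n_samples == 43
        fm = vectorize_features(binned, "whole-epoch")
        assert fm.X.shape[1] == 301
        fm1 = vectorize_features(binned, "single-interval", 0)
        assert fm1.X.shape[1] == 7

    def test_constant_signal_bins_to_constant(self):
        ep = make_epochs(np.full((1, 2, 441), 4.0))
        binned = bin_epochs(ep, 20.0)
        np.testing.assert_allclose(binned.data, 4.0, atol=1e-12)

    def test_bin_means_match_index_set_oracle(self):
        """Each bin mean equals the mean over the independently computed
        set of sample indices whose timestamps fall in the bin."""
        rng = np.random.default_rng(4)
        ep = make_epochs(rng.standard_normal((3, 2, 441)))
        binned = bin_epochs(ep, 20.0)
        starts = bin_starts(ep.times, SFREQ, 20.0)
        for k, s in enumerate(starts):
            idx = np.flatnonzero((ep.times >= s) & (ep.times < s + 20.0))
            assert len(idx) in (10, 11)  # 20 ms at 512 Hz
            np.testing.assert_allclose(
                binned.data[:, :, k], ep.data[:, :, idx].mean(axis=-1), atol=1e-12
            )

    def test_trailing_partial_bin_dropped(self):
        ep = make_epochs(np.zeros((1, 1, 256)))  # 500 ms
        binned = bin_epochs(ep, 20.0)
        assert binned.n_samples == 25

    def test_vectorize_roundtrip_channel_major(self):
        vals = np.arange(2 * 3 * 5, dtype=float).reshape(2, 3, 5)
        times = np.arange(5) * 20.0
        binned = EpochsSet(vals, times, 50.0, ["a", "b", "c"],
                           np.array(["S", "AD"], dtype=object),
                           info={"bin_width_ms": 20.0})
        fm = vectorize_features(binned, "whole-epoch")
        # channel-major ordering invertible through the column metadata
        rebuilt = np.empty_like(vals)
        for j in range(fm.X.shape[1]):
            ch = binned.channels.index(fm.columns["channel"][j])
            b = int(fm.columns["bin_start_ms"][j] / 20.0)
            rebuilt[:, ch, b] = fm.X[:, j]
        np.testing.assert_array_equal(rebuilt, vals)

    def test_interval_index_bounds(self):
        ep = make_epochs(np.zeros((1, 2, 441)))
        binned = bin_epochs(ep)
        with pytest.raises(ValueError, match="out of range"):
            vectorize_features(binned, "single-interval", 43)
        with pytest.raises(ValueError, match="requires interval_index"):
            vectorize_features(binned, "single-interval")

    def test_bin_width_below_sample_period_rejected(self):
        ep = make_epochs(np.zeros((1, 1, 441)))
        with pytest.raises(ValueError, match="sample period"):
            bin_epochs(ep, 0.5)


class TestStreamProperties:
    def test_streams_preserve_trial_order_and_labels(self, tiny_config):
        from caneeg.simulate import generate_subject

        ep = generate_subject(tiny_config, 0)
        erp_ep = erp_stream(ep)
        dec_ep = decoding_stream(ep)
        assert list(erp_ep.labels) == list(ep.labels)
        assert list(dec_ep.labels) == list(ep.labels)
        assert erp_ep.n_trials == ep.n_trials
        # decoding stream keeps every trial; ERP stream only flags
        assert dec_ep.kept.all()

    def test_pipeline_is_label_blind(self, tiny_config):
        """Applying the stream to label-permuted data equals permuting the
        labels of the output."""
        from caneeg.simulate import generate_subject

        ep = generate_subject(tiny_config, 1)
        rng = np.random.default_rng(0)
        perm = rng.permutation(ep.n_trials)
        ep_perm = EpochsSet(ep.data.copy(), ep.times, ep.sfreq, ep.channels,
                            ep.labels[perm], subject=ep.subject)
        out_a = decoding_stream(ep_perm)
        out_b = decoding_stream(ep)
        np.testing.assert_allclose(out_a.data, out_b.data, atol=1e-12)
        assert list(out_a.labels) == list(out_b.labels[perm])
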
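"""Preprocessing: filters, artifact excision, z-scoring, detection, binning."""

import numpy as np
import pandas as pd
import pytest

import avanet as an
from avanet.preprocess import (ContractError, InsufficientDataError,
                               ParameterError, SignalsEmptyError)

FS = 2000.0


def sine(freq, dur_s=4.0, fs=FS, amp=1.0):
    t = np.arange(int(dur_s * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestFilters:
    def test_notch_attenuates_line_frequency(self):
        sig = an.SignalRecording(data=sine(60.0)[None, :], fs_hz=FS)
        out = an.bandpass_and_notch(sig)
        mid = slice(2000, 6000)  # avoid filter edges
        assert np.abs(out.data[0, mid]).max() < 0.1  # > 20 dB down

    def test_passband_preserves_amplitude(self):
        sig = an.SignalRecording(data=sine(10.0)[None, :], fs_hz=FS)
        out = an.bandpass_and_notch(sig)
        mid = slice(2000, 6000)
        assert abs(np.abs(out.data[0, mid]).max() - 1.0) < 0.05

    def test_stopband_power_suppressed_on_white_noise(self):
        from scipy.signal import welch
        rng = np.random.default_rng(0)
        sig = an.SignalRecording(data=rng.normal(0, 1, (1, 40000)), fs_hz=FS)
        out = an.bandpass_and_notch(sig)
        f, p = welch(out.data[0], fs=FS, nperseg=4096)
        inband = p[(f > 5) & (f < 50)].mean()
        stop = p[f > 200].mean()
        assert stop < inband / 100  # > 20 dB

    def test_low_sampling_rate_rejected(self):
        sig = an.SignalRecording(data=np.zeros((1, 100)), fs_hz=150.0)
        with pytest.raises(ParameterError):
            an.bandpass_and_notch(sig)


class TestArtifactExcision:
    def test_clean_signal_leaves_mask_empty(self, rng):
        sig = an.SignalRecording(data=rng.normal(0, 1, (3, 8000)), fs_hz=FS)
        out = an.excise_artifacts(sig)
        assert not out.excluded_mask.any()

    def test_single_spike_masks_padded_window(self, rng):
        data = rng.normal(0, 1, (1, 8000))
        data[0, 4000] = 12.0
        out = an.excise_artifacts(an.SignalRecording(data=data, fs_hz=FS))
        pad = int(0.25 * FS)
        assert out.excluded_mask[4000 - pad:4000 + pad + 1].all()
        assert not out.excluded_mask[:4000 - pad - 10].any()

    def test_planted_artifact_fraction_recovered(self, rng):
        n = 200_000
        data = rng.normal(0, 1, (2, n))
        # plant brief 10-SD artifacts covering ~2% of samples
        n_art = 40
        width = int(0.02 * n / n_art)
        starts = rng.choice(n - width, n_art, replace=False)
        for s in starts:
            data[:, s:s + width] += 10.0
        out = an.excise_artifacts(an.SignalRecording(data=data, fs_hz=FS))
        frac = out.excluded_mask.mean()
        # planted fraction plus padding (0.5 s per artifact at most)
        upper = 0.02 + n_art * (2 * 0.25 * FS + width) / n
        assert 0.02 <= frac <= upper * 1.1

    def test_everything_excised_raises(self):
        data = np.random.default_rng(0).normal(0, 1, (1, 1000))
        data[0, ::100] = 1000.0  # huge spikes; padding covers everything
        sig = an.SignalRecording(data=data, fs_hz=FS)
        with pytest.raises(SignalsEmptyError):
            an.excise_artifacts(sig)


class TestZTransform:
    def test_normalizes_each_channel(self, rng):
        sig = an.SignalRecording(data=rng.normal(5, 3, (4, 5000)), fs_hz=FS)
        out = an.ztransform(sig)
        assert np.abs(out.data.mean(axis=1)).max() < 1e-10
        assert np.abs(out.data.std(axis=1) - 1).max() < 1e-10

    def test_affine_invariance(self, rng):
        x = rng.normal(0, 1, 5000)
        sig = an.SignalRecording(data=np.vstack([x, 7.5 * x - 3.0]), fs_hz=FS)
        out = an.ztransform(sig)
        np.testing.assert_allclose(out.data[0], out.data[1], atol=1e-10)

    def test_masked_samples_excluded_from_statistics(self, rng):
        x = rng.normal(0, 1, 5000)
        mask = np.zeros(5000, dtype=bool)
        mask[:1000] = True
        x[:1000] = 100.0  # masked garbage must not leak into mean/SD
        sig = an.SignalRecording(data=x[None, :], fs_hz=FS, excluded_mask=mask)
        out = an.ztransform(sig)
        keep = ~mask
        expect = (x[keep] - x[keep].mean()) / x[keep].std()
        np.testing.assert_allclose(out.data[0, keep], expect, atol=1e-10)

    def test_zero_variance_channel_dropped(self, rng):
        data = np.vstack([rng.normal(0, 1, 1000), np.full(1000, 2.0)])
        out = an.ztransform(an.SignalRecording(data=data, fs_hz=FS,
                                               channel_ids=["a", "b"]))
        assert out.channel_ids == ["a"]


def bump(center, width, depth, n=8000):
    x = np.zeros(n)
    t = np.arange(n)
    x -= depth * np.exp(-0.5 * ((t - center) / width) ** 2)
    return x


class TestDetection:
    def test_silent_signal_has_no_events(self):
        sig = an.SignalRecording(data=np.zeros((1, 1000)), fs_hz=FS)
        assert len(an.detect_nlfps(sig)) == 0

    def test_single_bump_detected_at_minimum(self, rng):
        x = rng.normal(0, 1, 8000) * 0.98
        x[3990:4010] = 0.0
        x += bump(4000, 4, 5.0)
        sig = an.SignalRecording(data=x[None, :], fs_hz=FS)
        ev = an.detect_nlfps(sig)
        strong = ev.events[ev.events.amplitude_sd < -4]
        assert len(strong) == 1
        assert abs(strong.time_ms.iloc[0] - 4000 / FS * 1000) < 1.0

    def test_two_bumps_with_suprathreshold_return_are_two_events(self):
        x = bump(2000, 10, 3.0) + bump(2100, 10, 3.0)
        x += np.random.default_rng(0).normal(0, 0.05, x.size)
        x = (x - x.mean()) / x.std()
        x = x / max(1.0, x.std())  # keep z-ish scale
        sig = an.SignalRecording(data=x[None, :], fs_hz=FS)
        ev = an.detect_nlfps(sig)
        deep = ev.events[ev.events.amplitude_sd < -5]
        assert len(deep) == 2

    def test_matches_brute_force_excursion_scan(self, rng):
        x = rng.normal(0, 1, 20_000)
        sig = an.SignalRecording(data=x[None, :], fs_hz=FS)
        ev = an.detect_nlfps(sig)
        # independent oracle: walk the trace sample by sample
        expected = []
        in_exc, best, best_i = False, 0.0, -1
        for i, v in enumerate(x):
            if v <= -2.0:
                if not in_exc or v < best:
                    best, best_i = v, i
                in_exc = True
            elif in_exc:
                expected.append(best_i)
                in_exc, best = False, 0.0
        if in_exc:
            expected.append(best_i)
        got = sorted(int(round(t / 1000 * FS)) for t in ev.events.time_ms)
        assert got == sorted(expected)

    def test_subthreshold_deflections_ignored(self, rng):
        x = rng.normal(0, 1, 8000)
        x = np.clip(x, -1.9, None)  # nothing reaches -2
        x = (x - x.mean()) / x.std()
        x = np.clip(x, -1.99, None)
        sig = an.SignalRecording(data=x[None, :], fs_hz=FS)
        assert len(an.detect_nlfps(sig)) == 0

    def test_raw_unscaled_input_rejected(self, rng):
        sig = an.SignalRecording(data=rng.normal(0, 40, (1, 4000)), fs_hz=FS)
        with pytest.raises(ContractError):
            an.detect_nlfps(sig)

    def test_events_in_masked_periods_discarded(self, rng):
        x = rng.normal(0, 1, 8000)
        x = (x - x.mean()) / x.std()
        mask = np.zeros(8000, dtype=bool)
        mask[:4000] = True
        sig = an.SignalRecording(data=x[None, :], fs_hz=FS, excluded_mask=mask)
        ev = an.detect_nlfps(sig)
        assert (ev.events.time_ms >= 4000 / FS * 1000).all()


def event_list(rows):
    return an.EventList(events=pd.DataFrame(
        rows, columns=["channel_id", "time_ms", "amplitude_sd"]))


class TestIEI:
    def test_pooled_mean_gap(self):
        ev = event_list([(0, 0.0, -3), (1, 2.0, -3), (0, 4.0, -3), (2, 6.0, -3)])
        assert an.mean_iei(ev) == pytest.approx(2.0)

    def test_single_event_is_an_error(self):
        with pytest.raises(InsufficientDataError):
            an.mean_iei(event_list([(0, 1.0, -3)]))

    def test_poisson_rate_gives_inverse_rate_iei(self, rng):
        lam = 0.8  # events per ms pooled
        t = np.cumsum(rng.exponential(1 / lam, 20_000))
        ev = event_list([(0, ti, -3.0) for ti in t])
        assert an.mean_iei(ev) == pytest.approx(1 / lam, rel=0.05)

    def test_iei_shrinks_with_rate(self, rng):
        ieis = []
        for lam in (0.2, 0.5, 1.0):
            t = np.cumsum(rng.exponential(1 / lam, 5000))
            ieis.append(an.mean_iei(event_list([(0, ti, -3.0) for ti in t])))
        assert ieis[0] > ieis[1] > ieis[2]


class TestBinning:
    def test_boundary_event_goes_to_later_bin(self):
        ev = event_list([(0, 2.0, -3)])
        raster = an.bin_events(ev, dt_ms=1.0)
        assert raster.counts[0, 2] == 1

    def test_total_events_conserved(self, rng):
        rows = [(int(c), float(t), -3.0)
                for c, t in zip(rng.integers(0, 5, 500),
                                rng.uniform(0, 100, 500))]
        ev = event_list(rows)
        raster = an.bin_events(ev, dt_ms=3.0)
        assert raster.total_events == 500

    def test_empty_list_gives_zero_raster(self):
        raster = an.bin_events(event_list([]), dt_ms=1.0, n_bins=10)
        assert raster.counts.sum() == 0


class TestCorrelationSummary:
    def test_duplicate_channel_has_unit_correlation(self, rng):
        x = rng.normal(0, 1, 2000)
        sig = an.SignalRecording(data=np.vstack([x, x, rng.normal(0, 1, 2000)]),
                                 fs_hz=FS)
        s = an.pairwise_correlation_summary([sig])
        assert s.r_matrices[0][0, 1] == pytest.approx(1.0)

    def test_orthogonal_sinusoids_uncorrelated(self):
        t = np.arange(4000) / FS
        sig = an.SignalRecording(
            data=np.vstack([np.sin(2 * np.pi * 10 * t),
                            np.cos(2 * np.pi * 10 * t)]), fs_hz=FS)
        s = an.pairwise_correlation_summary([sig])
        assert abs(s.r_matrices[0][0, 1]) < 0.01

    def test_stationary_sessions_have_flat_trend(self, rng):
        mixing = rng.normal(0, 1, (6, 3))
        sessions = []
        for _ in range(6):
            latent = rng.normal(0, 1, (3, 3000))
            data = mixing @ latent + rng.normal(0, 1, (6, 3000))
            sessions.append(an.SignalRecording(data=data, fs_hz=FS))
        s = an.pairwise_correlation_summary(sessions, days=[1, 4, 6, 9, 13, 20])
        assert s.trend.ci_contains(0.0)

    def test_single_channel_rejected(self, rng):
        sig = an.SignalRecording(data=rng.normal(0, 1, (1, 100)), fs_hz=FS)
        with pytest.raises(ParameterError):
            an.pairwise_correlation_summary([sig])

    def test_masked_samples_never_contribute(self, rng):
        data = rng.normal(0, 1, (3, 4000))
        mask = np.zeros(4000, dtype=bool)
        mask[1000:2000] = True
        data[:, 1000:2000] = 1e6
        sig = an.SignalRecording(data=data, fs_hz=FS, excluded_mask=mask)
        truncated = an.SignalRecording(
            data=np.delete(data, slice(1000, 2000), axis=1), fs_hz=FS)
        a = an.pairwise_correlation_summary([sig])
        b = an.pairwise_correlation_summary([truncated])
        np.testing.assert_allclose(a.r_matrices[0], b.r_matrices[0], atol=1e-12)
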
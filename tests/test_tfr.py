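"""Morlet TFR engine: frequency localization, flattening, baseline RPC,
evoked/induced modes, and the oscillation criterion."""

import numpy as np
import pytest

from epiosc.cohort import CohortConfig, EpochedRecording, InducedBurstSpec, generate_subject
from epiosc.tfr import (
    TFRMap,
    baseline_rpc,
    evoked_tfr,
    induced_tfr,
    morlet_power,
    oscillation_mask,
    spectral_flatten,
)

FS = 1000.0


def _sine_map(freq, n=1000, amp=1.0, frequencies=None):
    t = np.arange(n) / FS
    x = amp * np.sin(2 * np.pi * freq * t)
    if frequencies is None:
        frequencies = np.arange(10.0, 101.0)
    return morlet_power(x, FS, frequencies)


def _interior(tfr):
    return tfr.valid.all(axis=0)


class TestMorletPower:
    def test_sinusoid_ridge_at_its_frequency(self):
        tfr = _sine_map(40.0)
        cols = np.where(_interior(tfr))[0]
        ridge = tfr.frequencies[np.argmax(tfr.values[:, cols], axis=0)]
        assert np.all(np.abs(ridge - 40.0) <= 1.0)

    def test_zero_waveform_gives_zero_map(self):
        tfr = morlet_power(np.zeros(800), FS, np.arange(10.0, 101.0))
        assert not np.any(tfr.values)

    def test_two_tone_resolves_both_ridges(self):
        t = np.arange(1500) / FS
        x = np.sin(2 * np.pi * 20 * t) + np.sin(2 * np.pi * 80 * t)
        tfr = morlet_power(x, FS, np.arange(5.0, 101.0))
        col = np.where(_interior(tfr))[0][len(t) // 3]
        prof = tfr.values[:, col]
        lo = tfr.frequencies[np.argmax(prof * (tfr.frequencies < 50))]
        hi = tfr.frequencies[np.argmax(prof * (tfr.frequencies >= 50))]
        assert abs(lo - 20.0) <= 1.0 and abs(hi - 80.0) <= 1.0

    @pytest.mark.parametrize("freq", [20.0, 60.0, 90.0])
    def test_power_concentrates_within_wavelet_bandwidth(self, freq):
        # a 5-cycle wavelet has spectral SD f/5; >= 80% of the frequency
        # profile of a pure tone lies within +-2 bandwidths of the tone
        tfr = _sine_map(freq, n=2000)
        col = np.where(_interior(tfr))[0]
        prof = tfr.values[:, col].mean(axis=1)
        near = np.abs(tfr.frequencies - freq) <= 2.0 * freq / 5.0
        assert prof[near].sum() / prof.sum() >= 0.8

    @pytest.mark.parametrize("freq", [30.0, 70.0])
    def test_frequency_profile_matches_fft_oracle(self, freq):
        # the response of each wavelet to a pure tone equals the wavelet's
        # own power spectrum sampled at the tone frequency
        from scipy.signal.windows import gaussian  # noqa: F401  (doc anchor)

        tfr = _sine_map(freq, n=3000, frequencies=np.arange(10.0, 101.0))
        col = np.where(_interior(tfr))[0]
        prof = tfr.values[:, col].mean(axis=1)
        sigmas = 5.0 / (2 * np.pi * tfr.frequencies)
        oracle = np.empty_like(prof)
        for i, (fc, sig) in enumerate(zip(tfr.frequencies, sigmas)):
            h = int(np.ceil(3 * sig * FS))
            tt = np.arange(-h, h + 1) / FS
            w = np.exp(2j * np.pi * fc * tt) * np.exp(-(tt**2) / (2 * sig**2))
            w /= np.sqrt(np.sum(np.abs(w) ** 2))
            spec = np.fft.fft(w, 1 << 16)
            fgrid = np.fft.fftfreq(1 << 16, 1.0 / FS)
            k = np.argmin(np.abs(fgrid - freq))
            oracle[i] = np.abs(spec[k]) ** 2 / 4.0  # sine amplitude 1 -> A^2/4
        r = np.corrcoef(prof, oracle)[0, 1]
        assert r > 0.999
        np.testing.assert_allclose(prof, oracle, rtol=0.05, atol=1e-6 * oracle.max())

    def test_temporal_resolution_scales_inversely_with_frequency(self):
        # a transient's ridge FWHM shrinks as n_cycles/f: compare 20 vs 80 Hz
        def fwhm(freq):
            t = np.arange(1400) / FS
            x = np.exp(-((t - 0.7) ** 2) / (2 * 0.005**2)) * np.sin(2 * np.pi * freq * t)
            tfr = morlet_power(x, FS, np.array([freq]))
            row = tfr.values[0]
            half = row >= row.max() / 2
            return half.sum()

        assert fwhm(20.0) > 2.0 * fwhm(80.0)

    def test_nyquist_guard(self):
        with pytest.raises(ValueError, match="Nyquist"):
            morlet_power(np.zeros(500), FS, np.array([600.0]))

    def test_edge_mask_width_tracks_wavelet_support(self):
        tfr = _sine_map(40.0)
        i40 = np.where(tfr.frequencies == 40.0)[0][0]
        i90 = np.where(tfr.frequencies == 90.0)[0][0]
        assert (~tfr.valid[i40]).sum() > (~tfr.valid[i90]).sum()

    def test_matches_mne_ridge_locations(self):
        # independent cross-check against mne's Morlet implementation
        mne_tf = pytest.importorskip("mne.time_frequency")
        t = np.arange(1200) / FS
        x = np.sin(2 * np.pi * 35 * t) + 0.5 * np.sin(2 * np.pi * 70 * t)
        freqs = np.arange(20.0, 91.0)
        ours = morlet_power(x, FS, freqs)
        theirs = mne_tf.tfr_array_morlet(
            x[None, None, :], FS, freqs, n_cycles=5.0, output="power", zero_mean=False
        )[0, 0]
        cols = np.where(_interior(ours))[0]
        ridge_ours = np.argmax(ours.values[:, cols], axis=0)
        ridge_theirs = np.argmax(theirs[:, cols], axis=0)
        assert np.mean(np.abs(ridge_ours - ridge_theirs) <= 1) > 0.95


class TestSpectralFlatten:
    def _map(self, values, band=(1.0, 100.0)):
        f = np.arange(band[0], band[1] + 1)
        return TFRMap(frequencies=f, times=np.arange(values.shape[1], dtype=float),
                      values=values, band_range=band)

    def test_one_over_f_becomes_constant(self):
        f = np.arange(1.0, 101.0)
        values = (3.7 / f)[:, None] * np.ones((1, 50))
        flat = spectral_flatten(self._map(values))
        np.testing.assert_allclose(flat.values, 3.7, rtol=1e-12)

    def test_zero_stays_zero(self):
        flat = spectral_flatten(self._map(np.zeros((100, 10))))
        assert not np.any(flat.values)

    def test_double_flatten_refused(self):
        flat = spectral_flatten(self._map(np.ones((100, 10))))
        with pytest.raises(ValueError, match="already"):
            spectral_flatten(flat)

    def test_high_band_refused(self):
        f = np.arange(100.0, 251.0)
        m = TFRMap(frequencies=f, times=np.arange(10.0), values=np.ones((151, 10)),
                   band_range=(100.0, 250.0))
        with pytest.raises(ValueError, match="100 Hz"):
            spectral_flatten(m)


class TestBaselineRPC:
    def _map_with_baseline(self, post_factor):
        f = np.arange(10.0, 21.0)
        times = -200.0 + np.arange(701.0)
        values = np.ones((f.size, times.size))
        values[:, times > 0] = post_factor
        return TFRMap(frequencies=f, times=times, values=values)

    @pytest.mark.parametrize("factor,expected", [(1.0, 0.0), (2.0, 100.0), (0.5, -50.0)])
    def test_rpc_formula(self, factor, expected):
        rpc = baseline_rpc(self._map_with_baseline(factor))
        post = rpc.times > 0
        np.testing.assert_allclose(rpc.values[:, post], expected, atol=1e-9)
        np.testing.assert_allclose(rpc.values[:, ~post], 0.0, atol=1e-9)

    def test_double_correction_refused(self):
        rpc = baseline_rpc(self._map_with_baseline(2.0))
        with pytest.raises(ValueError, match="already"):
            baseline_rpc(rpc)

    def test_zero_baseline_refused(self):
        m = self._map_with_baseline(2.0)
        m.values[:, m.times <= 0] = 0.0
        with pytest.raises(ValueError, match="zero baseline"):
            baseline_rpc(m)

    def test_uncorrected_power_retained(self):
        m = self._map_with_baseline(2.0)
        rpc = baseline_rpc(m)
        np.testing.assert_array_equal(rpc.power, m.values)


class TestEvokedInduced:
    def test_evoked_recovers_phase_locked_burst_noiseless(self):
        # without noise the power ridge sits exactly on the planted burst
        # and the RPC there is strongly positive (off-ridge RPC is a ratio
        # of numerical dust and is not localizing in the noiseless limit)
        t = (-200.0 + np.arange(701)) / 1000.0
        sig = np.exp(-((t - 0.1) ** 2) / (2 * 0.025**2)) * np.cos(2 * np.pi * 40 * (t - 0.1))
        rec = EpochedRecording("s", "control", "MEG-like", FS,
                               -200.0 + np.arange(701.0), np.tile(sig, (5, 1)))
        ev = evoked_tfr(rec, "full")
        sel = ev.valid & (ev.times >= 10)[None, :]
        k = np.argmax(np.where(sel, ev.power, -np.inf))
        fi, ti = np.unravel_index(k, ev.power.shape)
        assert abs(ev.frequencies[fi] - 40.0) <= 1.0
        assert abs(ev.times[ti] - 100.0) <= 10.0
        assert ev.values[fi, ti] > 100.0  # far above baseline in RPC terms

    def test_induced_retains_random_phase_burst(self, burst_recording):
        ind = induced_tfr(burst_recording, "mid")
        sel = ind.valid & (ind.times >= 10)[None, :] & (ind.times <= 400)[None, :]
        k = np.argmax(np.where(sel, ind.values, -np.inf))
        fi, ti = np.unravel_index(k, ind.values.shape)
        assert abs(ind.frequencies[fi] - 40.0) <= 2.0
        assert abs(ind.times[ti] - 100.0) <= 25.0

    def test_random_phase_burst_attenuated_in_evoked_raw_power(self, burst_recording):
        # the classic dissociation, measured where it holds: uncorrected
        # wavelet power at the burst pixel drops ~n-fold under averaging
        ind = induced_tfr(burst_recording, "mid")
        ev = evoked_tfr(burst_recording, "full")
        fi_i = np.where(ind.frequencies == 40.0)[0][0]
        fi_e = np.where(ev.frequencies == 40.0)[0][0]
        ti = np.argmin(np.abs(ind.times - 100.0))
        # evoked power map is flattened like the induced one; same scale
        ratio = ind.power[fi_i, ti] / ev.power[fi_e, ti]
        assert ratio > 5.0

    def test_identical_trials_make_induced_equal_evoked(self, rng):
        trial = generate_subject(
            CohortConfig(n_control=1, n_patient=1, n_trials=1,
                         bursts=(InducedBurstSpec("NBG", 40.0, 100.0, 200.0, 1.0),),
                         noise_scale=0.3, seed=5),
            "control", 5).data[0]
        data = np.tile(trial, (10, 1))
        rec = EpochedRecording("s", "control", "MEG-like", FS,
                               -200.0 + np.arange(701.0), data)
        ind = induced_tfr(rec, "mid")
        ev = evoked_tfr(rec, "mid")
        np.testing.assert_allclose(ind.values, ev.values, atol=1e-9)

    def test_induced_trial_order_invariant(self, burst_recording):
        ind1 = induced_tfr(burst_recording, "mid")
        rec2 = EpochedRecording("s", "control", "MEG-like", FS,
                                burst_recording.times, burst_recording.data[::-1])
        ind2 = induced_tfr(rec2, "mid")
        np.testing.assert_allclose(ind1.values, ind2.values, rtol=1e-10)

    def test_modes_and_flags(self, burst_recording):
        ind = induced_tfr(burst_recording, "mid")
        assert ind.mode == "induced" and ind.flattened and ind.baseline_corrected
        hi = induced_tfr(burst_recording, "high")
        assert not hi.flattened  # 100-250 Hz left unadjusted
        ev = evoked_tfr(burst_recording, "full")
        assert ev.mode == "evoked" and ev.flattened


class TestOscillationMask:
    def _raw(self, post_amp):
        f = np.arange(30.0, 41.0)
        times = -200.0 + np.arange(701.0)
        values = np.ones((f.size, times.size))  # power 1 -> amplitude 1
        values[5, times > 50] = post_amp**2
        return TFRMap(frequencies=f, times=times, values=values)

    def test_background_level_is_below_threshold(self):
        mask = oscillation_mask(self._raw(1.0))
        assert not mask.any()

    def test_exactly_twice_background_included(self):
        mask = oscillation_mask(self._raw(2.0))
        assert mask[5, -1] and mask.sum() == np.sum(self._raw(2.0).times > 50)

    def test_strong_ridge_detected(self):
        mask = oscillation_mask(self._raw(3.0))
        assert mask[5][self._raw(3.0).times > 50].all()

    def test_missing_power_counterpart_rejected(self):
        m = self._raw(2.0)
        rpc = baseline_rpc(m)
        rpc.power = None
        with pytest.raises(ValueError, match="power"):
            oscillation_mask(rpc)
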
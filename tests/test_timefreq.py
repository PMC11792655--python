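"""Wavelet construction, induced-power extraction and ERS/ERD."""

import numpy as np
import pandas as pd
import pytest

from priomatch.erp import EpochArray
from priomatch.montage import CHANNELS
from priomatch.timefreq import (BANDS, build_wavelets, ers_erd,
                                remove_phase_locked, tf_power)

FS = 500.0


def _epochs(data, metadata=None, fs=FS, tmin=-500.0):
    chans = list(CHANNELS[: data.shape[1]])
    return EpochArray(data=data, fs=fs, tmin_ms=tmin, ch_names=chans,
                      metadata=metadata)


class TestWavelets:
    def test_sigma_t_follows_the_spectral_ratio(self):
        fam = build_wavelets(np.array([10.0]), ratio=5.0, fs=FS)
        # sigma_f = 2 Hz -> sigma_t = 1/(2 pi 2) ~ 0.0796 s
        assert fam.sigma_t[0] == pytest.approx(0.0796, abs=2e-4)

    def test_unit_energy(self):
        fam = build_wavelets(np.arange(2.0, 41.0, 6.0), fs=1000.0)
        for k in fam.kernels:
            energy = np.sum(np.abs(k) ** 2) / 1000.0
            assert energy == pytest.approx(1.0, abs=1e-3)

    def test_kernel_spectrum_peaks_at_f0(self):
        fam = build_wavelets(np.array([6.0, 14.0, 30.0]), fs=1000.0)
        for f0, k in zip(fam.freqs_hz, fam.kernels):
            spec = np.abs(np.fft.fft(k, 1 << 16))
            fax = np.fft.fftfreq(1 << 16, 1 / 1000.0)
            assert fax[np.argmax(spec)] == pytest.approx(f0, abs=0.2)

    def test_sigma_t_decreases_with_frequency(self):
        fam = build_wavelets(np.arange(1.0, 41.0), fs=1000.0)
        assert np.all(np.diff(fam.sigma_t) < 0)

    def test_nyquist_violation_raises(self):
        with pytest.raises(ValueError):
            build_wavelets(np.array([40.0]), fs=60.0)


class TestRemovePhaseLocked:
    def test_identical_trials_become_zero(self):
        md = pd.DataFrame({"label": ["self"] * 5, "match": ["match"] * 5})
        data = np.tile(np.random.default_rng(0).normal(size=(1, 4, 200)),
                       (5, 1, 1))
        out = remove_phase_locked(_epochs(data, md))
        assert np.allclose(out.data, 0.0)

    def test_condition_means_are_zero_after_subtraction(self):
        rng = np.random.default_rng(1)
        md = pd.DataFrame({"label": ["self", "friend"] * 10,
                           "match": ["match"] * 20})
        out = remove_phase_locked(_epochs(rng.normal(size=(20, 4, 100)), md))
        for lab in ("self", "friend"):
            idx = md.index[md["label"] == lab]
            assert np.allclose(out.data[idx].mean(axis=0), 0.0, atol=1e-12)

    def test_random_phase_power_survives_subtraction(self):
        """Non-phase-locked oscillation loses <5% power at 100+ trials."""
        rng = np.random.default_rng(2)
        t = np.arange(-500, 800) / 1000.0
        data = np.stack([[np.sin(2 * np.pi * 10 * t + rng.uniform(0, 2 * np.pi))]
                         for _ in range(120)])
        md = pd.DataFrame({"label": ["self"] * 120, "match": ["match"] * 120})
        ep = _epochs(data, md, fs=1000.0)
        out = remove_phase_locked(ep)
        assert np.mean(out.data ** 2) > 0.95 * np.mean(data ** 2)

    def test_singleton_condition_warns(self):
        md = pd.DataFrame({"label": ["self"], "match": ["match"]})
        with pytest.warns(UserWarning):
            remove_phase_locked(_epochs(np.ones((1, 4, 50)), md))


class TestTFPower:
    def test_pure_tone_peaks_at_its_frequency(self):
        t = np.arange(-500, 800) / 1000.0
        data = np.sin(2 * np.pi * 10 * t)[None, None, :] * np.ones((3, 2, 1))
        fam = build_wavelets(np.arange(2.0, 31.0), fs=1000.0)
        tfr = tf_power(_epochs(data, fs=1000.0), fam)
        mean_valid = np.array([
            tfr.power[:, :, i, tfr.valid[i]].mean() if tfr.valid[i].any()
            else -np.inf
            for i in range(len(fam.freqs_hz))])
        assert fam.freqs_hz[np.argmax(mean_valid)] == 10.0

    def test_white_noise_power_is_flat_over_time(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(40, 2, 650))
        fam = build_wavelets(np.array([12.0]), fs=FS)
        tfr = tf_power(_epochs(data), fam)
        p = tfr.power[:, :, 0, tfr.valid[0]].mean(axis=(0, 1))
        thirds = np.array_split(p, 3)
        means = [x.mean() for x in thirds]
        assert max(means) / min(means) < 1.3

    def test_amplitude_doubling_quadruples_power(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(2, 2, 650))
        fam = build_wavelets(np.array([10.0]), fs=FS)
        p1 = tf_power(_epochs(data), fam).power
        p2 = tf_power(_epochs(2 * data), fam).power
        assert np.allclose(p2, 4 * p1, rtol=1e-10)

    def test_band_limited_power_tracks_signal_variance(self):
        """Total wavelet power of a band-limited signal ~ its variance."""
        rng = np.random.default_rng(5)
        t = np.arange(-500, 1500) / 1000.0
        sig = sum(np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
                  for f in (9.0, 11.0, 13.0))
        data = sig[None, None, :] * np.ones((1, 1, 1))
        fam = build_wavelets(np.arange(5.0, 18.0), fs=1000.0)
        tfr = tf_power(_epochs(data, fs=1000.0), fam)
        centre = tfr.valid.all(axis=0)
        # the 1 Hz grid sum approximates the spectral integral; the complex
        # wavelet carries the analytic (positive-frequency) half of a real
        # signal's power, hence var/2
        total = tfr.power[0, 0][:, centre].mean(axis=1).sum()
        assert total == pytest.approx(np.var(sig) / 2.0, rel=0.10)

    def test_mne_morlet_agreement(self):
        """Power matches mne's Morlet TFR up to one global scale factor."""
        mne = pytest.importorskip("mne")
        from mne.time_frequency import tfr_array_morlet

        rng = np.random.default_rng(6)
        data = rng.normal(size=(5, 3, 1300))
        fam = build_wavelets(np.array([10.0]), fs=1000.0)
        ours = tf_power(_epochs(data, fs=1000.0), fam).power[:, :, 0, :]
        theirs = tfr_array_morlet(data, sfreq=1000.0, freqs=np.array([10.0]),
                                  n_cycles=5.0, output="power",
                                  zero_mean=False, verbose=False)[:, :, 0, :]
        sl = slice(300, 1000)
        ratio = ours[..., sl] / theirs[..., sl]
        assert ratio.std() / ratio.mean() < 1e-3


class TestERSERD:
    def _tfr(self, scale_post=1.0):
        t = np.arange(-500, 800) / 1000.0
        rng = np.random.default_rng(7)
        trials = []
        for _ in range(40):
            amp = np.where(t >= 0.2, np.sqrt(scale_post), 1.0)
            trials.append(amp * np.sin(2 * np.pi * 10 * t +
                                       rng.uniform(0, 2 * np.pi)))
        data = np.stack(trials)[:, None, :] * np.ones((1, 2, 1))
        fam = build_wavelets(np.array([10.0]), fs=1000.0)
        return tf_power(_epochs(data, fs=1000.0), fam)

    def _flat_tfr(self, post_scale):
        from priomatch.timefreq import TFR

        times = np.arange(-500.0, 800.0)
        power = np.ones((5, 2, 1, len(times)))
        power[..., times >= 0] = post_scale
        valid = np.ones((1, len(times)), dtype=bool)
        return TFR(power, np.array([10.0]), times, ["CZ", "FZ"], 1000.0, valid)

    def test_stationary_power_normalizes_to_exactly_zero(self):
        out = ers_erd(self._flat_tfr(1.0))
        assert np.allclose(out.power, 0.0)

    def test_doubled_power_reads_exactly_plus_one(self):
        out = ers_erd(self._flat_tfr(2.0))
        late = out.times_ms >= 0
        assert np.allclose(out.power[..., late], 1.0)

    def test_planted_30pct_drop_recovered(self):
        out = ers_erd(self._tfr(0.7))
        late = (out.times_ms >= 400) & (out.times_ms <= 700)
        assert out.power[:, :, 0, late].mean() == pytest.approx(-0.30,
                                                                abs=0.03)

    def test_invariant_to_global_scaling(self):
        tfr = self._tfr(0.7)
        scaled = type(tfr)(tfr.power * 25.0, tfr.freqs_hz, tfr.times_ms,
                           tfr.ch_names, tfr.fs, tfr.valid)
        a = ers_erd(tfr).power
        b = ers_erd(scaled).power
        assert np.allclose(a, b, rtol=1e-12)

    def test_erd_never_below_minus_one(self):
        out = ers_erd(self._tfr(0.7))
        assert out.power.min() >= -1.0

    def test_post_stimulus_baseline_raises(self):
        with pytest.raises(ValueError):
            ers_erd(self._tfr(1.0), baseline_ms=(100, 300))


def test_band_definitions_are_the_three_analysis_bands():
    assert BANDS == {"delta_theta": (2, 7), "alpha_low_beta": (8, 18),
                     "beta": (19, 29)}
    fam = build_wavelets(fs=1000.0)
    tfr_freqs = fam.freqs_hz
    idx = np.flatnonzero((tfr_freqs >= 8) & (tfr_freqs <= 18))
    assert list(tfr_freqs[idx]) == list(np.arange(8.0, 19.0))
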
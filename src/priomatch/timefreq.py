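"""Morlet wavelet time-frequency decomposition and ERS/ERD normalization.

The wavelet family is w(t, f0) = A exp(-t^2 / 2 sigma_t^2) exp(2 i pi f0 t)
with a constant spectral-width ratio f0 / sigma_f = 5 across a 1-40 Hz grid,
sigma_t = 1 / (2 pi sigma_f), and A = (sigma_t sqrt(pi))^(-1/2) so each
kernel has unit energy.  Instantaneous power is P(t) = Re[TF]^2 + Im[TF]^2;
event-related (de)synchronization is the fractional power change against the
pre-stimulus baseline: ERS/ERD = (P(t) - P0) / P0.

Phase-locked activity is removed before decomposition by subtracting each
condition's mean waveform from its member trials, so the power measures
induced (non-phase-locked) oscillations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .erp import EpochArray

RATIO_F0_SIGMA_F = 5.0
FREQ_GRID_HZ = np.arange(1.0, 41.0)
KERNEL_TRUNC_SD = 4.0

#: the three analysis bands (Hz, inclusive)
BANDS = {"delta_theta": (2, 7), "alpha_low_beta": (8, 18), "beta": (19, 29)}


@dataclass
class WaveletFamily:
    freqs_hz: np.ndarray
    sigma_t: np.ndarray         # s, per frequency
    kernels: list               # complex arrays, unit energy
    fs: float
    ratio: float = RATIO_F0_SIGMA_F


class TFR:
    """Time-frequency power: (trials, channels, freqs, times).

    ``valid`` is a (freqs, times) boolean mask, False within 2 sigma_t of the
    epoch edges where convolution power is edge-biased.
    """

    def __init__(self, power, freqs_hz, times_ms, ch_names, fs, valid,
                 metadata=None):
        self.power = power
        self.freqs_hz = np.asarray(freqs_hz, float)
        self.times_ms = np.asarray(times_ms, float)
        self.ch_names = list(ch_names)
        self.fs = fs
        self.valid = valid
        self.metadata = metadata

    def band_index(self, band) -> np.ndarray:
        lo, hi = BANDS[band] if isinstance(band, str) else band
        return np.flatnonzero((self.freqs_hz >= lo) & (self.freqs_hz <= hi))


def build_wavelets(freqs_hz=FREQ_GRID_HZ, ratio: float = RATIO_F0_SIGMA_F,
                   fs: float = 1000.0) -> WaveletFamily:
    """Discretized complex Morlet kernels, truncated at +-4 sigma_t."""
    freqs = np.atleast_1d(np.asarray(freqs_hz, float))
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be positive")
    if fs < 2.0 * freqs.max():
        raise ValueError(f"fs={fs} violates Nyquist for fmax={freqs.max()}")
    sigma_f = freqs / ratio
    sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
    kernels = []
    for f0, st in zip(freqs, sigma_t):
        half = int(np.ceil(KERNEL_TRUNC_SD * st * fs))
        t = np.arange(-half, half + 1) / fs
        amp = (st * np.sqrt(np.pi)) ** (-0.5)
        k = amp * np.exp(-t ** 2 / (2 * st ** 2)) * np.exp(2j * np.pi * f0 * t)
        kernels.append(k)
    return WaveletFamily(freqs_hz=freqs, sigma_t=sigma_t, kernels=kernels, fs=fs)


def remove_phase_locked(epochs: EpochArray, by=("label", "match")
                        ) -> EpochArray:
    """Subtract each condition's mean waveform from its member trials."""
    data = epochs.data.copy()
    if epochs.metadata is None:
        groups = {None: np.arange(len(data))}
    else:
        groups = {k: np.asarray(v) for k, v in
                  epochs.metadata.groupby(list(by), sort=True).groups.items()}
    for key, idx in groups.items():
        if len(idx) < 2:
            warnings.warn(f"condition {key}: single trial, subtraction "
                          "yields zeros", stacklevel=2)
        data[idx] -= data[idx].mean(axis=0, keepdims=True)
    return EpochArray(data, epochs.fs, epochs.tmin_ms, list(epochs.ch_names),
                      epochs.metadata)


def tf_power(epochs: EpochArray, family: WaveletFamily) -> TFR:
    """Per-trial instantaneous power by complex convolution.

    Samples within 2 sigma_t of the epoch edges are flagged invalid in
    ``TFR.valid`` (per frequency) rather than zero-padded away.
    """
    if family.fs != epochs.fs:
        raise ValueError("wavelet family and epochs have different fs")
    n_t = epochs.data.shape[2]
    longest = max(len(k) for k in family.kernels)
    if longest // 2 >= n_t:
        # the widest kernel support exceeds the epoch everywhere; power is
        # still defined, but no sample is edge-valid at that frequency
        pass
    n_f = len(family.freqs_hz)
    power = np.empty(epochs.data.shape[:2] + (n_f, n_t))
    valid = np.zeros((n_f, n_t), dtype=bool)
    dt = 1.0 / epochs.fs
    flat = epochs.data.reshape(-1, n_t)
    # FFT the signal once; each kernel is applied in the frequency domain
    from scipy.fft import fft, ifft, next_fast_len
    nfft = next_fast_len(n_t + longest - 1)
    sig_f = fft(flat, nfft, axis=1)
    for i, (k, st) in enumerate(zip(family.kernels, family.sigma_t)):
        kf = fft(k, nfft)
        conv = ifft(sig_f * kf[None, :], axis=1)
        # 'same' alignment: kernel is centered (odd length)
        start = (len(k) - 1) // 2
        tf = conv[:, start:start + n_t] * dt
        power[:, :, i, :] = (tf.real ** 2 + tf.imag ** 2).reshape(
            epochs.data.shape[0], epochs.data.shape[1], n_t)
        guard = int(np.ceil(2.0 * st * epochs.fs))
        if guard < n_t - guard:
            valid[i, guard:n_t - guard] = True
    return TFR(power=power, freqs_hz=family.freqs_hz,
               times_ms=epochs.times_ms, ch_names=epochs.ch_names,
               fs=epochs.fs, valid=valid, metadata=epochs.metadata)


def ers_erd(tfr: TFR, baseline_ms=(-300.0, -100.0), per_trial: bool = True
            ) -> TFR:
    """Baseline-normalize power: (P(t) - P0) / P0.

    P0 is the time-mean over the baseline window, computed per trial (then
    the normalized values can be trial-averaged) or on the trial-average
    power (``per_trial=False``).
    """
    b0, b1 = baseline_ms
    if b1 > 0:
        raise ValueError("baseline window must precede stimulus onset")
    tmask = (tfr.times_ms >= b0 - 1e-9) & (tfr.times_ms <= b1 + 1e-9)
    if not tmask.any():
        raise ValueError(f"baseline {baseline_ms} outside epoch")
    bad = ~tfr.valid[:, tmask].all(axis=1)
    if bad.any():
        warnings.warn(
            f"baseline window overlaps the edge-invalid region at "
            f"{int(bad.sum())} frequencies "
            f"({tfr.freqs_hz[bad].min():.0f}-{tfr.freqs_hz[bad].max():.0f} Hz)",
            stacklevel=2)
    power = tfr.power
    if not per_trial:
        power = power.mean(axis=0, keepdims=True)
    p0 = power[:, :, :, tmask].mean(axis=3, keepdims=True)
    if np.any(p0 <= 0):
        raise ValueError("zero baseline power; cannot normalize")
    norm = power / p0 - 1.0
    return TFR(power=norm, freqs_hz=tfr.freqs_hz, times_ms=tfr.times_ms,
               ch_names=tfr.ch_names, fs=tfr.fs, valid=tfr.valid,
               metadata=tfr.metadata if per_trial else None)


def band_power(tfr: TFR, band, window_ms=None, channels=None) -> np.ndarray:
    """Per-trial mean power over a band (and optional window / channels)."""
    fi = tfr.band_index(band)
    x = tfr.power[:, :, fi, :]
    if channels is not None:
        ci = [tfr.ch_names.index(c) for c in channels]
        x = x[:, ci]
    if window_ms is not None:
        w0, w1 = window_ms
        tmask = (tfr.times_ms >= w0 - 1e-9) & (tfr.times_ms <= w1 + 1e-9)
        x = x[..., tmask]
    return x.mean(axis=tuple(range(1, x.ndim)))
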
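"""Epoching, baseline correction, threshold artifact rejection, and ERP
component amplitude/latency extraction.

Component windows and electrode clusters follow the study's definitions
(frontal N1 100-150 ms at FCz/Fz/Cz; posterior N1 147-167 ms at TP7/T5;
P2 180-240 ms; N2 240-300 ms; P3 320-360 ms; LPP 500-700 ms).  Window
endpoints are inclusive at sample resolution.  Old temporal electrode names
(T3/T4/T5/T6) are resolved through the montage alias table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montage import resolve_cluster


@dataclass
class EpochArray:
    """Stimulus-locked EEG epochs: (n_trials, n_channels, n_times) in uV."""

    data: np.ndarray
    fs: float
    tmin_ms: float
    ch_names: list
    metadata: pd.DataFrame | None = None

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, times)")
        if self.data.shape[1] != len(self.ch_names):
            raise ValueError("channel-name count mismatch")
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel names must be unique")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.metadata is not None and len(self.metadata) != len(self.data):
            raise ValueError("metadata rows must match trials")

    @property
    def times_ms(self) -> np.ndarray:
        return self.tmin_ms + np.arange(self.data.shape[2]) * 1000.0 / self.fs

    def time_index(self, ms: float) -> int:
        return int(round((ms - self.tmin_ms) * self.fs / 1000.0))

    def window_slice(self, window_ms) -> slice:
        """Inclusive sample slice covering [w0, w1] ms."""
        w0, w1 = window_ms
        t = self.times_ms
        if w0 < t[0] - 1e-9 or w1 > t[-1] + 1e-9:
            raise ValueError(f"window {window_ms} outside epoch "
                             f"({t[0]:.0f}..{t[-1]:.0f} ms)")
        i0 = int(np.searchsorted(t, w0 - 1e-9))
        i1 = int(np.searchsorted(t, w1 + 1e-9))
        return slice(i0, i1)

    def channel_index(self, names) -> np.ndarray:
        resolved = resolve_cluster(names)
        have = {resolve_cluster([c])[0]: i for i, c in enumerate(self.ch_names)}
        missing = [n for n in resolved if n not in have]
        if missing:
            raise ValueError(f"channels not in epochs: {missing}")
        return np.array([have[n] for n in resolved])

    def select(self, idx) -> "EpochArray":
        md = self.metadata.iloc[idx].reset_index(drop=True) \
            if self.metadata is not None else None
        return EpochArray(self.data[idx], self.fs, self.tmin_ms,
                          list(self.ch_names), md)


@dataclass(frozen=True)
class ComponentDef:
    name: str
    window_ms: tuple
    cluster: tuple
    polarity: int  # +1 or -1


#: the six component definitions of the study
COMPONENT_REGISTRY = {
    "N1": ComponentDef("N1", (100, 150), ("FCZ", "FZ", "CZ"), -1),
    "posteriorN1": ComponentDef("posteriorN1", (147, 167), ("TP7", "T5"), -1),
    "P2": ComponentDef("P2", (180, 240),
                       ("FC3", "FC4", "FCZ", "C3", "C4", "CZ",
                        "CP3", "CP4", "CPZ"), +1),
    "N2": ComponentDef("N2", (240, 300),
                       ("P4", "PZ", "T4", "T6", "TP8", "C4", "CZ",
                        "CP4", "CPZ"), -1),
    "P3": ComponentDef("P3", (320, 360),
                       ("P3", "PZ", "TP7", "T5", "CP3", "O1", "O2", "OZ"), +1),
    "LPP": ComponentDef("LPP", (500, 700),
                        ("FZ", "FC3", "FC4", "FCZ", "C3", "C4", "CZ", "CPZ"),
                        +1),
}

#: latency peak search extends to the epoch end because the LPP peaks near
#: the upper edge of its amplitude window
LATENCY_SEARCH = {"LPP": (500, 800)}


def epoch_and_baseline(epochs: EpochArray, baseline_ms=(-200.0, 0.0)
                       ) -> EpochArray:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    sl = epochs.window_slice(baseline_ms)
    base = epochs.data[:, :, sl].mean(axis=2, keepdims=True)
    return EpochArray(epochs.data - base, epochs.fs, epochs.tmin_ms,
                      list(epochs.ch_names), epochs.metadata)


def reject_artifacts(epochs: EpochArray, threshold_uv: float = 70.0):
    """Drop trials exceeding +-threshold at any channel/timepoint.

    Returns (clean EpochArray, log DataFrame of surviving counts per
    condition).  Raises when every trial would be rejected.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    bad = np.abs(epochs.data).max(axis=(1, 2)) > threshold_uv
    if bad.all():
        peak = np.abs(epochs.data).max()
        raise ValueError(
            f"all {len(bad)} trials exceed +-{threshold_uv} uV "
            f"(max abs amplitude {peak:.1f} uV) - check scaling/baseline")
    clean = epochs.select(~bad)
    if epochs.metadata is not None and {"label", "match"} <= set(epochs.metadata):
        md = epochs.metadata.assign(_kept=~bad)
        log = md.groupby(["label", "match"])["_kept"].agg(
            n_total="size", n_kept="sum").reset_index()
    else:
        log = pd.DataFrame({"n_total": [len(bad)], "n_kept": [int((~bad).sum())]})
    return clean, log


def component_amplitude(epochs: EpochArray, cdef: ComponentDef,
                        by=("label", "match")) -> pd.DataFrame:
    """Mean amplitude over cluster channels, window samples and trials.

    One row per condition (grouping columns of the metadata given by ``by``);
    pass ``by=None`` for the grand mean over all trials.
    """
    ch = epochs.channel_index(cdef.cluster)
    sl = epochs.window_slice(cdef.window_ms)
    per_trial = epochs.data[:, ch, sl].mean(axis=(1, 2))
    if by is None or epochs.metadata is None:
        return pd.DataFrame({"component": [cdef.name],
                             "amplitude_uv": [per_trial.mean()],
                             "n_trials": [len(per_trial)]})
    md = epochs.metadata.copy()
    md["_amp"] = per_trial
    out = md.groupby(list(by), sort=True)["_amp"].agg(
        amplitude_uv="mean", n_trials="size").reset_index()
    out.insert(0, "component", cdef.name)
    return out


def peak_latency(waveform: np.ndarray, times_ms: np.ndarray,
                 window_ms, polarity: int) -> float:
    """Latency (ms) of the extremum of the stated polarity within a window.

    Ties resolve to the earliest sample; a flat signal returns the earliest
    sample with a warning.
    """
    import warnings

    t0, t1 = window_ms
    mask = (times_ms >= t0 - 1e-9) & (times_ms <= t1 + 1e-9)
    if not mask.any():
        raise ValueError(f"window {window_ms} outside waveform")
    w = waveform[mask] * polarity
    tt = times_ms[mask]
    if np.ptp(w) == 0:
        warnings.warn("flat waveform in latency window; returning earliest "
                      "sample", stacklevel=2)
        return float(tt[0])
    return float(tt[int(np.argmax(w))])


def condition_average(epochs: EpochArray, by=("label", "match")) -> dict:
    """Condition-mean waveforms: {condition tuple: (n_ch, n_t) array}."""
    if epochs.metadata is None:
        return {("all",): epochs.data.mean(axis=0)}
    out = {}
    for key, idx in epochs.metadata.groupby(list(by), sort=True).groups.items():
        key = key if isinstance(key, tuple) else (key,)
        out[key] = epochs.data[np.asarray(idx)].mean(axis=0)
    return out


def component_table(epochs: EpochArray, components=None,
                    by=("label", "match")) -> pd.DataFrame:
    """Tidy table of every component's amplitude per condition."""
    comps = components or COMPONENT_REGISTRY.values()
    return pd.concat([component_amplitude(epochs, c, by) for c in comps],
                     ignore_index=True)
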
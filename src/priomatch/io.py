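"""File I/O for pipeline artifacts: trial tables (TSV), epoch containers
(HDF5), generic tables, and schema validation with explicit error messages.

Behavioral files carry milliseconds; the DDM stage converts to seconds
internally (and only there), so the ms<->s conversion happens exactly once
at that boundary.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .erp import EpochArray

TRIAL_COLUMNS = ["subject", "label", "match", "response", "rt_ms",
                 "accuracy", "trial_index"]
_LABEL_VALUES = {"self", "friend", "stranger"}
_MATCH_VALUES = {"match", "nonmatch"}
_RESPONSE_VALUES = {"yes", "no", "none"}


class SchemaError(ValueError):
    pass


def validate_trials(trials: pd.DataFrame) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"trial table missing columns: {missing}")
    for col, allowed in (("label", _LABEL_VALUES), ("match", _MATCH_VALUES),
                         ("response", _RESPONSE_VALUES)):
        bad = ~trials[col].isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise SchemaError(
                f"column {col!r}: invalid value {trials[col].iloc[row]!r} "
                f"at row {row} (allowed: {sorted(allowed)})")
    responded = trials["response"] != "none"
    rts = trials.loc[responded, "rt_ms"]
    if rts.isna().any() or (rts <= 0).any():
        row = trials.index[responded][(rts.isna() | (rts <= 0)).to_numpy()][0]
        raise SchemaError(f"column 'rt_ms': nonpositive/missing RT at row {row}")


def write_trials(trials: pd.DataFrame, path) -> None:
    validate_trials(trials)
    trials.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_trials(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t")
    validate_trials(t)
    return t


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_epochs(epochs: EpochArray, path) -> None:
    """HDF5 container: data, fs, t0_offset_ms, channel names (+ metadata)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=epochs.data, compression="gzip",
                          compression_opts=1)
        fh.attrs["fs"] = epochs.fs
        fh.attrs["t0_offset_ms"] = epochs.tmin_ms
        fh.create_dataset("channels",
                          data=np.array(epochs.ch_names, dtype="S8"))
        if epochs.metadata is not None:
            fh.attrs["metadata_json"] = epochs.metadata.to_json(orient="split")


def read_epochs(path) -> EpochArray:
    with h5py.File(path, "r") as fh:
        data = fh["data"][()]
        fs = float(fh.attrs["fs"])
        tmin = float(fh.attrs["t0_offset_ms"])
        chans = [c.decode() for c in fh["channels"][()]]
        md = None
        if "metadata_json" in fh.attrs:
            from io import StringIO
            md = pd.read_json(StringIO(fh.attrs["metadata_json"]),
                              orient="split")
    return EpochArray(data=data, fs=fs, tmin_ms=tmin, ch_names=chans,
                      metadata=md)


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, default=_default))


def read_json(path):
    return json.loads(Path(path).read_text())
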
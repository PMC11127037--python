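"""Readers and writers for the package's on-disk containers.

Epochs live in a small HDF5 layout (datasets ``data``, ``time_ms``,
``labels``, ``repeat_flag``; root attributes ``sampling_rate`` and
optionally ``seed``); stimulus catalogs travel as JSON sidecars; tables as
CSV.  Datasets are written with ``track_times=False`` so that identical
arrays produce byte-identical files — the pipeline's reproducibility
contract checks artifact bytes, not just values.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preproc import EpochSet

__all__ = [
    "save_epochs",
    "load_epochs",
    "save_rdm_series",
    "load_rdm_series",
    "rdm_square_csv",
    "save_config",
    "write_csv",
    "write_json",
]

_H5_OPTS = dict(track_times=False)


def save_epochs(path, epochs: EpochSet, seed: int | None = None) -> None:
    with h5py.File(path, "w", track_order=False) as f:
        f.create_dataset("data", data=epochs.data, **_H5_OPTS)
        f.create_dataset("time_ms", data=epochs.time_ms, **_H5_OPTS)
        f.create_dataset("labels", data=epochs.labels, **_H5_OPTS)
        f.create_dataset("repeat_flag", data=epochs.repeat_flag, **_H5_OPTS)
        f.attrs["sampling_rate"] = float(epochs.sampling_rate)
        if seed is not None:
            f.attrs["seed"] = int(seed)


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()],
            time_ms=f["time_ms"][()],
            labels=f["labels"][()],
            repeat_flag=f["repeat_flag"][()].astype(bool),
            sampling_rate=float(f.attrs["sampling_rate"]),
        )


def save_rdm_series(path, rdm) -> None:
    """Write an RDM series (values, time axis, pair table) to HDF5."""
    with h5py.File(path, "w", track_order=False) as f:
        f.create_dataset("values", data=rdm.values, **_H5_OPTS)
        f.create_dataset("time_ms", data=rdm.time_ms, **_H5_OPTS)
        f.create_dataset("pairs", data=rdm.pair_index.pairs, **_H5_OPTS)
        f.create_dataset(
            "stimulus_ids", data=np.asarray(rdm.pair_index.stimulus_ids), **_H5_OPTS
        )
        f.attrs["n_folds"] = rdm.n_folds
        f.attrs["n_repetitions"] = rdm.n_repetitions
        f.attrs["subset"] = rdm.subset


def load_rdm_series(path):
    from .rdm import PairIndex, RDMSeries

    with h5py.File(path, "r") as f:
        return RDMSeries(
            values=f["values"][()],
            time_ms=f["time_ms"][()],
            pair_index=PairIndex(tuple(int(s) for s in f["stimulus_ids"][()])),
            n_folds=int(f.attrs["n_folds"]),
            n_repetitions=int(f.attrs["n_repetitions"]),
            subset=str(f.attrs["subset"]),
        )


def rdm_square_csv(path, rdm, time_index: int) -> None:
    """Export one timepoint of an RDM series as a square dissimilarity matrix."""
    ids = list(rdm.pair_index.stimulus_ids)
    frame = pd.DataFrame(rdm.square_matrix(time_index), index=ids, columns=ids)
    frame.index.name = "stimulus_id"
    frame.to_csv(path, float_format="%.10g", lineterminator="\n")


def save_config(path, config) -> None:
    """Dump a simulation config as YAML (arrays summarized by shape/seed)."""
    import yaml

    Path(path).write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True, default_flow_style=False)
    )


def write_csv(path, frame: pd.DataFrame) -> None:
    """Deterministic CSV: fixed float format, no index, LF endings."""
    frame.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def write_json(path, obj) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")
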
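"""Serialization: HDF5 containers for recordings and feature matrices,
JSON/TSV exports for results."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .cohort import EpochedRecording
from .features import FeatureMatrix

__all__ = [
    "save_recording",
    "load_recording",
    "save_feature_matrix",
    "load_feature_matrix",
    "results_json",
    "connectivity_long_table",
    "mse_long_table",
]


def save_recording(rec: EpochedRecording, path: str | Path) -> None:
    """One recording per file: dataset ``data`` (epochs x channels x samples,
    float32) with descriptive attributes."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=rec.data.astype(np.float32))
        d.attrs["sampling_rate"] = rec.sampling_rate
        d.attrs["channel_labels"] = list(rec.channel_labels)
        d.attrs["group"] = rec.group
        d.attrs["session"] = rec.session
        d.attrs["state"] = rec.state
        d.attrs["age"] = rec.age
        d.attrs["participant_id"] = rec.participant_id


def load_recording(path: str | Path) -> EpochedRecording:
    with h5py.File(path, "r") as f:
        d = f["data"]
        rec = EpochedRecording(
            participant_id=str(d.attrs["participant_id"]),
            group=str(d.attrs["group"]),
            session=str(d.attrs["session"]),
            state=str(d.attrs["state"]),
            age=float(d.attrs["age"]),
            data=np.asarray(d, dtype=float),
            sampling_rate=float(d.attrs["sampling_rate"]),
            channel_labels=tuple(str(c) for c in d.attrs["channel_labels"]),
        )
    rec.validate()
    return rec


def save_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=fm.values)
        f.attrs["provenance"] = fm.provenance
        f.attrs["rows"] = fm.rows.to_json(orient="split")
        f.attrs["cols"] = fm.cols.to_json(orient="split")


def load_feature_matrix(path: str | Path) -> FeatureMatrix:
    import io as _io
    with h5py.File(path, "r") as f:
        values = np.asarray(f["values"])
        rows = pd.read_json(_io.StringIO(str(f.attrs["rows"])), orient="split")
        cols = pd.read_json(_io.StringIO(str(f.attrs["cols"])), orient="split")
        prov = str(f.attrs["provenance"])
    return FeatureMatrix(values, rows, cols, prov)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def results_json(results: dict) -> str:
    """Deterministic JSON (sorted keys) so identical runs are byte-identical."""
    return json.dumps(_jsonify(results), sort_keys=True, indent=1)


def connectivity_long_table(cm) -> pd.DataFrame:
    """Long-format export of a ConnectivityMatrix."""
    rows = []
    for fi, f in enumerate(cm.grid.freqs):
        for pi, (a, b) in enumerate(cm.pairs):
            rows.append({**{k: v for k, v in cm.meta.items()},
                         "frequency": f, "channel_a": a, "channel_b": b,
                         "wpli": cm.values[fi, pi]})
    return pd.DataFrame(rows)


def mse_long_table(mm) -> pd.DataFrame:
    """Long-format export of an MSEMatrix."""
    rows = []
    for ci, ch in enumerate(mm.channel_labels):
        for si, sc in enumerate(mm.scales):
            rows.append({**{k: v for k, v in mm.meta.items()},
                         "channel": ch, "scale": int(sc),
                         "sampen": mm.values[ci, si]})
    return pd.DataFrame(rows)
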
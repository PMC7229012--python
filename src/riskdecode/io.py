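"""File round-trips: CSV trial tables, HDF5 recordings/epochs, JSON models.

The HDF5 layout keeps one dataset per array plus attribute scalars;
annotation and metadata tables are stored column-wise with UTF-8 string
columns.  Classifier models and channel selections serialise to JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .classifier import ClassifierModel
from .dynamics import ProbSeries
from .preprocessing import ChannelSelection, EpochSet
from .sensors import GroundTruth, SensorRecording
from .task import BehaviourPolicy, TaskConfig


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path):
    """Read a JSON file holding task / policy (and optional sensor) configs."""
    with open(path) as fh:
        raw = json.load(fh)
    cfg = TaskConfig(**raw.get("task", {}))
    policy = BehaviourPolicy(**raw.get("policy", {}))
    return cfg, policy, raw.get("sensors", {})


def _write_frame(group: h5py.Group, name: str, df: pd.DataFrame) -> None:
    g = group.create_group(name)
    g.attrs["columns"] = list(df.columns)
    for col in df.columns:
        values = df[col].to_numpy()
        if values.dtype == object or values.dtype.kind in "US":
            g.create_dataset(col, data=np.asarray(values, dtype="S32"))
        else:
            g.create_dataset(col, data=values)


def _read_frame(group: h5py.Group, name: str) -> pd.DataFrame:
    g = group[name]
    data = {}
    for col in g.attrs["columns"]:
        values = g[col][()]
        if values.dtype.kind == "S":
            values = np.char.decode(values, "utf-8")
        data[col] = values
    return pd.DataFrame(data)


def write_recording(rec: SensorRecording, path, truth: GroundTruth | None = None) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=rec.data)
        fh.attrs["fs"] = rec.fs
        _write_frame(fh, "annotations", rec.annotations)
        if truth is not None:
            g = fh.create_group("ground_truth")
            _write_frame(g, "schedule", truth.schedule)
            _write_frame(g, "blinks", truth.blinks)
            g.create_dataset("pattern_P", data=truth.pattern_P)
            g.create_dataset("pattern_N", data=truth.pattern_N)
            g.create_dataset("blink_channels", data=truth.blink_channels)
            g.attrs["evoked_amplitude"] = truth.evoked_amplitude
            g.attrs["delib_amplitude"] = truth.delib_amplitude


def read_recording(path):
    with h5py.File(path, "r") as fh:
        rec = SensorRecording(
            data=fh["data"][()],
            fs=float(fh.attrs["fs"]),
            annotations=_read_frame(fh, "annotations"),
        )
        truth = None
        if "ground_truth" in fh:
            g = fh["ground_truth"]
            truth = GroundTruth(
                schedule=_read_frame(g, "schedule"),
                blinks=_read_frame(g, "blinks"),
                pattern_P=g["pattern_P"][()],
                pattern_N=g["pattern_N"][()],
                blink_channels=g["blink_channels"][()],
                evoked_amplitude=float(g.attrs["evoked_amplitude"]),
                delib_amplitude=float(g.attrs["delib_amplitude"]),
            )
    return rec, truth


def write_epochs(epochs: EpochSet, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=epochs.data)
        fh.attrs["kind"] = epochs.kind
        fh.attrs["fs"] = epochs.fs
        fh.attrs["bin_width_ms"] = epochs.bin_width_ms
        fh.attrs["window_ms"] = epochs.window_ms
        if epochs.channels is not None:
            fh.create_dataset("channels", data=epochs.channels)
        _write_frame(fh, "meta", epochs.meta)


def read_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as fh:
        meta = _read_frame(fh, "meta")
        meta["loss_magnitude"] = meta["loss_magnitude"].astype(int)
        return EpochSet(
            kind=str(fh.attrs["kind"]),
            data=fh["data"][()],
            fs=float(fh.attrs["fs"]),
            bin_width_ms=float(fh.attrs["bin_width_ms"]),
            window_ms=tuple(fh.attrs["window_ms"]),
            meta=meta,
            channels=fh["channels"][()] if "channels" in fh else None,
        )


def write_series(series: ProbSeries, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("values", data=series.values)
        fh.attrs["kind"] = series.kind
        fh.attrs["contrast"] = series.contrast
        fh.attrs["bin_width_ms"] = series.bin_width_ms
        fh.attrs["participant_id"] = series.participant_id
        _write_frame(fh, "meta", series.meta)


def read_series(path) -> ProbSeries:
    with h5py.File(path, "r") as fh:
        return ProbSeries(
            values=fh["values"][()],
            kind=str(fh.attrs["kind"]),
            contrast=str(fh.attrs["contrast"]),
            bin_width_ms=float(fh.attrs["bin_width_ms"]),
            participant_id=int(fh.attrs["participant_id"]),
            meta=_read_frame(fh, "meta"),
        )


def model_to_dict(model: ClassifierModel) -> dict:
    d = dataclasses.asdict(model)
    d["weights"] = model.weights.tolist()
    return d


def model_from_dict(d: dict) -> ClassifierModel:
    return ClassifierModel(
        weights=np.asarray(d["weights"], float),
        intercept=d["intercept"],
        lam=d["lam"],
        train_bin=d.get("train_bin"),
        contrast=d.get("contrast", "P_vs_N"),
        label_permutation_id=d.get("label_permutation_id"),
    )


def write_models(suite: dict, path) -> None:
    """Serialise a classifier suite (contrast -> model + permuted list)."""
    payload = {
        contrast: {
            "model": model_to_dict(entry["model"]),
            "permuted": [model_to_dict(m) for m in entry["permuted"]],
        }
        for contrast, entry in suite.items()
        if contrast != "training_counts"
    }
    payload["training_counts"] = suite.get("training_counts")
    Path(path).write_text(json.dumps(payload))


def read_models(path) -> dict:
    payload = json.loads(Path(path).read_text())
    suite = {
        contrast: {
            "model": model_from_dict(entry["model"]),
            "permuted": [model_from_dict(d) for d in entry["permuted"]],
        }
        for contrast, entry in payload.items()
        if contrast != "training_counts"
    }
    suite["training_counts"] = payload.get("training_counts")
    return suite


def write_selection(selection: ChannelSelection, path) -> None:
    Path(path).write_text(
        json.dumps({"retained": selection.retained.tolist(), "scores": selection.scores.tolist()})
    )


def read_selection(path) -> ChannelSelection:
    d = json.loads(Path(path).read_text())
    return ChannelSelection(retained=np.asarray(d["retained"]), scores=np.asarray(d["scores"]))
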
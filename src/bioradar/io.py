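"""File formats: HDF5 measurements, CSV tables, JSON models, YAML config."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import FCCWMeasurement
from .ranging import RangeSubSignal
from .svm import LinearSVMModel


def save_measurement(path, m: FCCWMeasurement) -> None:
    """Write one measurement: dataset `tones` (complex64) + scalar attributes."""
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("tones", data=np.asarray(m.tones, dtype=np.complex64))
        d.attrs["fs"] = m.fs
        d.attrs["T_meas"] = m.T_meas
        d.attrs["label"] = m.label
        for key in ("measurement_id", "body_position", "seed"):
            val = m.metadata.get(key)
            if val is not None:
                d.attrs[key] = val.item() if isinstance(val, np.generic) else val


def load_measurement(path) -> FCCWMeasurement:
    import h5py

    with h5py.File(path, "r") as f:
        d = f["tones"]
        meta = {
            key: (v.item() if hasattr(v := d.attrs[key], "item") else v)
            for key in d.attrs
            if key not in ("fs", "T_meas", "label")
        }
        return FCCWMeasurement(
            tones=d[...],
            fs=float(d.attrs["fs"]),
            T_meas=float(d.attrs["T_meas"]),
            label=str(d.attrs["label"]),
            metadata=meta,
        )


def save_subsignal(path, s: RangeSubSignal) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("series", data=np.asarray(s.series, dtype=np.complex64))
        d.attrs["range_index"] = s.range_index
        d.attrs["fs"] = s.fs
        d.attrs["T_meas"] = s.T_meas
        d.attrs["filtered"] = s.filtered
        if s.parent_id is not None:
            d.attrs["parent_id"] = s.parent_id
        if s.label is not None:
            d.attrs["label"] = s.label


def load_subsignal(path) -> RangeSubSignal:
    import h5py

    with h5py.File(path, "r") as f:
        d = f["series"]
        return RangeSubSignal(
            range_index=int(d.attrs["range_index"]),
            series=d[...].astype(complex),
            fs=float(d.attrs["fs"]),
            T_meas=float(d.attrs["T_meas"]),
            filtered=bool(d.attrs["filtered"]),
            parent_id=str(d.attrs["parent_id"]) if "parent_id" in d.attrs else None,
            label=str(d.attrs["label"]) if "label" in d.attrs else None,
        )


def save_features(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def load_features(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_model(path, model: LinearSVMModel) -> None:
    payload = {
        "feature_names": model.feature_names,
        "mu": model.mu.tolist(),
        "sigma": model.sigma.tolist(),
        "beta": model.beta.tolist(),
        "s": model.s,
        "b": model.b,
        "positive_convention": model.positive_convention,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_model(path) -> LinearSVMModel:
    payload = json.loads(Path(path).read_text())
    return LinearSVMModel(
        feature_names=payload["feature_names"],
        mu=np.array(payload["mu"]),
        sigma=np.array(payload["sigma"]),
        beta=np.array(payload["beta"]),
        s=payload["s"],
        b=payload["b"],
        positive_convention=payload.get("positive_convention", "f(x) < 0 => with_person"),
    )


def load_config(path) -> dict:
    import yaml

    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg
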
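"""Persistence: HDF5 arrays with JSON-sidecar metadata, CSV geometry export."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .bands import BandDefinition
from .synthetic import Conductor, Coupling, EpochSet, SourceModel

__all__ = [
    "save_epochset",
    "load_epochset",
    "save_source_model",
    "load_source_model",
    "geometry_to_csv",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_epochset(epochs: EpochSet, path: str | Path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip")
    _sidecar(path).write_text(
        json.dumps({"fs": epochs.fs, "condition_tag": epochs.condition_tag,
                    "kind": "EpochSet"}, indent=2)
    )


def load_epochset(path: str | Path) -> EpochSet:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    if meta.get("kind") != "EpochSet":
        raise ValueError(f"{path} sidecar does not describe an EpochSet")
    with h5py.File(path, "r") as f:
        data = f["data"][...]
    return EpochSet(data=data, fs=meta["fs"], condition_tag=meta["condition_tag"])


def save_source_model(model: SourceModel, path: str | Path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("positions", data=model.positions)
        f.create_dataset("orientations", data=model.orientations)
        f.create_dataset("roi_labels", data=model.roi_labels)
        f.create_dataset("series", data=model.series, compression="gzip")
    meta = {
        "kind": "SourceModel",
        "fs": model.fs,
        "bands": [[b.name, b.f_low, b.f_high] for b in model.band_defs],
        "coupling": [asdict(c) for c in model.coupling],
        "conductor": {"center": list(model.conductor.center),
                      "radius": model.conductor.radius},
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def load_source_model(path: str | Path) -> SourceModel:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    if meta.get("kind") != "SourceModel":
        raise ValueError(f"{path} sidecar does not describe a SourceModel")
    with h5py.File(path, "r") as f:
        arrays = {k: f[k][...] for k in ("positions", "orientations",
                                          "roi_labels", "series")}
    return SourceModel(
        positions=arrays["positions"],
        orientations=arrays["orientations"],
        roi_labels=arrays["roi_labels"],
        series=arrays["series"],
        fs=meta["fs"],
        coupling=tuple(Coupling(**c) for c in meta["coupling"]),
        band_defs=tuple(BandDefinition(*b) for b in meta["bands"]),
        conductor=Conductor(center=tuple(meta["conductor"]["center"]),
                            radius=meta["conductor"]["radius"]),
    )


def geometry_to_csv(model: SourceModel, path: str | Path) -> None:
    """Voxel geometry as CSV: voxel, roi, x, y, z, ox, oy, oz."""
    df = pd.DataFrame(
        {
            "voxel": np.arange(model.n_voxels),
            "roi": model.roi_labels,
            "x": model.positions[:, 0],
            "y": model.positions[:, 1],
            "z": model.positions[:, 2],
            "ox": model.orientations[:, 0],
            "oy": model.orientations[:, 1],
            "oz": model.orientations[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")
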
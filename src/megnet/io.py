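"""Serialization: HDF5 recording containers, TSV tables, JSON results.

The recording container is self-describing: epoch data plus sampling
rate, epoch length and full channel geometry, so any stage can be rerun
from disk without the upstream objects.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .connectivity import ConnectivityNetwork
from .geometry import SensorArray
from .preprocessing import EpochedRecording, MarkerList
from .spectral import FrequencyBand

__all__ = [
    "save_recording",
    "load_recording",
    "save_network",
    "load_network",
    "read_markers_tsv",
    "write_markers_tsv",
    "save_json",
    "load_json",
    "network_edge_table",
]


def save_recording(path, rec: EpochedRecording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data, track_times=False)
        f.attrs["fs"] = rec.fs
        f.attrs["epoch_length_s"] = rec.epoch_length_s
        g = f.create_group("channels")
        g.create_dataset("positions", data=rec.sensors.positions, track_times=False)
        g.create_dataset("orientations", data=rec.sensors.orientations, track_times=False)
        g.create_dataset(
            "names",
            data=np.array(rec.sensors.names, dtype=h5py.string_dtype()),
            track_times=False,
        )


def load_recording(path) -> EpochedRecording:
    with h5py.File(path, "r") as f:
        sensors = SensorArray(
            positions=f["channels/positions"][()],
            orientations=f["channels/orientations"][()],
            names=tuple(n.decode() for n in f["channels/names"][()]),
        )
        return EpochedRecording(
            data=f["data"][()],
            fs=float(f.attrs["fs"]),
            sensors=sensors,
            epoch_length_s=float(f.attrs["epoch_length_s"]),
        )


def save_network(path, net: ConnectivityNetwork) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("adjacency", data=net.adjacency, track_times=False)
        f.attrs["resolution"] = net.resolution
        if net.band is not None:
            f.attrs["band_name"] = net.band.name
            f.attrs["band_center"] = net.band.center
            f.attrs["band_halfwidth"] = net.band.halfwidth
        if net.subject_id is not None:
            f.attrs["subject_id"] = net.subject_id
        f.create_dataset(
            "node_labels",
            data=np.array(net.node_labels, dtype=h5py.string_dtype()),
            track_times=False,
        )
        if net.node_positions is not None:
            f.create_dataset("node_positions", data=net.node_positions, track_times=False)


def load_network(path) -> ConnectivityNetwork:
    with h5py.File(path, "r") as f:
        band = None
        if "band_name" in f.attrs:
            band = FrequencyBand(
                name=str(f.attrs["band_name"]),
                center=float(f.attrs["band_center"]),
                halfwidth=float(f.attrs["band_halfwidth"]),
            )
        return ConnectivityNetwork(
            adjacency=f["adjacency"][()],
            resolution=str(f.attrs["resolution"]),
            node_labels=tuple(n.decode() for n in f["node_labels"][()]),
            band=band,
            subject_id=str(f.attrs["subject_id"]) if "subject_id" in f.attrs else None,
            node_positions=f["node_positions"][()] if "node_positions" in f else None,
        )


def read_markers_tsv(path) -> MarkerList:
    """Markers from a two-column TSV (time_s, label)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["time_s", "label"],
                     comment="#")
    label = str(df["label"].iloc[0]) if len(df) else "event"
    return MarkerList(times=df["time_s"].to_numpy(dtype=float), label=label)


def write_markers_tsv(path, markers: MarkerList) -> None:
    pd.DataFrame({"time_s": markers.times,
                  "label": [markers.label] * len(markers.times)}
                 ).to_csv(path, sep="\t", header=False, index=False)


def network_edge_table(net: ConnectivityNetwork) -> pd.DataFrame:
    """Upper-triangle edge list (node_a, node_b, weight)."""
    n = net.n_nodes
    iu = np.triu_indices(n, k=1)
    return pd.DataFrame({
        "node_a": [net.node_labels[i] for i in iu[0]],
        "node_b": [net.node_labels[j] for j in iu[1]],
        "weight": net.adjacency[iu],
    })


def save_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_coerce))


def load_json(path):
    return json.loads(Path(path).read_text())


def _coerce(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
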
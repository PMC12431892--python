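"""Readers and writers for the pipeline's on-disk formats.

Continuous EEG comes in as EDF or FIF (through MNE) or as a plain HDF5
matrix (data + sfreq + positions + events).  Intermediate artifacts use
HDF5 (epochs, peak sets) and CSV (maps, segmentations, marker tables);
ground truth and QC reports are JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .data import EpochedEEG, MapSet, PeakSet, RawEEG, Segmentation, SensorLayout

__all__ = [
    "read_raw",
    "write_raw_h5",
    "read_epochs_h5",
    "write_epochs_h5",
    "read_peaks_h5",
    "write_peaks_h5",
    "read_maps_csv",
    "write_maps_csv",
    "read_segmentation_csv",
    "write_segmentation_csv",
    "write_json",
]


def _layout_to_group(g: h5py.Group, layout: SensorLayout) -> None:
    g.create_dataset("ch_names",
                     data=np.array(layout.ch_names, dtype=h5py.string_dtype()))
    g.create_dataset("positions", data=layout.positions)
    g.create_dataset("edge_flags", data=layout.edge_flags)


def _layout_from_group(g: h5py.Group) -> SensorLayout:
    names = [n.decode() if isinstance(n, bytes) else str(n)
             for n in g["ch_names"][()]]
    return SensorLayout(names, g["positions"][()], g["edge_flags"][()])


def write_raw_h5(path, raw: RawEEG) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=raw.data)
        f.attrs["sfreq"] = raw.sfreq
        f.create_dataset("events", data=raw.events)
        _layout_to_group(f.create_group("layout"), raw.layout)


def _read_raw_h5(path) -> RawEEG:
    with h5py.File(path, "r") as f:
        return RawEEG(f["data"][()], float(f.attrs["sfreq"]),
                      _layout_from_group(f["layout"]), f["events"][()])


def _read_raw_mne(path, fmt: str) -> RawEEG:
    import mne

    if fmt == "edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raw = mne.io.read_raw_fif(path, preload=True, verbose="error")
    raw.pick("eeg")
    data = raw.get_data() * 1e6  # volts -> microvolts
    pos3 = np.array([raw.info["chs"][i]["loc"][:3]
                     for i in range(len(raw.ch_names))])
    if np.allclose(pos3, 0):
        # no montage: spread sensors on a circle so the layout is valid
        theta = np.linspace(0, 2 * np.pi, len(raw.ch_names), endpoint=False)
        pos = np.column_stack([np.cos(theta), np.sin(theta)])
    else:
        pos = pos3[:, :2]  # head-plane projection
    layout = SensorLayout(list(raw.ch_names), pos,
                          np.zeros(len(raw.ch_names), dtype=bool))
    try:
        events = mne.find_events(raw, verbose="error")[:, 0]
    except (ValueError, RuntimeError):
        events = np.array([], dtype=int)
    return RawEEG(data, float(raw.info["sfreq"]), layout, events)


def read_raw(path) -> RawEEG:
    """Read a continuous recording from EDF, FIF, or the HDF5 fallback."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".h5", ".hdf5"}:
        return _read_raw_h5(path)
    if suffix == ".edf":
        return _read_raw_mne(path, "edf")
    if suffix == ".fif":
        return _read_raw_mne(path, "fif")
    raise ValueError(f"unsupported raw format: {path.name}")


def write_epochs_h5(path, ep: EpochedEEG, ground_truth_json=None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ep.data)
        f.attrs["sfreq"] = ep.sfreq
        f.attrs["tmin"] = ep.tmin
        _layout_to_group(f.create_group("layout"), ep.layout)
    if ground_truth_json is not None:
        sidecar = Path(path).with_suffix(".truth.json")
        sidecar.write_text(json.dumps(ground_truth_json, indent=2,
                                      default=_json_default))


def read_epochs_h5(path) -> EpochedEEG:
    with h5py.File(path, "r") as f:
        return EpochedEEG(f["data"][()], float(f.attrs["sfreq"]),
                          _layout_from_group(f["layout"]),
                          tmin=float(f.attrs["tmin"]))


def write_peaks_h5(path, ps: PeakSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("topographies", data=ps.topographies)
        f.create_dataset("gfp", data=ps.gfp)
        f.create_dataset("source", data=ps.source)


def read_peaks_h5(path) -> PeakSet:
    with h5py.File(path, "r") as f:
        return PeakSet(f["topographies"][()], f["gfp"][()], f["source"][()])


def write_maps_csv(path, ms: MapSet) -> None:
    """Maps as channels x k CSV with one named column per map."""
    labels = ms.canonical_labels or [f"map{i}" for i in range(ms.k)]
    pd.DataFrame(ms.maps.T, columns=labels).to_csv(path, index=False)


def read_maps_csv(path) -> MapSet:
    df = pd.read_csv(path)
    return MapSet(df.to_numpy().T, canonical_labels=list(df.columns))


def write_segmentation_csv(path, seg: Segmentation) -> None:
    """Long-format (epoch, sample, label) table."""
    e, s = np.meshgrid(np.arange(seg.n_epochs), np.arange(seg.n_samples),
                       indexing="ij")
    pd.DataFrame({
        "epoch": e.ravel(), "sample": s.ravel(),
        "label": seg.labels.ravel(),
    }).to_csv(path, index=False)


def read_segmentation_csv(path, k: int, sfreq: float) -> Segmentation:
    df = pd.read_csv(path)
    n_epochs = int(df["epoch"].max()) + 1
    n_samples = int(df["sample"].max()) + 1
    labels = np.zeros((n_epochs, n_samples), dtype=int)
    labels[df["epoch"], df["sample"]] = df["label"]
    return Segmentation(labels, k=k, sfreq=sfreq)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")
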
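"""HDF5 persistence for recordings, trial TFR sets and FTF maps.

One schema for the whole pipeline: each object lives in its own group with
named dimension datasets (``time_s``, ``freq_hz``, channel labels…) and a
``provenance`` attribute carrying an arbitrary JSON blob (config, seeds,
wavelet parameters).  Writing then reading reproduces arrays bit-identically
and metadata field-for-field.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .ftf import FTFMap
from .signal_model import Recording
from .tfr import TFRSet, WaveletParams

__all__ = [
    "save_recording",
    "load_recording",
    "save_tfr",
    "load_tfr",
    "save_ftf",
    "load_ftf",
]


def _write_labels(grp: h5py.Group, name: str, labels) -> None:
    grp.create_dataset(name, data=np.array(list(labels), dtype=h5py.string_dtype()))


def _read_labels(grp: h5py.Group, name: str) -> list[str]:
    return [s.decode() if isinstance(s, bytes) else str(s) for s in grp[name][()]]


def _set_provenance(grp: h5py.Group, provenance: dict | None) -> None:
    if provenance is not None:
        grp.attrs["provenance"] = json.dumps(provenance, sort_keys=True)


def get_provenance(path: str | Path, group: str) -> dict | None:
    with h5py.File(path, "r") as fh:
        raw = fh[group].attrs.get("provenance")
    return json.loads(raw) if raw is not None else None


def save_recording(path: str | Path, rec: Recording, provenance: dict | None = None) -> None:
    with h5py.File(path, "a") as fh:
        if "recording" in fh:
            del fh["recording"]
        g = fh.create_group("recording")
        g.create_dataset("data_uv", data=rec.data)
        g.attrs["fs_hz"] = float(rec.fs)
        _write_labels(g, "channel", rec.channel_labels)
        if rec.montage is not None:
            _write_labels(g, "montage_label", list(rec.montage))
            g.create_dataset("montage_xy", data=np.array(list(rec.montage.values())))
        _set_provenance(g, provenance)


def load_recording(path: str | Path) -> Recording:
    with h5py.File(path, "r") as fh:
        g = fh["recording"]
        montage = None
        if "montage_label" in g:
            labs = _read_labels(g, "montage_label")
            xy = g["montage_xy"][()]
            montage = {l: (float(x), float(y)) for l, (x, y) in zip(labs, xy)}
        return Recording(
            data=g["data_uv"][()],
            fs=float(g.attrs["fs_hz"]),
            channel_labels=_read_labels(g, "channel"),
            montage=montage,
        )


def save_tfr(path: str | Path, tfr: TFRSet, provenance: dict | None = None) -> None:
    with h5py.File(path, "a") as fh:
        if "tfr" in fh:
            del fh["tfr"]
        g = fh.create_group("tfr")
        g.create_dataset("power", data=tfr.power)
        g.create_dataset("freq_hz", data=tfr.freqs)
        g.create_dataset("time_s", data=tfr.times)
        g.attrs["fs_hz"] = float(tfr.fs)
        _write_labels(g, "trial_condition", tfr.labels)
        _write_labels(g, "channel", tfr.channel_labels)
        _write_labels(g, "condition_set", tfr.condition_set)
        g.attrs["baseline_mode"] = tfr.baseline_mode
        if tfr.baseline_interval is not None:
            g.attrs["baseline_interval_s"] = np.array(tfr.baseline_interval)
        g.attrs["wavelet_n_cycles"] = tfr.wavelet.n_cycles
        g.attrs["wavelet_power"] = tfr.wavelet.power
        if tfr.coi_halfwidth_s is not None:
            g.create_dataset("coi_halfwidth_s", data=tfr.coi_halfwidth_s)
        _set_provenance(g, provenance)


def load_tfr(path: str | Path) -> TFRSet:
    with h5py.File(path, "r") as fh:
        g = fh["tfr"]
        bl = g.attrs.get("baseline_interval_s")
        return TFRSet(
            power=g["power"][()],
            freqs=g["freq_hz"][()],
            times=g["time_s"][()],
            fs=float(g.attrs["fs_hz"]),
            labels=_read_labels(g, "trial_condition"),
            channel_labels=_read_labels(g, "channel"),
            condition_set=tuple(_read_labels(g, "condition_set")),
            baseline_mode=str(g.attrs["baseline_mode"]),
            baseline_interval=tuple(float(v) for v in bl) if bl is not None else None,
            wavelet=WaveletParams(
                n_cycles=float(g.attrs["wavelet_n_cycles"]),
                power=str(g.attrs["wavelet_power"]),
            ),
            coi_halfwidth_s=g["coi_halfwidth_s"][()] if "coi_halfwidth_s" in g else None,
        )


def save_ftf(
    path: str | Path,
    fmap: FTFMap,
    mask: np.ndarray | None = None,
    threshold: float | None = None,
    provenance: dict | None = None,
) -> None:
    with h5py.File(path, "a") as fh:
        if "ftf" in fh:
            del fh["ftf"]
        g = fh.create_group("ftf")
        g.create_dataset("f_value", data=fmap.f_values)
        g.create_dataset("freq_hz", data=fmap.freqs)
        g.create_dataset("time_s", data=fmap.times)
        _write_labels(g, "channel", fmap.channel_labels)
        g.attrs["df_between"] = int(fmap.df_between)
        g.attrs["df_within"] = int(fmap.df_within)
        _write_labels(g, "group", list(fmap.group_sizes))
        g.create_dataset("group_size", data=np.array(list(fmap.group_sizes.values()), dtype=np.int64))
        if mask is not None:
            g.create_dataset("significant", data=mask.astype(bool))
        if threshold is not None:
            g.attrs["threshold_f"] = float(threshold)
        _set_provenance(g, provenance)


def load_ftf(path: str | Path) -> tuple[FTFMap, np.ndarray | None, float | None]:
    with h5py.File(path, "r") as fh:
        g = fh["ftf"]
        fmap = FTFMap(
            f_values=g["f_value"][()],
            df_between=int(g.attrs["df_between"]),
            df_within=int(g.attrs["df_within"]),
            group_sizes=dict(zip(_read_labels(g, "group"), (int(n) for n in g["group_size"][()]))),
            freqs=g["freq_hz"][()],
            times=g["time_s"][()],
            channel_labels=_read_labels(g, "channel"),
        )
        mask = g["significant"][()] if "significant" in g else None
        thr = float(g.attrs["threshold_f"]) if "threshold_f" in g.attrs else None
        return fmap, mask, thr
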
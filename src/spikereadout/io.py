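"""Session container I/O: HDF5 (default) or NPZ, plus WAV audio.

A session file carries the schedule (JSON attribute), per-stimulus
feature matrices for every stack and layer, the STRF frontend features,
spike counts per presentation, and ground-truth unit attributes when the
session is synthetic.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
from scipy.io import wavfile

from .containers import (
    FeatureMatrix,
    FeatureStack,
    GroundTruthUnit,
    ResponseTensor,
    StimulusSchedule,
)
from .synthetic import SyntheticSession

__all__ = ["save_session", "load_session", "write_wav", "read_wav"]


def write_wav(path: str | Path, waveform: np.ndarray, sample_rate: int) -> None:
    """16-bit PCM WAV output; amplitude clipped to [-1, 1]."""
    data = np.clip(np.asarray(waveform, dtype=float), -1.0, 1.0)
    wavfile.write(str(path), int(sample_rate), (data * 32767).astype(np.int16))


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    rate, data = wavfile.read(str(path))
    data = np.asarray(data, dtype=float)
    if data.dtype != float or np.max(np.abs(data)) > 1.0:
        data = data / 32768.0
    return data, int(rate)


def _save_hdf5(path: Path, session: SyntheticSession) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schedule"] = session.schedule.to_json()
        f.attrs["bin_width"] = session.responses.bin_width
        f.attrs["unit_ids"] = json.dumps(session.responses.unit_ids)
        g_counts = f.create_group("counts")
        for i, c in enumerate(session.responses.counts):
            g_counts.create_dataset(f"p{i:05d}", data=c)
        g_stacks = f.create_group("stacks")
        for name, stack in session.stacks.items():
            g = g_stacks.create_group(name)
            g.attrs["strides"] = stack.strides
            g.attrs["base_rate"] = stack.base_rate
            for li, layer in enumerate(stack.layers):
                gl = g.create_group(f"layer{li + 1:02d}")
                for sid, fm in layer.items():
                    d = gl.create_dataset(sid, data=fm.values)
                    d.attrs["sampling_rate"] = fm.sampling_rate
            gk = g.create_group("kernels")
            for ki, k in enumerate(stack.kernels):
                gk.create_dataset(f"k{ki:02d}", data=k)
            gb = g.create_group("base")
            for sid, vals in stack.base.items():
                gb.create_dataset(sid, data=vals)
        g_strf = f.create_group("strf_features")
        for sid, fm in session.strf_features.items():
            d = g_strf.create_dataset(sid, data=fm.values)
            d.attrs["sampling_rate"] = fm.sampling_rate
        g_units = f.create_group("units")
        for u in session.units:
            gu = g_units.create_group(u.unit_id)
            gu.attrs["target_layer"] = u.target_layer
            gu.attrs["gain"] = u.gain
            gu.attrs["baseline_rate"] = u.baseline_rate
            gu.attrs["region_label"] = u.region_label
            gu.create_dataset("true_trf", data=u.true_trf)


def _load_hdf5(path: Path) -> SyntheticSession:
    with h5py.File(path, "r") as f:
        schedule = StimulusSchedule.from_json(f.attrs["schedule"])
        bin_width = float(f.attrs["bin_width"])
        unit_ids = json.loads(f.attrs["unit_ids"])
        counts = [
            f["counts"][f"p{i:05d}"][()].astype(np.int64)
            for i in range(len(schedule.presentation_order))
        ]
        responses = ResponseTensor(
            counts, bin_width, list(schedule.presentation_order), unit_ids
        )
        stacks = {}
        for name, g in f["stacks"].items():
            layer_names = sorted(k for k in g if k.startswith("layer"))
            layers = []
            for ln in layer_names:
                layers.append(
                    {
                        sid: FeatureMatrix(d[()], float(d.attrs["sampling_rate"]))
                        for sid, d in g[ln].items()
                    }
                )
            kernels = [g["kernels"][k][()] for k in sorted(g["kernels"])]
            base = {sid: d[()] for sid, d in g["base"].items()}
            stacks[name] = FeatureStack(
                layers, kernels, list(g.attrs["strides"]),
                base=base, base_rate=float(g.attrs["base_rate"]),
            )
        strf_features = {
            sid: FeatureMatrix(d[()], float(d.attrs["sampling_rate"]))
            for sid, d in f["strf_features"].items()
        }
        units = [
            GroundTruthUnit(
                unit_id=uid,
                target_layer=int(gu.attrs["target_layer"]),
                true_trf=gu["true_trf"][()],
                gain=float(gu.attrs["gain"]),
                baseline_rate=float(gu.attrs["baseline_rate"]),
                region_label=str(gu.attrs["region_label"]),
            )
            for uid, gu in f["units"].items()
        ]
    units.sort(key=lambda u: u.unit_id)
    return SyntheticSession(schedule, stacks, strf_features, units, responses)


def save_session(path: str | Path, session: SyntheticSession) -> None:
    """Write a session container; format chosen by extension (.h5 / .npz)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        _save_hdf5(path, session)
    elif path.suffix == ".npz":
        _save_npz(path, session)
    else:
        raise ValueError(f"unknown session format {path.suffix!r}")


def load_session(path: str | Path) -> SyntheticSession:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return _load_hdf5(path)
    if path.suffix == ".npz":
        return _load_npz(path)
    raise ValueError(f"unknown session format {path.suffix!r}")


def _save_npz(path: Path, session: SyntheticSession) -> None:
    arrays: dict[str, np.ndarray] = {}
    meta = {
        "schedule": json.loads(session.schedule.to_json()),
        "bin_width": session.responses.bin_width,
        "unit_ids": session.responses.unit_ids,
        "stacks": {},
        "units": [],
    }
    for i, c in enumerate(session.responses.counts):
        arrays[f"counts/p{i:05d}"] = c
    for name, stack in session.stacks.items():
        meta["stacks"][name] = {
            "strides": stack.strides,
            "base_rate": stack.base_rate,
            "rates": stack.layer_rates,
            "n_layers": stack.n_layers,
        }
        for li, layer in enumerate(stack.layers):
            for sid, fm in layer.items():
                arrays[f"stacks/{name}/layer{li + 1:02d}/{sid}"] = fm.values
        for ki, k in enumerate(stack.kernels):
            arrays[f"stacks/{name}/kernels/k{ki:02d}"] = k
        for sid, vals in stack.base.items():
            arrays[f"stacks/{name}/base/{sid}"] = vals
    strf_rate = next(iter(session.strf_features.values())).sampling_rate
    meta["strf_rate"] = strf_rate
    for sid, fm in session.strf_features.items():
        arrays[f"strf_features/{sid}"] = fm.values
    for u in session.units:
        meta["units"].append(
            {
                "unit_id": u.unit_id,
                "target_layer": u.target_layer,
                "gain": u.gain,
                "baseline_rate": u.baseline_rate,
                "region_label": u.region_label,
            }
        )
        arrays[f"units/{u.unit_id}/true_trf"] = u.true_trf
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8
    )
    np.savez_compressed(path, **arrays)


def _load_npz(path: Path) -> SyntheticSession:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        schedule = StimulusSchedule.from_json(json.dumps(meta["schedule"]))
        counts = [
            z[f"counts/p{i:05d}"].astype(np.int64)
            for i in range(len(schedule.presentation_order))
        ]
        responses = ResponseTensor(
            counts, float(meta["bin_width"]),
            list(schedule.presentation_order), meta["unit_ids"],
        )
        stacks = {}
        for name, sm in meta["stacks"].items():
            layers = []
            for li in range(sm["n_layers"]):
                prefix = f"stacks/{name}/layer{li + 1:02d}/"
                layers.append(
                    {
                        k[len(prefix):]: FeatureMatrix(z[k], sm["rates"][li])
                        for k in z.files
                        if k.startswith(prefix)
                    }
                )
            kprefix = f"stacks/{name}/kernels/"
            kernels = [z[k] for k in sorted(f for f in z.files if f.startswith(kprefix))]
            bprefix = f"stacks/{name}/base/"
            base = {k[len(bprefix):]: z[k] for k in z.files if k.startswith(bprefix)}
            stacks[name] = FeatureStack(
                layers, kernels, list(sm["strides"]),
                base=base, base_rate=float(sm["base_rate"]),
            )
        strf_features = {
            k[len("strf_features/"):]: FeatureMatrix(z[k], float(meta["strf_rate"]))
            for k in z.files
            if k.startswith("strf_features/")
        }
        units = [
            GroundTruthUnit(
                unit_id=um["unit_id"],
                target_layer=um["target_layer"],
                true_trf=z[f"units/{um['unit_id']}/true_trf"],
                gain=um["gain"],
                baseline_rate=um["baseline_rate"],
                region_label=um["region_label"],
            )
            for um in meta["units"]
        ]
    return SyntheticSession(schedule, stacks, strf_features, units, responses)
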
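"""HDF5 persistence for continuous recordings, epoch files and checkpoints.

Layout (recordings file)::

    /trials/000000/eeg      (C_eeg, N_eeg) float64
    /trials/000000/emg      (C_emg, N_emg) float64
    attrs: label, subject_id, fs_eeg, fs_emg, eeg_channels, emg_channels,
           event_times, event_names

Epoch files hold ``x_eeg1 / x_eeg2 / x_semg`` per trial with the same attrs.
Checkpoints are ``.npz`` archives of named parameter arrays plus a JSON
config sidecar stored inside the archive.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .preprocess import MultimodalTrial
from .simulate import ContinuousTrialRecording


def _write_common_attrs(grp, obj) -> None:
    grp.attrs["label"] = obj.label
    grp.attrs["subject_id"] = int(obj.subject_id)
    grp.attrs["fs_eeg"] = float(obj.fs_eeg)
    grp.attrs["fs_emg"] = float(obj.fs_emg)
    grp.attrs["eeg_channels"] = [str(c) for c in obj.eeg_channels]
    grp.attrs["emg_channels"] = [str(c) for c in obj.emg_channels]


def save_recordings(path, recordings) -> None:
    with h5py.File(path, "w") as f:
        trials = f.create_group("trials")
        for i, rec in enumerate(recordings):
            g = trials.create_group(f"{i:06d}")
            g.create_dataset("eeg", data=rec.eeg)
            g.create_dataset("emg", data=rec.emg)
            _write_common_attrs(g, rec)
            g.attrs["event_times"] = [float(t) for t, _ in rec.events]
            g.attrs["event_names"] = [str(n) for _, n in rec.events]


def load_recordings(path) -> list:
    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f["trials"]):
            g = f["trials"][key]
            events = list(zip((float(t) for t in g.attrs["event_times"]),
                              (str(n) for n in g.attrs["event_names"])))
            out.append(ContinuousTrialRecording(
                eeg=g["eeg"][()],
                emg=g["emg"][()],
                events=events,
                label=str(g.attrs["label"]),
                subject_id=int(g.attrs["subject_id"]),
                fs_eeg=float(g.attrs["fs_eeg"]),
                fs_emg=float(g.attrs["fs_emg"]),
                eeg_channels=[str(c) for c in g.attrs["eeg_channels"]],
                emg_channels=[str(c) for c in g.attrs["emg_channels"]],
            ))
    return out


def save_epochs(path, trials) -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group("trials")
        for i, tr in enumerate(trials):
            g = grp.create_group(f"{i:06d}")
            g.create_dataset("x_eeg1", data=tr.x_eeg1)
            g.create_dataset("x_eeg2", data=tr.x_eeg2)
            g.create_dataset("x_semg", data=tr.x_semg)
            _write_common_attrs(g, tr)


def load_epochs(path) -> list:
    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f["trials"]):
            g = f["trials"][key]
            out.append(MultimodalTrial(
                x_eeg1=g["x_eeg1"][()],
                x_eeg2=g["x_eeg2"][()],
                x_semg=g["x_semg"][()],
                label=str(g.attrs["label"]),
                subject_id=int(g.attrs["subject_id"]),
                fs_eeg=float(g.attrs["fs_eeg"]),
                fs_emg=float(g.attrs["fs_emg"]),
                eeg_channels=[str(c) for c in g.attrs["eeg_channels"]],
                emg_channels=[str(c) for c in g.attrs["emg_channels"]],
            ))
    return out


def load_delimited_emg(path, delimiter: str = "\t") -> np.ndarray:
    """Read an sEMG recording from delimited text (samples in rows, channels
    in columns, optional header line) into a ``(channels, samples)`` array."""
    data = np.genfromtxt(path, delimiter=delimiter, names=None,
                         skip_header=0, dtype=float)
    if np.isnan(data).all(axis=1).any() or np.isnan(data[0]).any():
        data = np.genfromtxt(path, delimiter=delimiter, skip_header=1,
                             dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    return data.T


def save_checkpoint(path, params: dict, config: dict) -> None:
    """Save named parameter arrays plus a JSON-encoded config in one .npz."""
    payload = {f"param/{k}": np.asarray(v) for k, v in params.items()}
    payload["__config__"] = np.frombuffer(
        json.dumps(config, sort_keys=True).encode(), dtype=np.uint8)
    np.savez(path, **payload)


def load_checkpoint(path):
    with np.load(path) as z:
        config = json.loads(bytes(z["__config__"]).decode())
        params = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    return params, config
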
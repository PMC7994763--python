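"""On-disk HDF5 container for TrialSets and analysis maps.

Layout (TrialSet)::

    /data            float64 (n_trials, n_channels, n_times), uV or uV/m^2
    /pulse_samples   int64   (n_trials, n_pulses)
    /montage/positions, /montage/adjacency
    attrs: fs_hz, units, condition, participant_id, channels,
           montage labels/head_radius_mm, protocol fields (JSON)

Datasets are written with ``track_times=False`` so identical inputs give
byte-identical files (the run manifest checksums rely on this).
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .montage import Montage
from .protocol import StimProtocol
from .synth import TrialSet

_OPTS = dict(track_times=False)


def _write(group, name, arr):
    group.create_dataset(name, data=np.asarray(arr), **_OPTS)


def save_trialset(path, trials: TrialSet) -> None:
    with h5py.File(path, "w", track_order=True) as f:
        _write(f, "data", trials.data)
        _write(f, "pulse_samples", trials.pulse_samples)
        f.attrs["fs_hz"] = trials.fs_hz
        f.attrs["units"] = trials.units
        f.attrs["condition"] = trials.condition
        f.attrs["participant_id"] = trials.participant_id
        f.attrs["channels"] = json.dumps(trials.channels)
        f.attrs["protocol"] = json.dumps({
            "site": trials.protocol.site,
            "n_pulses": trials.protocol.n_pulses,
            "train_freq_hz": trials.protocol.train_freq_hz,
            "n_trials": trials.protocol.n_trials,
            "iti_s": list(trials.protocol.iti_s),
            "epoch_pre_s": trials.protocol.epoch_pre_s,
            "epoch_post_s": trials.protocol.epoch_post_s,
        })
        g = f.create_group("montage")
        _write(g, "positions", trials.montage.positions)
        _write(g, "adjacency", trials.montage.adjacency.astype(np.uint8))
        g.attrs["labels"] = json.dumps(trials.montage.labels)
        g.attrs["head_radius_mm"] = trials.montage.head_radius_mm


def load_trialset(path) -> TrialSet:
    with h5py.File(path, "r") as f:
        proto = json.loads(f.attrs["protocol"])
        proto["iti_s"] = tuple(proto["iti_s"])
        g = f["montage"]
        montage = Montage(
            labels=json.loads(g.attrs["labels"]),
            positions=g["positions"][()],
            head_radius_mm=float(g.attrs["head_radius_mm"]),
            adjacency=g["adjacency"][()].astype(bool))
        return TrialSet(
            data=f["data"][()],
            fs_hz=float(f.attrs["fs_hz"]),
            montage=montage,
            channels=json.loads(f.attrs["channels"]),
            pulse_samples=f["pulse_samples"][()],
            protocol=StimProtocol(**proto),
            participant_id=str(f.attrs["participant_id"]),
            condition=str(f.attrs["condition"]),
            units=str(f.attrs["units"]))


def save_map(path, values: np.ndarray, channels, freqs_hz, times_s,
             n_trials: int, meta: dict | None = None) -> None:
    """Persist a PLF/ZPLF-style (channel, frequency, time) map."""
    with h5py.File(path, "w", track_order=True) as f:
        _write(f, "values", values)
        _write(f, "freqs_hz", freqs_hz)
        _write(f, "times_s", times_s)
        f.attrs["channels"] = json.dumps(list(channels))
        f.attrs["n_trials"] = int(n_trials)
        f.attrs["meta"] = json.dumps(meta or {})


def load_map(path):
    from .phaselock import ZPLFMap

    with h5py.File(path, "r") as f:
        return ZPLFMap(values=f["values"][()],
                       n_trials=int(f.attrs["n_trials"]),
                       channels=json.loads(f.attrs["channels"]),
                       freqs_hz=f["freqs_hz"][()],
                       times_s=f["times_s"][()],
                       meta=json.loads(f.attrs["meta"]))
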
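"""Persistence: HDF5 recording/weight containers and tidy CSV summaries."""

from __future__ import annotations

import json
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .network import SpikeRecording

__all__ = ["save_recording", "load_recording", "save_curve_csv"]


def save_recording(
    path,
    recording: SpikeRecording,
    w_ee: Optional[np.ndarray] = None,
    t_e: Optional[np.ndarray] = None,
    config: Optional[dict] = None,
) -> None:
    """Write a spike recording (and optional weight snapshot) to HDF5.

    Layout: ``/spikes`` (uint8 T x N), ``/letters`` (fixed-width bytes),
    ``/W_ee`` sparse triplets (row, col, weight), ``/T_e``; the fully
    resolved config is stored as a JSON string attribute.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("spikes", data=recording.spikes, compression="gzip")
        f.create_dataset(
            "letters", data=np.char.encode(recording.letters.astype("U8"), "utf-8")
        )
        f.attrs["phase"] = recording.phase
        f.attrs["noise_flips"] = recording.noise_flips
        if recording.inhibitory_spikes is not None:
            f.create_dataset("inhibitory_spikes", data=recording.inhibitory_spikes,
                             compression="gzip")
        if recording.connection_fraction is not None:
            f.create_dataset("connection_fraction", data=recording.connection_fraction)
            f.attrs["connection_sample_every"] = recording.connection_sample_every
        if w_ee is not None:
            rows, cols = np.nonzero(w_ee)
            trip = f.create_group("W_ee")
            trip.create_dataset("row", data=rows.astype(np.int32))
            trip.create_dataset("col", data=cols.astype(np.int32))
            trip.create_dataset("weight", data=w_ee[rows, cols])
            trip.attrs["shape"] = w_ee.shape
        if t_e is not None:
            f.create_dataset("T_e", data=t_e)
        if config is not None:
            f.attrs["config"] = json.dumps(config, default=str, sort_keys=True)


def load_recording(path):
    """Read back a recording container; returns (SpikeRecording, w_ee, t_e, config)."""
    with h5py.File(path, "r") as f:
        rec = SpikeRecording(
            spikes=f["spikes"][()],
            letters=np.char.decode(f["letters"][()], "utf-8").astype("U8"),
            phase=str(f.attrs.get("phase", "")),
            inhibitory_spikes=f["inhibitory_spikes"][()]
            if "inhibitory_spikes" in f else None,
            connection_fraction=f["connection_fraction"][()]
            if "connection_fraction" in f else None,
            connection_sample_every=int(f.attrs.get("connection_sample_every", 0)),
            noise_flips=int(f.attrs.get("noise_flips", 0)),
        )
        w_ee = None
        if "W_ee" in f:
            g = f["W_ee"]
            w_ee = np.zeros(tuple(g.attrs["shape"]))
            w_ee[g["row"][()], g["col"][()]] = g["weight"][()]
        t_e = f["T_e"][()] if "T_e" in f else None
        config = json.loads(f.attrs["config"]) if "config" in f.attrs else None
    return rec, w_ee, t_e, config


def save_curve_csv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)
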
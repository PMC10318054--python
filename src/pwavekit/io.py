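"""Recording bundle I/O.

Container layout (HDF5, schema version 1):

    /channels/<name>/data      float64 dataset
    /channels/<name>  attrs: rate_hz, units
    /hypnogram/labels          fixed-width string dataset; attrs: epoch_s
    /laser/onsets_s, /laser/durations_ms, optional /laser/train_ids
        attrs: mode; optional episode_onsets_s + episode_on for closed loop
    /events/<name>/times_s (+ one dataset per event attribute)
    root attrs: schema = "pwavekit-bundle", version, metadata (JSON)

Datasets are written with ``track_times=False`` so identical content yields
byte-identical files. The hypnogram can additionally be mirrored to CSV
(epoch_index,state) for hand inspection.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import Channel, EventSeries, Hypnogram, LaserProtocol, Recording

SCHEMA = "pwavekit-bundle"
VERSION = 1


def write_bundle(
    path,
    recording: Recording,
    hypnogram: Hypnogram | None = None,
    laser: LaserProtocol | None = None,
    events: dict[str, EventSeries] | None = None,
) -> None:
    """Write a recording and optional annotations to one HDF5 bundle."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = SCHEMA
        f.attrs["version"] = VERSION
        f.attrs["start_time"] = recording.start_time
        f.attrs["metadata"] = json.dumps(recording.metadata, sort_keys=True)
        ch = f.create_group("channels")
        for name, c in recording.channels.items():
            g = ch.create_group(name)
            g.create_dataset("data", data=c.data, track_times=False)
            g.attrs["rate_hz"] = c.rate_hz
            g.attrs["units"] = c.units
        if hypnogram is not None:
            g = f.create_group("hypnogram")
            g.create_dataset(
                "labels",
                data=np.array(hypnogram.labels, dtype="S1"),
                track_times=False,
            )
            g.attrs["epoch_s"] = hypnogram.epoch_s
        if laser is not None:
            g = f.create_group("laser")
            g.create_dataset("onsets_s", data=laser.onsets_s, track_times=False)
            g.create_dataset("durations_ms", data=laser.durations_ms, track_times=False)
            if laser.train_ids is not None:
                g.create_dataset("train_ids", data=laser.train_ids, track_times=False)
            g.attrs["mode"] = laser.mode
            if laser.episode_on is not None:
                keys = sorted(laser.episode_on)
                g.create_dataset("episode_onsets_s", data=np.array(keys), track_times=False)
                g.create_dataset(
                    "episode_on",
                    data=np.array([laser.episode_on[k] for k in keys], dtype=bool),
                    track_times=False,
                )
        if events:
            eg = f.create_group("events")
            for name, es in events.items():
                g = eg.create_group(name)
                g.create_dataset("times_s", data=es.times, track_times=False)
                for k, v in es.attrs.items():
                    data = v
                    if data.dtype.kind == "U":
                        data = data.astype("S")
                    g.create_dataset(k, data=data, track_times=False)


def read_bundle(path) -> tuple[
    Recording, Hypnogram | None, LaserProtocol | None, dict[str, EventSeries]
]:
    """Read a bundle written by :func:`write_bundle`; fails closed on schema
    mismatch or truncation (no partial objects are returned)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise ValueError(f"not a readable HDF5 bundle: {path} ({exc})") from exc
    with f:
        if f.attrs.get("schema") != SCHEMA:
            raise ValueError(
                f"unrecognized container schema {f.attrs.get('schema')!r}; "
                f"expected {SCHEMA!r}"
            )
        if int(f.attrs.get("version", -1)) > VERSION:
            raise ValueError("bundle written by a newer schema version")
        channels = {}
        for name, g in f["channels"].items():
            channels[name] = Channel(
                g["data"][...], float(g.attrs["rate_hz"]), str(g.attrs["units"])
            )
        rec = Recording(
            channels,
            start_time=float(f.attrs.get("start_time", 0.0)),
            metadata=json.loads(f.attrs.get("metadata", "{}")),
        )
        hyp = None
        if "hypnogram" in f:
            labels = f["hypnogram/labels"][...].astype("U1")
            hyp = Hypnogram(labels, float(f["hypnogram"].attrs["epoch_s"]))
        laser = None
        if "laser" in f:
            g = f["laser"]
            episode_on = None
            if "episode_onsets_s" in g:
                episode_on = dict(
                    zip(g["episode_onsets_s"][...].tolist(),
                        g["episode_on"][...].astype(bool).tolist())
                )
            laser = LaserProtocol(
                g["onsets_s"][...],
                g["durations_ms"][...],
                mode=str(g.attrs["mode"]),
                train_ids=g["train_ids"][...] if "train_ids" in g else None,
                episode_on=episode_on,
            )
        events: dict[str, EventSeries] = {}
        if "events" in f:
            for name, g in f["events"].items():
                attrs = {}
                for k in g:
                    if k == "times_s":
                        continue
                    v = g[k][...]
                    if v.dtype.kind == "S":
                        v = v.astype("U")
                    attrs[k] = v
                events[name] = EventSeries(g["times_s"][...], attrs)
    return rec, hyp, laser, events


def hypnogram_to_csv(hyp: Hypnogram, path) -> None:
    pd.DataFrame(
        {"epoch_index": np.arange(len(hyp)), "state": hyp.labels}
    ).to_csv(path, index=False)


def hypnogram_from_csv(path, epoch_s: float = 2.5) -> Hypnogram:
    df = pd.read_csv(path)
    return Hypnogram(df["state"].to_numpy(dtype="U1"), epoch_s)
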
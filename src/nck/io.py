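"""Session container I/O.

HDF5 layout::

    /regions/<name>/lfp            float32 (channels x samples), attrs: fs, depths_um, t0
    /regions/<name>/units/<id>/spike_times   float64 seconds
    /stimulation/pulse_onsets      float64, attrs: width_s, freq_hz,
                                   train_duration_s, inter_train_s, n_repeats

Event tables are exported as CSV with one row per event
(region, channel, start_s, stop_s, amplitude_uv). Module parameters travel
as JSON. Vendor formats (e.g. Neuralynx .ncs) are intentionally not read;
see ``convert_stub`` for the documented mapping.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import PulseProtocol, Recording, SpikeTrainSet


class SchemaError(ValueError):
    """Session container is missing a required group or attribute."""


def write_session(path, recordings: dict, spikes: dict | None = None,
                  stim: PulseProtocol | None = None) -> Path:
    """Write recordings/spike trains/protocol to an HDF5 container."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        regions = f.create_group("regions")
        for name, rec in recordings.items():
            g = regions.create_group(name)
            d = g.create_dataset("lfp", data=rec.samples.astype(np.float32))
            d.attrs["fs"] = float(rec.fs)
            d.attrs["depths_um"] = rec.channel_depths.astype(np.float64)
            d.attrs["t0"] = float(rec.t0)
            if spikes and name in spikes:
                sts = spikes[name]
                ug = g.create_group("units")
                ug.attrs["recording_duration"] = float(sts.recording_duration)
                for uid, st in sts:
                    ug.create_dataset(str(uid), data=np.asarray(st, dtype=np.float64))
        if stim is not None:
            sg = f.create_group("stimulation")
            d = sg.create_dataset("pulse_onsets",
                                  data=stim.pulse_onsets.astype(np.float64))
            d.attrs["width_s"] = float(stim.pulse_width)
            d.attrs["freq_hz"] = float(stim.train_frequency)
            d.attrs["train_duration_s"] = float(stim.train_duration)
            d.attrs["inter_train_s"] = float(stim.inter_train_interval)
            d.attrs["n_repeats"] = int(stim.n_repeats)
    return path


def read_session(path):
    """Read a session container; returns (recordings, spikes, stim_or_None)."""
    path = Path(path)
    recordings: dict[str, Recording] = {}
    spikes: dict[str, SpikeTrainSet] = {}
    stim = None
    with h5py.File(path, "r") as f:
        if "regions" not in f:
            raise SchemaError("missing required group: /regions")
        for name, g in f["regions"].items():
            if "lfp" not in g:
                raise SchemaError(f"missing required dataset: /regions/{name}/lfp")
            d = g["lfp"]
            if "depths_um" not in d.attrs:
                raise SchemaError(
                    f"missing required attribute: /regions/{name}/lfp@depths_um")
            if "fs" not in d.attrs:
                raise SchemaError(f"missing required attribute: /regions/{name}/lfp@fs")
            recordings[name] = Recording(
                samples=d[()].astype(float),
                fs=float(d.attrs["fs"]),
                channel_depths=np.asarray(d.attrs["depths_um"], dtype=float),
                region=name,
                t0=float(d.attrs.get("t0", 0.0)))
            if "units" in g:
                ug = g["units"]
                ids = sorted(ug, key=lambda s: (len(s), s))
                spikes[name] = SpikeTrainSet(
                    unit_ids=ids,
                    spike_times=[ug[i][()] for i in ids],
                    region=name,
                    recording_duration=float(
                        ug.attrs.get("recording_duration",
                                     recordings[name].duration)))
        if "stimulation" in f:
            d = f["stimulation"]["pulse_onsets"]
            stim = PulseProtocol(
                pulse_onsets=d[()],
                pulse_width=float(d.attrs["width_s"]),
                train_frequency=float(d.attrs["freq_hz"]),
                train_duration=float(d.attrs.get("train_duration_s", 3.0)),
                inter_train_interval=float(d.attrs.get("inter_train_s", 6.0)),
                n_repeats=int(d.attrs.get("n_repeats", 30)))
    return recordings, spikes, stim


def events_to_frame(events, region: str = "", channel: int = 0) -> pd.DataFrame:
    """Event list (oscillatory or SPW) to the canonical CSV schema."""
    rows = []
    for ev in events:
        if hasattr(ev, "start"):
            rows.append(dict(region=ev.region or region, channel=ev.channel,
                             start_s=ev.start, stop_s=ev.stop,
                             amplitude_uv=ev.peak_amplitude))
        else:
            rows.append(dict(region=region, channel=ev.pyr_channel,
                             start_s=ev.peak_time, stop_s=ev.peak_time,
                             amplitude_uv=ev.amplitude))
    return pd.DataFrame(rows, columns=["region", "channel", "start_s",
                                       "stop_s", "amplitude_uv"])


def write_events_csv(path, events, region: str = "") -> Path:
    path = Path(path)
    events_to_frame(events, region).to_csv(path, index=False)
    return path


def load_config(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def save_config(path, config: dict) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True, default=_json_default)
    return path


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"cannot serialize {type(obj)}")


def convert_stub(src_path) -> None:
    """Vendor-format conversion is out of scope.

    Mapping for a future converter: each vendor continuous channel becomes a
    row of /regions/<name>/lfp (after low-pass < 1400 Hz, third-order
    Butterworth, and downsampling to 3.2 kHz); sorted unit timestamps map to
    /regions/<name>/units/<id>/spike_times in seconds; TTL event records of
    the laser line map to /stimulation/pulse_onsets.
    """
    raise NotImplementedError(
        "vendor formats are not supported; write the HDF5 layout described "
        "in the docstring with your acquisition tooling")
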
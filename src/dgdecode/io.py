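"""Persistence: HDF5 recording containers, JSON parameters, plain-text
spike trains and CSV exports."""

from __future__ import annotations

import json

import numpy as np
import h5py

from .stimulus import StimulusTrace, trace_to_hdf5, trace_from_hdf5
from .srm import SRMParams, Recording
from .metrics import SpikeTrain, TrialSet


def save_params(path, params: SRMParams) -> None:
    with open(path, "w") as fh:
        fh.write(params.to_json())


def load_params(path) -> SRMParams:
    with open(path) as fh:
        return SRMParams.from_json(fh.read())


def _write_recording(group, rec: Recording) -> None:
    trace_to_hdf5(group.create_group("stimulus"), rec.stimulus)
    if rec.voltage is not None:
        group.create_dataset("voltage", data=rec.voltage)
    group.create_dataset("spike_times", data=rec.spikes.times)
    group.attrs["duration"] = rec.spikes.duration
    group.attrs["cell_id"] = rec.cell_id
    group.attrs["trial_id"] = rec.trial_id


def _read_recording(group) -> Recording:
    stim = trace_from_hdf5(group["stimulus"])
    voltage = group["voltage"][:] if "voltage" in group else None
    spikes = SpikeTrain(group["spike_times"][:], float(group.attrs["duration"]))
    return Recording(stimulus=stim, voltage=voltage, spikes=spikes,
                     cell_id=str(group.attrs.get("cell_id", "")),
                     trial_id=int(group.attrs.get("trial_id", 0)))


def write_recordings(path, recordings: dict) -> None:
    """Write {cell_id: {"train": Recording, "validation": [Recording...]}}."""
    with h5py.File(path, "w") as fh:
        for cell_id, recs in recordings.items():
            cg = fh.create_group(cell_id)
            _write_recording(cg.create_group("train"), recs["train"])
            vg = cg.create_group("validation")
            for i, rec in enumerate(recs["validation"]):
                _write_recording(vg.create_group(f"trial{i:02d}"), rec)


def read_recordings(path) -> dict:
    out = {}
    with h5py.File(path, "r") as fh:
        for cell_id, cg in fh.items():
            out[cell_id] = {
                "train": _read_recording(cg["train"]),
                "validation": [_read_recording(cg["validation"][k])
                               for k in sorted(cg["validation"])],
            }
    return out


def write_spike_trains_text(path, trains: list) -> None:
    """One train per line: duration_ms followed by spike times (ms)."""
    with open(path, "w") as fh:
        for tr in trains:
            fields = [f"{tr.duration:.6f}"] + [f"{t:.6f}" for t in tr.times]
            fh.write(" ".join(fields) + "\n")


def read_spike_trains_text(path) -> list:
    trains = []
    with open(path) as fh:
        for line in fh:
            parts = [float(x) for x in line.split()]
            if parts:
                trains.append(SpikeTrain(np.asarray(parts[1:]), parts[0]))
    return trains


def coincidence_matrix_csv(path, matrix: np.ndarray, ids: list) -> None:
    import pandas as pd

    pd.DataFrame(matrix, index=ids, columns=ids).to_csv(path)
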
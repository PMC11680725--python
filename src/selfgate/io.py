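"""Serialization: HDF5 containers for array types, CSV for trigger trains."""

from __future__ import annotations

import pandas as pd
import h5py

from .si_preproc import SGMatrix
from .synth import PhysioGroundTruth, SIStack
from .triggers import TriggerTrain

__all__ = [
    "save_si_stack",
    "load_si_stack",
    "save_sg_matrix",
    "load_sg_matrix",
    "write_triggers_csv",
    "read_triggers_csv",
]


def save_si_stack(path, stack: SIStack) -> None:
    """HDF5 layout: /readouts, /segment_index, /fs, /ground_truth/*."""
    with h5py.File(path, "w") as f:
        f.create_dataset("readouts", data=stack.readouts)
        f.create_dataset("segment_index", data=stack.segment_index)
        f["fs"] = stack.fs
        gt = f.create_group("ground_truth")
        gt.create_dataset("trigger_times", data=stack.ground_truth.trigger_times)
        gt.create_dataset("resp_waveform", data=stack.ground_truth.resp_waveform)
        gt.create_dataset("resp_phase_labels", data=stack.ground_truth.resp_phase_labels)
        gt["fs"] = stack.ground_truth.fs
        for k, v in stack.ground_truth.params.items():
            gt.attrs[k] = v
        aux = f.create_group("aux")
        aux.create_dataset("resp_weights", data=stack.resp_weights)
        aux.create_dataset("card_weights", data=stack.card_weights)
        aux.create_dataset("resp_source", data=stack.resp_source)
        aux.create_dataset("cardiac_source", data=stack.cardiac_source)
        aux.create_dataset("modulation", data=stack.modulation)
        for k, v in stack.params.items():
            aux.attrs[k] = v


def load_si_stack(path) -> SIStack:
    with h5py.File(path, "r") as f:
        gt = PhysioGroundTruth(
            trigger_times=f["ground_truth/trigger_times"][()],
            resp_waveform=f["ground_truth/resp_waveform"][()],
            resp_phase_labels=f["ground_truth/resp_phase_labels"][()].astype(bool),
            fs=float(f["ground_truth/fs"][()]),
            params=dict(f["ground_truth"].attrs),
        )
        return SIStack(
            readouts=f["readouts"][()],
            segment_index=f["segment_index"][()],
            fs=float(f["fs"][()]),
            ground_truth=gt,
            resp_weights=f["aux/resp_weights"][()],
            card_weights=f["aux/card_weights"][()],
            resp_source=f["aux/resp_source"][()],
            cardiac_source=f["aux/cardiac_source"][()],
            modulation=f["aux/modulation"][()],
            params=dict(f["aux"].attrs),
        )


def save_sg_matrix(path, m: SGMatrix) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=m.values)
        f["fs"] = m.fs
        f.create_dataset("positions", data=m.positions)
        f.create_dataset("coils", data=m.coils)
        f.create_dataset("segment_index", data=m.segment_index)


def load_sg_matrix(path) -> SGMatrix:
    with h5py.File(path, "r") as f:
        return SGMatrix(
            values=f["values"][()],
            fs=float(f["fs"][()]),
            positions=f["positions"][()],
            coils=f["coils"][()],
            segment_index=f["segment_index"][()],
        )


def write_triggers_csv(path, train: TriggerTrain) -> None:
    pd.DataFrame(
        {"time_ms": train.times, "source": train.source, "flag": train.flags}
    ).to_csv(path, index=False)


def read_triggers_csv(path) -> TriggerTrain:
    df = pd.read_csv(path)
    source = str(df["source"].iloc[0]) if len(df) else "unknown"
    return TriggerTrain(
        times=df["time_ms"].to_numpy(float),
        flags=df["flag"].to_numpy(object),
        source=source,
    )
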
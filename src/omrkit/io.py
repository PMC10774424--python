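"""Plain-text I/O for sessions, traces, schedules and configs.

Tracking goes to CSV with header ``t,x,y,heading_deg`` (s, cm, cm, deg) plus
a JSON sidecar holding the trial schedule, condition metadata and — for
synthetic sessions — the ground-truth bouts.  Unit traces go to a long CSV
(unit_id, t, f) or an HDF5 container; protocols and fish parameters
round-trip through YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .behavior_metrics import Bout
from .synthetic_behavior import (
    BehaviorProtocol,
    BehaviorSession,
    FishParams,
    Trial,
)
from .synthetic_imaging import (
    BlockSchedule,
    ImagingProtocol,
    ImagingTrial,
    UnitTrace,
)


def write_session(session: BehaviorSession, csv_path: str | Path) -> Path:
    """Write tracking CSV plus a JSON sidecar (<stem>.json) next to it."""
    csv_path = Path(csv_path)
    session.tracking.to_csv(csv_path, index=False)
    sidecar = {
        "fish_id": session.fish_id,
        "condition_label": session.condition_label,
        "washout_h": session.washout_h,
        "seed": session.seed,
        "protocol": dataclasses.asdict(session.protocol),
        "params": dataclasses.asdict(session.params),
        "trials": [dataclasses.asdict(tr) for tr in session.trials],
        "truth_bouts": [dataclasses.asdict(b) for b in session.truth_bouts],
    }
    side_path = csv_path.with_suffix(".json")
    side_path.write_text(json.dumps(sidecar))
    return side_path


def read_session(csv_path: str | Path) -> BehaviorSession:
    csv_path = Path(csv_path)
    tracking = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    proto = meta["protocol"]
    proto["conditions"] = tuple(proto["conditions"])
    params = meta["params"]
    params["washout_accuracy_curve"] = tuple(
        tuple(p) for p in params["washout_accuracy_curve"]
    )
    return BehaviorSession(
        fish_id=meta["fish_id"],
        condition_label=meta["condition_label"],
        washout_h=meta["washout_h"],
        trials=[Trial(**tr) for tr in meta["trials"]],
        tracking=tracking,
        truth_bouts=[Bout(**b) for b in meta["truth_bouts"]],
        seed=meta["seed"],
        protocol=BehaviorProtocol(**proto),
        params=FishParams(**params),
    )


def write_traces_csv(traces: Sequence[UnitTrace], path: str | Path) -> Path:
    """Long table unit_id,t,f; the schedule goes to <stem>.schedule.json."""
    path = Path(path)
    frames = [
        pd.DataFrame({"unit_id": tr.unit_id, "t": tr.t, "f": tr.f})
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    if traces and traces[0].schedule is not None:
        write_schedule(traces[0].schedule, path.with_suffix(".schedule.json"))
    return path


def read_traces_csv(path: str | Path) -> list[UnitTrace]:
    path = Path(path)
    df = pd.read_csv(path)
    sched_path = path.with_suffix(".schedule.json")
    schedule = read_schedule(sched_path) if sched_path.exists() else None
    traces = []
    for uid, sub in df.groupby("unit_id", sort=False):
        traces.append(
            UnitTrace(
                unit_id=str(uid),
                t=sub["t"].to_numpy(dtype=float),
                f=sub["f"].to_numpy(dtype=float),
                schedule=schedule,
            )
        )
    return traces


def write_traces_h5(traces: Sequence[UnitTrace], path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as h5:
        for tr in traces:
            grp = h5.create_group(tr.unit_id)
            grp.create_dataset("t", data=tr.t)
            grp.create_dataset("f", data=tr.f)
    return path


def read_traces_h5(path: str | Path, schedule: BlockSchedule | None = None) -> list[UnitTrace]:
    out = []
    with h5py.File(path, "r") as h5:
        for uid in h5:
            out.append(
                UnitTrace(
                    unit_id=uid,
                    t=np.asarray(h5[uid]["t"]),
                    f=np.asarray(h5[uid]["f"]),
                    schedule=schedule,
                )
            )
    return out


def write_schedule(schedule: BlockSchedule, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "experiment": schedule.experiment,
        "block_labels": schedule.block_labels,
        "washout_start_s": schedule.washout_start_s,
        "protocol": dataclasses.asdict(schedule.protocol),
        "trials": [dataclasses.asdict(tr) for tr in schedule.trials],
    }
    path.write_text(json.dumps(doc))
    return path


def read_schedule(path: str | Path) -> BlockSchedule:
    doc = json.loads(Path(path).read_text())
    return BlockSchedule(
        experiment=doc["experiment"],
        block_labels=list(doc["block_labels"]),
        trials=[ImagingTrial(**tr) for tr in doc["trials"]],
        protocol=ImagingProtocol(**doc["protocol"]),
        washout_start_s=doc["washout_start_s"],
    )


def write_params_yaml(
    path: str | Path,
    protocol: BehaviorProtocol | None = None,
    params: FishParams | None = None,
) -> Path:
    doc = {}
    if protocol is not None:
        doc["protocol"] = dataclasses.asdict(protocol)
    if params is not None:
        p = dataclasses.asdict(params)
        p["washout_accuracy_curve"] = [list(x) for x in p["washout_accuracy_curve"]]
        doc["fish_params"] = p
    path = Path(path)
    path.write_text(yaml.safe_dump(doc))
    return path


def read_params_yaml(path: str | Path) -> tuple[BehaviorProtocol, FishParams]:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    proto_doc = doc.get("protocol", {})
    if "conditions" in proto_doc:
        proto_doc["conditions"] = tuple(proto_doc["conditions"])
    params_doc = doc.get("fish_params", {})
    if "washout_accuracy_curve" in params_doc:
        params_doc["washout_accuracy_curve"] = tuple(
            tuple(x) for x in params_doc["washout_accuracy_curve"]
        )
    return BehaviorProtocol(**proto_doc), FishParams(**params_doc)


def write_rois(rois: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    rois.to_csv(path, index=False)
    return path


def read_rois(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
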
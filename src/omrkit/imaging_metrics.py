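"""Trial-response metric and per-unit indices for calcium imaging data.

The response metric is C - C0: the per-frame fluorescence minus the mean of
the 10 s pre-motion baseline window.  It is used instead of dF/F because the
baseline is frequently zero, which a ratio cannot handle; subtraction keeps
every trial finite.

Two per-unit indices are built on the per-trial average C - C0:

* responsiveness index — each trial's average divided by the unit's own
  maximum absolute trial average across the whole experiment, preserving
  sign, so net-increasing units peak at +1 and net-decreasing units at -1;
* direction-selectivity index (DSI) — for adjacent left-then-right trial
  pairs, the left-minus-right response difference, normalized per unit by its
  maximum absolute pair difference: +1 leftward-selective, -1 rightward.

Units whose maximum C - C0 exceeds 100 fluorescence units anywhere in the
experiment are "fittable" and eligible for kinetics fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .synthetic_imaging import BlockSchedule, ImagingProtocol, UnitTrace

#: fittable-unit threshold on max C - C0, strict inequality
FITTABLE_THRESHOLD = 100.0


@dataclass
class TrialResponse:
    trial_id: int
    stimulus: str
    block: str
    c0: float
    c_minus_c0: np.ndarray
    trial_mean: float


@dataclass
class ResponsivenessSeries:
    unit_id: str
    values: np.ndarray  # per-trial, in [-1, 1]
    sign_of_net_response: int  # +1, -1, or 0 for an unresponsive unit
    unresponsive: bool = False


@dataclass
class DSISeries:
    unit_id: str
    values: np.ndarray  # per-pair, in [-1, 1]
    pair_indices: list[tuple[int, int]]
    empty: bool = False


def extract_roi_traces(
    movie: np.ndarray, rois: pd.DataFrame, schedule: BlockSchedule | None = None
) -> list[UnitTrace]:
    """Per-ROI mean pixel value per frame (0-based half-open boxes)."""
    n_frames, h, w = movie.shape
    traces = []
    for row in rois.itertuples():
        if not (0 <= row.x0 < row.x1 <= w and 0 <= row.y0 < row.y1 <= h):
            raise ValueError(f"ROI {row.unit_id} out of frame bounds")
        f = movie[:, row.y0 : row.y1, row.x0 : row.x1].mean(axis=(1, 2))
        traces.append(
            UnitTrace(
                unit_id=str(row.unit_id),
                t=np.arange(n_frames, dtype=float),
                f=np.asarray(f, dtype=float),
                schedule=schedule,
            )
        )
    return traces


def segment_trials(trace: UnitTrace, schedule: BlockSchedule | None = None) -> np.ndarray:
    """Reshape a unit trace into (n_trials, frames_per_trial).

    Frames 0-9 are the pre-motion baseline, 10-39 motion, 40-59 post at the
    default 1 Hz protocol.  The trace must cover the full schedule.
    """
    schedule = schedule or trace.schedule
    if schedule is None:
        raise ValueError("a block schedule is required to segment trials")
    fpt = schedule.protocol.frames_per_trial
    n_trials = len(schedule.trials)
    if len(trace.f) < n_trials * fpt:
        raise ValueError(
            f"trace length {len(trace.f)} shorter than schedule "
            f"({n_trials} trials x {fpt} frames)"
        )
    return np.asarray(trace.f[: n_trials * fpt]).reshape(n_trials, fpt)


def compute_trial_response(
    frames: np.ndarray,
    protocol: ImagingProtocol | None = None,
    window: Literal["full", "motion"] = "full",
    trial_id: int = 0,
    stimulus: str = "",
    block: str = "",
) -> TrialResponse:
    """C - C0 for one trial.

    c0 is the mean over the pre-motion baseline frames; c_minus_c0 subtracts
    it from every frame (no division anywhere, so c0 = 0 is valid input);
    trial_mean averages c_minus_c0 over the full trial by default or the
    motion window only when ``window='motion'``.
    """
    protocol = protocol or ImagingProtocol()
    frames = np.asarray(frames, dtype=float)
    n_base = protocol.motion_onset_frame
    if len(frames) < n_base:
        raise ValueError("trial shorter than the baseline window")
    c0 = float(frames[:n_base].mean())
    cmc0 = frames - c0
    if window == "motion":
        sel = cmc0[protocol.motion_onset_frame : protocol.motion_offset_frame]
    else:
        sel = cmc0
    return TrialResponse(
        trial_id=trial_id,
        stimulus=stimulus,
        block=block,
        c0=c0,
        c_minus_c0=cmc0,
        trial_mean=float(sel.mean()),
    )


def trial_responses(
    trace: UnitTrace,
    schedule: BlockSchedule | None = None,
    window: Literal["full", "motion"] = "full",
) -> list[TrialResponse]:
    """C - C0 responses for every trial of a unit trace, in schedule order."""
    schedule = schedule or trace.schedule
    mat = segment_trials(trace, schedule)
    return [
        compute_trial_response(
            mat[i],
            schedule.protocol,
            window,
            trial_id=tr.index,
            stimulus=tr.stimulus,
            block=tr.block,
        )
        for i, tr in enumerate(schedule.trials)
    ]


def responsiveness_index(
    trial_means: Sequence[float], unit_id: str = ""
) -> ResponsivenessSeries:
    """Per-trial responsiveness normalized by the unit's own extreme.

    Each trial mean is divided by the maximum absolute trial mean across all
    the unit's trials, preserving sign; an all-zero unit returns an all-zero
    series flagged unresponsive.
    """
    vals = np.asarray(trial_means, dtype=float)
    if len(vals) == 0:
        raise ValueError("at least one trial is required")
    peak = np.abs(vals).max()
    net = float(vals.sum())
    if peak == 0.0:
        return ResponsivenessSeries(unit_id, np.zeros_like(vals), 0, True)
    return ResponsivenessSeries(
        unit_id, vals / peak, int(np.sign(net)) if net != 0 else 0, False
    )


def pair_left_right(stimuli: Sequence[str]) -> list[tuple[int, int]]:
    """Adjacent left-then-right trial pairs, in schedule order.

    Scans forward, pairing each (left, right) adjacency and skipping
    non-conforming adjacencies; paired trials are not reused.
    """
    pairs = []
    i = 0
    while i < len(stimuli) - 1:
        if stimuli[i] == "left" and stimuli[i + 1] == "right":
            pairs.append((i, i + 1))
            i += 2
        else:
            i += 1
    return pairs


def dsi_series(
    trial_means: Sequence[float],
    stimuli: Sequence[str],
    unit_id: str = "",
) -> DSISeries:
    """Direction-selectivity index per adjacent left-then-right trial pair.

    Raw difference d = mean(left) - mean(right) per pair, then per-unit
    normalization by the maximum |d|; values lie in [-1, 1] with +1 meaning
    leftward-selective.  A schedule without pairs yields an empty flagged
    series.
    """
    vals = np.asarray(trial_means, dtype=float)
    if len(vals) != len(stimuli):
        raise ValueError("trial_means and stimuli must have equal length")
    pairs = pair_left_right(stimuli)
    if not pairs:
        return DSISeries(unit_id, np.array([]), [], empty=True)
    diffs = np.array([vals[i] - vals[j] for i, j in pairs])
    peak = np.abs(diffs).max()
    if peak == 0.0:
        return DSISeries(unit_id, np.zeros_like(diffs), pairs, empty=False)
    return DSISeries(unit_id, diffs / peak, pairs, empty=False)


def max_c_minus_c0(trace: UnitTrace, schedule: BlockSchedule | None = None) -> float:
    """Maximum C - C0 over every frame of every trial in the experiment."""
    responses = trial_responses(trace, schedule)
    return float(max(r.c_minus_c0.max() for r in responses))


def filter_fittable(
    traces: Sequence[UnitTrace],
    schedule: BlockSchedule | None = None,
    threshold: float = FITTABLE_THRESHOLD,
) -> list[UnitTrace]:
    """Units whose maximum C - C0 strictly exceeds the threshold (100)."""
    return [tr for tr in traces if max_c_minus_c0(tr, schedule) > threshold]


def unit_index_table(
    traces: Sequence[UnitTrace],
    schedule: BlockSchedule | None = None,
    window: Literal["full", "motion"] = "full",
) -> pd.DataFrame:
    """Tidy per-unit index table: one row per trial (responsiveness) or pair
    (DSI), with block labels, for plotting and group summaries."""
    rows = []
    for tr in traces:
        sched = schedule or tr.schedule
        resp = trial_responses(tr, sched, window)
        means = [r.trial_mean for r in resp]
        stims = [r.stimulus for r in resp]
        blocks = [r.block for r in resp]
        ri = responsiveness_index(means, tr.unit_id)
        for k, v in enumerate(ri.values):
            rows.append(
                {"unit_id": tr.unit_id, "index": "responsiveness",
                 "trial_or_pair": k, "value": v, "block": blocks[k]}
            )
        ds = dsi_series(means, stims, tr.unit_id)
        for (i, _j), v in zip(ds.pair_indices, ds.values):
            rows.append(
                {"unit_id": tr.unit_id, "index": "dsi",
                 "trial_or_pair": i, "value": v, "block": blocks[i]}
            )
    return pd.DataFrame(
        rows, columns=["unit_id", "index", "trial_or_pair", "value", "block"]
    )
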
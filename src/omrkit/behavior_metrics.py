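"""Bout extraction and behavioral statistics for optomotor-response sessions.

Works on 100 Hz tracking (t, x, y, heading_deg).  Bouts are contiguous epochs
where angular or translational speed exceeds thresholds; every statistic of
the behavioral figures (turn-angle distributions, proportion of correct turns,
bout frequency, cumulative turn angle, performance versus time-in-stimulus and
versus trial ordinal) is computed from the resulting bout lists.

Group summaries are median plus interquartile range throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .synthetic_behavior import BehaviorSession, Trial

#: turn bouts with |angle| <= this are treated as forward swims and excluded
#: from the correctness denominator
FORWARD_BAND_DEG = 10.0


@dataclass(frozen=True)
class Bout:
    """One swim event: onset, duration, signed turn angle (positive = left)."""

    t_on: float
    duration: float
    turn_angle_deg: float
    displacement_cm: float = 0.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("bout duration must be > 0")


@dataclass(frozen=True)
class BoutThresholds:
    """Detection thresholds on smoothed angular / translational speed."""

    angular_speed_deg_s: float = 80.0
    translational_speed_cm_s: float = 0.4
    smooth_s: float = 0.03
    merge_gap_s: float = 0.03
    min_duration_s: float = 0.05


@dataclass
class TurnDistribution:
    """Normalized histogram of signed bout angles over [-180, 180)."""

    bin_edges_deg: np.ndarray
    probability: np.ndarray
    n_bouts: int

    @property
    def empty(self) -> bool:
        return self.n_bouts == 0


@dataclass
class CorrectCount:
    """Correct-turn tally for one fish/stimulus; fraction is None when the
    denominator (turn bouts outside the forward band) is empty."""

    n_correct: int
    n_total: int

    @property
    def fraction(self) -> float | None:
        if self.n_total == 0:
            return None
        return self.n_correct / self.n_total


def _uniform_dt(t: np.ndarray) -> float:
    dt = np.diff(t)
    if len(dt) == 0:
        raise ValueError("tracking must contain at least two samples")
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("tracking time base must be uniform")
    return float(dt[0])


def detect_bouts(
    tracking: pd.DataFrame, thresholds: BoutThresholds | None = None
) -> list[Bout]:
    """Detect swim bouts from uniform tracking.

    Angular speed (|d heading|/dt) and translational speed (|d position|/dt)
    are smoothed with a short boxcar; samples where either exceeds its
    threshold form candidate epochs, epochs closer than ``merge_gap_s`` are
    merged, and each epoch becomes one bout whose turn angle is the heading
    change from epoch start to end.
    """
    thr = thresholds or BoutThresholds()
    t = np.asarray(tracking["t"], dtype=float)
    dt = _uniform_dt(t)
    heading = np.asarray(tracking["heading_deg"], dtype=float)
    x = np.asarray(tracking["x"], dtype=float)
    y = np.asarray(tracking["y"], dtype=float)

    ang_speed = np.abs(np.diff(heading)) / dt
    trans_speed = np.hypot(np.diff(x), np.diff(y)) / dt
    win = max(1, int(round(thr.smooth_s / dt)))
    kernel = np.ones(win) / win
    ang_speed = np.convolve(ang_speed, kernel, mode="same")
    trans_speed = np.convolve(trans_speed, kernel, mode="same")

    active = (ang_speed > thr.angular_speed_deg_s) | (
        trans_speed > thr.translational_speed_cm_s
    )
    if not active.any():
        return []
    edges = np.diff(active.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    stops = list(np.flatnonzero(edges == -1) + 1)
    if active[0]:
        starts.insert(0, 0)
    if active[-1]:
        stops.append(len(active))

    # merge epochs separated by less than the merge gap
    merged: list[list[int]] = []
    gap_n = int(round(thr.merge_gap_s / dt))
    for s, e in zip(starts, stops):
        if merged and s - merged[-1][1] <= gap_n:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    min_n = int(round(thr.min_duration_s / dt))
    merged = [[s, e] for s, e in merged if e - s >= min_n]

    bouts = []
    # pad the epoch edges by the smoothing half-window so the start/end heading
    # samples sit outside the bout's own ramp
    pad = win // 2 + 1
    for s, e in merged:
        i0 = max(0, s - pad)
        i1 = min(len(heading) - 1, e + pad)
        angle = heading[i1] - heading[i0]
        disp = float(np.hypot(x[i1] - x[i0], y[i1] - y[i0]))
        bouts.append(
            Bout(
                t_on=float(t[s]),
                duration=float(max(e - s, 1) * dt),
                turn_angle_deg=float(angle),
                displacement_cm=disp,
            )
        )
    return bouts


def turn_distribution(
    bouts: Sequence[Bout], bin_width_deg: float = 5.0
) -> TurnDistribution:
    """Normalized histogram of signed bout angles, left-closed bins over
    [-180, 180).  Zero bouts yield an explicit empty marker, not NaNs."""
    n_bins = int(round(360.0 / bin_width_deg))
    edges = -180.0 + bin_width_deg * np.arange(n_bins + 1)
    if len(bouts) == 0:
        return TurnDistribution(edges, np.zeros(n_bins), 0)
    angles = np.array([b.turn_angle_deg for b in bouts])
    counts, _ = np.histogram(np.clip(angles, -180.0, 179.9999), bins=edges)
    return TurnDistribution(edges, counts / counts.sum(), len(bouts))


def group_turn_distribution(
    per_fish_bouts: Sequence[Sequence[Bout]], bin_width_deg: float = 5.0
) -> pd.DataFrame:
    """Per-bin median and quartiles of the turn-angle probability across fish."""
    dists = [turn_distribution(b, bin_width_deg) for b in per_fish_bouts]
    probs = np.vstack([d.probability for d in dists])
    edges = dists[0].bin_edges_deg
    return pd.DataFrame(
        {
            "bin_left_deg": edges[:-1],
            "bin_right_deg": edges[1:],
            "median": np.median(probs, axis=0),
            "q25": np.percentile(probs, 25, axis=0),
            "q75": np.percentile(probs, 75, axis=0),
        }
    )


def proportion_correct(
    bouts: Sequence[Bout],
    stimulus_label: str,
    forward_band_deg: float = FORWARD_BAND_DEG,
) -> CorrectCount:
    """Fraction of motion-phase turn bouts whose sign matches the stimulus.

    Positive angles are leftward, so a leftward stimulus makes positive turns
    correct.  Bouts with |angle| <= ``forward_band_deg`` are forward swims and
    excluded from the denominator (exact zeros likewise).
    """
    if stimulus_label not in ("left", "right"):
        raise ValueError("stimulus_label must be 'left' or 'right'")
    sign = 1.0 if stimulus_label == "left" else -1.0
    n_total = 0
    n_correct = 0
    for b in bouts:
        if abs(b.turn_angle_deg) <= forward_band_deg or b.turn_angle_deg == 0.0:
            continue
        n_total += 1
        if np.sign(b.turn_angle_deg) == sign:
            n_correct += 1
    return CorrectCount(n_correct, n_total)


def bout_frequency(bouts: Sequence[Bout], window_s: float) -> float:
    """Bouts per second over a window of the given duration."""
    if window_s <= 0:
        raise ValueError("window duration must be > 0")
    return len(bouts) / window_s


def annotate_bouts(
    bouts: Sequence[Bout], trials: Sequence["Trial"]
) -> pd.DataFrame:
    """Tidy table of bouts with trial index, stimulus, phase, and time since
    motion onset (NaN outside the motion phase)."""
    rows = []
    if not trials:
        return pd.DataFrame(
            columns=["t_on", "turn_angle_deg", "trial_index", "stimulus",
                     "phase", "t_since_motion_s"]
        )
    trial_dur = trials[0].t_end - trials[0].t_start
    for b in bouts:
        idx = min(int(b.t_on / trial_dur), len(trials) - 1)
        tr = trials[idx]
        if b.t_on < tr.t_motion_on:
            phase, tsm = "pre", np.nan
        elif b.t_on < tr.t_motion_off:
            phase, tsm = "motion", b.t_on - tr.t_motion_on
        else:
            phase, tsm = "post", np.nan
        rows.append(
            {
                "t_on": b.t_on,
                "turn_angle_deg": b.turn_angle_deg,
                "trial_index": tr.index,
                "stimulus": tr.stimulus,
                "phase": phase,
                "t_since_motion_s": tsm,
            }
        )
    return pd.DataFrame(rows)


def motion_phase_bouts(
    session: "BehaviorSession",
    bouts: Sequence[Bout] | None = None,
    stimuli: tuple[str, ...] = ("left", "right"),
) -> pd.DataFrame:
    """Bouts within the motion phase of trials with the given stimuli."""
    if bouts is None:
        bouts = detect_bouts(session.tracking)
    ann = annotate_bouts(bouts, session.trials)
    if ann.empty:
        return ann
    return ann[(ann["phase"] == "motion") & ann["stimulus"].isin(stimuli)]


def session_proportion_correct(
    session: "BehaviorSession",
    bouts: Sequence[Bout] | None = None,
    forward_band_deg: float = FORWARD_BAND_DEG,
) -> CorrectCount:
    """Pooled correct-turn tally over left and right motion phases."""
    ann = motion_phase_bouts(session, bouts)
    n_c = n_t = 0
    for stim in ("left", "right"):
        sub = ann[ann["stimulus"] == stim] if not ann.empty else ann
        sub_bouts = [
            Bout(t, 1e-3, a)
            for t, a in zip(sub.get("t_on", []), sub.get("turn_angle_deg", []))
        ]
        cc = proportion_correct(sub_bouts, stim, forward_band_deg)
        n_c += cc.n_correct
        n_t += cc.n_total
    return CorrectCount(n_c, n_t)


def cumulative_turn_angle(
    sessions: Sequence["BehaviorSession"],
    stimulus_label: str,
    per_session_bouts: Sequence[Sequence[Bout]] | None = None,
    dt_s: float = 1.0,
) -> pd.DataFrame:
    """Cumulative signed turn angle across trials of one stimulus.

    Per fish, the trials showing ``stimulus_label`` are concatenated on a
    common clock and the running sum of bout angles is evaluated on a
    ``dt_s`` grid; the group summary is the per-time median and quartiles.
    """
    curves = []
    grid = None
    for i, ses in enumerate(sessions):
        bouts = per_session_bouts[i] if per_session_bouts is not None else None
        if bouts is None:
            bouts = detect_bouts(ses.tracking)
        ann = annotate_bouts(bouts, ses.trials)
        sel = [tr for tr in ses.trials if tr.stimulus == stimulus_label]
        trial_dur = ses.protocol.trial_duration_s
        pos = {tr.index: j for j, tr in enumerate(sel)}
        total = len(sel) * trial_dur
        if grid is None:
            grid = np.arange(0.0, total + dt_s / 2, dt_s)
        if ann.empty:
            curves.append(np.zeros(len(grid)))
            continue
        sub = ann[ann["trial_index"].isin(pos)]
        t_cat = np.array(
            [
                pos[int(r.trial_index)] * trial_dur
                + (r.t_on - ses.trials[int(r.trial_index)].t_start)
                for r in sub.itertuples()
            ]
        )
        order = np.argsort(t_cat)
        t_cat = t_cat[order]
        csum = np.cumsum(np.asarray(sub["turn_angle_deg"])[order])
        idx = np.searchsorted(t_cat, grid, side="right") - 1
        curve = np.where(idx >= 0, csum[np.clip(idx, 0, None)], 0.0)
        curves.append(curve)
    arr = np.vstack(curves)
    return pd.DataFrame(
        {
            "t_s": grid,
            "median": np.median(arr, axis=0),
            "q25": np.percentile(arr, 25, axis=0),
            "q75": np.percentile(arr, 75, axis=0),
        }
    )


def performance_vs_time(
    sessions: Sequence["BehaviorSession"],
    bin_s: float = 1.0,
    per_session_bouts: Sequence[Sequence[Bout]] | None = None,
    forward_band_deg: float = FORWARD_BAND_DEG,
) -> pd.DataFrame:
    """Proportion correct binned by time since motion onset.

    Bouts of left/right motion phases are pooled into half-open [k, k+1) bins
    of ``bin_s``; the output is the per-bin median and quartiles across fish.
    Bins where a fish has no turn bouts stay undefined (NaN) for that fish and
    are excluded from the group summary, never interpolated.
    """
    if bin_s <= 0:
        raise ValueError("bin_s must be > 0")
    motion_s = sessions[0].protocol.motion_s
    n_bins = int(np.ceil(motion_s / bin_s))
    per_fish = np.full((len(sessions), n_bins), np.nan)
    for i, ses in enumerate(sessions):
        bouts = per_session_bouts[i] if per_session_bouts is not None else None
        ann = motion_phase_bouts(ses, bouts)
        if ann.empty:
            continue
        correct_sign = np.where(ann["stimulus"] == "left", 1.0, -1.0)
        angles = np.asarray(ann["turn_angle_deg"], dtype=float)
        keep = np.abs(angles) > forward_band_deg
        bins = (np.asarray(ann["t_since_motion_s"]) // bin_s).astype(int)
        for k in range(n_bins):
            m = keep & (bins == k)
            if m.sum() == 0:
                continue
            per_fish[i, k] = np.mean(np.sign(angles[m]) == correct_sign[m])
    with np.errstate(all="ignore"):
        return pd.DataFrame(
            {
                "bin_start_s": np.arange(n_bins) * bin_s,
                "median": np.nanmedian(per_fish, axis=0),
                "q25": np.nanpercentile(per_fish, 25, axis=0),
                "q75": np.nanpercentile(per_fish, 75, axis=0),
                "n_fish": np.sum(~np.isnan(per_fish), axis=0),
            }
        )


def performance_vs_trial(
    sessions: Sequence["BehaviorSession"],
    per_session_bouts: Sequence[Sequence[Bout]] | None = None,
    forward_band_deg: float = FORWARD_BAND_DEG,
) -> pd.DataFrame:
    """Proportion correct per trial ordinal (directional trials only).

    Sessions must share schedule length; the ordinal is the position of the
    trial among each fish's left/right trials, so randomization of stimulus
    order does not misalign fish.
    """
    n_trials = len(sessions[0].trials)
    if any(len(s.trials) != n_trials for s in sessions):
        raise ValueError("sessions must share schedule length")
    n_dir = sum(1 for tr in sessions[0].trials if tr.stimulus in ("left", "right"))
    per_fish = np.full((len(sessions), n_dir), np.nan)
    for i, ses in enumerate(sessions):
        bouts = per_session_bouts[i] if per_session_bouts is not None else None
        ann = motion_phase_bouts(ses, bouts)
        ordinals = {
            tr.index: j
            for j, tr in enumerate(
                t for t in ses.trials if t.stimulus in ("left", "right")
            )
        }
        if ann.empty:
            continue
        for idx, sub in ann.groupby("trial_index"):
            angles = np.asarray(sub["turn_angle_deg"], dtype=float)
            keep = np.abs(angles) > forward_band_deg
            if keep.sum() == 0:
                continue
            sign = 1.0 if sub["stimulus"].iloc[0] == "left" else -1.0
            per_fish[i, ordinals[int(idx)]] = np.mean(
                np.sign(angles[keep]) == sign
            )
    with np.errstate(all="ignore"):
        return pd.DataFrame(
            {
                "trial_ordinal": np.arange(n_dir),
                "median": np.nanmedian(per_fish, axis=0),
                "q25": np.nanpercentile(per_fish, 25, axis=0),
                "q75": np.nanpercentile(per_fish, 75, axis=0),
                "n_fish": np.sum(~np.isnan(per_fish), axis=0),
            }
        )
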
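"""Trial-structured synthetic calcium imaging under anesthesia and washout.

Generates 1 Hz fluorescence traces for imaged "units" (clusters of 1-5
similarly tuned neurons) over multi-hour block schedules: 60 s trials
(10 s static / 30 s motion / 20 s static) with left/right gratings, recorded
in 1 h blocks that are either baseline, tricaine anesthesia (activity fully
silenced), or washout (activity returning along a logistic in time).

A unit's drive rises toward its amplitude with an onset time constant during
preferred-direction motion and decays with an offset constant afterwards; the
drive is convolved with a slow-indicator impulse response (single-exponential,
GCaMP6s-like), multiplied by the anesthesia gain, and sampled by averaging
over 1 s frames.  Frame k covers [k, k+1) s; motion starts at trial frame 10.

Optional rendering draws each unit as Gaussian blobs inside an ROI box of a
TIFF movie, so ROI-mean extraction can be exercised end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

TUNINGS = ("left_selective", "right_selective", "motion_selective", "suppressed")
REGIONS = ("tectum", "pretectum", "hindbrain")

#: indicator impulse-response decay constant (s); config field, GCaMP6s-like
KERNEL_TAU_S = 1.8


@dataclass(frozen=True)
class ImagingProtocol:
    """60 s visual-stimulation trials recorded at 1 Hz in 1 h blocks."""

    frame_rate_hz: float = 1.0
    static_pre_s: float = 10.0
    motion_s: float = 30.0
    static_post_s: float = 20.0
    block_length_h: float = 1.0
    kernel_tau_s: float = KERNEL_TAU_S

    def __post_init__(self) -> None:
        if self.trial_duration_s != 60.0:
            raise ValueError("trial phases must sum to 60 s")
        n = self.block_length_h * 3600.0 / self.trial_duration_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("block must hold an integer number of trials")

    @property
    def trial_duration_s(self) -> float:
        return self.static_pre_s + self.motion_s + self.static_post_s

    @property
    def trials_per_block(self) -> int:
        return int(round(self.block_length_h * 3600.0 / self.trial_duration_s))

    @property
    def frames_per_trial(self) -> int:
        return int(round(self.trial_duration_s * self.frame_rate_hz))

    @property
    def motion_onset_frame(self) -> int:
        return int(round(self.static_pre_s * self.frame_rate_hz))

    @property
    def motion_offset_frame(self) -> int:
        return int(round((self.static_pre_s + self.motion_s) * self.frame_rate_hz))


@dataclass(frozen=True)
class UnitParams:
    """Ground-truth generative parameters of one imaged unit."""

    unit_id: str
    region: str = "tectum"
    tuning: str = "left_selective"
    amplitude: float = 300.0
    tau_on_s: float = 1.0
    tau_off_s: float = 4.0
    recovery_x0_min: float = 60.0
    recovery_k_min: float = 15.0
    baseline_f: float = 50.0
    noise_sd: float = 5.0
    n_neurons: int = 3
    tricaine_flicker_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.tuning not in TUNINGS:
            raise ValueError(f"unknown tuning {self.tuning!r}")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if min(self.tau_on_s, self.tau_off_s, self.recovery_k_min) <= 0:
            raise ValueError("time constants must be > 0")
        if not 1 <= self.n_neurons <= 5:
            raise ValueError("n_neurons must lie in [1, 5]")


@dataclass(frozen=True)
class ImagingTrial:
    index: int
    block: str
    stimulus: str  # "left" | "right"
    t_start_s: float


@dataclass
class BlockSchedule:
    experiment: str
    block_labels: list[str]
    trials: list[ImagingTrial]
    protocol: ImagingProtocol
    washout_start_s: float  # time at which the first washout block begins

    @property
    def total_duration_s(self) -> float:
        return len(self.block_labels) * self.protocol.block_length_h * 3600.0

    @property
    def stimuli(self) -> list[str]:
        return [tr.stimulus for tr in self.trials]


@dataclass
class UnitTrace:
    """One unit's 1 Hz fluorescence trace with its schedule and, for synthetic
    data, the ground-truth parameters that generated it."""

    unit_id: str
    t: np.ndarray  # frame start times (s); frame k covers [k, k+1)
    f: np.ndarray
    schedule: BlockSchedule
    truth: UnitParams | None = None
    flags: tuple[str, ...] = ()


def build_block_schedule(
    experiment: Literal["acute", "lifetime"],
    n_washout_blocks: int,
    protocol: ImagingProtocol | None = None,
    seed: int = 0,
) -> BlockSchedule:
    """Block and stimulus schedule for an anesthesia-washout experiment.

    acute: baseline, tricaine, washout_1..n; lifetime: tricaine, washout_1..n
    (tricaine-reared fish have no awake baseline).  Per-block stimulus labels
    are balanced left/right pairs in shuffled order, guaranteeing adjacent
    left-then-right pairs for the direction-selectivity pairing.
    """
    if n_washout_blocks < 1:
        raise ValueError("n_washout_blocks must be >= 1")
    if experiment not in ("acute", "lifetime"):
        raise ValueError("experiment must be 'acute' or 'lifetime'")
    protocol = protocol or ImagingProtocol()
    labels = (["baseline"] if experiment == "acute" else []) + ["tricaine"]
    labels += [f"washout_{k + 1}" for k in range(n_washout_blocks)]
    rng = np.random.default_rng(seed)
    n_pairs = protocol.trials_per_block // 2
    trials: list[ImagingTrial] = []
    t = 0.0
    idx = 0
    for lab in labels:
        pairs = [("left", "right")] * ((n_pairs + 1) // 2) + [
            ("right", "left")
        ] * (n_pairs // 2)
        rng.shuffle(pairs)
        stims = [s for p in pairs for s in p]
        if len(stims) < protocol.trials_per_block:  # odd trial count
            stims.append("left")
        for s in stims:
            trials.append(ImagingTrial(idx, lab, s, t))
            idx += 1
            t += protocol.trial_duration_s
    washout_start = labels.index("washout_1") * protocol.block_length_h * 3600.0
    return BlockSchedule(experiment, labels, trials, protocol, washout_start)


def anesthesia_gain(
    times_s: np.ndarray, schedule: BlockSchedule, params: UnitParams
) -> np.ndarray:
    """Multiplicative activity gain: 1 at baseline, 0 under tricaine, and a
    logistic of washout time (minutes) with midpoint ``recovery_x0_min`` and
    time constant ``recovery_k_min`` during washout."""
    block_len = schedule.protocol.block_length_h * 3600.0
    block_idx = np.clip(
        (times_s // block_len).astype(int), 0, len(schedule.block_labels) - 1
    )
    labels = np.array(schedule.block_labels)[block_idx]
    gain = np.ones_like(times_s, dtype=float)
    gain[labels == "tricaine"] = 0.0
    in_washout = np.char.startswith(labels.astype(str), "washout")
    t_min = (times_s[in_washout] - schedule.washout_start_s) / 60.0
    gain[in_washout] = 1.0 / (
        1.0 + np.exp(-(t_min - params.recovery_x0_min) / params.recovery_k_min)
    )
    return gain


def _drive(
    params: UnitParams, schedule: BlockSchedule, dt: float
) -> np.ndarray:
    """Piecewise-exponential drive on a fine time grid, segment by segment.

    Reference implementation of the drive equation alone (no kernel); the
    simulator itself uses the analytic cascade in _convolved_signal.
    """
    proto = schedule.protocol
    n = int(round(len(schedule.trials) * proto.trial_duration_s / dt))
    out = np.empty(n)
    r0 = 0.0
    pre_n = int(round(proto.static_pre_s / dt))
    mot_n = int(round(proto.motion_s / dt))
    post_n = int(round(proto.static_post_s / dt))
    t_pre = np.arange(1, pre_n + 1) * dt
    t_mot = np.arange(1, mot_n + 1) * dt
    t_post = np.arange(1, post_n + 1) * dt
    pos = 0
    for tr in schedule.trials:
        if params.tuning == "motion_selective":
            driven = True
        elif params.tuning == "suppressed":
            driven = True
        else:
            driven = tr.stimulus == (
                "left" if params.tuning == "left_selective" else "right"
            )
        target = (
            -params.amplitude if params.tuning == "suppressed" else params.amplitude
        )
        # pre: decay toward 0
        seg = r0 * np.exp(-t_pre / params.tau_off_s)
        out[pos : pos + pre_n] = seg
        r0 = seg[-1] if pre_n else r0
        pos += pre_n
        # motion: rise toward target if driven, else keep decaying
        if driven:
            seg = target + (r0 - target) * np.exp(-t_mot / params.tau_on_s)
        else:
            seg = r0 * np.exp(-t_mot / params.tau_off_s)
        out[pos : pos + mot_n] = seg
        r0 = seg[-1] if mot_n else r0
        pos += mot_n
        # post: decay toward 0
        seg = r0 * np.exp(-t_post / params.tau_off_s)
        out[pos : pos + post_n] = seg
        r0 = seg[-1] if post_n else r0
        pos += post_n
    return out


def _segments(params: UnitParams, schedule: BlockSchedule):
    """(n_samples target, tau_drive, duration) triples per trial phase."""
    proto = schedule.protocol
    target = -params.amplitude if params.tuning == "suppressed" else params.amplitude
    for tr in schedule.trials:
        if params.tuning in ("motion_selective", "suppressed"):
            driven = True
        else:
            driven = tr.stimulus == (
                "left" if params.tuning == "left_selective" else "right"
            )
        yield proto.static_pre_s, 0.0, params.tau_off_s
        if driven:
            yield proto.motion_s, target, params.tau_on_s
        else:
            yield proto.motion_s, 0.0, params.tau_off_s
        yield proto.static_post_s, 0.0, params.tau_off_s


def _convolved_signal(
    params: UnitParams, schedule: BlockSchedule, dt: float
) -> np.ndarray:
    """Indicator-kernel-convolved drive at midpoint sample times, exact.

    Within each phase the drive is A + (r0 - A) e^{-t/tau_d}; the kernel ODE
    tau_k y' = r - y then has the closed-form solution
    y(t) = A + beta e^{-t/tau_d} + C e^{-t/tau_k} with
    beta = (r0 - A) tau_d / (tau_d - tau_k) and C = y0 - A - beta, so the
    cascade is integrated segment by segment without discretization error.
    """
    tau_k = schedule.protocol.kernel_tau_s
    out = []
    r0 = 0.0
    y0 = 0.0
    for dur, target, tau_d in _segments(params, schedule):
        if abs(tau_d - tau_k) < 1e-9 * tau_k:
            tau_d = tau_k * (1.0 + 1e-6)  # avoid the degenerate double pole
        n = int(round(dur / dt))
        t = (np.arange(n) + 0.5) * dt
        beta = (r0 - target) * tau_d / (tau_d - tau_k)
        c = y0 - target - beta
        out.append(target + beta * np.exp(-t / tau_d) + c * np.exp(-t / tau_k))
        r0 = target + (r0 - target) * math.exp(-dur / tau_d)
        y0 = target + beta * math.exp(-dur / tau_d) + c * math.exp(-dur / tau_k)
    return np.concatenate(out)


def simulate_unit_trace(
    params: UnitParams,
    schedule: BlockSchedule,
    seed: int = 0,
    dt: float = 0.1,
    gain_fn: Callable[[np.ndarray], np.ndarray] | None = None,
) -> UnitTrace:
    """Simulate one unit's 1 Hz fluorescence trace over the block schedule.

    fluorescence = baseline_f * (1 + tricaine flicker)
                   + gain(t) * (indicator kernel (*) drive) + Gaussian noise.

    The drive/kernel cascade is integrated analytically segment by segment
    (no discretization error); ``dt`` only sets the sampling used for the
    anesthesia gain and the 1 s frame averaging.  ``gain_fn`` replaces the
    logistic anesthesia gain (used for the model-mismatch robustness checks
    with a piecewise-linear gain).
    """
    proto = schedule.protocol
    rng = np.random.default_rng(seed)
    conv = _convolved_signal(params, schedule, dt)
    n_fine = len(conv)
    t_fine = (np.arange(n_fine) + 0.5) * dt
    if gain_fn is not None:
        gain = np.asarray(gain_fn(t_fine), dtype=float)
    else:
        gain = anesthesia_gain(t_fine, schedule, params)
    signal = gain * conv

    frame_len = int(round(1.0 / (proto.frame_rate_hz * dt)))
    n_frames = n_fine // frame_len
    f = signal[: n_frames * frame_len].reshape(n_frames, frame_len).mean(axis=1)

    f = f + params.baseline_f
    if params.tricaine_flicker_sd > 0:
        block_len = proto.block_length_h * 3600.0
        t_frames = np.arange(n_frames) / proto.frame_rate_hz
        bidx = np.clip(
            (t_frames // block_len).astype(int), 0, len(schedule.block_labels) - 1
        )
        in_tric = np.array(
            [schedule.block_labels[i] == "tricaine" for i in bidx]
        )
        flick = rng.normal(0.0, params.tricaine_flicker_sd, n_frames)
        f = f * np.where(in_tric, 1.0 + flick, 1.0)
    if params.noise_sd > 0:
        f = f + rng.normal(0.0, params.noise_sd, n_frames)

    flags = ()
    if params.tau_on_s < 1.0 / proto.frame_rate_hz:
        flags = ("sub-frame, unrecoverable",)
    return UnitTrace(
        unit_id=params.unit_id,
        t=np.arange(n_frames) / proto.frame_rate_hz,
        f=f,
        schedule=schedule,
        truth=params,
        flags=flags,
    )


def simulate_population(
    n_units: int,
    experiment: Literal["acute", "lifetime"],
    n_washout_blocks: int = 3,
    seed: int = 0,
    protocol: ImagingProtocol | None = None,
    recovery_x0_mean_min: float | None = None,
    recovery_x0_sd_min: float = 12.0,
    frac_subthreshold: float = 0.15,
    dt: float = 0.1,
) -> list[UnitTrace]:
    """A population of units with mixed tunings over one block schedule.

    Tuning mix 30/30/25/15% (left/right/motion/suppressed); onset constants
    log-uniform on 0.2-3 s, offset constants log-uniform on 2-20 s; recovery
    midpoints Gaussian around 45 min (acute) or 90 min (lifetime); a
    ``frac_subthreshold`` fraction of units gets a small amplitude so it fails
    the fittable-unit filter.
    """
    rng = np.random.default_rng(seed)
    schedule = build_block_schedule(
        experiment, n_washout_blocks, protocol, seed=seed
    )
    if recovery_x0_mean_min is None:
        recovery_x0_mean_min = 45.0 if experiment == "acute" else 90.0
    tuning_choices = rng.choice(
        TUNINGS, size=n_units, p=[0.30, 0.30, 0.25, 0.15]
    )
    traces = []
    for i in range(n_units):
        sub = rng.uniform() < frac_subthreshold
        params = UnitParams(
            unit_id=f"u{i:04d}",
            region=REGIONS[i % len(REGIONS)],
            tuning=str(tuning_choices[i]),
            amplitude=float(rng.uniform(30, 60) if sub else rng.uniform(200, 500)),
            tau_on_s=float(np.exp(rng.uniform(np.log(0.2), np.log(3.0)))),
            tau_off_s=float(np.exp(rng.uniform(np.log(2.0), np.log(20.0)))),
            recovery_x0_min=float(
                max(5.0, rng.normal(recovery_x0_mean_min, recovery_x0_sd_min))
            ),
            recovery_k_min=float(max(3.0, rng.normal(15.0, 3.0))),
            baseline_f=float(rng.uniform(20, 80)),
            noise_sd=5.0,
            n_neurons=int(rng.integers(1, 6)),
        )
        traces.append(
            simulate_unit_trace(
                params, schedule, seed=int(rng.integers(0, 2**31 - 1)), dt=dt
            )
        )
    return traces


def render_movie(
    units: Sequence[UnitTrace],
    field_shape: tuple[int, int] = (64, 64),
    roi_size: int = 10,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render unit traces as a movie of Gaussian blobs inside ROI boxes.

    Units are placed on a non-overlapping grid of ``roi_size`` boxes; each
    unit is drawn as its ``n_neurons`` Gaussian blobs whose intensity scales
    with the unit's f(t), plus pixel noise.  Returns (stack, ROI table) with
    0-based half-open box coordinates.  An empty unit list yields a pure
    noise stack.
    """
    h, w = field_shape
    ncols, nrows = w // roi_size, h // roi_size
    if units and len(units) > ncols * nrows:
        raise ValueError("field too small for requested units")
    rng = np.random.default_rng(seed)
    n_frames = len(units[0].f) if units else 10
    stack = rng.normal(0.0, noise_sd, (n_frames, h, w)).astype(np.float32)
    yy, xx = np.mgrid[0:roi_size, 0:roi_size]
    rows = []
    for k, u in enumerate(units):
        r, c = divmod(k, ncols)
        y0, x0 = r * roi_size, c * roi_size
        n_blobs = u.truth.n_neurons if u.truth is not None else 3
        footprint = np.zeros((roi_size, roi_size))
        for _ in range(n_blobs):
            cy = rng.uniform(2, roi_size - 2)
            cx = rng.uniform(2, roi_size - 2)
            sd = rng.uniform(0.8, 1.4)
            footprint += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sd**2))
        footprint /= footprint.mean()  # ROI mean equals the unit's f exactly
        stack[:, y0 : y0 + roi_size, x0 : x0 + roi_size] += (
            u.f[:, None, None] * footprint[None, :, :]
        ).astype(np.float32)
        rows.append(
            {"unit_id": u.unit_id, "x0": x0, "y0": y0,
             "x1": x0 + roi_size, "y1": y0 + roi_size}
        )
    rois = pd.DataFrame(rows, columns=["unit_id", "x0", "y0", "x1", "y1"])
    return stack, rois
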
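"""Agent-based closed-loop simulator of larval-zebrafish optomotor behavior.

Produces 100 Hz tracking sessions (time, position, heading) for a virtual
freely swimming fish presented with whole-field moving gratings, under the
standard trial protocol (5 s static / 10 s motion / 5 s static, 30 randomized
sets of five stimulus conditions).  Rearing/treatment conditions modulate the
turn-direction bias and the bout rate: dark- and strobe-rearing lower the
asymptotic accuracy slightly, rearing under tricaine anesthesia caps the bout
rate at a fraction of control and sets accuracy by washout duration, and acute
tricaine silences bouts which then recover with an exponential time constant.

The closed loop is emulated rather than rendered: gratings are locked to the
fish's body axis, so stimulus direction is defined in the fish frame and is
unaffected by heading changes; no visual scene is simulated.

Sign convention (used throughout the package): positive angles are leftward
(counter-clockwise) turns; a leftward-moving stimulus makes positive turns
"correct".
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .behavior_metrics import Bout

CONDITION_LABELS = ("control", "dark", "strobe", "tricaine_reared", "acute_tricaine")
STIMULUS_LABELS = ("none", "forward", "backward", "left", "right")

#: duration of the smooth heading ramp a bout deposits in the tracking trace
BOUT_RAMP_S = 0.15
#: hard refractory period between bout onsets
REFRACTORY_S = 0.20


@dataclass(frozen=True)
class BehaviorProtocol:
    """Stimulus protocol for one free-swimming session.

    Each trial is ``pre_static_s`` of static grating, ``motion_s`` of grating
    motion at ``grating_speed_cm_s``, then ``post_static_s`` static.  A session
    is ``n_sets`` sets, each containing every condition exactly once in
    randomized order.
    """

    pre_static_s: float = 5.0
    motion_s: float = 10.0
    post_static_s: float = 5.0
    grating_speed_cm_s: float = 1.0
    spatial_period_cm: float = 1.0
    n_sets: int = 30
    conditions: tuple[str, ...] = STIMULUS_LABELS
    sample_rate_hz: float = 100.0

    def __post_init__(self) -> None:
        for name in ("pre_static_s", "motion_s", "post_static_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")
        if self.n_sets < 0:
            raise ValueError("n_sets must be >= 0")
        unknown = set(self.conditions) - set(STIMULUS_LABELS)
        if unknown:
            raise ValueError(f"unknown stimulus conditions: {sorted(unknown)}")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("conditions must be unique")

    @property
    def trial_duration_s(self) -> float:
        return self.pre_static_s + self.motion_s + self.post_static_s


@dataclass(frozen=True)
class FishParams:
    """Generative parameters of the virtual fish.

    Bout rates are 0.5 Hz without motion and 1 Hz during motion, matching
    free-swimming larvae.  ``p_correct`` is the asymptotic probability that a
    turn bout matches the stimulus direction (0.967 for normally reared fish).
    Turn angles are drawn from a forward/turn mixture; ``tau_int_s`` sets how
    quickly the direction bias builds up after motion onset (leaky evidence
    accumulator).  Anesthesia-related fields: ``tau_rec_min`` is the bout-rate
    recovery constant after acute tricaine, ``washout_accuracy_curve`` maps
    washout duration (hours) to asymptotic accuracy for tricaine-reared fish,
    and ``rate_cap_fraction`` caps their bout rate relative to control.
    """

    rate_nostim_hz: float = 0.5
    rate_stim_hz: float = 1.0
    p_correct: float = 0.967
    sigma_forward_deg: float = 3.5
    mu_turn_deg: float = 32.0
    sigma_turn_deg: float = 12.0
    w_turn_nostim: float = 0.4
    w_turn_stim: float = 0.6
    tau_int_s: float = 0.1
    tau_rec_min: float = 25.0
    washout_accuracy_curve: tuple[tuple[float, float], ...] = (
        (0.0, 0.55),
        (2.0, 0.75),
        (6.0, 0.89),
        (24.0, 0.93),
    )
    rate_cap_fraction: float = 0.5
    displacement_cm: float = 0.12
    heading_noise_deg: float = 0.1
    position_noise_cm: float = 0.0005

    def __post_init__(self) -> None:
        if not (0.5 <= self.p_correct <= 1.0):
            raise ValueError("p_correct must lie in [0.5, 1]")
        if self.rate_nostim_hz < 0 or self.rate_stim_hz < 0:
            raise ValueError("bout rates must be >= 0")
        if self.tau_int_s <= 0 or self.tau_rec_min <= 0:
            raise ValueError("time constants must be > 0")
        if not (0 <= self.w_turn_nostim <= 1 and 0 <= self.w_turn_stim <= 1):
            raise ValueError("turn-bout weights must lie in [0, 1]")
        curve = tuple(sorted(self.washout_accuracy_curve))
        accs = [a for _, a in curve]
        if any(b < a for a, b in zip(accs, accs[1:])):
            raise ValueError("washout_accuracy_curve must be nondecreasing")
        object.__setattr__(self, "washout_accuracy_curve", curve)


@dataclass(frozen=True)
class Trial:
    """One stimulus presentation: [t_start, t_end) with motion in the middle."""

    index: int
    stimulus: str
    t_start: float
    t_motion_on: float
    t_motion_off: float
    t_end: float


@dataclass
class BehaviorSession:
    fish_id: str
    condition_label: str
    washout_h: float | None
    trials: list[Trial]
    tracking: pd.DataFrame  # columns t, x, y, heading_deg
    truth_bouts: list[Bout]
    seed: int
    protocol: BehaviorProtocol
    params: FishParams  # effective (washout-modulated) parameters

    @property
    def duration_s(self) -> float:
        return self.trials[-1].t_end if self.trials else 0.0


def build_trial_schedule(protocol: BehaviorProtocol, seed: int) -> list[Trial]:
    """Randomized trial order: each set contains every condition exactly once."""
    rng = np.random.default_rng(seed)
    order: list[str] = []
    for _ in range(protocol.n_sets):
        block = list(protocol.conditions)
        rng.shuffle(block)
        order.extend(block)
    trials = []
    dur = protocol.trial_duration_s
    for i, stim in enumerate(order):
        t0 = i * dur
        trials.append(
            Trial(
                index=i,
                stimulus=stim,
                t_start=t0,
                t_motion_on=t0 + protocol.pre_static_s,
                t_motion_off=t0 + protocol.pre_static_s + protocol.motion_s,
                t_end=t0 + dur,
            )
        )
    return trials


def interp_washout_accuracy(params: FishParams, washout_h: float) -> float:
    """Linear interpolation of asymptotic accuracy on the washout curve.

    Clamped to the end anchors outside the curve's range.
    """
    hours = np.array([h for h, _ in params.washout_accuracy_curve])
    accs = np.array([a for _, a in params.washout_accuracy_curve])
    return float(np.interp(washout_h, hours, accs))


def apply_washout_modulation(
    params: FishParams, condition_label: str, washout_h: float | None
) -> FishParams:
    """Effective fish parameters for a rearing/treatment condition.

    control/dark/strobe are returned unchanged (their accuracy handling is a
    per-trial target, see :func:`trial_p_targets`); tricaine_reared fish get
    ``p_correct`` from the washout-accuracy curve and bout rates capped at
    ``rate_cap_fraction`` of control; acute_tricaine is unchanged here because
    its bout-rate recovery is a within-session gain applied by
    :func:`simulate_session`.
    """
    if condition_label not in CONDITION_LABELS:
        raise ValueError(
            f"unknown condition_label {condition_label!r}; "
            f"expected one of {CONDITION_LABELS}"
        )
    if condition_label == "tricaine_reared":
        if washout_h is None or washout_h < 0:
            raise ValueError("tricaine_reared requires washout_h >= 0")
        return dataclasses.replace(
            params,
            p_correct=interp_washout_accuracy(params, washout_h),
            rate_nostim_hz=params.rate_nostim_hz * params.rate_cap_fraction,
            rate_stim_hz=params.rate_stim_hz * params.rate_cap_fraction,
        )
    if condition_label == "acute_tricaine" and washout_h is not None and washout_h < 0:
        raise ValueError("washout_h must be >= 0")
    return params


# Dark- and strobe-reared fish: asymptotic accuracy and a short transient over
# the first trials (first-trial accuracy ~0.94, settling within ~3 trials).
_REARING_TRANSIENTS = {
    "dark": (0.94, 0.949, 3.0),
    "strobe": (0.94, 0.95, 3.0),
}


def trial_p_targets(
    params: FishParams, condition_label: str, n_trials: int
) -> np.ndarray:
    """Per-trial asymptotic turn-accuracy targets.

    Dark/strobe rearing shows a small transient over the first trials; all
    other conditions use the (washout-modulated) ``p_correct`` throughout.
    """
    if condition_label in _REARING_TRANSIENTS:
        p0, p_inf, tau_trials = _REARING_TRANSIENTS[condition_label]
        k = np.arange(n_trials)
        return p_inf - (p_inf - p0) * np.exp(-k / tau_trials)
    return np.full(n_trials, params.p_correct)


def evidence_trace(
    trials: Sequence[Trial], times: np.ndarray, tau_int_s: float
) -> np.ndarray:
    """Leaky evidence accumulator E at arbitrary times.

    dE/dt = (s(t) - E)/tau, with s = 1 during the motion phase of any
    moving-grating trial and 0 otherwise.  Solved analytically phase by phase,
    then evaluated at ``times`` (must be sorted).
    """
    # phase boundaries: (t_on, t_off) motion intervals of moving trials
    segs: list[tuple[float, float, float]] = []  # (t0, t1, s)
    t_prev = 0.0
    for tr in trials:
        drive = 1.0 if tr.stimulus in ("forward", "backward", "left", "right") else 0.0
        segs.append((t_prev, tr.t_motion_on, 0.0))
        segs.append((tr.t_motion_on, tr.t_motion_off, drive))
        t_prev = tr.t_motion_off
    if trials:
        segs.append((t_prev, trials[-1].t_end, 0.0))
    out = np.empty(len(times))
    e0 = 0.0
    i = 0
    for t0, t1, s in segs:
        while i < len(times) and times[i] < t1:
            out[i] = s + (e0 - s) * math.exp(-(times[i] - t0) / tau_int_s)
            i += 1
        e0 = s + (e0 - s) * math.exp(-(t1 - t0) / tau_int_s)
    while i < len(times):  # times at/after the session end
        out[i] = e0
        i += 1
    return out


def _draw_bout_times(
    rng: np.random.Generator,
    duration_s: float,
    rate_at: Callable[[float], float],
    rate_max_hz: float,
) -> np.ndarray:
    """Inhomogeneous renewal process: thinning with a hard refractory period.

    The instantaneous hazard after the refractory period is inflated to
    r/(1 - r*refractory) so the long-run bout rate matches r(t) exactly when
    the rate is locally constant.
    """
    if rate_max_hz <= 0:
        return np.array([])
    lam_max = rate_max_hz / max(1.0 - rate_max_hz * REFRACTORY_S, 1e-9)
    times = []
    t = 0.0
    last = -np.inf
    while True:
        t += rng.exponential(1.0 / lam_max)
        if t >= duration_s:
            break
        if t < last + REFRACTORY_S:
            continue
        r = rate_at(t)
        if r <= 0:
            continue
        lam = r / max(1.0 - r * REFRACTORY_S, 1e-9)
        if rng.uniform() < lam / lam_max:
            times.append(t)
            last = t
    return np.asarray(times)


def simulate_session(
    protocol: BehaviorProtocol,
    params: FishParams,
    condition_label: str = "control",
    washout_h: float | None = None,
    seed: int = 0,
    fish_id: str | None = None,
    gain_override: float | Callable[[np.ndarray], np.ndarray] | None = None,
) -> BehaviorSession:
    """Simulate one closed-loop free-swimming session.

    Bout onsets follow an inhomogeneous renewal process whose rate is the
    stimulus-dependent base rate times an anesthesia gain g(t) (1 everywhere
    except acute tricaine, where g = 1 - exp(-t/tau_rec)).  Each bout draws a
    signed turn angle from a forward/turn mixture; during left/right motion
    the turn component matches the stimulus with probability
    p_eff(t) = 0.5 + (p_target - 0.5) * E(t), E the leaky accumulator.
    Heading and position are integrated into 100 Hz tracking with smooth
    150 ms bout ramps.  ``gain_override`` fixes or replaces the anesthesia
    gain (testing hook).
    """
    if condition_label not in CONDITION_LABELS:
        raise ValueError(
            f"unknown condition_label {condition_label!r}; "
            f"expected one of {CONDITION_LABELS}"
        )
    eff = apply_washout_modulation(params, condition_label, washout_h)
    ss = np.random.SeedSequence(seed)
    sched_seed, dyn_seed = ss.spawn(2)
    trials = build_trial_schedule(
        protocol, int(sched_seed.generate_state(1, np.uint32)[0])
    )
    rng = np.random.default_rng(dyn_seed)
    duration = trials[-1].t_end if trials else 0.0
    dt = 1.0 / protocol.sample_rate_hz
    n = int(round(duration / dt))
    t_grid = np.arange(n) * dt

    trial_dur = protocol.trial_duration_s

    def trial_of(t: float) -> Trial:
        return trials[min(int(t / trial_dur), len(trials) - 1)]

    def gain(t: float) -> float:
        if gain_override is not None:
            if callable(gain_override):
                return float(gain_override(np.asarray(t)))
            return float(gain_override)
        if condition_label == "acute_tricaine":
            return 1.0 - math.exp(-(t / 60.0) / eff.tau_rec_min)
        return 1.0

    def rate_at(t: float) -> float:
        tr = trial_of(t)
        in_motion = tr.t_motion_on <= t < tr.t_motion_off and tr.stimulus != "none"
        base = eff.rate_stim_hz if in_motion else eff.rate_nostim_hz
        return base * gain(t)

    rate_max = max(eff.rate_nostim_hz, eff.rate_stim_hz)
    bout_times = _draw_bout_times(rng, duration, rate_at, rate_max)

    p_targets = trial_p_targets(eff, condition_label, len(trials))
    e_vals = evidence_trace(trials, bout_times, eff.tau_int_s)

    truth: list[Bout] = []
    angles = np.zeros(len(bout_times))
    for i, tb in enumerate(bout_times):
        tr = trial_of(tb)
        in_motion = tr.t_motion_on <= tb < tr.t_motion_off
        directional = in_motion and tr.stimulus in ("left", "right")
        w_turn = eff.w_turn_stim if directional else eff.w_turn_nostim
        if rng.uniform() < w_turn:
            mag = abs(rng.normal(eff.mu_turn_deg, eff.sigma_turn_deg))
            if directional:
                p_eff = 0.5 + (p_targets[tr.index] - 0.5) * e_vals[i]
                correct_sign = 1.0 if tr.stimulus == "left" else -1.0
                sign = correct_sign if rng.uniform() < p_eff else -correct_sign
            else:
                sign = 1.0 if rng.uniform() < 0.5 else -1.0
            angle = sign * mag
        else:
            angle = rng.normal(0.0, eff.sigma_forward_deg)
        angles[i] = angle
        disp = max(0.05, rng.normal(eff.displacement_cm, 0.03))
        truth.append(
            Bout(t_on=float(tb), duration=BOUT_RAMP_S, turn_angle_deg=float(angle),
                 displacement_cm=float(disp)))

    # integrate heading and position at 100 Hz with smooth cosine ramps
    heading = np.zeros(n)
    x = np.zeros(n)
    y = np.zeros(n)
    ramp_n = max(1, int(round(BOUT_RAMP_S / dt)))
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(1, ramp_n + 1) / ramp_n))
    d_heading = np.zeros(n)
    d_disp = np.zeros(n)
    ramp_steps = np.diff(np.concatenate(([0.0], ramp)))
    for b in truth:
        k0 = int(round(b.t_on / dt))
        k1 = min(k0 + ramp_n, n)
        d_heading[k0:k1] += b.turn_angle_deg * ramp_steps[: k1 - k0]
        d_disp[k0:k1] += b.displacement_cm * ramp_steps[: k1 - k0]
    heading = np.cumsum(d_heading)
    # displacement along the instantaneous heading (positive heading = CCW/left)
    hx = np.cos(np.deg2rad(heading))
    hy = np.sin(np.deg2rad(heading))
    x = np.cumsum(d_disp * hx)
    y = np.cumsum(d_disp * hy)

    heading = heading + rng.normal(0.0, eff.heading_noise_deg, n)
    x = x + rng.normal(0.0, eff.position_noise_cm, n)
    y = y + rng.normal(0.0, eff.position_noise_cm, n)

    tracking = pd.DataFrame({"t": t_grid, "x": x, "y": y, "heading_deg": heading})
    return BehaviorSession(
        fish_id=fish_id or f"fish-{seed}",
        condition_label=condition_label,
        washout_h=washout_h,
        trials=trials,
        tracking=tracking,
        truth_bouts=truth,
        seed=seed,
        protocol=protocol,
        params=eff,
    )
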
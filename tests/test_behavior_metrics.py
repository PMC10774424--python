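"""Bout detection against ground truth and the behavioral statistics of the
turn-accuracy / turn-distribution / integration analyses."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from omrkit.behavior_metrics import (
    Bout,
    CorrectCount,
    bout_frequency,
    cumulative_turn_angle,
    detect_bouts,
    performance_vs_time,
    performance_vs_trial,
    proportion_correct,
    session_proportion_correct,
    turn_distribution,
)
from omrkit.synthetic_behavior import (
    BOUT_RAMP_S,
    BehaviorProtocol,
    BehaviorSession,
    FishParams,
    build_trial_schedule,
    simulate_session,
)


def _flat_tracking(duration_s=10.0, dt=0.01):
    n = int(duration_s / dt)
    t = np.arange(n) * dt
    return pd.DataFrame(
        {"t": t, "x": np.zeros(n), "y": np.zeros(n), "heading_deg": np.zeros(n)}
    )


def _inject_bout(track, t_on, angle_deg, disp_cm=0.12, dt=0.01):
    """Deposit one cosine-ramp bout into a flat tracking frame."""
    ramp_n = int(BOUT_RAMP_S / dt)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(1, ramp_n + 1) / ramp_n))
    k0 = int(t_on / dt)
    h = track["heading_deg"].to_numpy()
    x = track["x"].to_numpy()
    h[k0 : k0 + ramp_n] += angle_deg * ramp
    h[k0 + ramp_n :] += angle_deg
    x[k0 : k0 + ramp_n] += disp_cm * ramp
    x[k0 + ramp_n :] += disp_cm
    track["heading_deg"] = h
    track["x"] = x


class TestDetectBouts:
    def test_constant_tracking_has_no_bouts(self):
        assert detect_bouts(_flat_tracking()) == []

    def test_nonuniform_time_base_rejected(self):
        track = _flat_tracking()
        track.loc[5, "t"] = 0.2
        with pytest.raises(ValueError, match="uniform"):
            detect_bouts(track)

    def test_three_injected_bouts_recovered_within_1_degree(self):
        track = _flat_tracking(duration_s=10.0)
        truth = [(2.0, 20.0), (5.0, -15.0), (8.0, 0.0)]
        for t_on, ang in truth:
            _inject_bout(track, t_on, ang)
        bouts = detect_bouts(track)
        assert len(bouts) == 3
        for b, (t_on, ang) in zip(bouts, truth):
            assert abs(b.t_on - t_on) <= 0.1
            assert abs(b.turn_angle_deg - ang) <= 1.0

    def test_full_session_recall_and_precision(self, control_session):
        """On a complete synthetic session, detection matches ground-truth
        bouts one-to-one within 100 ms at recall and precision >= 0.99."""
        bouts = detect_bouts(control_session.tracking)
        truth_t = np.array([b.t_on for b in control_session.truth_bouts])
        det_t = np.array([b.t_on for b in bouts])
        used = np.zeros(len(det_t), bool)
        matched = 0
        for x in truth_t:
            d = np.abs(det_t - x)
            d[used] = np.inf
            j = int(np.argmin(d))
            if d[j] <= 0.1:
                used[j] = True
                matched += 1
        assert matched / len(truth_t) >= 0.99
        assert matched / len(det_t) >= 0.99

    def test_metrics_from_detected_match_truth(self, control_session):
        """Proportion correct from detected bouts agrees with the same metric
        from ground-truth bouts within 1 percentage point."""
        det = session_proportion_correct(control_session)
        tru = session_proportion_correct(
            control_session, control_session.truth_bouts
        )
        assert abs(det.fraction - tru.fraction) <= 0.01


class TestTurnDistribution:
    def test_all_zero_angles_concentrate_in_central_bin(self):
        bouts = [Bout(t, 0.1, 0.0) for t in range(10)]
        dist = turn_distribution(bouts, bin_width_deg=5.0)
        k = np.searchsorted(dist.bin_edges_deg, 0.0, side="right") - 1
        assert dist.probability[k] == 1.0

    def test_counting_oracle_20_degree_bins(self):
        bouts = [Bout(i, 0.1, a) for i, a in enumerate([30.0, 30.0, -30.0, 0.0])]
        dist = turn_distribution(bouts, bin_width_deg=20.0)
        edges = dist.bin_edges_deg
        mass = {
            edges[k]: p for k, p in enumerate(dist.probability) if p > 0
        }
        assert mass == {20.0: 0.5, -40.0: 0.25, 0.0: 0.25}

    def test_zero_bouts_is_flagged_empty(self):
        dist = turn_distribution([])
        assert dist.empty and not np.isnan(dist.probability).any()

    @given(
        st.lists(
            st.floats(min_value=-179.9, max_value=179.9),
            min_size=1,
            max_size=200,
        )
    )
    def test_probabilities_sum_to_one(self, angles):
        bouts = [Bout(i, 0.1, a) for i, a in enumerate(angles)]
        dist = turn_distribution(bouts)
        assert abs(dist.probability.sum() - 1.0) < 1e-12


class TestProportionCorrect:
    def test_sign_convention(self):
        left = proportion_correct([Bout(0, 0.1, 20.0)], "left")
        assert (left.n_correct, left.n_total) == (1, 1)
        wrong = proportion_correct([Bout(0, 0.1, -20.0)], "left")
        assert (wrong.n_correct, wrong.n_total) == (0, 1)

    def test_counting_oracle_96_of_100(self):
        bouts = [Bout(i, 0.1, -20.0) for i in range(96)] + [
            Bout(96 + i, 0.1, 20.0) for i in range(4)
        ]
        cc = proportion_correct(bouts, "right")
        assert cc.fraction == pytest.approx(0.96)

    def test_forward_band_excluded_and_empty_denominator_undefined(self):
        bouts = [Bout(i, 0.1, a) for i, a in enumerate([3.0, -9.9, 0.0, 10.0])]
        cc = proportion_correct(bouts, "right")
        assert cc.n_total == 0 and cc.fraction is None

    def test_unknown_stimulus_rejected(self):
        with pytest.raises(ValueError):
            proportion_correct([], "forward")


class TestBoutFrequency:
    def test_count_over_duration(self):
        assert bout_frequency([Bout(i, 0.1, 0) for i in range(30)], 60.0) == 0.5
        assert bout_frequency([], 60.0) == 0.0

    def test_motion_window_rate_matches_generator(self, control_session):
        """Motion-phase bout count over a control session sits inside the
        99% Poisson CI of rate_stim_hz x total motion time."""
        from omrkit.behavior_metrics import motion_phase_bouts

        ann = motion_phase_bouts(
            control_session, stimuli=("left", "right", "forward", "backward")
        )
        total_motion = 120 * control_session.protocol.motion_s  # 120 moving trials
        expected = control_session.params.rate_stim_hz * total_motion
        lo, hi = stats.poisson.interval(0.99, expected)
        assert lo <= len(ann) <= hi


def _session_with_bouts(trials, protocol):
    return BehaviorSession(
        fish_id="f",
        condition_label="control",
        washout_h=None,
        trials=trials,
        tracking=pd.DataFrame({"t": [0.0, 0.01], "x": [0, 0], "y": [0, 0],
                               "heading_deg": [0, 0]}),
        truth_bouts=[],
        seed=0,
        protocol=protocol,
        params=FishParams(),
    )


class TestCumulativeTurnAngle:
    def test_no_bouts_gives_zero_trace(self):
        proto = BehaviorProtocol(conditions=("left",), n_sets=2)
        ses = _session_with_bouts(build_trial_schedule(proto, 0), proto)
        out = cumulative_turn_angle([ses], "left", per_session_bouts=[[]])
        assert (out["median"] == 0).all()

    def test_prefix_sum_oracle(self):
        proto = BehaviorProtocol(conditions=("left",), n_sets=1)
        trials = build_trial_schedule(proto, 0)
        ses = _session_with_bouts(trials, proto)
        bouts = [Bout(6.0, 0.1, 10.0), Bout(8.0, 0.1, 10.0), Bout(12.0, 0.1, -5.0)]
        out = cumulative_turn_angle([ses], "left", per_session_bouts=[bouts])
        vals = out.set_index("t_s")["median"]
        assert vals.loc[7.0] == 10.0
        assert vals.loc[9.0] == 20.0
        assert vals.loc[13.0] == 15.0
        assert vals.loc[19.0] == 15.0

    def test_terminal_sign_tracks_generator_bias(self):
        proto = BehaviorProtocol(conditions=("left", "right"), n_sets=10)
        sessions = [
            simulate_session(proto, FishParams(), "control", seed=s)
            for s in range(5)
        ]
        left = cumulative_turn_angle(sessions, "left")
        right = cumulative_turn_angle(sessions, "right")
        assert left["median"].iloc[-1] > 0
        assert right["median"].iloc[-1] < 0


class TestPerformanceVsTime:
    def test_slow_integrator_gives_rising_curve(self):
        """With a seconds-scale accumulator the within-stimulus accuracy
        rises: first bin below last bin and positive rank correlation."""
        proto = BehaviorProtocol(conditions=("left", "right"), n_sets=20)
        params = dataclasses.replace(FishParams(), tau_int_s=2.0)
        sessions = [
            simulate_session(proto, params, "control", seed=100 + s)
            for s in range(12)
        ]
        curve = performance_vs_time(sessions, bin_s=1.0)
        med = curve["median"].to_numpy()
        assert med[0] < med[-1]
        rho, p = stats.spearmanr(np.arange(len(med)), med)
        assert rho > 0 and p < 0.01

    def test_fast_integrator_gives_flat_curve(self):
        proto = BehaviorProtocol(conditions=("left", "right"), n_sets=20)
        params = dataclasses.replace(FishParams(), tau_int_s=1e-3, p_correct=0.9)
        sessions = [
            simulate_session(proto, params, "control", seed=200 + s)
            for s in range(12)
        ]
        curve = performance_vs_time(sessions, bin_s=1.0)
        med = curve["median"].to_numpy()
        # every bin median within binomial scatter of the target
        assert np.all(np.abs(med - 0.9) < 0.08)

    def test_empty_bins_stay_undefined(self):
        proto = BehaviorProtocol(conditions=("left",), n_sets=1)
        trials = build_trial_schedule(proto, 0)
        ses = _session_with_bouts(trials, proto)
        bouts = [Bout(5.5, 0.1, 20.0)]  # only the first motion second
        curve = performance_vs_time([ses], bin_s=1.0, per_session_bouts=[bouts])
        assert curve["median"].iloc[0] == 1.0
        assert curve["median"].iloc[1:].isna().all()


class TestPerformanceVsTrial:
    def test_stationary_generator_has_no_trend(self):
        proto = BehaviorProtocol(conditions=("left", "right"), n_sets=15)
        sessions = [
            simulate_session(proto, FishParams(), "control", seed=300 + s)
            for s in range(10)
        ]
        curve = performance_vs_trial(sessions)
        med = curve["median"].dropna()
        res = stats.linregress(med.index.to_numpy(), med.to_numpy())
        ci = 1.96 * res.stderr
        assert res.slope - ci <= 0 <= res.slope + ci

    def test_dark_rearing_transient_rises_over_first_trials(self):
        """Dark-reared accuracy targets start near 0.94 at trial 1 and rise
        monotonically toward the 0.949 asymptote over the first trials."""
        from omrkit.synthetic_behavior import trial_p_targets

        p = trial_p_targets(FishParams(), "dark", 12)
        assert p[0] == pytest.approx(0.94)
        assert np.all(np.diff(p[:4]) > 0)
        assert p[-1] == pytest.approx(0.949, abs=1e-3)

    def test_single_fish_single_trial(self):
        proto = BehaviorProtocol(conditions=("left",), n_sets=1)
        trials = build_trial_schedule(proto, 0)
        ses = _session_with_bouts(trials, proto)
        curve = performance_vs_trial([ses], per_session_bouts=[[Bout(7.0, 0.1, 30.0)]])
        assert len(curve) == 1 and curve["median"].iloc[0] == 1.0

    def test_mismatched_schedules_rejected(self):
        p1 = BehaviorProtocol(conditions=("left",), n_sets=1)
        p2 = BehaviorProtocol(conditions=("left",), n_sets=2)
        s1 = _session_with_bouts(build_trial_schedule(p1, 0), p1)
        s2 = _session_with_bouts(build_trial_schedule(p2, 0), p2)
        with pytest.raises(ValueError):
            performance_vs_trial([s1, s2])
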
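"""Group statistics over the behavioral cohorts of 01: turn-angle
distributions, cumulative turn angle, washout-ladder comparisons, and the
within-stimulus integration curve.

Reads results/behavior_per_fish.csv; writes turn-distribution and
cumulative-angle tables, the per-cohort accuracy summaries with
Kolmogorov-Smirnov / Kruskal-Wallis / Mann-Whitney statistics (effect sizes
as absolute median differences against control), and the time-resolved
accuracy curve for a slow-integrator cohort.
"""

import dataclasses
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from omrkit.behavior_metrics import (
    cumulative_turn_angle,
    detect_bouts,
    group_turn_distribution,
    performance_vs_time,
)
from omrkit.stats_reporting import (
    compare_multi_groups,
    compare_two_groups,
    summarize_group,
)
from omrkit.synthetic_behavior import BehaviorProtocol, FishParams, simulate_session

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 0) -> None:
    per_fish = pd.read_csv(RESULTS / "behavior_per_fish.csv")

    stats_out = {}
    control = per_fish.query("condition == 'control'")["proportion_correct"]
    for cond in ("dark", "strobe"):
        sub = per_fish.query("condition == @cond")["proportion_correct"]
        res = compare_two_groups(control, sub, "ks_two_sided")
        stats_out[f"{cond}_vs_control"] = dataclasses.asdict(res)
    ladder = [
        per_fish.query("condition == 'tricaine_reared' and washout_h == @h")[
            "proportion_correct"
        ]
        for h in (0.0, 2.0, 6.0, 24.0)
    ]
    stats_out["washout_ladder_kruskal"] = dataclasses.asdict(
        compare_multi_groups(ladder)
    )
    for h, grp in zip((0.0, 2.0, 6.0, 24.0), ladder):
        res = compare_two_groups(control, grp, "mann_whitney")
        stats_out[f"washout_{h}h_vs_control"] = dataclasses.asdict(res)
        stats_out[f"washout_{h}h_summary"] = dataclasses.asdict(
            summarize_group(grp)
        )
    (RESULTS / "behavior_stats.json").write_text(json.dumps(stats_out, indent=2))

    # fresh small cohorts for trace-level figures
    proto = BehaviorProtocol(conditions=("left", "right"), n_sets=15)
    sessions = [
        simulate_session(proto, FishParams(), "control", seed=seed + 100 + s)
        for s in range(8)
    ]
    bouts = [detect_bouts(s.tracking) for s in sessions]
    dist = group_turn_distribution(bouts)
    dist.to_csv(RESULTS / "turn_distribution_control.csv", index=False)
    for stim in ("left", "right"):
        cum = cumulative_turn_angle(sessions, stim, per_session_bouts=bouts)
        cum.to_csv(RESULTS / f"cumulative_turn_{stim}.csv", index=False)

    # slow-integrator cohort: accuracy builds over seconds of stimulation
    slow = dataclasses.replace(FishParams(), tau_int_s=2.0)
    slow_sessions = [
        simulate_session(proto, slow, "control", seed=seed + 300 + s)
        for s in range(12)
    ]
    curve = performance_vs_time(slow_sessions, bin_s=1.0)
    curve.to_csv(RESULTS / "performance_vs_time.csv", index=False)

    print("washout-ladder Kruskal-Wallis p:",
          stats_out["washout_ladder_kruskal"]["p_value"])
    for h in (0.0, 2.0, 6.0, 24.0):
        eff = stats_out[f"washout_{h}h_vs_control"]["effect_size_abs_median_diff"]
        med = stats_out[f"washout_{h}h_summary"]["median"]
        print(f"  washout {h:>4} h: median accuracy {med:.3f}, "
              f"effect vs control {eff:.3f}")
    print("integration curve (first/last bin):",
          round(curve['median'].iloc[0], 3), "->",
          round(curve['median'].iloc[-1], 3))
    print(f"wrote tables + stats under {RESULTS}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
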
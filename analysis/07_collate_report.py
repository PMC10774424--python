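"""Collate the study-level summary from every table under results/.

One JSON with the headline quantities: cohort accuracy medians and effect
sizes, the bout-rate recovery constant, per-population tuning breakdown,
and the recovery-midpoint contrast between acute and lifetime anesthesia.
"""

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from omrkit.stats_reporting import compare_two_groups, summarize_group

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    report = {}

    behavior = pd.read_csv(RESULTS / "behavior_per_fish.csv")
    for (cond, washout), sub in behavior.groupby(
        ["condition", "washout_h"], dropna=False
    ):
        key = cond if pd.isna(washout) else f"{cond}_{washout:g}h"
        report[f"accuracy/{key}"] = dataclasses.asdict(
            summarize_group(sub["proportion_correct"].dropna())
        )

    fits = pd.read_csv(RESULTS / "bout_rate_recovery_fits.csv")
    report["bout_rate_recovery_tau_min"] = dataclasses.asdict(
        summarize_group(fits.query("converged")["tau_min"])
    )

    logi = pd.read_csv(RESULTS / "logistic_recovery_fits.csv")
    for experiment, sub in logi.query("converged").groupby("experiment"):
        report[f"recovery_midpoint_min/{experiment}"] = dataclasses.asdict(
            summarize_group(sub["x0_min"])
        )
    a = logi.query("experiment == 'acute' and converged")["x0_min"]
    l = logi.query("experiment == 'lifetime' and converged")["x0_min"]
    report["recovery_midpoint_acute_vs_lifetime"] = dataclasses.asdict(
        compare_two_groups(a, l, "mann_whitney")
    )

    kin = pd.read_csv(RESULTS / "kinetics_fits.csv")
    resolved = kin[kin["flags"].fillna("") == ""]
    report["tau_on_s"] = dataclasses.asdict(summarize_group(resolved["tau_on_s"]))
    report["tau_off_s"] = dataclasses.asdict(summarize_group(resolved["tau_off_s"]))

    (RESULTS / "report.json").write_text(json.dumps(report, indent=2))
    print(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
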
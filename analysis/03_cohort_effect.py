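#!/usr/bin/env python
"""Run the full session pipeline over both cohorts; tabulate percent-of-pre.

Regenerates each session deterministically from the seeds in
results/cohort_plan.csv (written by 01_simulate.py), runs analyze_session
(inclusion screening, event and spectral metrics per epoch, percent-of-pre
normalization), and writes:

  results/cohort_sessions.csv       tidy per-session, per-epoch, per-metric
  results/cohort_group_summary.csv  mean / SD / n per treatment x sex

Printed at the end: the group-mean HPD percent-of-pre in the early post
epoch — the treated cohort should sit near its programmed 20% while the
null cohort stays near 100%.
"""

from pathlib import Path

import pandas as pd

from ihkalfp.pipeline import analyze_session, summarize_group
from ihkalfp.synthetic import SimConfig, simulate_session

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
PLAN = RESULTS / "cohort_plan.csv"


def main() -> None:
    if not PLAN.exists():
        raise SystemExit("run 01_simulate.py first (missing cohort_plan.csv)")
    plan = pd.read_csv(PLAN)

    results = []
    for _, row in plan.iterrows():
        cfg = SimConfig(
            fs=row["fs_hz"],
            duration_s=row["duration_s"],
            injection_time_s=row["injection_time_s"],
            rate_multipliers={"pre": 1.0, "excluded": 1.0,
                              "post_early": row["post_early_multiplier"],
                              "post_late": 1.0},
            seed=int(row["seed"]),
        )
        recording, _, _ = simulate_session(cfg)
        result = analyze_session(
            recording, cfg.injection_time_s,
            session_meta={
                "session_id": row["session_id"],
                "subject_id": row["subject_id"],
                "sex": row["sex"],
                "treatment": row["treatment"],
                "dose_mg_per_kg": 1651.0 if row["treatment"].startswith("dmso") else 0.0,
            },
        )
        if not result.included:
            print(f"excluded {result.session_id}: {result.exclusion_reason}")
        results.append(result)

    tidy = pd.concat([r.to_tidy() for r in results], ignore_index=True)
    tidy.to_csv(RESULTS / "cohort_sessions.csv", index=False)
    groups = summarize_group(results)
    groups.to_csv(RESULTS / "cohort_group_summary.csv", index=False)

    focus = tidy[
        (tidy["epoch"] == "post_early")
        & tidy["metric"].isin(["hpd_count_per_h", "hpd_s_per_h"])
        & tidy["included"]
    ]
    table = focus.groupby(["treatment", "metric"])["percent_of_pre"].agg(
        ["mean", "std", "count"]
    )
    print("\nHPD metrics, early post epoch, % of the pre-treatment hour:")
    print(table.round(1).to_string())


if __name__ == "__main__":
    main()
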
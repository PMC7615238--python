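#!/usr/bin/env python
"""Plan the synthetic cohorts and write a demo session to disk.

Two 8-session cohorts mirror the study design: a null (saline-like) cohort
with no programmed effect, and a treated cohort whose post-injection event
rates are suppressed to 20% of baseline during the early post epoch. The
cohort plan (seeds, multipliers, programmed rates) goes to
results/cohort_plan.csv; downstream scripts regenerate the sessions
deterministically from these seeds, so the plan table *is* the dataset.

A 2-minute demo session is also rendered to scratch/demo/ in both delimited
and EDF form, with its ground-truth annotations.
"""

from pathlib import Path

import pandas as pd

from ihkalfp.io import write_annotations, write_recording
from ihkalfp.synthetic import SimConfig, cohort_configs, simulate_session

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "demo"

COHORTS = {"saline": 1.0, "dmso_100pct": 0.2}
N_PER_GROUP = 8
PLAN_SEED = 20260925


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)

    rows = []
    for group_index, (treatment, multiplier) in enumerate(COHORTS.items()):
        base = SimConfig(
            rate_multipliers={"pre": 1.0, "excluded": 1.0,
                              "post_early": multiplier, "post_late": 1.0},
        )
        for i, cfg in enumerate(
            cohort_configs(base, N_PER_GROUP, seed=PLAN_SEED + group_index)
        ):
            rows.append(
                {
                    "session_id": f"{treatment}_{i:02d}",
                    "subject_id": f"m{i:02d}",
                    "sex": "f" if i % 2 == 0 else "m",
                    "treatment": treatment,
                    "post_early_multiplier": multiplier,
                    "seed": cfg.seed,
                    "fs_hz": cfg.fs,
                    "duration_s": cfg.duration_s,
                    "injection_time_s": cfg.injection_time_s,
                    "pre_spiketrain_rate_per_h": cfg.spiketrain_rate_per_h,
                    "pre_hpd_rate_per_h": cfg.hpd_rate_per_h,
                }
            )
    plan = pd.DataFrame(rows)
    plan.to_csv(RESULTS / "cohort_plan.csv", index=False)
    print(f"cohort plan: {len(plan)} sessions -> {RESULTS / 'cohort_plan.csv'}")

    demo_cfg = SimConfig(duration_s=120.0, injection_time_s=None, seed=7)
    recording, schedule, annotations = simulate_session(demo_cfg)
    write_recording(recording, SCRATCH / "demo_session.csv")
    write_recording(recording, SCRATCH / "demo_session.edf")
    write_annotations(annotations, SCRATCH / "demo_truth.csv")
    counts = schedule.counts()
    print(
        f"demo session: {demo_cfg.duration_s:.0f} s, "
        f"{counts['spike_trains']} spike trains, {counts['hpds']} HPDs, "
        f"{counts['spikes']} spikes -> {SCRATCH}"
    )


if __name__ == "__main__":
    main()
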
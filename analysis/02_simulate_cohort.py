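#!/usr/bin/env python
"""Simulate the study-style cohort.

24 subjects, each tested on PR, PRR-10 and PRR-60 (45-min sessions), with
trait press rates in 0.4-1.6 presses/s, reward-collection latencies near
0.7 s and return-to-work latencies near 2.4 s (PRR) / ~5 s (PR).  Agents
follow an overharvesting policy: their own rate-maximizing bout length
plus 3 ratios (jitter +/-1).

Writes the event logs to scratch/cohort/ (regenerable, not a deliverable)
and the ground-truth table to results/cohort_ground_truth.csv.
"""

from pathlib import Path

from prrforage import BoutPolicy, simulate_cohort, write_event_log

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "cohort"
DATA.mkdir(parents=True, exist_ok=True)
RESULTS = ROOT / "results"
RESULTS.mkdir(exist_ok=True)

SEED = 11

logs, truth = simulate_cohort(
    n_subjects=24,
    sessions_per_task=1,
    duration_s=2700.0,
    bout_policy=BoutPolicy(kind="optimal_plus_bias", bias=3, jitter=1),
    pr_stop_ratio="trait",
    seed=SEED,
)
for log in logs:
    write_event_log(log, DATA / f"{log.meta.session_id}.csv")
truth.to_csv(RESULTS / "cohort_ground_truth.csv", index=False)

print(f"wrote {len(logs)} sessions ({truth['subject_id'].nunique()} subjects) "
      f"to {DATA}")
print("generative press rates: "
      f"{truth['press_rate'].min():.2f}-{truth['press_rate'].max():.2f} presses/s")
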
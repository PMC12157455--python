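#!/usr/bin/env python
"""Per-session behavioral metrics for the simulated cohort.

Reads scratch/cohort/ (produced by 02_simulate_cohort.py), segments every
session into bouts, computes the session metrics table, and checks press-
rate recovery against the generative ground truth.

Writes results/session_metrics.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from prrforage import compute_session_metrics, read_event_log, segment_bouts

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"
if not DATA.exists():
    raise SystemExit("run analysis/02_simulate_cohort.py first")

rows = []
for path in sorted(DATA.glob("*.csv")):
    if path.name == "ground_truth.csv":
        continue
    log = read_event_log(path)
    bouts = segment_bouts(log)
    m = compute_session_metrics(log, bouts)
    rows.append(dict(
        session_id=log.meta.session_id, subject_id=log.meta.subject_id,
        task=log.meta.task, reset_delay_s=log.meta.reset_delay_s,
        active_presses=m.active_presses, reset_presses=m.reset_presses,
        pellets=m.pellets, press_rate=m.press_rate,
        median_reward_latency_s=m.median_reward_latency_s,
        median_work_latency_s=m.median_work_latency_s,
        median_bout_length=m.median_bout_length,
        n_bouts_complete=m.n_bouts_complete, breakpoint=m.breakpoint,
    ))
df = pd.DataFrame(rows)
df.to_csv(RESULTS / "session_metrics.csv", index=False)

truth = pd.read_csv(RESULTS / "cohort_ground_truth.csv")
merged = df.merge(truth[["session_id", "press_rate"]], on="session_id",
                  suffixes=("_rec", "_gen"))
r = np.corrcoef(merged["press_rate_gen"], merged["press_rate_rec"])[0, 1]
print(f"{len(df)} sessions; press-rate recovery r = {r:.3f}")
for task, grp in df.groupby(df["task"] + df["reset_delay_s"].fillna(0)
                            .map(lambda d: f"-{d:g}" if d else "")):
    length = (f"median bout length {grp['median_bout_length'].median()}"
              if task != "PR" else
              f"median breakpoint {grp['breakpoint'].median():.0f}")
    print(f"  {task:7s} median reward latency "
          f"{grp['median_reward_latency_s'].median():.2f} s, "
          f"work latency {grp['median_work_latency_s'].median():.2f} s, {length}")
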
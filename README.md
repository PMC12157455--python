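# prrforage

Analysis of **Progressive-Ratio-with-Reset (PRR)** operant sessions, for
behavioral neuroscientists studying cost–benefit decision making and
foraging-style choice in rodents.

In a PRR session a rat works a progressive-ratio lever (each pellet costs
one more press than the last) but can press a second *reset* lever that
retracts both levers for a fixed delay and returns the requirement to one.
That makes the task a patch-leaving problem: the ratio is a depleting
patch, the reset delay a travel time, and the number of rewards earned per
*bout of work* is the animal's patch-residence policy. This package
provides:

- an event-log data model for sessions (CSV + JSON sidecar), with
  validation and exact round-trip I/O (`prrforage.session`);
- bout segmentation and the behavioral metrics — press counts and rates,
  reward-collection latency, return-to-work latency, reset latency,
  median bout length, PR breakpoint, cumulative records
  (`prrforage.bouts`);
- the normative model of bout length (`prrforage.optimality`): with press
  rate `p`, reset delay `T` and handling time `h`, a bout of `n` ratios
  takes `t_bout(n) = T + n·h + n(n+1)/(2p)` seconds, yields reward rate
  `R_bout(n) = n / t_bout(n)`, and the optimal bout length is the integer
  argmax of `R_bout` (within one ratio of the closed form `√(2pT)`, and
  exactly independent of `h`);
- a task + agent simulator with known ground truth
  (`prrforage.simulate`);
- a dataset pipeline comparing observed and optimal bout lengths per
  session and quantifying *excess ratios* — overharvesting
  (`prrforage.pipeline`), plus a CLI (`prrforage optimal|grid|simulate|analyze`).

## Worked example

```python
from prrforage import (BoutPolicy, OptimalityParams, optimal_bout_length,
                       simulate_cohort, compute_session_metrics)

# Rate-maximizing bout length at 1.8 presses/s, 2 s handling time:
for T in (10.0, 60.0):
    res = optimal_bout_length(OptimalityParams(press_rate=1.8, reset_delay_s=T))
    print(T, res.n_opt)
# 10.0 6
# 60.0 15

# An agent that overshoots its own optimum by 3 ratios:
logs, truth = simulate_cohort(
    12, tasks=[("PRR", 10.0), ("PRR", 60.0)],
    bout_policy=BoutPolicy(kind="optimal_plus_bias", bias=3, jitter=1),
    seed=11)
m = compute_session_metrics(logs[0])
print(m.median_bout_length, truth.loc[0, "n_opt"])
# 8.0 5
```

The first block evaluates the reward-rate curve and reports the optimum:
6 rewards per bout under a 10 s reset delay, 15 under 60 s — longer travel
times justify staying longer in the depleting patch. The second simulates
a 24-session cohort whose agents overharvest by 3 ratios; the first
session's observed median bout length (8.0) sits exactly 3 above the
optimum implied by that subject's press rate (5).

The numbered scripts under `analysis/` run the full narrative — model
curves and grids (`01`), cohort simulation (`02`, writes event logs to
`scratch/`), session metrics and parameter recovery (`03`), observed vs.
optimal bout lengths, excess ratios and cross-task correlations (`04`) —
and write their tables to `results/`. On the default cohort the pipeline
recovers generative press rates at r = 0.99, measures mean excess ratios
of 3.01 against a built-in bias of 3, and finds cross-task bout-length
correlations of r = 0.92–0.98.

See `docs/methods.md` for the model, estimator choices and simulator
assumptions.

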
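# Methods

## The task and the analysis problem

In a progressive-ratio (PR) schedule the number of lever presses required
for each successive food pellet increments by one. The Progressive Ratio
with Reset (PRR) variant adds a second lever that, when pressed, retracts
both levers for a fixed *reset delay* (10 s or 60 s in the conditions this
package emulates) and then returns the ratio requirement to one. This turns
the schedule into a patch-leaving problem: the progressive ratio is a
depleting patch, the reset delay a travel time, and the subject's *bout
length* — the number of rewards earned before pressing the reset lever —
is its patch-residence policy.

The package does four things: (1) represents and validates sessions as
timestamped event logs; (2) segments logs into bouts and computes the
behavioral metrics (press counts and rates, reward-collection latency,
return-to-work latency, reset latency, median bout length, PR breakpoint);
(3) evaluates the normative model for the rate-maximizing bout length; and
(4) compares observed and optimal bout lengths session by session
("excess ratios"). A simulator generates sessions with known ground truth
so every stage is testable without animal data.

## The normative model

With a work tempo of `p` presses/s, ratio `n` takes `n/p` s, so a bout of
`n` ratios lasts

    t_bout(n) = t_reset + n·t_handle + (1/p)·Σ_{k=1..n} k
              = t_reset + n·t_handle + n(n+1)/(2p)

and delivers `n` rewards, giving a bout-level reward rate
`R_bout(n) = n / t_bout(n)`. The optimal bout length `n_opt` is the integer
argmax of `R_bout`, found by brute force over `n = 1..max_bout`
(default 1000; an argmax on the bound raises instead of silently
truncating). Ties within a relative tolerance of 1e-12 resolve to the
smaller `n` (identical rate, less work). Exact rational ties exist: at
`p = 1`, `t_reset = 10`, `R(4) = 4/28 = R(5) = 5/35 = 1/7`, and the model
returns 4.

Two structural properties are exploited as oracles in the tests:

- **Handling-time independence.** Comparing `R(n1)` and `R(n2)` by
  cross-multiplication, the handling terms contribute `n1·n2·t_handle` to
  both sides and cancel, so `n_opt` is exactly independent of `t_handle`.
  `t_handle` defaults to 2 s and only scales the height of the curve.
- **Continuous closed form.** Maximizing `R_bout` in real `n` gives
  stationarity at `t_reset = n²/(2p)`, i.e. `n* = √(2·p·t_reset)`,
  independent of handling time. The integer argmax lies within one ratio
  of `n*` over the tested range (`p ∈ [0.25, 3]`, `t_reset ∈ [5, 120]`).

With `t_handle = 2 s`, the printed reference optima — 6 ratios at a 10 s
delay and 15 at a 60 s delay — are jointly reproduced at `p = 1.8`
presses/s (`√(2·1.8·10) = 6`, `√(2·1.8·60) ≈ 14.7`). At `p = 1` press/s the
10 s condition instead ties exactly at 4/5; no single press rate maps
1 press/s onto those optima, so 1.8 presses/s is used as the reference
work tempo throughout (`analysis/01_optimality_model.py`,
`scripts/acceptance.py`).

## Event-log format and conventions

Times are seconds from session start (`t = 0` at `session_start`), stored
as arbitrary reals; the CSV rendering is exact (shortest round-tripping
decimal, padded to ≥3 fractional digits) so write→read is an identity.
Events logged at the same timestamp are ordered by a fixed precedence —
`levers_retracted < levers_extended < active_press < reset_press <
reward_delivered < magazine_entry < session_end` — which keeps cause
before effect for press→reward→collection chains. One consequence: the
retraction triggered by a reset press shares its timestamp and sorts
first; the lever-absence check therefore uses strict time comparison, and
bout segmentation accepts a same-instant retraction on either side of the
reset press.

Active presses made while the reward light is lit (between a reward
delivery and the magazine entry collecting it) are stored as ordinary
events; the *counting* rule — such presses do not advance the ratio —
lives in the metrics layer, not the format.

## Metric definitions

- **Reward-collection latency**: magazine entry time minus reward delivery
  time, one value per collected reward; session value is the median.
- **Return-to-work latency**: first counting press after a magazine entry
  minus that entry, computed only when pressing resumes within the same
  bout; session median.
- **Reset latency**: reset press time minus the preceding lever extension,
  one value per complete bout.
- **Bout length**: rewards earned in a bout; session value is the median
  over *complete* bouts (those ending in a reset press). The trailing
  incomplete bout counts toward pellet totals but not bout-length or
  reset-latency statistics. Medians of even counts are midpoints, so
  bout lengths can be half-integers.
- **Breakpoint** (PR only): total rewards earned, i.e. the highest
  successfully completed ratio.

**Press rate.** The session press rate feeds the optimality model, so what
it estimates matters. The default estimator is the reciprocal of the mean
within-ratio inter-press interval: only gaps between consecutive counting
presses with no intervening reward are used. This measures the chosen
tempo of work and is unbiased for the simulator's renewal process.
Dividing press counts by lever-available time (offered as
`rate_mode="lever_available"`) folds post-reward pauses into the
denominator and underestimates tempo by tens of percent, which would bias
the session-specific optimum low and inflate excess ratios; it remains
available for comparison, along with `rate_mode="session"`. Sessions whose
every ratio was completed with a single press have no within-ratio
intervals; the estimator then falls back to lever-available time.

## The simulator

The task side is a faithful state machine: ratio starts at 1 and
increments per reward; a reset press in PRR retracts both levers for
exactly the reset delay and restores ratio 1; in PR the reset lever does
nothing. The agent side is a small stochastic generative model:

- **Inter-press intervals**: gamma with mean `1/press_rate` and shape
  `ipi_shape` (default 3; infinity degenerates to constant intervals for
  hand-checkable traces).
- **Latencies**: lognormal, parameterized by median and log-scale
  dispersion (default 0.4). Defaults emulate the study's scales: reward
  collection ~0.7 s; return to work ~2.4 s in PRR and ~2.7 s longer in PR.
  No distributional forms are dictated by the data; these are modeling
  choices.
- **Sequencing**: the first press of a bout occurs one inter-press
  interval after lever extension; each later press of a ratio follows one
  interval; the magazine entry follows the reward by one reward latency;
  the next press — or the reset press when the bout policy's target is
  reached — follows the magazine entry by one return-to-work latency.
- **Bout policy**: `fixed` (always N), `jittered` (N ± uniform integer
  jitter), or `optimal_plus_bias` — the agent computes the rate-maximizing
  bout length for its *own* generative press rate and the session's reset
  delay, then adds a bias `b`. Positive `b` builds overharvesting into the
  data, making excess ratios recoverable by construction.
- **PR extras**: Poisson inconsequential reset presses (default 1.8/min,
  ~80 per 45-min session) so reset-press accounting is exercised on PR
  data, and an optional stopping ratio after which the agent quiesces
  (PR breakpoint behavior; real rats stop, the model needs to be told to).
  In cohorts the stopping ratio can be derived from the subject's own
  traits (`pr_stop_ratio="trait"`), which ties PR breakpoints to the same
  trait that drives PRR bout lengths and makes cross-task correlations
  positive by construction.

Each session draws from a single RNG stream seeded by `(seed,
session_id)`, so logs are bit-reproducible regardless of how many other
sessions are generated. Activity in progress at session end is truncated;
no event exceeds the session duration. Cohorts draw per-subject traits
once (press rate uniform on 0.4–1.6 presses/s by default, matching the
observed across-rat spread) and reuse them across tasks.

**What the simulator does not emulate** — and hence what passing tests do
not certify about real data: within-session satiety or motivational drift,
post-reinforcement pauses that scale with the upcoming ratio, inactive-
lever pressing, and any press-rate dependence on the ratio in progress.
Parameter-recovery results show the pipeline is correct under the
generative model, not that the model captures rat behavior.

## Pipeline conventions

Per PRR session, the observed median bout length is compared with the
optimum computed from that session's measured press rate and reset delay,
handling time fixed at 2 s (configurable). Excess ratios = observed −
optimal. PR sessions contribute breakpoint rows. QC flags (sessions with
fewer reset presses than a threshold, default 1, or with no complete
bouts) keep rows in the table but exclude them from summary statistics —
mirroring the exclusion of a subject who essentially never used the reset
lever. Cross-task trait correlations use each subject's mean of session
medians (breakpoint for PR); subject-level summaries are unweighted means
over sessions.

Problem sizes in the analysis scripts and tests (24-subject cohorts,
45-min sessions, 12×12–15×15 model grids, 100-seed conservation sweeps)
were chosen to give stable statistics at interactive runtimes.

## Known limitations

- The press-rate estimator requires multi-press ratios; sessions that
  never pass ratio 1 fall back to a throughput-based rate.
- Bout-policy targets are in rewards; policies conditioned on elapsed time
  or momentary rate are out of scope.
- The mixed-effects convenience wrapper (`prrforage.stats`) is a thin
  delegation to statsmodels and is not exercised by the acceptance
  checks; session-level inference is not part of the package's
  contribution.
- Native MED-PC log dialects are not parsed; sessions must be converted
  to the CSV + JSON sidecar format first.
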
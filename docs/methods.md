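# Model and methods

## The model

`crewrisk` simulates the day-by-day evolution of unsafe behavior in a
construction crew as a discrete-time multi-agent system.  Each worker *i*
carries a cognitive state: safety awareness `SA_i`, safety knowledge `SK_i`,
safety attitude `AT_i` (a risk-taking propensity in [0, 1]; values above 0.5
lean toward risk-taking), a risk-perception coefficient `p_i > 0` (>1
over-estimates hazards, <1 under-estimates), a risk-acceptance threshold
`RA_i`, a conformity weight `c_i`, a formal-rule-awareness weight `a_i`, and
a personal management norm `WN_i`.

On each day, each worker runs a five-stage safety-cognition chain:

1. **Exposure.** With probability `SR` (site risk) the worker is in a
   dangerous environment.  Unexposed workers behave safely and their state
   is untouched.
2. **Hazard discovery.** An exposed worker notices the hazard with
   probability `SA_i × SK_i`.  An undetected hazard produces no deliberate
   decision: the day is recorded as safe behavior (a configuration flag,
   `count_undetected_as_unsafe`, instead records it as an unsafe act with an
   accident draw).
3. **Perception and acceptance.** The objective hazard level is
   `AR ~ N(μ, σ²)` truncated to [0, 1]; the worker perceives
   `PR_i = p_i × AR`.  Their tolerance is

   `RA_i = (1 − a_i)·[(1 − c_i)·AT_i + c_i·Co_i] + a_i·WN_i + ε`,

   clamped to [0, 1], where `Co_i` is the mean previous-day acceptance of
   the worker's 20 nearest colleagues on the team grid and `ε` is an
   optional uniform disturbance (half-width 0 by default).
4. **Behavior choice.** Unsafe iff `PR_i < RA_i` (risk homeostasis: a hazard
   that looks tolerable is taken); ties resolve to safe.
5. **Accident and feedback.** Unsafe behavior ends in an accident with
   probability `accident_prob` (defaults to `SR`).  An accident lowers the
   attitude by `delta_accident`; a lucky escape raises it by `delta_lucky`;
   safe behavior leaves it unchanged.  The perception coefficient moves
   inversely with the attitude change, `p ← max(p − ΔAT, 0.01)`, so a
   worker drifting toward risk-taking also perceives less risk.

Updates are synchronous: every worker's day uses the previous day's
acceptance values of their colleagues, so results do not depend on agent
iteration order.

The attitude-feedback rule in stage 5 is a deliberately minimal additive
surrogate: the qualitative directions (accidents correct, escapes breed
complacency, safe days change nothing) are well grounded, but no
quantitative functional form is available, so two configurable magnitudes
are used, with the accident response the stronger by design
(`delta_accident = 0.1`, `delta_lucky = 0.02`).

## Team topology

Workers occupy a fixed rectangular grid (default 200 workers, 20×10),
row-major by id.  The colleague set is the `k = 20` nearest co-workers by
Euclidean distance on grid coordinates, ties broken by ascending id, cached
once per layout.  The colleague effect is their unweighted mean acceptance
(the minimal aggregation assumption); acceptance is initialized to the
initial attitude so the day-1 colleague effect is defined.  A one-worker
team falls back to the worker's own acceptance.

## Parameters and defaults

| parameter | default | meaning |
| --- | --- | --- |
| `n_workers`, grid | 200, 20×10 | crew size and layout |
| `n_days` | 200 | working days simulated |
| `replicates` | 30 | seeded runs per scenario |
| `site_risk` | 0.45 | per-worker per-day exposure probability; also the default conditional accident probability |
| `sa0`, `sk0` | 0.8, 0.8 | initial awareness and knowledge (constant thereafter) |
| `at0` | 0.5 | initial attitude (the risk-neutral point) |
| `p0` | U(0.4, 1) | initial perception coefficient, per worker |
| `WN` | U(0.1, 0.9) | per-worker management norm, drawn once (norm heterogeneity is manager-level, so it is not re-drawn daily) |
| `ar_mu`, `ar_sigma` | 0.5, 0.15 | actual-risk distribution: mid-scale hazard with moderate spread, truncated to [0, 1] |
| `conformity`, `rule_awareness` | 0.4, 0.4 | behavioral weights; level anchors L/M/H = 0.05/0.4/0.9 for conformity and 0.1/0.4/0.9 for rule awareness (the endpoints of the studied range and its critical midpoint) |
| `delta_accident`, `delta_lucky` | 0.1, 0.02 | attitude feedback magnitudes |
| `eps_halfwidth` | 0 | disturbance on the acceptance equation |
| `steady_window` | 50 | trailing days averaged for the steady-state rate (the trailing quartile of the default horizon; clamped to the horizon on short runs) |

The "high-level management norms" regime used for the rule-awareness sweep
is `WN ~ U(0.6, 0.9)` with conformity 0.05 — the upper third of the default
norm support.

## Randomness and reproducibility

Replicate seeds are spawned deterministically from a single master seed
(`numpy.random.SeedSequence.spawn`), and scenarios inside one experiment
family share the master seed so replicate draws are paired and comparisons
are matched.  Each simulated day consumes a fixed number of uniform draws
(four length-N vectors: exposure, actual-risk quantile, discovery,
accident; plus a disturbance vector only when `eps_halfwidth > 0`),
regardless of outcomes, so a run is a pure function of (config, seed) and
can be replayed worker-by-worker.  The actual risk is produced from its
uniform draw through the truncated-normal quantile function, so it costs
exactly one draw.  Everything downstream (ensembles, sweeps, the phase
surface, CSV outputs) is byte-reproducible from the manifest the CLI writes
next to every result.

## Numerical choices

* All unit-interval state variables are clamped after every update; the
  perception coefficient is floored at 0.01 (its update is unbounded below,
  and a non-positive coefficient would invert risk semantics).
* The tie `PR = RA` resolves to safe behavior — a measure-zero, conservative
  convention.
* Boxplot summaries use Tukey's 1.5×IQR whiskers; quartiles use linear
  interpolation.
* The "low-rate region" of the phase surface is the set of (c, a) cells with
  ensemble-mean rate below 0.1 at a checkpoint, matching the bound quoted
  for the best scenario.

## What the simulator does and does not emulate

The synthetic crews are homogeneous in awareness, knowledge and initial
attitude; only perception coefficients and norms vary across workers.  Real
crews have heterogeneous experience, turnover, task-dependent exposure and
within-day sequences of hazards, none of which are modelled.  Passing tests
therefore demonstrate the internal consistency and the qualitative
mechanics of the cognition chain under the stated conditions, not predictive
accuracy for any real construction site.

## Known limitations

* **Attitude collapse dominates the long run.**  With the default feedback
  magnitudes and the accident probability equal to the site risk (0.45),
  the expected attitude drift per unsafe act is
  0.55·0.02 − 0.45·0.1 = −0.034 < 0, so attitudes of risk-taking workers
  collapse toward 0 well within the 200-day horizon.  The steady-state
  acceptance then reduces to roughly `a·E[WN]` plus a conformity echo, which
  *increases* with rule awareness.  Consequently the steady unsafe rate is
  monotone in `a` in every norm regime this package can express, and the
  dedicated acceptance tests for a mid-`a` dip and for a corrective effect
  of rule awareness under high conformity measure the opposite direction
  and fail.  Reproducing those non-monotonic effects requires an attitude
  feedback law with more structure (for example, relaxation toward the
  norm-attitude discrepancy) than the additive surrogate; raising
  `delta_lucky` enough to flip the drift sign instead destabilizes every
  low-`a` scenario and destroys the low-rate optimum scenario, so it is not
  a fix.
* The accident probability given unsafe behavior reuses the site risk — a
  modelling shortcut that makes accidents very frequent; `accident_prob`
  can be set independently.
* Awareness and knowledge are constants: training and demonstration effects
  are outside the model's scope.
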
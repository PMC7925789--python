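# Methods

## Model class and update scheme

`reifnet` simulates temporal–causal networks in which every state `Y`
relaxes toward its aggregated causal impact,

    Y(t+Δt) = Y(t) + η_Y · [ c_Y(ω_{X1,Y}X1(t), …, ω_{Xk,Y}Xk(t)) − Y(t) ] · Δt,

with per-state speed factor `η_Y` and combination function `c_Y`.
Adaptivity is expressed by *reification*: a connection weight, speed factor
or function parameter may be supplied, at every step, by the current
activation of a dedicated self-model state. A first-order self-model level
(W-states, Hebbian weight dynamics) and a second-order level (H-states for
the learning rate, M-states for the persistence factor of the Hebbian
update) give a second-order adaptive network: plasticity whose own
mechanism is plastic (metaplasticity).

Key numerical choices:

- **Explicit Euler, Δt = 0.5 by default.** The scenario horizons are long
  (hundreds of model-time units) and every right-hand side is bounded and
  smooth, so a first-order explicit scheme is appropriate; the test suite
  verifies the O(Δt) convergence order by step-halving. A spec is warned
  when `η·Δt > 1` for any state, the regime where the update stops being a
  convex combination.
- **Synchronous (Jacobi) update.** All aggregated impacts *and* all reified
  characteristics are read from the snapshot at `t` before any state is
  written, so results are independent of state declaration order. A
  sequential (Gauss–Seidel) sweep would make trajectories depend on row
  order in the role matrices, which is fatal for reproducibility.
- **Clamping.** Activations are clipped to [0, 1] after each step
  (`clamp_mode`, on by default). For well-formed specs — combination values
  in [0, 1], `η·Δt ≤ 1`, initial values in [0, 1] — the update is a convex
  combination and the clamp never engages; property tests run unclamped to
  confirm it. The clamp matters only for models that use negative
  (suppressive) weights feeding linear (`eucl`, n = 1) states.
- **Exogenous inputs.** Stimulus states are overwritten from the scenario
  schedule after every step; they are world states, not dynamical ones.
- **alogistic tails.** The printed advanced-logistic formula is slightly
  negative for inputs far below threshold; since activations are
  interpreted on [0, 1] the function clamps below at 0 (exact-formula mode
  is available via the `clamp` parameter). The algebraic supremum 1 is also
  enforced against float round-off.
- **eucl domain.** Odd integer orders accept negative values (signed root);
  fractional orders with a negative value raise a domain error. `λ` is
  conventionally the sum of the incoming positive weights, which normalises
  the output to [0, 1].
- **Equilibrium detection** reports the earliest grid time from which every
  state moves less than `tol` per unit time through the end of the run,
  requiring at least `window` time units of evidence; nothing is
  interpolated below the grid.
- **Degenerate inputs.** A state with no incoming connections keeps its
  value (inputs are schedule-driven); an empty impact list evaluates to 0
  under both `eucl` and `alogistic`; all-zero blend weights are a
  specification error, not a silent NaN.

## The bundled child-agent model

The 84-state network (39 base states, 21 W-states, 12 M- and 12 H-states)
models a child interacting with a narcissistic parent through three input
channels: the parent looking happy (`es_happy`), the parent unhappy/abusive
(`es_unhappy`), and social-media use (`ws_s`). Level I wires five
pathways: sensing; social contagion (belief `cbs_plus` → striatum → insula
→ self-love/self-reward feelings → happy expression `ces_happy`); an
own-evaluation/action pathway (`eval_h` → `cps_act` → satisfaction) that
*suppresses* the mimicry circuit; content sharing (evaluation, novelty /
emotion / urge feelings, `ps_share`); and an abuse pathway (low esteem
`cbs_minus`, depression, stress, isolation) with a learned
avoidance/coping branch (`eval_d` → `os_avd` → `ps_avd` → `es_avd`) that
feeds back suppressively on exposure, distress and isolation.

All 21 printed W-state connections are wired as listed (e.g. `W_4` =
striatum→insula, `W_10..12` = novelty/emotion/urge → `ps_share`); M/H
metaplasticity covers `W_1..W_12`, while `W_13..W_21` get constant learning
rate and persistence (the second-order level is only defined for the first
twelve in the source description; the constants are flagged in the ledger).

### Parameter provenance and calibration

The source model description prints only: `ps_share` has in-degree 4 with
constant weight 0.5 on its `eval_s` slot, speed factor 0.6 and
`alogistic(σ=10, τ=0.2)`; ten named states use the Euclidean function; and
`M_7`, `M_8` start at 1 in the non-narcissistic profile. Every other
number is a reconstruction, and `ParameterLedger` tags each numeric
role-matrix cell `printed` or `reconstructed-default` so the gap is
auditable (`ledger.json` beside the CSVs).

The reconstructed defaults were calibrated once, by simulating the four
scenarios, to the operating point where the narrated qualitative behaviours
emerge; they are not fits to any quantitative data. The governing choices:

- **Excitatory weight 0.7**, suppressive weights −0.4 to −0.9 (coping and
  avoidance links are the strong ones — they must break the
  esteem↔distress feedback loop).
- **Thresholds.** Each alogistic state's τ is set near the midpoint of its
  quiescent and active summed impact (σ = 8), so pathways are silent until
  driven and saturate when carried. A uniform τ-per-in-degree rule was
  tried first and rejected: it leaves every state partially active at rest,
  and the whole network saturates within ~30 time units, destroying the
  plateau/episode structure the scenarios are about.
- **Level III slow and initially low** (upward weights 0.35, σ = 4,
  τ = 0.7, speed 0.02, initial 0.02): learning rates and persistence start
  near zero and charge up only while pre- and post-synaptic states are
  co-active. This is the mechanism behind the narrated *late acceleration*:
  `W_4` (striatum→insula) strengthens first, raises insula activation,
  which recruits `W_5`/`W_6` and only then lets the happy expression leave
  its mimicry plateau.
- **Memory traces integrate slowly** (hippocampal states 0.01–0.02,
  sharing experience 0.05, realisation learning `W_19` at 0.011): the
  coping pathway needs a long exposure history before `eval_d` crosses its
  (raised, 0.48) threshold, which places endogenous coping onset around
  t ≈ 440 — after the 400-unit isolation horizon, inside the 800-unit
  relief horizon.
- **Profiles.** `narcissistic-prone` is the ledger baseline.  `resistant`
  starts with evaluation ability and own-behaviour memories
  (`W_1` = 0.5, `hipp_1` = 0.6), a weaker belief drive (srs_h→cbs_plus
  0.15), harder evaluation-suppression of the striatum (−0.7), and the
  printed `M_7 = M_8 = 1`. Profiles differ only in reconstructed cells.
- **Scenarios.** Stimuli ramp 0→1 as a 5-unit staircase (avoids
  step artefacts); social-media episodes strictly alternate 60 off / 60 on.
  `unhappy_coping` overlays `hipp_2 = 0.6`, `W_19 = 0.3` (coping memories
  already formed — the "firm" child), which is what distinguishes it from
  the cold-start `unhappy_isolation` under identical inputs.

### Problem sizes

Shipped runs use Δt = 0.5: horizons 320 (`happy_offline`), 480
(`happy_social`), 400 (`unhappy_isolation`/`unhappy_coping`) and 800
(`coping_relief`), i.e. 641–1601 grid points over 84 states; the
engine-correctness probes use 100 random 6-base-state networks × 500
unclamped steps, ten ≤ 4-state networks × 50 steps against the
straight-line oracle, and 10,000 Hebbian iterations against the closed-form
fixed point `V1V2/(1−μ+V1V2)`.

## What the tests do and do not show

The synthetic scenarios emulate the *study conditions*: constant or
square-wave parent/social-media stimuli driving one child agent. Passing
tests show that the engine implements the stated equations exactly (oracle
equivalence to 1e−12, analytic closed forms, boundedness, first-order
convergence) and that the reconstructed model reproduces the narrated
qualitative signatures — mimicry plateau then post-learning contagion;
urge persistence across off-episodes; flat self-love weights for the
resistant profile; distress growth under abuse; monotone post-coping
relief; equilibrium under firm coping.

They do not show quantitative agreement with the original runs (the full
numeric parameterisation is deposited elsewhere and not printed, so exact
trajectories — including the original's slower time axis, e.g. contagion
at t ≈ 280 rather than ≈ 150 here — are out of reach by design), nor
anything about real children: the model is a theory instrument, with no
empirical validation in its source either.

## Known limitations

- The parent is exogenous (three stimulus signals); no parent-internal
  dynamics, no child→parent feedback loop.
- Explicit Euler only in the engine proper; no event handling beyond
  equilibrium detection.
- `combine` supports weighted blends of several functions per state for
  format fidelity, but no bundled state uses more than one.
- The roster of 39 base states required dropping two text-named states
  (a cortex conceptualisation state and a separate action-execution state)
  whose roles are absorbed by neighbours; the ledger and tests pin the
  resulting structure.
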
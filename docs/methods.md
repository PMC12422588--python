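# Methods

## Model

`polcomp` studies capacity-limited action selection in contextual bandits.
A task is a state distribution P(s) over |S| discrete states and a reward
matrix Q(s, a) over |A| actions. A policy π(a|s) earns trial-averaged
reward

    V_π = Σ_s P(s) Σ_a π(a|s) Q(s, a)

and pays a cognitive cost equal to its *policy complexity*, the mutual
information between states and actions,

    I_π(S; A) = Σ_s P(s) Σ_a π(a|s) log [ π(a|s) / P(a) ],
    P(a) = Σ_s P(s) π(a|s).

The resource-rational agent maximizes V_π subject to I_π(S; A) ≤ C. The
Lagrangian solution is

    π*(a|s) ∝ exp[ β Q(s, a) + log P*(a) ],

with P*(a) the optimal marginal, computed by the Blahut–Arimoto (BA)
alternating fixed point. Sweeping the multiplier β ≥ 0 traces the
reward-complexity frontier: the maximal reward attainable at each
complexity. The frontier is concave and its slope at the point traced at β
is 1/β (in nats). At β = 0 the optimum is the best state-independent
policy, a point mass on the action with the highest general value
V(a) = Σ_s P(s) Q(s, a); this endpoint is computed analytically (BA is
degenerate there) with ties broken towards the lowest action index.

The package's contribution on top of plain policy compression is *action
subsampling*: the agent optimizes over a consideration set drawn from a
proposal distribution — flat, proportional to general value, or the oracle
marginal P*(a) of the full task — with or without replacement, and either
runs BA on the retained actions (no bias correction) or applies
self-normalized importance sampling (SNIS) to estimate the full-task
optimum from the with-replacement sample:

    π̂*(a|s) ∝ Σ_j exp(β Q(s, α_j)) · P̂(α_j)/P₀(α_j) · 1[α_j = a].

The unknown optimal marginal is replaced self-consistently by the current
estimate's marginal P̂ and the update is iterated BA-style. Repeated draws
enter through their counts, so the estimator is frequency-aware; it is
asymptotically unbiased in the sample size n but biased at finite n.

## Units and conventions

All internal computation is in natural log; complexities are reported in
bits. β is defined against the natural-log stationarity condition above.
Action and state indices are 0-based everywhere, including files. Reported
"loss" is signed: V_π minus the full frontier's reward at the achieved
complexity, ≤ 0 for any realizable policy (comparisons between algorithms
in the tests use magnitudes).

## Numerical choices

* **BA stopping.** Two rules. (1) Max absolute policy change < `tol`
  (default 1e-10 for a single call). (2) An optional duality-gap
  certificate: the iteration maximizes the concave potential
  G(P) = Σ_s P(s) logsumexp_a[β Q(s, a) + log P(a)] over the marginal
  simplex, and concavity bounds the remaining improvement by
  max_a ∂G/∂P(a) − 1. Stopping at gap < `gap_tol` certifies the achieved
  Lagrangian within `gap_tol` nats. This matters because tasks with
  near-tied rewards (e.g. i.i.d. Uniform(0,1) matrices) leave the policy
  drifting along near-flat directions for tens of thousands of iterations
  after the achieved (complexity, reward) pair has stopped moving at any
  relevant precision. `trace_frontier` uses tol 1e-12, gap 1e-10 scaled by
  min(β, 1) — the gap bounds βV − I, so the implied reward error is
  gap/β — plus a 20000-iteration cap; capped betas are collected into one
  aggregated warning and their points are feasible, monotonically improved
  iterates. Frontier invariants (complexity non-decreasing in β, reward
  non-decreasing and concave in complexity) are validated on construction.
* **Initialization.** Uniform by default: the optimization is convex, so
  the converged value is init-independent, and uniform init makes runs
  reproducible; a seeded Dirichlet init is available. SNIS initializes
  uniform over the sampled support. SNIS row normalization runs in log
  space (log-sum-exp), so strongly negative β·Q cannot underflow.
* **β grid.** Default: 60 geometric points in [0.05, 50] plus the analytic
  β = 0 endpoint. There is no general closed form linking β to the
  capacity C, so the frontier is traced on the grid and queried by
  piecewise-linear interpolation (`frontier_reward_at`; clamped at both
  ends). The chord under-estimates a concave curve between knots, so
  *verification* of dominance claims uses `frontier_upper_bound`, the
  pointwise minimum of knot tangents — a certified upper envelope.
* **Probability floors.** Marginals below 1e-300 are floored inside logs;
  mass outside a sampled support is exactly zero.
* **Degenerate inputs.** β = 0 is handled analytically; single-action
  tasks collapse to a frontier at 0 bits; states never visited in choice
  data fall back to the prior-mean (uniform) policy row with a logged
  warning; general-value proposals on tasks with non-positive V(a) shift
  by −min V + 1e-6·range before normalizing, preserving the ranking.

## Simulation design

One "rep" draws a consideration set from the proposal, derives a policy
(BA on the retained actions, or SNIS on the raw sample), and is scored on
the *true* task against the full-task frontier. Per-β aggregation is
mean ± SEM (sample SD / √n_reps) of complexity, reward, and loss. The
default design is 200 reps per β (the tests and worked examples run 50 to
keep a desk-scale footprint; the examples state the sizes they use). The
three regimes are: BA without replacement (sizes are consideration-set
sizes Nₐ), SNIS with replacement and BA with replacement (sizes are sample
sizes n); SNIS is undefined without replacement and the condition type
enforces that. Default size grids are {2, 4, 8, 16, 32} for both regimes —
the powers of two spanning singleton-like sets up to the full 32-action
space of the random task; they are configuration options, not fixed
constants.

Two reproducibility mechanisms are deliberate:

* every rep's seed is `SeedSequence((master_seed, crc32(key), rep))` with
  a key of (task, sampling regime, size, β) — any condition can be re-run
  in isolation;
* the key omits the proposal and the algorithm, and sampling inverts the
  proposal CDF on uniform variates, so conditions differing only in
  proposal or algorithm consume identical uniforms. Comparisons the suite
  exists to make — flat vs general-value, BA vs SNIS at matched n — are
  thereby paired (common random numbers), which shrinks the variance of
  mean-loss differences well below that of independent sampling. At n = 2
  under a flat proposal, BA and SNIS coincide exactly (counts are equal or
  the support is a singleton), so their comparison there is an equality.

The noisy-representation suite perturbs Q(s, a) with i.i.d. Gaussian noise
of a given SD, lets the agent pick its consideration set (uniformly among
non-safety actions, with the safety action either retained or excluded)
and optimize via BA *on the noisy Q*, then scores the policy on the true
task. The perturbed task drops the safety marker, since its column is no
longer constant.

## Synthetic choice data and estimators

`simulate_agent` emulates a test block: counterbalanced schedules present
each state exactly n_trials/|S| times in shuffled order (the empirical
state distribution is exactly flat, as in a counterbalanced design);
actions are drawn from the generating policy; rewards follow Q
deterministically. It does not model response times, learning within a
block, lapses, or timeout trials — so recovery results certify the
estimators under the model's own assumptions, not robustness to real
attentional or motor noise.

Policy complexity is estimated as the MI of the Dirichlet posterior-mean
policy: per state, π̂(a|s) = (count(s,a) + α) / (count(s) + |A|·α) with
symmetric α = 0.01, evaluated under the empirical state frequencies. The
small α shrinks the plug-in estimate just enough that empirical
(complexity, reward) points do not land above the frontier — the property
the recovery tests check at 96 trials. The plug-in MI of raw counts is
biased upward by roughly (|S|−1)(|A|−1)/(2 N ln 2) bits; at 96 trials this
≈ 0.2 bits of head-room is what keeps noisy reward means below the
interpolated frontier. The consideration-set size Nₐ is the number of
distinct actions chosen at least `min_count` times (default 1; 2–3 guard
against stray key presses and make the count non-increasing in the
threshold).

## Known limitations

* Near a support transition of the optimal policy (for the 6×7 safety
  task, β ≈ 1.3–1.9, where the optimum leaves the all-safety vertex) the
  SNIS fixed point is hypersensitive to count noise: single draws at
  n = 10⁴ can land on the wrong branch entirely. The consistency checks
  therefore report the median over seeds at such betas.
* BA converges sublinearly towards reduced-support optima; at small β on
  near-tied tasks some betas stop at the iteration cap. Their points are
  feasible lower bounds and never violate the validated frontier
  invariants.
* Exhaustive subset enumeration refuses beyond 10⁵ subsets; optimal
  consideration-set *search* is out of scope.
* The scarce-reward task generator (rich columns Uniform(0.5, 1), poor
  columns Uniform(0, 0.05)) is a synthetic stand-in pinned down only by
  the qualitative property that reward concentrates on few actions; both
  ranges are parameters.
* Frontiers assembled pointwise across branches (the Nₐ-specific curve)
  carry no meaningful β per point (stored as NaN) and are ordered by
  complexity; the symmetric-task shortcut solving one representative
  subset per safety branch is valid only when non-safety actions are
  exchangeable, and full enumeration is available behind a flag.
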
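# Model and methods

## The model

`trustsim` simulates a society of `n = |I| + |J|` agents split into a dominant
group I (default 80) and a subordinate group J (default 20).  Every social
encounter is a two-player coordination game with Pareto-ranked pure-strategy
equilibria — mutual collaboration strictly better than mutual defection, with
no incentive to cheat, only to match.  Because intentions cannot be credibly
revealed, each player acts on a belief about the partner, and beliefs are held
about *groups*, not individuals: agent `i` carries one directed willingness
`rho_{i:G,t} ∈ [0,1]` toward each group `G`, read both as the subjective
probability that a member of `G` will collaborate and as `i`'s own probability
of choosing to collaborate with one.

One **period** is one dyadic interaction (the model counts time in
interactions; at, say, 50 interactions per society per day, the default 10^7
horizon spans more than five centuries — `metrics.years_equivalent`).  Each
period:

1. a dyad is drawn uniformly from all C(n,2) unordered pairs, so cross-group
   encounters occur with probability |I||J|/C(n,2);
2. both participants simultaneously choose collaborate/defect from their
   pre-interaction belief toward the partner's group (a Bernoulli draw with
   success probability equal to the belief);
3. each participant updates that same directed belief by exponential
   smoothing toward the partner's observed action `s ∈ {0,1}`:

       rho_new = alpha * s + (1 - alpha) * rho_old.

Initial beliefs encode prejudice: subordinate members' beliefs toward I are
drawn U(0,1) while dominant members' beliefs toward J are drawn U(0, theta)
with theta < 1, i.e. the dominant group systematically underestimates the
subordinate group's worth as collaborators while individual variation remains.

### Conformity

In conformity mode the learning rate is endogenous: at every moment

    alpha_{i,t} = | rho_{i:G,t} - rho_{I:G,t} |,

the absolute deviation of the agent's belief from its group's norm toward the
target group.  The norm is a weighted group average in which members whose
beliefs sit close to their peers' weigh most: with total pairwise distance
`d_i = sum_k |rho_i - rho_k|`,

    rho_{I:G,t} = sum_i rho_i / d_i  /  sum_i 1 / d_i.

Agents near the norm have alpha near zero and effectively stop learning;
deviants update quickly.  Two robustness variants weight by the inverse
distance from the arithmetic group mean or median instead.  The direction of
the weighting for these variants (inverse rather than direct) follows the
primary formula's logic — normative members weigh more.

### Interventions

*Instant enlightenment*: from period `T_e` onward the whole dominant group is
replaced by "perfectly enlightened" individuals holding one baseline value
toward both groups (`rho_{i:J} = rho_{i:I}`), drawn once per agent from
U(0,1).  The default `frozen` baseline mode re-imposes these values every
period — long-term enlightenment in which the new generation keeps
collaborating regardless of the subordinate group's learned distrust; a
`redraw` mode draws a fresh enlightened generation every period instead.
*Gradual replacement*: one uniformly chosen dominant agent is replaced every
`replacement_interval` periods (default 100) by an enlightened individual
who, by default, then learns like everyone else.  The distribution of
enlightened baselines is not pinned down by the equality constraint alone;
U(0,1) is used.

## What the simulator emulates — and what it does not

The synthetic societies are well-mixed (no spatial or network structure),
payoff-free (only the behavioral implication of the coordination game is
kept: act on your belief), and memory-free at the individual level (beliefs
attach to groups, not partners).  Group membership is fixed apart from
explicit replacement.  Passing tests therefore demonstrate properties of this
idealized mechanism — self-fulfilling prophecy, conformity-induced freezing,
asymmetric recovery — not calibrated predictions for any real society.

In-group beliefs are simulated with neutral U(0,1) priors but are *exactly*
decoupled from every cross-group statistic: separate RNG substreams for
in-group vs cross-group initialization and fixed per-period consumption of
action randomness make cross-group trajectories bit-identical under any
change of in-group priors (a tested invariant).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_dominant`, `n_subordinate` | 80, 20 | group sizes; the 4:1 ratio drives the asymmetry in how fast each group's mean moves and whose learning rate decays first |
| `theta` | 0.5 | upper bound of the dominant group's prejudiced prior U(0, theta); expected initial stigma is (1−theta)/2 |
| `alpha_constant` | — | constant learning rate (constant mode); 0 freezes all beliefs |
| `norm_variant` | inverse pairwise | how the conformity norm weights members |
| `horizon` | 10^7 | interactions simulated; conformity dynamics freeze around 10^4–10^5, the long tail verifies persistence |
| `checkpoints` | 200 | log-spaced recording times (all figures of merit live on log time) |
| `convergence_threshold` | 1e-4 | group-mean gap defining belief convergence |
| `n_replications` | 10 | desk-scale default; raise to 100 for smoother aggregates |

## Numerical and design choices

* **Hot path.** The interaction loop is compiled (numba).  For every directed
  (observer-group → target-group) pair a sorted copy of the member beliefs is
  maintained incrementally (one O(n) memmove per belief change); all `d_i`
  and the norm are evaluated in one O(n) prefix-sum pass.  An exact sublinear
  refresh of the norm is not possible — a single belief change perturbs every
  `d_k` and the weights enter nonlinearly — so O(n) per query is the
  efficient frontier; equivalence with the O(n^2) brute-force definition is
  enforced by tests and an optional periodic in-run audit (`audit_interval`).
* **Degenerate weights.** If all member beliefs coincide the norm is that
  common value.  Distances below 1e-12 are floored at 1e-12 (this also guards
  the prefix-sum formula against catastrophic cancellation when the spread is
  at float resolution); the mean/median variants use weights
  `1/(|rho_i − m| + 1e-12)` so the member at the median gets the largest
  finite weight.
* **Simultaneity.** Both dyad members act from pre-interaction beliefs and
  both update afterwards; conformity rates are evaluated on the
  pre-interaction configuration.  This removes within-interaction order
  dependence.
* **RNG.** A master seed spawns named substreams (cross-group init, in-group
  init, dyad sampling, each group's action draws, interventions) via
  `numpy.random.SeedSequence`; replications get independent child streams.
  Random numbers are pre-drawn in fixed chunks of 2^20 interactions (part of
  the reproducibility contract).  Identical configuration and seed give
  bit-identical output.
* **Actions.** The Bernoulli rule is the default reading of "willingness" as
  a probability; a deterministic threshold rule (collaborate iff belief ≥
  0.5) is available as a config variant.  Under the threshold rule an
  initially prejudiced society collapses to mutual defection — the observed
  stable convergence near the size-weighted mean requires the stochastic
  rule, which is one reason it is the default.
* **Convergence measurement.** The kernel tracks the exact first interaction
  at which |mean_I→J − mean_J→I| drops below the threshold (checked every
  period against running sums that are re-synchronized at checkpoints to
  cancel float drift).  With Bernoulli actions the gap keeps fluctuating in a
  stationary band of width ~alpha/|J| after beliefs have converged, so first
  passage below 1e-4 is dominated by the chance of landing inside a band far
  narrower than the noise floor — odds that scale like 1/alpha and cancel the
  faster approach.  The speed-of-learning trend (faster learning → faster
  convergence) is therefore measured at threshold 0.01, above the noise
  floor, where the approach phase dominates; the 1e-4 default is kept for
  the convergence statistic itself.
* **Checkpoint statistics.** Summary statistics other than the exact
  convergence time are pure functions of the recorded trajectory (the `stats`
  CLI subcommand recomputes them from a saved CSV).  The decline/recovery
  ratio uses endpoint rates: mean per-period decline from t=0 to the
  checkpoint nearest `T_e`, over mean per-period accrual from there to the
  horizon; it is NaN when the accrual is non-positive.
* **Truncated-normal priors** are rejection-sampled into the open interval
  (0,1).

## Scaled-down study sizes

Full-scale runs (10^7 interactions, up to 100 replications) complete in
minutes; the test suite uses reduced sizes chosen so each check retains
power: trend and persistence checks run at horizon 10^5–10^6 (the conformity
dynamics freeze around 10^4, so longer horizons only confirm persistence)
with 5–20 replications, except the two weak-stigma presets (theta = 0.9,
0.99), where the expected terminal gap is tiny relative to per-replication
noise (sd ≈ 0.04) and 100 replications are used.  The acceptance script runs
the two headline scenarios at full horizon.

## Known limitations

* The norm evaluation cost makes conformity runs O(horizon × group size);
  the 1000-agent presets take proportionally longer.
* Statistics involving a common "converged value" inherit the neutral drift
  of the consensus level: the population mean is a martingale, so individual
  replications wander while the replication average stays near the
  size-weighted initial mean — replication counts matter more than horizon
  for those estimates.
* `redraw` enlightenment consumes `|I|` random numbers per period and is
  correspondingly slower; it exists as a robustness variant, not a default.
* The spec-level claim that stigma persists holds only in expectation for
  near-vanishing initial prejudice (theta → 1); single replications can show
  either sign of the terminal gap.
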
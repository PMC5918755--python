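# trustsim

Agent-based simulation of how initial prejudice becomes self-sustaining
intergroup mistrust.  `trustsim` is aimed at computational social scientists
studying discrimination, opinion dynamics, and self-fulfilling prophecies: it
models a society of two groups — a dominant majority I and a subordinate
minority J — whose members repeatedly meet in pairwise coordination games,
act on beliefs about each other's groups, and learn from what they observe.

## The model

Each agent holds a directed willingness to collaborate `ρ_{i:G,t} ∈ [0,1]`
toward each group G — both a belief about G and the probability of choosing
the collaborate strategy against one of its members.  Each period one dyad is
drawn uniformly from all pairs; both participants act simultaneously
(collaborate with probability equal to their belief) and then update the
belief toward the partner's group by exponential smoothing toward the
partner's action `s ∈ {0,1}`:

    ρ_{i:J,t} = α_i · s_{j,t−1} + (1 − α_i) · ρ_{i:J,t−1}

Initial beliefs encode prejudice: `ρ_{j:I,0} ~ U(0,1)` for the subordinate
group but `ρ_{i:J,0} ~ U(0,θ)`, θ < 1, for the dominant group.  With a
constant learning rate the stigmatized group learns to distrust right back
and both groups meet near the size-weighted mean of their initial levels (a
self-fulfilling prophecy).  Under **social conformity** the learning rate is
endogenous,

    α_{i,t} = | ρ_{i:J,t} − ρ_{I:J,t} |,

the deviation from a group norm that weights each member inversely to its
total pairwise belief distance `d_i = Σ_k |ρ_i − ρ_k|`:

    ρ_{I:J,t} = Σ_i ρ_{i:J,t} · d_i⁻¹ / Σ_i d_i⁻¹

Learning then freezes before stigma disappears, and the society stabilizes
with the dominant group permanently underestimating the subordinate group.
Enlightenment interventions (instant or gradual replacement of the dominant
group by agents who treat both groups identically) can be scheduled at any
period; destroyed trust recovers orders of magnitude more slowly than it was
lost.  See `docs/methods.md` for the full model description and numerical
choices.

## Worked example

```python
import numpy as np
from trustsim import load_preset, run_simulation

result = run_simulation(load_preset("base_conformity", n_replications=10, seed=1))
sub = np.mean([r.summary.terminal_mean_subordinate_toward_dominant
               for r in result.replications])
dom = np.mean([r.summary.terminal_mean_dominant_toward_subordinate
               for r in result.replications])
print(f"after 1e7 interactions: subordinate->dominant {sub:.3f}, "
      f"dominant->subordinate {dom:.3f}")
tr = result.aggregate_trajectory
for t in (0, 10_000, 10_000_000):
    k = int(np.argmin(np.abs(tr.times - t)))
    print(f"t={tr.times[k]:>8}  I->J {tr.mean_dominant_toward_subordinate[k]:.3f}  "
          f"J->I {tr.mean_subordinate_toward_dominant[k]:.3f}  "
          f"mean alpha I {tr.mean_alpha_dominant[k]:.4f}")
```

prints

```
after 1e7 interactions: subordinate->dominant 0.386, dominant->subordinate 0.327
t=       0  I->J 0.257  J->I 0.480  mean alpha I 0.1238
t=    9884  I->J 0.324  J->I 0.388  mean alpha I 0.0070
t=10000000  I->J 0.327  J->I 0.386  mean alpha I 0.0000
```

Read: the subordinate group starts willing to collaborate about half the time
(0.480) but, facing a prejudiced majority (0.257), suppresses its trust to
~0.39 within 10^4 interactions; the dominant group's learning rate has by
then collapsed (0.124 → 0.007), so its unfairly low view of the subordinate
group (~0.33) freezes and the gap never closes over the remaining 10^7
interactions — the subordinate group remains more trusting than it is
trusted.

The same experiments are available from the shell:

```bash
trustsim presets                       # list every scenario
trustsim run --preset base_conformity --replications 10 --seed 1 --out-dir out/
trustsim stats out/trajectories.csv    # recompute summaries from the CSV
```

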
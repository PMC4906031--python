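# emolearn

Simulators for implicit emotional learning: how the brain revalues the
stimuli that elicit it, and when the resulting responses become resistant to
extinction.

## The problem

An unconditioned stimulus (UCS) elicits a CNS response with two components:
an **active** part `x`, sustained by the stimulus' energy flux, and a
**reactive** part `i_R`, self-induced by mere perception of the stimulus.
The reactive part equals a gain `α` times the *expected* response
(`|α| < 1` is required for a stable emotional system), and the expectation is
revised trial by trial through prediction errors.  The basic recursion and
its consequences are

    y[n] = x[n] + α·y[n-1]          →  y∞ = x/(1-α)     (revaluation)
    y[n] = α·y[n-1] = y0·αⁿ                              (devaluation)

with extensions for contrast overshoots (`K`), weighted-history and periodic
pattern expectations, classical conditioning with implicit UCS inflation (a
causal extension of the Rescorla–Wagner model whose acquisition curve it
contains exactly), misattribution of reactive responses (the mechanism of
evaluative conditioning, ceiling `i_U/(1-α)`), and a continuous-time
tracking system with transfer function

    H(s) = (K·τ₂·s² + (K+τ₂)·s + 1) /
           (τ₁(τ₂+K-Kα)·s² + (τ₂+K-Kα+τ₁-ατ₁)·s + (1-α))

whose saturating realization explains trauma-like responses that safe-context
exposure cannot devalue.  The package is for computational
neuroscientists and psychologists who want to simulate these dynamics,
reproduce the worked regimes, and run parameter-recovery experiments on
synthetic data.

## Worked example

```python
import numpy as np
from emolearn.revaluation import RevaluationParams, StimulusSchedule, simulate_revaluation
from emolearn.protocols import ClimbingConfig, iterative_climbing
from emolearn.continuous import scenario_figure6

# Three constant-intensity trials, alpha = 0.5: the response climbs toward x/(1-alpha) = 2
trace = simulate_revaluation(StimulusSchedule.constant(1.0, 3), RevaluationParams(alpha=0.5))
print(trace.y)                        # [1.    1.5   1.75 ]
print(trace.i_R)                      # [0.    0.5   0.75 ]

# Iterative climbing, alpha = 0.5, x1 = x2 = 1: phase asymptotes 4x then 6x
result = iterative_climbing(ClimbingConfig(x1=1, x2=1, alpha=0.5, phases=2))
print(result.asymptote)               # [4. 6.]

# Traumatic acquisition: the amygdala expected response saturates at 150,
# clamping the reactive response at alpha * 150 = 60
b1 = scenario_figure6("B1")
print(round(b1.i_R[-1], 6))           # 60.0
```

The first block shows revaluation: each trial's prediction error inflates the
expected response, so the reactive share grows from 0 to 0.75 while the
active intensity stays at 1.  The climbing protocol alternates two stimuli
while cross-injecting each other's reactive responses; with `α = 0.5` the
attributed response ratchets up by `2x` per phase without bound unless a
saturation cap freezes it.  The saturated scenario is the resistant-to-
extinction regime: zero active input, zero prediction error, reactive
response pinned at 60.

The same runs are available from the shell:

```
$ emolearn revalue --config cfg.yaml --out trace.csv     # cfg: {alpha: 0.5, x: 1.0, n_trials: 3}
$ emolearn figure6 --panel B1 --out b1.csv
$ emolearn climb --config climb.yaml --out phases.csv
```

Every run writes a manifest (command, config hash, seed, version) alongside
its trace.  See `docs/methods.md` for the model equations, the saturation
semantics and all numerical conventions.

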
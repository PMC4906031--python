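# Methods

## The model in one paragraph

A stimulus elicits a CNS response `y` made of an *active* part `x` (driven by
the physical energy flux) and a *reactive* part `i_R` (self-induced, driven by
information alone).  The reactive part is a fraction `alpha` of the *expected*
response, and the expectation is revised by prediction errors — the difference
between what was experienced and what was expected.  Everything in this
package follows from that loop: the discrete recursion `y[n] = x[n] +
alpha*y[n-1]` and its asymptote `x/(1-alpha)`; contrast overshoots scaled by a
coefficient `K`; a conditioning model in which a CS gradually gates the
reactive response of its paired UCS; misattribution dynamics that pump a
purely reactive response up to `i_U/(1-alpha)`; and a continuous-time tracking
system whose saturating accumulator produces responses that extinction cannot
touch.

## Discrete revaluation (`emolearn.revaluation`)

Per signalled trial, with expectation `p[n]` formed from the history:

    e_A[n] = x[n] + p[n]*(alpha - 1)          same-trial (actual) error
    y[n]   = x[n] + alpha*p[n] + K*e_A[n]     response with contrast
    e[n]   = y[n] - p[n]                      prediction error

With a last-outcome expectation this collapses to
`y[n] = (1+K)x[n] + (alpha + K*alpha - K) y[n-1]`, which is what the
simulator's trace must (and is tested to) reproduce against the explicit
two-equation construction.  Unsignalled (unexpected) trials elicit `x + K*x`
with no reactive component; the stored expectation snaps to that value, so a
run of unexpected elicitations produces a prediction error only on the first
one — otherwise the expectation would inflate without bound.

**Parameters.** `alpha` (dimensionless, `|alpha| < 1`; the stability theorem's
necessity direction is verified numerically, since at `alpha >= 1` the
constant-input response provably diverges).  `K` in `[0, 1)` (emotional
stability).  `filter_weights h_1..h_L`: nonnegative history weights.  The
package default is the single weight `(1,)` — the last-outcome expectation that
every closed-form result assumes.  A finite exponentially weighted window is
available through `exponential_weights(L=5, decay=0.5)`; the weights are
renormalized to sum to one because otherwise the constant-input fixed point
moves away from `x/(1-alpha)` (an un-normalized window of total weight `w`
gives `x/(1-alpha*w)`).  The CLI switches to the exponential filter whenever
`L`/`filter_lambda` appear in a config.

**Pattern expectation.** When a periodic stimulation pattern (period `N0`) is
recognized, the expectation blends the bottom-up filtered history with the
top-down stored pattern value `y[n-N0]`, weighted by a per-trial belief
`omega_P in [0,1]` (the two weights sum to one).  No update law for the belief
is imposed: it is a user-supplied sequence, with `ramp_belief` offered as a
convenience (zero during the first repetitions, then a linear rise) and
explicitly flagged as a modelling convenience.  With full belief and zero
input the trace replays the stored pattern scaled by `alpha` each period.

**Contrast feedback (open design point).** Whether the contrast term `K*e_A`
should feed the stored expectation is genuinely ambiguous: the collapsed
recursion implies it does, the unexpected-trial argument implies a one-shot
overshoot.  Both are implemented behind
`contrast_updates_expectation` (default True, the collapsed-recursion
behaviour); unexpected trials always store the full experienced response.

## Conditioning (`emolearn.conditioning`)

Synaptic strength `omega` is the potentiated fraction of a binary synapse
population: reinforcement moves it by `pot_rate*(1-omega)`, CS-alone trials by
`-dep_rate*omega`, so `[0,1]` is invariant.  Under pure acquisition this is
exactly the Rescorla–Wagner curve `1-(1-pot_rate)**(n-1)` (tested to 1e-12).
The package's point of difference is UCS inflation: within a trial, `omega` is
updated first, then

    i_R[n]  = alpha * (X + i_R[n-1]*omega[n])
    y_CS[n] = omega[n] * i_R[n-1]

— the literal index pattern of the recursions, which makes the model causal.
`i_R` rises from `alpha*X` to `alpha*X/(1-alpha)`; the CR converges to the
same value and is therefore always smaller than the UCR `X + i_R`.  On
extinction trials the UCS is not perceived, so `i_R` is frozen by default; the
`devalue_on_extinction` flag covers the perceived-without-elicitation case.
`y_UCS` is reported as `X + i_R[n-1]` on reinforced trials (integration
property) and 0 when no UCS is delivered.  A seeded binomial population
update (`n_synapses` finite) replaces the mean-field rule on request; its
expectation is the mean-field rule, verified by Monte Carlo.

## Misattribution (`emolearn.misattribution`)

With attributed expectation `E` (initially 0) and a persisting unattributed
reactive intensity `i_U`:

    y = i_U + alpha*E,   e = y - E,   E <- E + p*e

`p = 1` gives the geometric sum `y[n] = i_U*(1+alpha+...+alpha**(n-1))`;
any `p > 0` converges to the same ceiling `i_U/(1-alpha)` (the linear
fractional-attribution law is the minimal choice for partial attribution; the
literature gives only the range).  At the ceiling the expectation is purely
reactive and equals the elicited response, so `e = 0` identically: the
acquired valence is resistant to extinction because there is no active
component left to remove.  `inextinguishability_check` certifies exactly that
state on any trace: over the final window, `|e| < tol`, `|x| < tol`,
`i_R > tol` (default window 50, tol 1e-6).

## Continuous time (`emolearn.continuous`)

Sampling the discrete model at the sensory time-discrimination threshold `T`
and inverting the bilinear map `Z = (1 + sT/2)/(1 - sT/2)` yields

    H(s) = (K*tau2*s^2 + (K+tau2)*s + 1) /
           (tau1*(tau2+K-K*alpha)*s^2 + (tau2+K-K*alpha+tau1-alpha*tau1)*s + (1-alpha))

with DC gain `1/(1-alpha)`.  `simulate_lti` integrates this with
`scipy.signal.lsim`; both bilinear directions are implemented as Möbius
polynomial substitutions (scipy offers no z-to-s inverse) and cross-checked
against `scipy.signal.cont2discrete`; DC gain is preserved to machine
precision because the map fixes `s=0 ↔ z=1`.

**Saturating realization.** Saturation cannot be expressed in a linear
transfer function, so the nonlinear simulator uses three states: `x1` (tau1
low-pass of the input), `y2` (tau2 low-pass of the perceived response) and `P`
(amygdala expected response), with output
`y = (1+K)(x1 + i_R) - K*y2`, `i_R = alpha*sat(P; T_S)` and
`e_A = (x1+i_R) - y2` folded in algebraically.  `P` integrates the tracking
error `(y2 - P)/T` plus injected error spikes.  This realization reproduces
the fixed point `y = x/(1-alpha)` exactly and the transfer function's DC
behaviour; exact pole-zero equality with H(s) is *not* claimed, and the
linear-regime agreement test is accordingly an asymptote (2%) check, not a
transient one.

Design choices at the threshold, made once and used everywhere:

- the saturation is a hard clip at `T_S` (a `tanh` option exists but is
  non-default), per the linear-zone/saturation-zone picture;
- while `P >= T_S` the expected response delivered downstream is the clamped
  value, which coincides with the triggered reactive response, so the tracking
  error is not computed there.  Consequence: moderate negative (safe-context)
  spikes lower `P` without moving the output; only an inhibition larger than
  the accumulated degree of saturation (`P - T_S`) can pull the system back
  into the linear zone, where deflation works again;
- `P` is clipped at zero (a nonnegative expected response);
- error spikes are rectangular pulses, mass = amplitude × width; a sustained
  signal into this integrating node grows linearly without bound (the
  error-to-output path has a pole at the origin when the loop is cut), which
  is why inferred errors arrive in spike form.  `error_path_analysis` reports
  the poles and the numeric verdict for both the raw accumulator (unbounded)
  and the closed loop (stable for `|alpha| < 1`).

**Integration.** Fixed-step classical Runge–Kutta; `dt` defaults to
`min(tau1, tau2, T)/20` and is further reduced to a tenth of the narrowest
spike.  Halving `dt` changes trajectories by < 0.1% (tested).

**Worked scenarios (`scenario_figure6`).** `alpha=0.4`, `K=0.5`,
`tau1=tau2=T=2 s` (a single printed time constant governs the scenario; the
identification of `T` with it is an interpretation), `T_S=150`, no active
input.  Acquisition is a train of ten positive spikes at 0.5 s spacing; each
spike's mass is `gain × (inferred outcome − OFC expectation)` with gain 12 and
the conscious OFC expectation revised toward the inferred outcome by 0.4 per
presentation — masses shrink geometrically as the subject's explicit
expectation catches up.  The stressful panels start from a prior expectation
of 8 against an inferred outcome of 10 (total mass ≈ 60, well below
threshold); the traumatic panels start from 1 (total mass ≈ 268, crossing the
threshold on the second spike).  Devaluation panels append ten inhibitory
spikes of mass 5.  The plateau value `alpha*T_S = 60` is clamp-exact and does
not depend on the train's construction; the train parameters only decide
*whether* the threshold is crossed, and were chosen once for that contrast.

**Parameter recovery.** `fit_parameters` estimates `(alpha, K, tau2)` from a
known-input continuous trace by nonlinear least squares on the transfer
function response, with `tau1` supplied as known; on a discrete trial trace
the collapsed recursion is a two-regressor linear model solved in closed form
(`tau2` unidentifiable there).  Noiseless step traces are recovered to well
under 1%, 1%-noise traces to under 5% (seeded).  A constant-zero trace raises
an ill-posed-fit error.

## Protocols (`emolearn.protocols`)

**Iterative climbing.**  Reactive responses start at `alpha*x_i/(1-alpha)`.
A phase stimulating one UCS while the other's engram is optically co-activated
has constant per-trial input `x_target + i_R_partner` (the idealization that
the co-elicited response is fully misattributed), hence asymptote
`(x_target + i_R_partner)/(1-alpha)` and updated
`i_R_target = alpha × asymptote`.  With `alpha=0.5` and equal intensities the
phase asymptotes are `4x, 6x, 8x, ...` — each phase adds `2x` — and the
sequence is unbounded.  Note the algebra: the phase map has contraction ratio
`alpha/(1-alpha)`, so strictly increasing-but-convergent behaviour occurs for
`alpha < 0.5` and true divergence requires `alpha >= 0.5`; the canonical
worked case sits exactly at the boundary, where growth is linear.  A
saturation cap clamps both reactive responses at `alpha*sat_threshold`, making
the asymptotes monotone, capped and eventually constant.  "Run to asymptote"
means per-trial change below 1e-8 or 10 000 trials.  The closed-form recursion
and the trial-level co-simulation (revaluation module seeded with the phase's
initial expectation) agree to 1e-6 (tested).

**Extinction probe.**  After climbing, zero-active-input presentations of the
last UCS either elicit the clamped response with zero error (saturated: the
certificate passes for ≥ 50 probes) or devalue geometrically (unsaturated:
the certificate fails).

**Inextinguishable-input search.**  Piecewise-constant `x(t)` (default 40
segments) optimized by seeded differential evolution (the objective is
non-smooth at the clamp, so a derivative-free method is the default) to
minimize `-w0*mean(y) + w1*mean(|e|) + w2*mean(|x|)` over the terminal
window.  In the stable linear regime the terminal response provably decays
with the input, and the search documents this (its result fails the
certificate); a self-sustained solution requires the saturating regime.  Any
candidate is screened with `inextinguishability_check` before being reported.

## Synthetic data (`emolearn.fixtures`)

Generators emit the study conditions directly: constant and staircase
intensities, periodic Gaussian intensity bumps (`x[n] = x[n-N0]` by
construction), a single signalled omission trial (the negative-contrast
probe), acquisition/extinction phase blocks, and the inference/safe-context
spike trains above.  All are pure functions of `(spec, seed)`; none add
physiological noise — stochasticity enters the package only through the
binomial synapse mode and the measurement noise a user adds to fitting
traces.  Passing tests on these fixtures therefore demonstrates internal
consistency of the model family under its own idealized conditions, not
goodness of fit to any recorded data.

## Numerical conventions and limitations

- Trials are 1-based in every exported trace, matching the recursions.
- Closed-form comparisons use absolute tolerance 1e-6 unless a tighter oracle
  identity (1e-9, 1e-12) is available; geometric convergence means the trial
  budget for a 1e-6 approach scales like `1/log(1/alpha)`.
- One emotional component per run; multi-component responses are independent
  runs, not coupled dynamics.
- The mapping from physical stimulus features to `x(t)` is out of scope; all
  intensities are already in response units.
- Estimating parameters from empirical recordings is out of scope; the
  fitting routine is a parameter-recovery tool for simulated experiments.
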
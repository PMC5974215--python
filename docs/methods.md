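# Methods

## Model and assumptions

The simulated neuron is the discrete-time leaky integrate-and-fire map

    u[t] = u[t-1] * f(o[t-1]) + x[t] + b,      o[t] = 1{u[t] >= v_th},

iterated over a window of `T` steps from zero initial state (`u[0] = 0`,
`o[0] = 0` — the only initial condition under which total silence is an
exact fixed point).  The threshold comparison uses `>=`, so the boundary
fires; this matters because integer-valued toy inputs can place `u`
exactly at `v_th`.  Reset is implemented entirely through the forget gate
`f` — there is no subtractive or clamp-to-`u_reset` branch — so the reset
potential is identically zero.  The drive at step `t` uses pre-synaptic
spikes at the same step `t`: input and membrane update share a time index,
with no synaptic delay.  Refractory periods, axonal delays and stochastic
firing are out of scope; the discrete map itself is the model, not an
integration scheme for an underlying ODE.

Two forget-gate modes exist.  The exact gate `f(o) = tau*exp(-o/tau)` is
smooth in `o`; the approximate gate (`tau` if silent, `0` after a spike)
is the spiking-simulation default, justified because the exact post-spike
retention `tau*exp(-1/tau)` is below 1% of `tau` for every tabulated decay
factor (0.1, 0.15, 0.2).  Note it is *not* below 1e-4 absolutely except at
`tau = 0.1`; the often-quoted "approximately zero" is relative, and the
test suite asserts the relative form.

`tau` is treated as the dimensionless per-step retention factor in (0, 1).
The same symbol is sometimes printed with millisecond units alongside a
1 ms simulation step; at `dt = 1 ms` the two readings coincide numerically,
and the package stores `dt` for bookkeeping only.

## Loss, decoding, and the backward recursion

The loss is the mean squared error between one-hot labels and
time-averaged output activity; prediction is arg-max of the mean rate with
ties broken toward the lowest class index.  Because the loss touches every
output step symmetrically through the time average, the direct gradient
term `-(1/TS)(y - mean rate)` applies at the output layer at *every* step,
not only the last.

The backward pass is the chain rule of the network unrolled over layers
and time (see the `stbp.engine` docstring for the recursion).  Published
presentations of this recursion are sometimes marred by index slips in the
temporal terms (e.g. evaluating the threshold derivative at step `t` inside
a term generated by the step-`t+1` output); this implementation follows
the unambiguous unrolled-graph derivation, and the finite-difference
oracle below is the arbiter: on the relaxed network the recursion *is* the
exact gradient, so any mis-indexed term would surface as an error around
1e-2, not the observed ~1e-10.

Two temporal channels carry credit between steps: through the retained
potential (`delta_u[t+1] * f(o[t])`) and through the gate's dependence on
the previous output (`delta_u[t+1] * u[t] * f'(o[t])`).  In approximate
forget mode `f` is piecewise constant, so `f' = 0` and the second channel
is inert; in exact mode `f'(o) = -exp(-o/tau)`.  Spiking training defaults
to the approximate gate; gradient-check runs force the exact gate because
the relaxation is only differentiable there.  Whether published experiments
ran with the gate channel active is not documented; both paths are exposed
via `LIFConfig.forget_mode`.

With `temporal=False` every `t+1`-indexed term is dropped (SDBP).  Average
pooling distributes incoming error uniformly over its window (factor
1/k²); convolution backward is the standard transposed correlation.  All
time accumulations are full-window sums — at these problem sizes truncated
backpropagation through time would save nothing.

## Surrogate derivatives

Four unit-mass families approximate the Dirac derivative of the threshold:
rectangular window, triangle ("polynomial"), logistic derivative
("sigmoid"), and Gaussian.  Conventions worth stating:

- Rectangular: half-open support `[v_th - a/2, v_th + a/2)` so exactly one
  convention holds at the boundary.
- Triangle: parameterized with half-width `2a` and peak `1/(2a)`.  The
  customary half-width-`2/a` form *widens* as `a` shrinks, which breaks
  the shared Dirac limit `a -> 0+` and inverts the steepness semantics
  relative to the other three families; the two forms coincide at the
  default `a = 1`, so this choice changes nothing at the tabulated setting.
  Negative lobes outside the support are clipped to zero — a derivative
  approximation of a monotone step must be nonnegative.
- Sigmoid: `logistic'((u - v_th)/a)/a`, peak `1/(4a)`.
- Gaussian: variance `a` (not `a²`), density peak `1/sqrt(2*pi*a)`.

Normalization is verified by adaptive quadrature (tolerance 1e-9,
truncated where the density falls below 1e-12) rather than assumed.  Each
family's closed-form antiderivative (clipped ramp, piecewise quadratic,
logistic, normal CDF) is the smooth relaxation used by the oracle.

## The gradient oracle

`numerical_gradient_relaxed` central-differences the relaxed loss
parameter-by-parameter (default epsilon 1e-5; accepted range
[1e-8, 1e-4] balances truncation against round-off in float64).
`gradient_check` draws a random network — weights U[-2, 2], biases
U[-0.5, 0.5], wide enough that potentials populate every family's
responsive region — plus Bernoulli(0.5) input spikes and random labels,
and reports the max absolute gradient difference relative to the larger
gradient magnitude.  Draws with identically zero gradients are redrawn
(a vacuous comparison), as are rectangular-family draws whose potentials
sit within 1e-3 of a window edge, where a two-sided difference quotient
measures a subgradient rather than the one-sided derivative the backward
pass computes.  Redraws are deterministic (seed, attempt)-derived.

## Synthetic tasks: what they emulate and what they do not

The generators stand in for rate-coded static images and event streams at
desk scale; they reproduce the statistical structure the method cares
about (Bernoulli rate coding, class-dependent spatial rate profiles,
rate-matched temporal order structure, on/off polarity channels) but not
the dimensionality, correlations, or noise of real image/event datasets.
Passing tests therefore demonstrate correctness of the machinery and the
qualitative phenomena, not benchmark-level accuracy on real data.

- **Rate task** — classes differ in which contiguous input block fires at
  `rate_hi` (default 0.8) vs `rate_lo` (0.1); linearly separable in
  mean-rate space by construction.  Defaults: 2 classes, 20 inputs,
  T = 10, 200 samples, 30% held out.
- **Temporal-pattern task** — inputs split into two groups; each sample
  contains `n_events` (3) non-overlapping two-step events in which class 0
  fires group A then B and class 1 fires B then A, each unit firing with
  probability `p_fire` (0.7) in its active step.  Both groups are active
  for the same number of steps in either class, so class-conditional
  per-input mean rates are equal; a logistic regression on mean rates
  scores within the binomial chance band (verified in the suite).  Order
  detection requires cross-step membrane carryover (e.g. inhibition from
  the leading group decaying into the trailing step), which is exactly the
  credit the temporal gradient terms assign.
- **Event synthesizer** — one saccade leg (unit shifts, default diagonal)
  of an image across a larger canvas; intensity increases/decreases beyond
  a contrast threshold (0.05) emit on/off events with 1000 µs per motion
  step.  Binning clips each (bin, channel, pixel) to a single spike
  because the network consumes binary activity.  Coordinates are 0-based,
  row-major, origin top-left throughout.

## Experiment configurations

Desk-scale experiment sizes were chosen so each study completes in seconds
while leaving clear margins on its effect:

- **Learnability**: 20-30-2 MLP, T = 10, τ = 0.2, V_th = 0.2, Adam
  lr = 0.05, batch 64, ≤ 50 epochs, 5 seeds.  The tabulated thresholds
  1.5/2.0 are calibrated to ~784-input drive; with 20 inputs and unit-norm
  rows the membrane potential never approaches 1.5, so the small-input
  tabulated setting (0.2) is the appropriate choice.
- **STBP vs SDBP**: temporal-pattern task above, τ = 0.5 (stronger
  cross-step carryover makes order information accessible), V_th = 0.2,
  Adam lr = 0.02, 15 epochs, 10 paired seeds sharing initialization and
  data order; summary reports means and a paired sign test.  SDBP still
  trains a temporally dynamic network — only its gradients ignore
  cross-time paths — so the expected effect is a moderate accuracy gap,
  not failure.
- **Steepness sweep**: 4-class, 40-input rate task (rates 0.7/0.4, hard
  enough that convergence speed differentiates cells), 40-30-4, τ = 0.5,
  V_th = 0.6, SGD lr = 0.5 (with Adam's per-parameter rescaling the 1/a
  gradient magnitude is partly washed out, masking the steepness effect),
  15 epochs, 5 seeds per cell, rectangular family, cells
  a ∈ {0.1, 1, 2.5, 5, 10}.  The useful band of `a` tracks the membrane-
  potential spread around threshold: too narrow (0.1) and almost no
  potential falls in the window, starving the backward pass; too wide (10)
  and the gradient is dense but weak and unselective.  At this network's
  potential spread (≈ ±1 around V_th = 0.6) the band {1, 2.5, 5}
  outperforms both extremes.

Stochastic-encoding mode (fresh Bernoulli draws per presentation) is the
training default where rate images are available — it matches rate-coding
semantics and acts as augmentation; frozen-train mode exists for exact
regression tests.  Batch size defaults to 64.  The Adam epsilon is 1e-8
(the conventional reading of the "1-10⁻⁸" parameter listing).

## Numerical choices and degenerate inputs

- Tie-breaks: rate decoding takes the lowest class index; documented and
  tested.
- Weight normalization: each post-synaptic neuron's incoming vector is
  scaled to unit L2 norm (conv: per output channel over the full receptive
  field).  The printed normalization formula is ambiguous between dividing
  by the norm and by the sum of squares; unit-L2 is the default and
  `mode="sumsq"` exposes the alternative for sensitivity checks.  An
  all-zero incoming vector raises (resample the init seed).
- Biases initialize to zero and are not normalized — only weights control
  the initial activity balance; `v_th` itself is frozen.
- Conv layers use valid padding and stride 1; pool stride equals pool
  size — the only chain consistent with the standard
  28 → C5 → 24 → P2 → 12 → C5 → 8 → P2 → 4 arithmetic.  Pool outputs are
  real-valued in [0, 1] and are *not* re-thresholded (average pooling is
  used precisely because binary activity breaks max pooling, implying the
  mean is passed on as-is); the CNN's output layer spikes like the MLP's.
- Non-finite potentials, losses or updates raise immediately
  (`DivergenceError` carries the last finite parameters).
- Event streams with decreasing timestamps or out-of-range coordinates are
  rejected at construction; truncated IDX/AER files report the byte offset.

## Known limitations

- No refractory dynamics, delays, or stochastic neurons; no max pooling,
  batch normalization, dropout, or learning-rate schedules.
- The event synthesizer is a geometric intensity-difference model; it does
  not model sensor noise, latency jitter, or per-pixel thresholds, and how
  real event streams are best binned into short windows is a choice this
  package documents (binary clipping at 1 ms bins) but validates only on
  synthetic streams.
- Dense finite differencing scales linearly in parameter count, so the
  gradient oracle is for desk-scale audits, not large networks.
- Accuracy numbers from the synthetic studies characterize the method's
  behaviour under the generators' assumptions; they are not predictions of
  benchmark accuracy on real datasets.
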
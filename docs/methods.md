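# Methods

## Model and assumptions

The neuron is the Izhikevich model with a rectified, noise-driven membrane
equation:

    dv = max(0, 0.04 v² + 5 v + 140 − u + I(t)) dt + β dW
    du = a (b v − u) dt,         v ← c, u ← u + d  when v ≥ v_f.

* `v` (mV) and time (ms) follow the conventional Izhikevich scaling; the
  control bounds (±100) are kept in the model's printed units without
  dimensional reconciliation.
* The four presets are RS (0.02, 0.2, −65, 8), IB (0.02, 0.2, −55, 4),
  CH (0.02, 0.2, −50, 2) and FS (0.1, 0.2, −65, 2); the spike peak
  `v_f = 30 mV` is the conventional cut-off (configurable — the model
  definition leaves it free).
* Initial state defaults to the pattern's rest, `(v, u) = (c, b c)`
  (configurable).
* Noise enters only the membrane equation. `β` is in mV·ms^(−1/2); the
  benchmark levels are 0.5 / 1.0 / 2.0 (small / medium / large).
* The rectifier `max(0, ·)` makes the deterministic drift non-negative.
  This is what permits the reset-free reformulation, but it also removes
  the model's repolarizing drift: below-rest excursions are produced only
  by noise, and the rest state is sustained by the rectifier clamping the
  drift at zero.

## Reset-free coordinates and their domain

With `n(t)` the spike count, `y₁ = n(v_f − c) + v` and `y₂ = u − d n`
evolve without resets; `v` and `u` are recovered through the modular maps
`φ` and `ψ`, and the k-th spike time is the level crossing
`y₁ = c + k(v_f − c)`. The correspondence presumes `c ≤ v ≤ v_f`, which
the rectified drift guarantees in the absence of noise. Under noise, `v`
can diffuse below `c`; there the modular read-out wraps to just below
threshold and the two formulations part ways. This is a genuine property
of the noisy reset-free model, visible only for weakly driven states
hovering near a spike level; the trained controls of interest drive the
membrane away from the levels except during crossings. The equivalence
checker reports the discrepancy rather than hiding it.

## Discretization

Explicit Euler–Maruyama with step `h = 0.1 ms`; increments `ΔW ~ N(0, h)`.
Spike times are interpolated linearly within the crossing step, since the
reported timing errors are an order of magnitude below `h`. Two reset
conventions are exposed:

* biological (`carry_overshoot=False`, default): the overshoot above `v_f`
  accumulated within the crossing step is discarded, `v ← c` exactly;
* overshoot-carry (`carry_overshoot=True`): `v ← c + (v − v_f)`, which
  makes the discrete reset map coincide step-for-step with the discrete
  reset-free map (the overshoot is what `y₁` retains past the level).

At `h = 0.1` the overshoot is O(f·h) ≈ up to ~40 mV at the crossing, so
the two conventions differ noticeably; they converge as `h → 0`. Training
and evaluation both use the biological convention (see below), and the
overshoot-carry mode exists to certify the reset-free reformulation.

### Equivalence certification in extended precision

The reset (carry) and reset-free recursions are one map in two coordinate
systems, so any discrepancy on shared noise is pure round-off. That
round-off (~1e−13 per step from the modular read-out in float64) is
amplified by roughly the upstroke Jacobian (×10–20 per spike), which for a
chattering neuron over 10 ms exceeds the 1e−9 certification scale.
`check_equivalence` therefore integrates both maps in 80-bit extended
precision (`numpy.longdouble`), which keeps representation error orders of
magnitude below the tolerance while changing neither simulation.

## Loss

Composite three-case loss with the k-th actual spike always paired with
the k-th desired time:

* match (N = N̂): Σ (t_k − t̂_k)²;
* underfire (N < N̂): add `Σ_{h k ≥ t_N} w₁ (v_f − v(hk))²` over the grid
  samples from the last actual spike (from 0 if none) to the horizon;
* overfire (N > N̂): add `Σ_{h k ≥ t_{N̂}} w₂ (v(hk) − c)²` from the time
  of the N̂-th actual spike (a variant starting at the first excess spike
  is available via `overfire_from_excess`).

The summation bounds mix a time with a step index in the original
formulation; they are read as sample indices `k` with `h·k ≥ t_ref`.
Default weights `w₁ = w₂ = 0.01` keep the mV²-scale penalties from
dwarfing the ms²-scale timing terms; under the normalized optimizer
(below) only their relative balance matters. The case branch, the pairing
and the penalty windows are constants of each forward pass: gradients flow
through trajectory samples and interpolated spike times only, never
through the integer spike count.

## Gradients

Reverse-mode differentiation is hand-derived for both discretizations
(the adjoint of a 2-state Euler recursion is a few lines) and verified
against central finite differences with frozen noise.

* Transformed path: `dφ/dy₁ = 1` and `dψ/dy₁ = 0` almost everywhere, so
  the adjoint is the plain linearization of the recursion.
* Reset path (training default): the reset writes the constant `c`, whose
  Jacobian in `v` is zero, so a spike time's gradient naturally stops at
  the preceding reset. This gives per-interspike-segment credit
  assignment — each segment of the control owns the spike it triggers —
  and matches the simulator used to evaluate trained controls. By
  contrast, the transformed path carries the (noise-dependent) overshoot
  across spikes, entangling all downstream timings with all upstream
  inputs.

**Rectifier backward slope.** Where the raw drift is negative its true
derivative is zero. From the zero-control rest state the drift is inactive
along the entire path, the exact gradient is identically zero, and
gradient descent cannot start. The backward pass therefore substitutes a
small surrogate slope (`leak = 0.1`, roughly the drift slope in the slow
depolarization region) wherever the raw drift is negative — the standard
surrogate-gradient device for spiking models. The forward dynamics are
untouched; `leak = 0` recovers the exact almost-everywhere gradient (with
the subgradient at exactly zero taken as 0) and is what the
finite-difference oracle certifies.

## Optimizer

The loss landscape is only piecewise smooth: the spike count is integer
valued, and each count change switches the active case, discontinuously
adding a penalty that is orders of magnitude larger than the timing terms.
Plain Adam/SGD on the composite gradient exhibit two failure modes on this
terrain: the intermittent penalty spikes poison adaptive second-moment
estimates (freezing progress), and near a count boundary the optimizer
enters a limit cycle in which a marginal spike appears and disappears.
Both reference optimizers remain available (`optimizer="adam" | "sgd"`),
but the default is a two-phase scheme built for this structure:

1. **Count acquisition** — normalized gradient descent with momentum
   (`x ← x − lr · m/‖m‖`, `lr = 15` mV): the normalization preserves the
   *shape* of the gradient (which naturally digs troughs early in each
   interspike segment and leaves drive near the crossings) while
   controlling the step scale across the wildly different loss magnitudes.
   If the batch-median spike count stalls, the step is boosted
   geometrically (×1.7, capped) until a new spike is recruited.
2. **Timing refinement** — entered once the batch-median count has matched
   the target for 5 consecutive epochs (at the latest after 85% of the
   epochs): the spike-timing problem is a nonlinear least-squares in the
   residuals `t_k − t̂_k`, so each spike takes a damped Gauss–Newton step
   `Δx = −α ē_k J_k / ‖J_k‖²` with `J_k = ∂t_k/∂x` from the same backward
   pass, `ē_k` the batch-mean error, `α = 0.5` annealed over the phase and
   a per-spike step cap of 10 mV. Because the reset severs the Jacobians,
   the per-spike steps act on nearly disjoint control segments. A small
   normalized step on the count-penalty gradient guards the acquired count.

Training runs 100 epochs with batches of 5 Brownian paths, resampled every
epoch from substreams keyed by `(stream, seed, epoch, path)`; the run is
bit-reproducible from the seed. Box bounds are enforced by projection
after every step.

## Evaluation conventions

A trained control is evaluated over independent noise realizations drawn
from a substream disjoint from training noise, by default with the
biological reset simulator. Per trial the k-th actual spike is paired with
the k-th desired time for `k ≤ min(N, N̂)`; trials with a wrong count
still contribute those pairable errors and are tallied as miss/excess
rates. Per-spike statistics are the sample mean, SD (n−1 denominator,
reported as 0 for a single sample) and median. The benchmark campaigns
use 100 trials per condition; horizons are `max(t̂) + 1 ms` (10 ms for the
five-spike sequences, 20 ms for the ten-spike sweep).

## Synthetic fixtures

All test inputs are generated programmatically: a deterministic current
pulse whose single spike time is validated against an `h = 0.001 ms`
integration of the same input, linear ramps in the transformed coordinate
crossing a known number of spike levels, and loss scenarios small enough
to sum by hand. These fixtures pin the arithmetic; what they cannot show
is behaviour on real neurons — the model's noise is idealized additive
white noise on the membrane equation, there are no conductance dynamics,
synaptic input statistics or parameter uncertainty, and the rectified
drift removes repolarizing excursions below rest.

## Known limitations

* First-order (Euler) spike-time accuracy: with `h = 0.1 ms` a coarse-grid
  spike time can differ from a fine-grid reference by up to ~2h on slowly
  depolarizing approaches; trained controls compensate within the
  discretization they are trained on.
* Long sequences at the drive bound: recruiting the last spikes of the
  ten-spike sequence requires ~1.5 ms of near-maximal drive against the
  accumulated recovery variable; at low noise the trainer sometimes ends
  one spike short of the target count within the 100-epoch budget, and
  the reported statistics then cover the paired spikes only.
* Tightly spaced targets below the refractory limit (e.g. a 0.4 ms gap)
  are physically unreachable at `|I| ≤ 100`; training converges to the
  closest achievable timing and the residual error is structural.
* Mean timing errors of later spikes are limited by noise accumulated over
  the sequence; their spread grows with `β` and with the spike index.
* The noisy reset-free coordinates wrap below the reset potential (see
  above); the reset-free simulator should not be used to evaluate weakly
  driven controls near rest.
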
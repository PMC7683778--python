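# Methods

`mdds-loops` implements a systems-and-control account of Mal de
Debarquement Syndrome (MdDS): a feedback-loop reading of how the brain
adapts posture to wave-like passive motion, and of how that adaptation can
become pathologically permanent.  The package has three model layers plus a
verification layer; this note records the models, the defaults, and the
design choices made where the modeling was genuinely open.

## 1. The vestibulocerebellar loop network (`jacobian_ensemble`)

The network has four nodes in fixed order — Purkinje cells and vestibular
nuclei on the two brainstem sides, (PJ_A, VN_A, VN_B, PJ_B) — and a fixed
signed connection pattern: self-inhibition on every node; two excitatory
projections VN→PJ (one per side); and six inhibitory edges forming two
ipsilateral PJ→VN loops (one inhibitory edge each, hence negative loops /
candidate oscillators), a commissural VN↔VN double-negative loop (a
candidate bistable element), and two extra contralateral VN→PJ inhibitory
connections.

A random Jacobian of this structure has each nonzero entry drawn as
`sign · u · w_class`, `u ~ Uniform[0, 1]` independently per entry, with one
scaling weight per connection class: `w_self` (diagonal, the parameter `d`),
`w_exc`, `w_inh`, all in arbitrary units.  A matrix is *oscillatory* when
its spectrum contains a strictly complex eigenvalue with positive real
part; the oscillation probability of a weight scheme is the fraction of
oscillatory matrices in a Monte Carlo sample.

Choices and defaults:

* **Distribution.** Uniform on [0, 1] is the minimal reading of "random
  number with absolute value between 0 and 1"; it is a pluggable detail in
  the sampler, and all entries are independent.
* **Diagonal sampling.** The diagonal is scaled by a random factor like
  every other entry (`random_diagonal=True`); a switch disables that and
  fixes the diagonal at `-w_self`.
* **Tolerances.** `tol_re = tol_im = 1e-9 · max(1, |J|_max)` separates
  genuinely complex/unstable spectra from numerical noise on 4×4 problems.
* **Sample sizes.** The headline sweeps use 100 000 samples per grid point;
  tests and the acceptance script use 10 000 with 3-standard-error criteria
  and a coarser (step-5) inhibition grid.  Binomial standard errors
  `sqrt(p(1-p)/n)` are attached to every estimate.
* **Seeding.** Every sweep point gets its own `SeedSequence([master, index])`
  stream, so points are independent and individually reproducible; the
  derived seed is stored in the sweep table.

The two standard sweeps: `sweep_inhibition` (`w_self = 1`, `w_inh` from 1 to
100, `w_exc ∈ {1, 10, 100}`) and `sweep_self_inhibition` (`w_inh` 1–30,
same `w_exc` set, `w_self ∈ {0.1, 1, 10}`).  The reproduced regime
structure: at weak inhibition the oscillation tendency *decreases* with
excitation strength; around `w_inh ≈ 20–40` it is high and nearly
independent of excitation; at strong inhibition the excitation effect
*reverses*; and weaker self-inhibition always makes oscillations more
likely.

### Time-domain oracle

The spectral criterion is cross-checked by a method that never inspects the
matrix's spectrum: integrate `dx/dt = Jx` from a random initial state
(matrix-exponential stepping, 64 samples over a window scaled to
`0.3/|J|_max` per step) and decompose the sampled trajectory into complex
exponentials with a matrix pencil (ESPRIT).  The trajectory is oscillatory
iff a recovered mode both grows and oscillates with non-negligible
amplitude.  This operationalizes "an oscillating component grows" exactly,
and — unlike envelope or zero-crossing heuristics — still works for the
~20% of sampled matrices whose positive complex pair is hidden under a
faster-growing *real* eigenvalue.  Disagreements are only possible inside
the oracle's dead band (`1e-6 · |J|_max` around the axes); measured
agreement is 100% on 1000+ matrices spanning the sweep range.

## 2. Nonlinear rate-network realization (`rate_network`)

The spectral analysis concerns a linearization; the rate network realizes it
nonlinearly:

    dx_i/dt = −d_i x_i + Σ_j W_ij tanh(s x_j) + u_i(t)

`tanh` is the standard saturating firing-rate choice and keeps the origin an
equilibrium; the linearization there is `J = −D + sW`, matching the
canonical sign pattern.  A sampled Jacobian `J` is embedded by choosing
decays `d_i = min(0.5, |J_ii|/2)` and `W = (J + D)/s`, so
`linearize(params, 0) = J` exactly.  Integration is adaptive RK (rtol 1e-8,
atol 1e-10) on a uniform output grid.

Two empirical facts shape the verification tests:

* **Latching.** The commissural double-negative loop is a positive loop and
  makes the saturated network bistable.  Deep in the unstable regime a
  trajectory leaving the origin usually latches into a winner-take-all
  equilibrium instead of settling on a limit cycle (measured: only ~20–60%
  of spectrally oscillatory schemes produce sustained cycles).  The
  prediction-consistency property is therefore checked as *oscillatory
  departure from equilibrium*: the small-amplitude epoch of the nonlinear
  simulation (initial norm 1e-12, so nonlinear corrections stay below the
  mode-recovery noise) is decomposed with the same matrix pencil.  Agreement
  with the spectral classification is ≥95% by test (measured 100%).  A
  committed mildly unstable scheme (`w_self=1, w_exc=1, w_inh=2.5`)
  demonstrates an actual sustained limit cycle.
* **Frequency pulling.** The saturated cycle's frequency deviates from the
  linear eigenfrequency by tens of percent (relaxation-type cycle); the 5%
  eigenfrequency match is asserted on the pre-saturation growing epoch,
  where it holds to better than 1%.

Entrainment drives the two VN nodes with equal-amplitude antiphase
sinusoids (side-to-side vestibular stimulation); PJ nodes receive no direct
input.  Oscillation descriptors use a periodogram peak for frequency and a
log-envelope slope on |peak| samples for the damping label, with a
sustained dead band of 1e-3 per cycle.

## 3. Posture control with an internal model (`posture_adaptation`)

Posture is a normalized linearized inverted pendulum with unit inertia,
`θ'' = ω_u² θ + u_C + u_A + d(t)`.  Loop C is the proportional-derivative
stabilizer `u_C = −Kp θ − Kd θ'` (stability requires `Kp > ω_u²`,
`Kd > 0`).  Loop A — the adaptation mechanism — is a second-order resonant
compensator with poles `−ρω_c ± iω_c√(1−ρ²)`, driven by the posture error
with gain `k_a`; its velocity state is `u_A`.  The disturbance-to-angle
transfer is

    θ/d = (s² + 2ρω_c s + ω_c²) / [(s² + Kd s + Kp − ω_u²)(s² + 2ρω_c s + ω_c²) + k_a s]

whose numerator puts a notch at ω_c: with ρ = 0 the rejection of a matched
sinusoid is *exact* (internal model principle), and `u_A = −d` in steady
state (phase opposition).  After the disturbance stops, the compensator
rings down at its own pole, time constant `1/(ρω_c)`: transient MdD for
ρ > 0, a permanent phantom-motion oscillator (MdDS) at ρ = 0.  The
stabilizing loop always prevails — the phantom input produces bounded sway
at the scale the PD loop alone would tolerate, never instability.

Defaults and rationale:

* `ω_u = 3 /s` (≈ √(g/l) for a 1 m pendulum), `Kp = 20`, `Kd = 8` — a
  well-damped stabilizer with poles at −1.76 and −6.24 /s.
* `ω_c = 2π · 0.25 rad/s`, inside the 0.2–0.3 Hz band of sea travel; the
  disturbance default is a 0.25 Hz sine of amplitude 0.05.
* `k_a = 5e-4` (weak error coupling).  Coupling through the plant damps the
  compensator by ≈ 0.0185·k_a even at ρ = 0 (measured from the root
  perturbation); weak coupling keeps the ashore ring-down governed by ρ
  itself (bias < 0.2% on τ) and the ρ = 0 oscillator drifting < 0.5% per
  100 cycles.  The price is slow adaptation from rest, so…
* **Entrained start.** Aboard simulations begin at the phasor steady state:
  entrainment is treated as accomplished, and `ω_c` is set to the drive
  frequency (frequency self-tuning is out of scope).  A from-rest option
  exposes the adaptation transient.
* Ring-down analysis fits a log-linear envelope on |peak| samples kept
  above 1e-6 of the maximum (below that the integrator noise floor
  flattens the envelope); the regime is `persistent_MdDS` iff the fitted
  envelope drifts < 1% over the last 50 compensator cycles.

Disturbance kinds (`scenarios_io.make_disturbance`): `pure_sine` (boat or
plane — single dominant line), `sine_plus_noise`, and `broadband` (car or
train — 4th-order low-passed Gaussian noise, RMS-matched, no dominant
line).  Spectral dominance is measured with a Hann-windowed periodogram
summed over the ±2-bin mainlobe, so a pure tone scores ≈1 at any frequency
and broadband stays ≈0.01; contracts: ≥0.99 for `pure_sine`, ≤0.2 for
`broadband`.

## 4. The LTP switch (`plasticity_switch`)

Long-term potentiation is modeled as the canonical one-variable
positive-feedback switch

    dL/dt = −δ L + g Lⁿ/(Kⁿ + Lⁿ) + η B

with BDNF level `B` as the stimulus and loop strength `g = g0 (1 + c)`
scaled by the CGRP factor `c` (CGRP is an LTP promoter; it enters only as
this scalar).  Defaults: `δ = K = η = 1`, `n = 4`, `g0 = 1.2`,
`c ∈ {0, 1.5}`.  For these values the three regimes are analytic:
bistability requires `g > 1/max σ'(L) ≈ 0.93879`, and the high state
survives at `B = 0` (irreversibility) for `g > (256/27)^{1/4} ≈ 1.75480` —
so `g = 1.2` is reversible-bistable (hysteresis window
`B ∈ [0.3862, 0.4687]`) and `g = 3.0` is irreversible (high state
`L ≈ 2.9615` at zero stimulus).  These thresholds were verified with the
scan oracle before the defaults were frozen.

Saddle-nodes are located by scanning the equilibrium branch
`ηB = h(L) = δL − gσ(L)` over L and bracketing the critical points of `h`
(sign changes of `h'`, polished by Brent's method) — robust even for the
vanishingly narrow window just above bistability onset, where counting
equilibria over a B grid fails.  Equilibria at fixed B use dense
sign-change bracketing plus Brent polishing; stability is the sign of the
rhs derivative.  Hysteresis traces relax `L` for `20/δ` per quasi-static
step (default step 1% of the range), which lags the moving equilibrium by
~1e-4 — the tolerance used when comparing traces.

**Coupling to the network.**  Excess LTP in the GABAergic fibers multiplies
the inhibitory weights: `m(L) = 1 + λ L/(L + K_m)`, saturating, `m(0)=1`,
with `λ = 6`, `K_m = 1`; the high-CGRP LTP state maps a base `w_inh = 10`
to ≈ 55, inside the strong-inhibition regime.  An analogous optional
multiplier exists for the excitatory weights but defaults to off.

## 5. The end-to-end chain (`plasticity_switch.full_chain`)

For low and high CGRP: classify the switch, apply a quasi-static BDNF pulse
(0 → 1 → 0), map the residual LTP to weights, estimate oscillation
probability (10 000 samples per arm, seeded per arm), map the switch regime
to compensator damping, and simulate disembarkation.  Two interpretive
defaults, flagged as such: the regime→ρ map (irreversible → ρ = 0,
reversible → 0.02, monostable → 0.2) and the base weights
`(w_self, w_exc, w_inh) = (1, 100, 10)` — a point on the strong-excitation
curve where inhibitory strengthening moves the network from the low- to the
high-probability regime (p ≈ 0.60 → 0.98), i.e. where the hypothesized
MdDS transition is actually expressed; on the `w_exc = 10` curve the same
weight change barely moves the probability.  Whether transient MdD versus
persistent MdDS truly corresponds to small-versus-zero ρ, rather than to
distinct mechanisms, is an interpretation, not a result.

## What the synthetic data does and does not show

All inputs are generated internally (the source model deposited no data):
random structured Jacobians, synthetic disturbance series, and parameter
files.  Passing tests therefore demonstrate the *internal consistency* of
the loop hypothesis — that the stated network structure oscillates with the
claimed weight dependence, that an internal-model compensator reproduces
the adaptation/ring-down phenomenology, and that a strengthened positive
loop becomes irreversible — not that any of this occurs in human
vestibular physiology.  The network is a four-node caricature (no
spiking, delays, or stochastic afferents); the posture model is planar with
a single segment and noiseless sensors; LTP biochemistry is a single
scalar.  Clinical validation protocols are out of scope.

## Reproducibility

Every stochastic computation takes a seed; sweep tables store per-point
derived seeds; experiment runs write a `RunRecord` (config digest, stage
seeds, output manifest with content hashes) sufficient to re-run
bit-identically.  Adaptive integrations are deterministic on a given
platform; across platforms they agree to integrator tolerance rather than
bit-exactly.
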
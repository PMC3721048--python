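# Methods

## Model

critmem simulates a fully connected network of `N` non-leaky
integrate-and-fire neurons. Each neuron carries a membrane potential
`h_i ∈ [0, θ)` between avalanches. A slow external drive selects one
neuron uniformly at random per event (exponential inter-event times of
mean `τ`) and deposits an increment `I_ext`. When a neuron reaches the
threshold `θ` an avalanche unfolds on an effectively infinitely faster
time scale, with the external drive and synaptic recovery frozen:

- all currently suprathreshold neurons of a *generation* fire
  synchronously;
- a firing neuron `j` loses exactly `θ` and delivers `J_ij / N` to every
  other neuron `i` (`J_ii = 0`, purely excitatory);
- the loop repeats until no neuron is suprathreshold.

The avalanche *size* `L` counts firings and its *duration* `D` counts
generations; `ℓ` denotes the number of firings in the second generation
(the immediate offspring of the trigger).

### Refractoriness and the state space

Two closures of this model family are under-determined by the equations
alone and matter greatly for heterogeneous couplings:

1. **One spike per neuron per avalanche.** By default a neuron fires at
   most once per avalanche, which bounds `L ≤ N`. The alternative
   (re-firing whenever the residual potential still exceeds `θ`,
   available as `propagate_avalanche(..., refractory=False)`) makes the
   cascade non-terminating whenever a sub-population is locally
   supercritical — which is precisely the structure a sparse memory
   matrix creates at low load — so the recording kernels use the
   refractory rule.
2. **Repolarization of surplus.** The model's state space is
   `h ∈ [0, θ)` between avalanches. A refractory neuron can end an
   avalanche above threshold; hoarding that surplus lets multi-pattern
   neurons accumulate potential without bound and freezes the network in
   recurring system-size avalanche chains. At the end of each avalanche,
   any suprathreshold neuron is therefore repolarized to a uniform random
   value in `[0, θ)` — the same distribution as the initial condition and
   the standard mean-field assumption for this model family.

With these closures the uniform-coupling network has a sharp
goodness-of-fit optimum at `J_cr ≈ 0.92 θ` (N = 300) and the fixed
memory-matrix network crosses into the critical regime at load
`α ≈ 0.6–0.7`, reproducing the study conditions this package targets.

## Criticality statistic

An ensemble of recorded avalanche sizes is reduced to the empirical
distribution `P(L)` on raw integer sizes. The *best-matching power law*
is the ordinary least-squares line of `log10 P(L)` against `log10 L`
over the non-empty bins with `1 ≤ L ≤ N/2`, and `Δγ` is the mean squared
residual of that fit — least squares *is* the "best-matching" objective,
so no separate estimator choice arises. Empty bins are excluded (their
log-probability is undefined); a distribution with fewer than three
occupied bins in the fit range cannot be assessed and is treated by the
sweep drivers as maximally non-critical (this happens when a locked
network emits only system-size avalanches). The network is declared
critical when `Δγ < Δγ^max` (strictly), with `Δγ^max = 0.005`.

**Sampling bias.** `Δγ` is biased upward by multinomial sampling noise;
measured on uniform critical networks the bias is ≈ 4·10⁻³ at 10⁵
recorded avalanches, ≈ 1.5·10⁻³ at 3·10⁵ and ≈ 6·10⁻⁴ at 10⁶. Because
the threshold 0.005 presumes the 10⁶-avalanche scale, the desk preset
records 3·10⁵ avalanches per batch — the smallest batch at which the
bias floor leaves useful headroom below the threshold.

## Coupling scale conventions

Couplings are stored on the membrane-equation scale (delivery
`J_ij / N`, entries `O(θ)`). Quantities quoted on the per-spike transfer
scale are converted by `×N` when installed:

- the uniform maximal-resource initialization `T^max = 1.4 (uN)^{-1}`
  becomes `T^max = 1.4 θ/u`, i.e. a branching-ratio ceiling of 1.4;
- for the **pure-memory experiments** the correlational matrix `W`
  (`W_ij ∝ Σ_η ξ_i ξ_j`, zero diagonal, symmetric, normalized to
  `ΣW = N`) is installed as `J = 0.92 · N · W`, i.e. with the mean
  coupling at the critical value of the uniform fixed-weight model (the
  Δγ-minimizing uniform coupling, measured by the package's own
  brute-force scan; close to the finite-size estimate `1 − N^{-1/2}`
  that the homeostatic rule regulates toward).  Installing `N·W`
  verbatim (mean branching exactly 1) is marginally supercritical for a
  finite network and locks it into system-size avalanches at every
  load.

## Self-organization mechanisms

**Homeostatic regulation.** Once per avalanche every regulated weight
receives `ε_hom (1 − ℓ − N^{-1/2})`, clipped at zero from below (the
model is excitatory). The default scope is *global* (all off-diagonal
weights); the local variant restricted to the first-generation neurons'
outgoing synapses is available (`homeostatic_scope="trigger_outgoing"`).
The rule stays active throughout a critical phase, including while a
batch is being recorded — the criticalization protocol is "keep
recording batches of `A_ava` avalanches until the distribution has
converged to a power law", with the `T_L`-avalanche learning episode at
the start of each critical phase. Batches are not accumulated; the
reported distribution always reflects the latest weights.

**Dynamical synapses.** Each synapse carries a resource `T_ij ≤ T^max_ij`;
a presynaptic spike delivers `u T_ij / N` and then consumes the fraction
`u` of the column; between spikes resources recover exponentially toward
`T^max` with time constant `τ_J = τ ν N`. The kernels integrate recovery
lazily per presynaptic column (closed form), so the cost per spike is
`O(N)`. The effective coupling is `J = u T`, and the time-averaged
`⟨u T⟩` approaches the uniform-model critical coupling for a wide range
of ceilings (verified against the brute-force scan at N = 100, within
10%).

## Associative memory

Patterns are binary with exactly `round(pN)` active units. Retrieval is
one synchronous thresholding step `S_i = [Σ_j J_ij κ_j > Θ]`; the sign
nonlinearity of the update equation is read as a Heaviside step into
{0,1}, since patterns and the overlap measure live on {0,1} and the
threshold is optimized anyway. The overlap is the Pearson-type
correlation with *population* standard deviations, making
`o(ξ, ξ) = 1` exact. Reference values at N = 300, 30 active units:
one-digit deviation 0.9817 (mean of the remove-one and add-one cases),
single-swap (operator Q) deviation 26/27 ≈ 0.96296.

**Threshold search.** The mean retrieved overlap is piecewise constant
in `Θ` with breakpoints at the pooled input-field values. The optimizer
sweeps the globally sorted pooled fields in descending order, updating
each cue's overlap incrementally as its retrieved state gains one unit;
the maximum over all admissible intervals is exact, with ties broken
toward the smallest maximizing threshold. Thresholds at which any
retrieved state would be constant are excluded. For efficiency the sweep
is restricted to the window where every retrieved state has at most
`K = max(4·pN, 120)` active units; beyond that window a cue's overlap
has decayed far below the retrieval regime, so the restriction does not
affect the optimum in practice (small problems are swept in full).

## Dual optimization

One run alternates:

1. **critical episode** — transient (`A_0` avalanches, mechanism
   active), then recorded batches of `A_ava` until `Δγ < Δγ^max`;
2. **convergence check** — `n_p` single-swap perturbations per pattern;
   converged when the mean retrieved overlap beats the perturbed-cue
   baseline by more than `Δ_conv` (in dynamical mode this check uses
   `J = uT`, while Hebbian-phase checks use `J = u T^max`);
3. **Hebbian phase** — stochastic relaxation steps (each off-diagonal
   synapse updated with probability `1/N` per step), after each step
   evaluating the single-perturbation improvement criterion with
   `Δ_hebb`; the phase ends on success, or on saturation of the quality.

**Hebbian targets.** In homeostatic mode the couplings are initialized
by and relaxed toward `W` with its own `ΣW = N` normalization — deeply
subcritical on the membrane-equation scale. Hebbian learning therefore
pulls the network *away* from criticality and the homeostatic rule pulls
it back; because the homeostatic shift is additive and clipping is
inactive once the background sits at the critical level, the structural
tilt built by Hebbian phases survives critical episodes, and the
alternation settles on a critical background carrying `W` as a small
additive tilt (ε_hom·T_L ≈ the critical coupling, which is why those two
constants fit together). In dynamical mode the resource ceilings relax
toward the critically-scaled matrix `0.92 · N W / u`:
depression tames the resulting locally dense structure, which is exactly
the advantage of this mechanism — the memory lives in the ceilings and
is untouched (bit-for-bit) by critical episodes.

**Saturation.** The per-step quality is noisy (one fresh perturbation
per pattern), so saturation is detected on a 200-step windowed mean that
must set a new maximum by at least 2·10⁻⁴ within 15 000 steps; the long
patience covers the slow initial climb while the structural tilt is
still below the uniform background. A saturated run performs one last
excursion to the critical regime and reports `converged = False`
together with its final Δγ and retrieval quality. A critical episode
that exhausts its round budget is likewise reported as a non-converged
final state rather than an error.

**Retrieval geometry and capacity.** With no self-coupling, an active
cue unit lacks its own background synapse, so its input field trails an
out-of-pattern unit's by one background weight; retrieval requires the
summed structural tilt over the ~`pN` co-active pattern synapses to
exceed one background weight. In homeostatic mode the tilt is bounded by
`W`'s own entry scale (per-pattern row mass `≈ N/(M·pN)`), which makes
the convergent range end near `α ≈ 0.03–0.05` in this implementation —
earlier than the dynamical variant, whose critically-scaled ceilings
support retrieval up to `α ≈ 0.13`, the same capacity as the pure memory
network and with the better avalanche statistics of the two mechanisms.

## Problem sizes

Default parameters are the full study conditions (N = 300, θ = 1,
p = 0.1, `A_0 = 10⁴`, `A_ava = 10⁶`, ε_hebb = 0.01, Δγ^max = 0.005,
Δ_hebb = 0.035, Δ_conv = 0.03, n_p = 1000, T_L = 10³, ε_hom = 0.001,
I_ext = 0.0067 (homeostatic/pure) or 0.025 (dynamical), ν = 10, u = 0.2,
τ = 1 arbitrary). `RunConfig.desk()` is the scaled preset used by the
test suite and the acceptance script: 3·10⁵ avalanches per batch
(2·10⁵ in the dynamical sweeps; 6·10⁵ for the single-shot pure-memory
criticality onset, where the Δγ bias floor matters most), 10³
transients, n_p = 100 for convergence checks, and 2–6 trials per load
instead of 10. The pure-memory retrieval sweeps keep n_p = 1000.
Capacity sweeps stop at the first load past the crossing they report,
and the dynamical capacity sweep uses a 0.02-step load grid.

## Synthetic inputs and their limits

All inputs are generated internally: patterns are uniform random
k-subsets, so pattern overlaps are as small as finite size allows.
Correlated patterns, inhibition, conduction delays, leak currents and
multi-step (iterated) retrieval are outside the model. Passing tests
demonstrate the self-organization and storage properties of this
idealized network, not of biological tissue: in particular the noise-free
single-step retrieval makes the capacity estimates optimistic relative
to any stochastic readout.

## Numerical choices

- Event-driven kernels are numba-compiled; avalanche propagation is
  deterministic given the state and is cross-checked against the numpy
  reference implementation to 10⁻¹² in the tests.
- Per-kernel randomness is seeded from the run's single seed through
  `numpy.random.SeedSequence`; whole runs are bit-reproducible.
- Degenerate cases: empty ensembles, constant activity vectors
  (undefined overlap), all-zero memory matrices and sub-3-bin
  distributions raise typed exceptions rather than returning sentinel
  values; sweep drivers map the fit failure to "maximally non-critical".
- The homeostatic clip at zero keeps the model excitatory; clip events
  are the only mechanism by which relative coupling structure erodes.
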
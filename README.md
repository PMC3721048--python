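# critmem

Critical avalanche dynamics in associative memory networks: an
event-driven simulator of non-leaky integrate-and-fire networks whose
spontaneous activity forms neuronal avalanches, together with the
machinery to make such a network **simultaneously** a self-organized
critical system and a Hopfield-style associative memory.

It is written for computational neuroscientists studying the interplay
of criticality and memory: it provides the avalanche statistics
(power-law fits and the Δγ goodness-of-fit criterion), two biologically
motivated criticalization mechanisms, sparse-pattern storage and
retrieval, and the alternating optimization that reconciles the two.

## Model in brief

`N` neurons with membrane potentials `h_i ∈ [0, θ)` receive slow random
external inputs of size `I_ext`; a threshold crossing triggers an
avalanche in which every firing neuron `j` is reset by `θ` and delivers
`J_ij/N` to each neuron `i`. Avalanche sizes `L` follow a scale-free
distribution `P(L) ~ L^γ` when the couplings are critical; the statistic

> Δγ = mean squared residual of the OLS line to `log10 P(L)` vs
> `log10 L` over `1 ≤ L ≤ N/2`

declares the network critical when `Δγ < Δγ^max = 0.005`. Criticality is
self-organized either by **homeostatic regulation**
(`J_ij ← J_ij + ε_hom (1 − ℓ − N^{-1/2})`, with `ℓ` the second-generation
firing count) or by **dynamical synapses** (per-spike depression
`T ← (1−u)T` with exponential recovery toward ceilings `T^max`,
effective coupling `J = uT`).

Memories are `M = αN` sparse binary patterns `ξ^η` (fraction `p`
active), stored in the correlational matrix
`W_ij ∝ Σ_η ξ^η_i ξ^η_j (1−δ_ij)`, `ΣW = N`. Retrieval is one
thresholding step `S_i = [Σ_j J_ij κ_j > Θ]` from a perturbed cue `κ`,
with `Θ` chosen to maximize the mean pattern overlap (a Pearson-type
correlation). The dual optimization alternates critical episodes with
stochastic Hebbian relaxation `J_ij ← J_ij + ε_hebb (W_ij − J_ij)`
(update probability `1/N` per synapse) until the network passes both the
criticality test and the retrieval-improvement test — a *converged
state*.

## Worked example

```python
import numpy as np
from critmem import RunConfig, run_dual_optimization

cfg = RunConfig.desk(mode="dynamical", alpha=0.02, seed=1, A_ava=200_000)
result = run_dual_optimization(cfg)
rep = result.final_report
print(f"converged          : {result.converged}")
print(f"hebbian steps      : {result.hebbian_steps_total}")
print(f"delta_gamma        : {result.final_delta_gamma:.4f}")
print(f"mean overlap       : {rep.mean_overlap_retrieved:.4f}")
print(f"perturbed baseline : {rep.mean_overlap_perturbed:.4f}")
print(f"within one digit   : {rep.fraction_within_digits[1]:.2f}")
```

```
converged          : True
hebbian steps      : 973
delta_gamma        : 0.0018
mean overlap       : 1.0000
perturbed baseline : 0.9630
within one digit   : 1.00
```

At load α = 0.02 the dynamical-synapse network reaches a state whose
avalanche size distribution is an excellent power law (Δγ = 0.0018,
far below the 0.005 criterion) while every stored pattern is
reconstructed from single-swap perturbations essentially perfectly
(mean overlap 1.000, against the 0.963 overlap the perturbed cues
themselves have).

There is also a scikit-learn-style facade:

```python
from critmem import AssociativeMemory, generate_patterns
import numpy as np

rng = np.random.default_rng(0)
X = generate_patterns(M=15, N=300, p=0.1, rng=rng).patterns
mem = AssociativeMemory(n_perturbations=200, random_state=0).fit(X)
print(mem.report_.mean_overlap_retrieved)   # ~1.0 at this load
```

and a CLI: `critmem pure-memory`, `critmem optimize`,
`critmem analyze-avalanches` (see `critmem --help`).

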
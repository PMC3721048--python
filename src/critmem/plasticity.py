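"""Synaptic mechanisms: homeostatic regulation, short-term depression with
exponential recovery (dynamical synapses), and stochastic Hebbian relaxation
toward a memory matrix.

Homeostatic rule
----------------
Once per avalanche every regulated weight is nudged by
``eps_hom * (1 - ell - N**-0.5)`` where ``ell`` is the number of firings in
the avalanche's second generation.  At the fixed point the trigger neuron
activates on average ``1 - N**-0.5`` others: a critical branching process
with a finite-size correction.  The rule as written can drive weights
negative; the model is purely excitatory, so updates are clipped at zero.

Dynamical synapses
------------------
Each synapse carries a resource ``T_ij`` bounded by ``T^max_ij``.  A
presynaptic spike of ``j`` consumes a fraction ``u`` of every outgoing
resource ``T_ij``; between spikes resources recover exponentially toward
``T^max`` with time constant ``tau_J``.  The effective coupling is
``J_ij = u * T_ij``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import CouplingMatrix


@dataclass
class DynamicSynapses:
    """Instantaneous resources ``T``, their ceilings ``T_max``, and the
    usage fraction / recovery time constant of the depression model."""

    T: np.ndarray
    T_max: np.ndarray
    u: float
    tau_J: float
    N: int

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=np.float64)
        self.T_max = np.asarray(self.T_max, dtype=np.float64)
        if self.T.shape != (self.N, self.N) or self.T_max.shape != (self.N, self.N):
            raise ValueError(f"T and T_max must have shape ({self.N}, {self.N})")
        if not 0 < self.u < 1:
            raise ValueError("u must be in (0, 1)")
        if self.tau_J <= 0:
            raise ValueError("tau_J must be positive")
        if np.any(np.diag(self.T) != 0) or np.any(np.diag(self.T_max) != 0):
            raise ValueError("T and T_max must have zero diagonals")
        if np.any(self.T < 0) or np.any(self.T > self.T_max + 1e-12):
            raise ValueError("T must satisfy 0 <= T <= T_max elementwise")

    @property
    def effective_weights(self) -> np.ndarray:
        """Current coupling matrix J = u * T."""
        return self.u * self.T

    @classmethod
    def uniform(cls, N: int, T_max_value: float, u: float, tau_J: float) -> "DynamicSynapses":
        T_max = np.full((N, N), float(T_max_value))
        np.fill_diagonal(T_max, 0.0)
        return cls(T=T_max.copy(), T_max=T_max, u=u, tau_J=tau_J, N=N)

    def copy(self) -> "DynamicSynapses":
        return DynamicSynapses(self.T.copy(), self.T_max.copy(), self.u, self.tau_J, self.N)


@dataclass
class PlasticityParams:
    """Bundle of plasticity constants (see :class:`critmem.config.RunConfig`)."""

    eps_hom: float
    eps_hebb: float
    update_prob: float
    T_L: int
    nu: float

    def __post_init__(self) -> None:
        if self.eps_hom <= 0 or self.eps_hebb <= 0:
            raise ValueError("learning rates must be positive")
        if self.eps_hebb >= 0.1:
            raise ValueError("eps_hebb must be << 1 (enforced as < 0.1)")
        if not 0 < self.update_prob <= 1:
            raise ValueError("update_prob must be in (0, 1]")


# --------------------------------------------------------------------------- #
# homeostatic regulation
# --------------------------------------------------------------------------- #


def homeostatic_update(
    J: CouplingMatrix,
    second_gen_count: int,
    eps_hom: float,
    N: int,
    scope: str = "global",
    trigger: int | None = None,
) -> CouplingMatrix:
    """One homeostatic step driven by the second-generation count ℓ.

    With ``scope='global'`` every off-diagonal weight receives the same
    additive nudge; with ``scope='trigger_outgoing'`` only the outgoing
    synapses of the avalanche's trigger neuron are regulated.  Weights are
    clipped at zero from below and the result is returned as a new matrix.
    """
    if second_gen_count < 0:
        raise ValueError("second_gen_count must be nonnegative")
    if N < 2:
        raise ValueError("N must be >= 2")
    if eps_hom <= 0:
        raise ValueError("eps_hom must be positive")
    delta = eps_hom * (1.0 - second_gen_count - N ** -0.5)
    out = J.J.copy()
    if scope == "global":
        out += delta
    elif scope == "trigger_outgoing":
        if trigger is None:
            raise ValueError("trigger_outgoing scope requires a trigger index")
        out[:, trigger] += delta
    else:
        raise ValueError(f"unknown homeostatic scope {scope!r}")
    np.clip(out, 0.0, None, out=out)
    np.fill_diagonal(out, 0.0)
    return CouplingMatrix(out, J.N)


# --------------------------------------------------------------------------- #
# dynamical synapses
# --------------------------------------------------------------------------- #


def depress_on_spike(syn: DynamicSynapses, presyn: int) -> DynamicSynapses:
    """Consume a fraction ``u`` of the resources of presyn's outgoing synapses."""
    if not 0 <= presyn < syn.N:
        raise ValueError(f"presynaptic index {presyn} out of range")
    syn.T[:, presyn] *= 1.0 - syn.u
    return syn


def recover(syn: DynamicSynapses, dt: float) -> DynamicSynapses:
    """Spike-free exponential recovery over an interval ``dt``.

    Closed-form integration: ``T <- T_max - (T_max - T) * exp(-dt / tau_J)``.
    """
    if dt < 0:
        raise ValueError("dt must be nonnegative")
    decay = np.exp(-dt / syn.tau_J)
    syn.T[:] = syn.T_max - (syn.T_max - syn.T) * decay
    np.fill_diagonal(syn.T, 0.0)
    return syn


# --------------------------------------------------------------------------- #
# Hebbian relaxation
# --------------------------------------------------------------------------- #


def _hebbian_mask(N: int, update_prob: float, rng: np.random.Generator) -> np.ndarray:
    mask = rng.random((N, N)) < update_prob
    np.fill_diagonal(mask, False)
    return mask


def hebbian_step(
    J: CouplingMatrix,
    W: np.ndarray,
    eps_hebb: float,
    update_prob: float,
    rng: np.random.Generator,
) -> CouplingMatrix:
    """One stochastic relaxation step of the couplings toward a target matrix.

    Independently for each off-diagonal synapse, with probability
    ``update_prob`` (1/N in the reference setting):
    ``J_ij <- J_ij + eps_hebb * (W_ij - J_ij)``.
    """
    W = np.asarray(W, dtype=np.float64)
    if W.shape != J.J.shape:
        raise ValueError("dimension mismatch between J and W")
    if not 0 < eps_hebb <= 1:
        raise ValueError("eps_hebb must be in (0, 1]")
    mask = _hebbian_mask(J.N, update_prob, rng)
    out = J.J.copy()
    out[mask] += eps_hebb * (W[mask] - out[mask])
    return CouplingMatrix(out, J.N)


def hebbian_step_dynamic(
    syn: DynamicSynapses,
    W: np.ndarray,
    eps_hebb: float,
    update_prob: float,
    rng: np.random.Generator,
) -> DynamicSynapses:
    """Hebbian relaxation of the *maximal* resources toward ``W / u``.

    The instantaneous resources are not learned directly (their structure
    would be erased by recovery); instead the ceilings relax so that
    ``u * T^max`` has the same fixed point as the static Hebbian rule.
    ``T`` is clipped to remain below a lowered ceiling.
    """
    W = np.asarray(W, dtype=np.float64)
    if W.shape != syn.T_max.shape:
        raise ValueError("dimension mismatch between synapses and W")
    if not 0 < eps_hebb <= 1:
        raise ValueError("eps_hebb must be in (0, 1]")
    mask = _hebbian_mask(syn.N, update_prob, rng)
    target = W / syn.u
    syn.T_max[mask] += eps_hebb * (target[mask] - syn.T_max[mask])
    np.fill_diagonal(syn.T_max, 0.0)
    np.minimum(syn.T, syn.T_max, out=syn.T)
    return syn
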
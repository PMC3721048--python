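"""Event-driven integrate-and-fire network with avalanche dynamics.

The model is non-leaky: between avalanches, membrane potentials only change
when the slow external drive deposits an increment ``I_ext`` on a uniformly
chosen neuron.  As soon as a neuron reaches the threshold θ an avalanche
unfolds on an (effectively) infinitely faster time scale: all suprathreshold
neurons of a *generation* fire synchronously, each firing neuron loses
exactly θ and delivers ``J_ij / N`` to every other neuron, and the loop
repeats until no neuron is suprathreshold.  External input and synaptic
recovery are frozen for the duration of an avalanche.

This module is the readable reference implementation of the dynamics; long
recording runs go through the compiled kernels in :mod:`critmem.engine`,
which are cross-checked against these functions in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class NetworkState:
    """Membrane potentials and firing machinery of ``N`` neurons.

    Between avalanches every potential satisfies ``0 <= h_i < theta``;
    potentials transiently exceed ``theta`` only inside
    :func:`propagate_avalanche`.
    """

    h: np.ndarray
    theta: float
    N: int
    sim_time: float = 0.0

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=np.float64)
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.h.shape != (self.N,):
            raise ValueError(f"h must have shape ({self.N},)")

    def copy(self) -> "NetworkState":
        return NetworkState(self.h.copy(), self.theta, self.N, self.sim_time)


@dataclass
class CouplingMatrix:
    """Static synaptic weights; ``J[i, j]`` is the synapse from j to i.

    Entries are nonnegative (the model is purely excitatory) and the
    diagonal is zero (no self-coupling).  A spike of neuron ``j`` delivers
    ``J[i, j] / N`` to neuron ``i``.
    """

    J: np.ndarray
    N: int

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=np.float64)
        if self.J.shape != (self.N, self.N):
            raise ValueError(f"J must have shape ({self.N}, {self.N})")
        if np.any(np.diag(self.J) != 0.0):
            raise ValueError("J must have a zero diagonal")
        if np.any(self.J < 0.0):
            raise ValueError("J must be elementwise nonnegative")

    @classmethod
    def uniform(cls, N: int, value: float) -> "CouplingMatrix":
        J = np.full((N, N), float(value))
        np.fill_diagonal(J, 0.0)
        return cls(J, N)

    def copy(self) -> "CouplingMatrix":
        return CouplingMatrix(self.J.copy(), self.N)


@dataclass
class AvalancheRecord:
    """Bookkeeping of one avalanche.

    ``size`` counts firings with multiplicity (a neuron may fire in several
    generations), ``duration`` counts synchronous generations, and
    ``second_gen_count`` is the number of firings in the second generation
    (the ℓ that drives the homeostatic rule).
    """

    size: int
    duration: int
    generations: list = field(default_factory=list)
    second_gen_count: int = 0
    trigger_neuron: int = -1

    def validate(self) -> None:
        assert self.size == sum(len(g) for g in self.generations)
        assert self.duration == len(self.generations)
        assert len(self.generations[0]) == 1
        assert self.generations[0][0] == self.trigger_neuron
        expected_ell = len(self.generations[1]) if self.duration >= 2 else 0
        assert self.second_gen_count == expected_ell


# --------------------------------------------------------------------------- #
# operations
# --------------------------------------------------------------------------- #


def init_network(N: int, theta: float, rng: np.random.Generator) -> NetworkState:
    """Fresh network state with potentials drawn uniformly on [0, theta)."""
    if N < 2:
        raise ValueError("N must be >= 2")
    if theta <= 0:
        raise ValueError("theta must be positive")
    h = rng.random(N) * theta
    return NetworkState(h=h, theta=theta, N=N, sim_time=0.0)


def external_input_event(
    state: NetworkState,
    I_ext: float,
    rng: np.random.Generator,
    tau: float = 1.0,
) -> tuple[NetworkState, bool, int]:
    """Deposit one external input on a uniformly chosen neuron.

    Advances the slow-regime clock by one exponentially distributed
    inter-event interval of mean ``tau`` and returns
    ``(state, triggered, neuron)`` where ``triggered`` indicates that the
    chosen neuron reached threshold.  The state is modified in place.
    """
    if I_ext <= 0:
        raise ValueError("I_ext must be positive")
    neuron = int(rng.random() * state.N)
    state.sim_time += -tau * np.log(1.0 - rng.random())
    state.h[neuron] += I_ext
    triggered = bool(state.h[neuron] >= state.theta)
    return state, triggered, neuron


def propagate_avalanche(
    state: NetworkState,
    couplings,
    on_presyn_spike=None,
    refractory: bool = True,
) -> tuple[NetworkState, AvalancheRecord]:
    """Run one avalanche to completion (generation-synchronous loop).

    ``couplings`` is a :class:`CouplingMatrix` or any object exposing a
    current effective weight matrix via an ``effective_weights`` attribute
    (e.g. dynamical synapses, whose weights may change between generations
    when ``on_presyn_spike`` depresses them).  ``on_presyn_spike(j)`` is
    invoked once per firing, after the firings of the generation have been
    delivered.

    All spikes of one generation are accumulated before any threshold
    re-check, which removes any dependence on delivery order.

    With ``refractory=True`` (the default, and what the recording kernels
    use) a neuron fires at most once per avalanche; surplus potential
    beyond θ is kept and triggers an immediate follow-on avalanche, which
    bounds every avalanche at ``L <= N``.  ``refractory=False`` lets a
    neuron fire again in later generations whenever its residual potential
    still exceeds θ; note that locally supercritical coupling structures
    can then sustain the cascade indefinitely.
    """
    h, theta, N = state.h, state.theta, state.N
    fired = np.flatnonzero(h >= theta)
    if fired.size == 0:
        raise ValueError("propagate_avalanche requires a suprathreshold neuron")
    if fired.size > 1:
        raise ValueError("exactly one trigger neuron expected at avalanche start")

    generations: list[list[int]] = []
    trigger = int(fired[0])
    has_fired = np.zeros(N, dtype=bool)
    while fired.size:
        generations.append([int(j) for j in fired])
        has_fired[fired] = True
        W = _effective_weights(couplings)
        h[fired] -= theta
        # summed in ascending neuron order; matches the compiled kernels
        for j in fired:
            h += W[:, j] / N
        if on_presyn_spike is not None:
            for j in fired:
                on_presyn_spike(int(j))
        fired = np.flatnonzero(h >= theta)
        if refractory:
            fired = fired[~has_fired[fired]]

    size = sum(len(g) for g in generations)
    duration = len(generations)
    ell = len(generations[1]) if duration >= 2 else 0
    record = AvalancheRecord(
        size=size,
        duration=duration,
        generations=generations,
        second_gen_count=ell,
        trigger_neuron=trigger,
    )
    return state, record


def shed_surplus(state: NetworkState, rng: np.random.Generator) -> NetworkState:
    """Re-enter the slow regime: repolarize suprathreshold neurons.

    The membrane potential lives in ``[0, theta)`` between avalanches; a
    refractory neuron whose suppressed spikes would have carried it beyond
    the threshold is repolarized to a uniform random subthreshold value
    (surplus potential is not hoarded across avalanches).
    """
    over = state.h >= state.theta
    state.h[over] = state.theta * rng.random(int(over.sum()))
    return state


def _effective_weights(couplings) -> np.ndarray:
    if isinstance(couplings, CouplingMatrix):
        return couplings.J
    if hasattr(couplings, "effective_weights"):
        return couplings.effective_weights
    return np.asarray(couplings)
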
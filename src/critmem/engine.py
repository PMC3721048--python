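"""Compiled event-driven simulation kernels.

These numba kernels implement exactly the dynamics of
:mod:`critmem.network` (slow Poisson drive, generation-synchronous
avalanche propagation with per-firing reset by θ and delivery ``J_ij/N``)
plus the in-loop plasticity of the two criticalization mechanisms.  The
avalanche map is deterministic given the state, which the test suite uses
to verify exact agreement with the numpy reference implementation.

A neuron fires at most once per avalanche (refractory until the avalanche
ends), which bounds every avalanche at L <= N even when heterogeneous
couplings make a sub-population locally supercritical.  Between avalanches
the membrane potentials live in [0, theta): a neuron whose suppressed
spikes would have carried it beyond the threshold is repolarized to a
uniform random subthreshold value once the avalanche is over (surplus
potential is not hoarded across avalanches).

Randomness inside the kernels comes from numba's internal generator,
seeded explicitly at every kernel entry; callers pass fresh sub-seeds
drawn from their own numpy Generator, so whole runs are reproducible from
a single integer seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _drive(h, theta, I_ext, tau, N):
    """Deposit external inputs until one neuron crosses the threshold.

    Returns (trigger_neuron, elapsed_slow_time).
    """
    t_add = 0.0
    while True:
        i = int(np.random.random() * N)
        t_add += -tau * math.log(1.0 - np.random.random())
        h[i] += I_ext
        if h[i] >= theta:
            return i, t_add


@njit(cache=True)
def _shed_surplus(h, theta, N):
    """Repolarize suprathreshold neurons to uniform [0, theta)."""
    for i in range(N):
        if h[i] >= theta:
            h[i] = theta * np.random.random()


@njit(cache=True)
def _avalanche_static(h, J, theta, invN, buf, fired):
    """One avalanche with frozen couplings.

    Returns ``(size, ell, n_first)`` where ``n_first`` is the size of the
    first generation; ``buf[:n_first]`` still holds the first-generation
    neurons on exit (used by the trigger-outgoing homeostatic scope).
    """
    N = h.shape[0]
    for i in range(N):
        fired[i] = False
    L = 0
    ell = 0
    n_first = 0
    gen = 0
    while True:
        nf = 0
        off = n_first if gen > 0 else 0
        for i in range(N):
            if h[i] >= theta and not fired[i]:
                buf[off + nf] = i
                fired[i] = True
                nf += 1
        if nf == 0:
            return L, ell, n_first
        gen += 1
        if gen == 1:
            n_first = nf
        elif gen == 2:
            ell = nf
        L += nf
        for idx in range(nf):
            h[buf[off + idx]] -= theta
        for idx in range(nf):
            j = buf[off + idx]
            for i in range(N):
                h[i] += J[i, j] * invN
        # J[j, j] == 0, so self-delivery vanishes


@njit(cache=True)
def record_static(h, J, theta, I_ext, tau, n_discard, n_record, seed):
    """Record avalanche sizes of the static-coupling network.

    Modifies ``h`` in place; returns the int64 array of recorded sizes.
    """
    np.random.seed(seed)
    N = h.shape[0]
    invN = 1.0 / N
    buf = np.empty(N, np.int64)
    fired = np.empty(N, np.bool_)
    sizes = np.empty(n_record, np.int64)
    for k in range(n_discard + n_record):
        _drive(h, theta, I_ext, tau, N)
        L, _, _ = _avalanche_static(h, J, theta, invN, buf, fired)
        _shed_surplus(h, theta, N)
        if k >= n_discard:
            sizes[k - n_discard] = L
    return sizes


@njit(cache=True)
def run_homeostatic(
    h, J, theta, I_ext, tau, n_avalanches, eps_hom, scope_global, record, seed
):
    """Run avalanches with the homeostatic rule applied once per avalanche.

    After each avalanche every regulated weight receives
    ``eps_hom * (1 - ell - N**-0.5)`` (clipped at zero), where ``ell`` is
    that avalanche's second-generation firing count; with
    ``scope_global == False`` only the outgoing synapses of the
    first-generation (triggering) neurons are regulated, so each neuron's
    own branching ratio is driven toward the critical value.  ``h`` and
    ``J`` are modified in place.  Returns the sizes array (empty when
    ``record`` is False).
    """
    np.random.seed(seed)
    N = h.shape[0]
    invN = 1.0 / N
    corr = 1.0 / math.sqrt(N)
    buf = np.empty(N, np.int64)
    fired = np.empty(N, np.bool_)
    sizes = np.empty(n_avalanches if record else 0, np.int64)
    for k in range(n_avalanches):
        _drive(h, theta, I_ext, tau, N)
        L, ell, n_first = _avalanche_static(h, J, theta, invN, buf, fired)
        _shed_surplus(h, theta, N)
        if record:
            sizes[k] = L
        delta = eps_hom * (1.0 - ell - corr)
        if scope_global:
            for i in range(N):
                for j in range(N):
                    if i != j:
                        x = J[i, j] + delta
                        J[i, j] = x if x > 0.0 else 0.0
        else:
            for idx in range(n_first):
                j = buf[idx]
                for i in range(N):
                    if i != j:
                        x = J[i, j] + delta
                        J[i, j] = x if x > 0.0 else 0.0
    return sizes


@njit(cache=True)
def run_dynamical(
    h, T, T_max, u, tau_J, theta, I_ext, tau, t0, t_sync,
    n_discard, n_record, seed,
):
    """Record avalanches of the dynamical-synapse network.

    Resources recover lazily: each presynaptic column carries the time
    ``t_sync[j]`` of its last update and is advanced analytically
    (``T <- T_max - (T_max - T) exp(-dt/tau_J)``) just before its neuron
    fires.  A spike of ``j`` delivers ``u T_ij / N`` and then consumes the
    fraction ``u`` of the column.  During an avalanche the slow clock is
    frozen.  ``h``, ``T`` and ``t_sync`` are modified in place; returns
    ``(sizes, t_end)``.
    """
    np.random.seed(seed)
    N = h.shape[0]
    invN = 1.0 / N
    buf = np.empty(N, np.int64)
    fired = np.empty(N, np.bool_)
    sizes = np.empty(n_record, np.int64)
    t = t0
    for k in range(n_discard + n_record):
        trig, dt = _drive(h, theta, I_ext, tau, N)
        t += dt
        for i in range(N):
            fired[i] = False
        L = 0
        while True:
            nf = 0
            for i in range(N):
                if h[i] >= theta and not fired[i]:
                    buf[nf] = i
                    fired[i] = True
                    nf += 1
            if nf == 0:
                break
            L += nf
            for idx in range(nf):
                h[buf[idx]] -= theta
            for idx in range(nf):
                j = buf[idx]
                decay = math.exp(-(t - t_sync[j]) / tau_J)
                for i in range(N):
                    Tij = T_max[i, j] - (T_max[i, j] - T[i, j]) * decay
                    h[i] += u * Tij * invN
                    T[i, j] = Tij * (1.0 - u)
                t_sync[j] = t
        _shed_surplus(h, theta, N)
        if k >= n_discard:
            sizes[k - n_discard] = L
    return sizes, t


def sync_resources(T, T_max, t_sync, t_now, tau_J):
    """Advance every column's resources to a common time (numpy, in place)."""
    decay = np.exp(-(t_now - np.asarray(t_sync)) / tau_J)
    T[:] = T_max - (T_max - T) * decay[None, :]
    np.fill_diagonal(T, 0.0)
    t_sync[:] = t_now
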
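"""Avalanche-ensemble statistics and the criticality decision.

The empirical avalanche size distribution ``P(L)`` is compared with its
best-matching power law over the fit range ``1 <= L <= N/2``: an ordinary
least-squares line in log10 P versus log10 L over the non-empty bins, whose
mean squared residual is the deviation statistic Δγ.  A network is deemed
critical when ``Δγ < Δγ^max`` (strict).

The least-squares objective *is* the definition of "best-matching" here:
Δγ is the minimal mean squared log-deviation achievable by any power law
over the fit range.  Raw (unbinned) integer sizes are used; empty bins are
excluded (their log-probability is undefined).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FitError, NonConvergenceError


@dataclass
class AvalancheEnsemble:
    """Recorded avalanche sizes plus bookkeeping of the recording protocol."""

    sizes: np.ndarray
    N: int
    n_discarded: int = 0

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        if self.sizes.ndim != 1:
            raise ValueError("sizes must be a 1-D sequence")
        if self.sizes.size and self.sizes.min() < 1:
            raise ValueError("avalanche sizes must be >= 1")

    @property
    def n_recorded(self) -> int:
        return int(self.sizes.size)


@dataclass
class SizeDistribution:
    """Empirical P(L) on integer support 1..L_max."""

    support: np.ndarray
    probability: np.ndarray

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=np.int64)
        self.probability = np.asarray(self.probability, dtype=np.float64)
        if self.support.shape != self.probability.shape:
            raise ValueError("support and probability must have equal shapes")
        if np.any(self.probability < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(self.probability.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")


@dataclass
class PowerLawFit:
    """Best-fit power law P(L) ∝ L^gamma and its mean squared log-deviation."""

    gamma: float
    log_intercept: float
    delta_gamma: float
    fit_range: tuple[int, int]
    n_bins: int = 0

    def to_dict(self) -> dict:
        return {
            "gamma": float(self.gamma),
            "log_intercept": float(self.log_intercept),
            "delta_gamma": float(self.delta_gamma),
            "fit_range": [int(self.fit_range[0]), int(self.fit_range[1])],
            "n_bins": int(self.n_bins),
        }


# --------------------------------------------------------------------------- #


def size_distribution(ensemble: AvalancheEnsemble) -> SizeDistribution:
    """Empirical probability of each avalanche size up to the largest observed."""
    if ensemble.n_recorded == 0:
        raise ValueError("cannot build a distribution from an empty ensemble")
    counts = np.bincount(ensemble.sizes)[1:]  # drop the impossible size 0
    support = np.arange(1, counts.size + 1)
    return SizeDistribution(support=support, probability=counts / ensemble.n_recorded)


def fit_power_law(dist: SizeDistribution, N: int) -> PowerLawFit:
    """OLS power-law fit of log10 P(L) vs log10 L over 1 <= L <= N/2.

    ``gamma`` is the slope (negative for decaying laws) and ``delta_gamma``
    the mean squared residual over the non-empty bins in the fit range.
    """
    L_hi = N // 2
    in_range = (dist.support >= 1) & (dist.support <= L_hi) & (dist.probability > 0)
    L = dist.support[in_range]
    if L.size < 3:
        raise FitError(
            f"need at least 3 non-empty bins in [1, {L_hi}] to fit, got {L.size}"
        )
    x = np.log10(L.astype(np.float64))
    y = np.log10(dist.probability[in_range])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return PowerLawFit(
        gamma=float(slope),
        log_intercept=float(intercept),
        delta_gamma=float(np.mean(resid**2)),
        fit_range=(1, L_hi),
        n_bins=int(L.size),
    )


def fit_sizes(sizes: np.ndarray, N: int) -> PowerLawFit:
    """Convenience: distribution + power-law fit from raw sizes."""
    return fit_power_law(size_distribution(AvalancheEnsemble(sizes, N)), N)


def is_critical(fit: PowerLawFit, delta_gamma_max: float) -> bool:
    """Criticality decision: Δγ strictly below the threshold."""
    return bool(fit.delta_gamma < delta_gamma_max)


def sample_until_critical(
    sim,
    A_0: int,
    A_ava: int,
    delta_gamma_max: float,
    max_rounds: int = 50,
) -> tuple[AvalancheEnsemble, PowerLawFit]:
    """Drive a simulator until its avalanche size distribution is a power law.

    ``sim`` is a :class:`critmem.orchestrate.AvalancheSimulator` (or any
    object with the same ``discard`` / ``learn`` / ``record`` interface).
    The first ``A_0`` avalanches are discarded as transients, then batches
    of ``A_ava`` avalanches are recorded and fitted; while the fit fails the
    criticality test, the simulator's criticalization mechanism keeps
    running (another homeostatic learning episode, or simply further
    depression/recovery dynamics) and a fresh batch is recorded.  Batches
    are not accumulated: the reported distribution reflects the latest
    weights.
    """
    sim.discard(A_0)
    last_dg = None
    for _ in range(max_rounds):
        sizes = sim.record(A_ava)
        ensemble = AvalancheEnsemble(sizes, sim.N, n_discarded=A_0)
        fit = fit_power_law(size_distribution(ensemble), sim.N)
        last_dg = fit.delta_gamma
        if is_critical(fit, delta_gamma_max):
            return ensemble, fit
        sim.criticalize_more()
    raise NonConvergenceError(
        f"size distribution did not converge to a power law in "
        f"{max_rounds} rounds (last delta_gamma = {last_dg:.6g})",
        last_delta_gamma=last_dg,
    )


def find_critical_coupling(
    N: int,
    theta: float = 1.0,
    I_ext: float = 0.0067,
    n_avalanches: int = 10_000,
    n_grid: int = 21,
    J_lo: float = 0.5,
    J_hi: float = 1.2,
    seed: int = 0,
    n_discard: int = 1_000,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Brute-force scan for the critical uniform coupling.

    Runs the static network at ``n_grid`` uniform coupling values (units of
    theta) and returns ``(J_cr, grid, delta_gammas)`` where ``J_cr``
    minimizes Δγ.  This is the independent oracle against which the
    self-organizing mechanisms are checked.
    """
    from .engine import record_static
    from .network import CouplingMatrix, init_network

    grid = np.linspace(J_lo, J_hi, n_grid)
    dgs = np.empty(n_grid)
    rng = np.random.default_rng(seed)
    for idx, Jval in enumerate(grid):
        state = init_network(N, theta, rng)
        J = CouplingMatrix.uniform(N, Jval * theta)
        kernel_seed = int(rng.integers(2**31 - 1))
        sizes = record_static(
            state.h, J.J, theta, I_ext, 1.0, n_discard, n_avalanches, kernel_seed
        )
        dgs[idx] = fit_sizes(sizes, N).delta_gamma
    return float(grid[int(np.argmin(dgs))]), grid, dgs
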
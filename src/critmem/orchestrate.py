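"""Experiment drivers: pure memory networks, and the dual optimization that
alternates critical episodes with Hebbian learning until the network is
simultaneously critical and an associative memory.

Episode protocol (homeostatic mode)
-----------------------------------
1. homeostatic learning over ``T_L`` avalanches (plus the ``A_0`` transient
   at the start of each critical phase, also with learning active);
2. record a batch of ``A_ava`` avalanches — the homeostatic rule stays
   active while recording — and fit the size distribution; while
   ``Δγ >= Δγ^max`` keep recording fresh batches;
3. convergence check: retrieval of ``n_p`` perturbations per pattern must
   improve the mean overlap by more than ``Δ_conv``; if so the run has
   converged;
4. otherwise Hebbian learning: stochastic relaxation steps toward the
   memory matrix, after each step checking the single-perturbation
   improvement criterion with ``Δ_hebb``; on success return to 1, on
   saturation stop (with one last excursion toward the critical regime so
   that non-converged runs still report Δγ and retrieval quality).

In dynamical mode the criticalization mechanism is intrinsic (depression
and recovery), Hebbian learning acts on the maximal resources, retrieval
quality during Hebbian learning is assessed on ``u T^max`` and the
convergence check on the instantaneous ``u T``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import engine
from .config import RunConfig
from .criticality import PowerLawFit, fit_sizes, sample_until_critical
from .errors import NonConvergenceError, UndefinedOverlapError
from .memory import (
    MemoryMatrix,
    PatternSet,
    RetrievalReport,
    _threshold_sweep,
    assess_retrieval,
    build_memory_matrix,
    generate_patterns,
    improvement_criterion,
    perturb_many,
    two_digit_reference_overlap,
)
from .network import init_network

# Saturation detection for the Hebbian phase: the windowed mean of the
# single-perturbation quality must set a new maximum (by at least
# SAT_MIN_DELTA) within SAT_PATIENCE steps, otherwise the overlap is
# considered saturated.  The windowing absorbs the perturbation-sampling
# noise of the per-step quality estimate; the patience spans several
# characteristic relaxation times of the stochastic rule (each synapse is
# updated every ~N steps), because the quality trajectory has a long slow
# start while the structural tilt is still below the uniform background.
SAT_WINDOW = 200
SAT_PATIENCE = 15000
SAT_MIN_DELTA = 2e-4


@dataclass
class RunResult:
    """Outcome of one dual-optimization run."""

    converged: bool
    hebbian_steps_total: int
    final_delta_gamma: float
    final_report: RetrievalReport | None
    episode_log: list = field(default_factory=list)
    final_sizes: np.ndarray | None = None
    final_couplings: np.ndarray | None = None
    avalanche_sizes_path: str | None = None

    def to_dict(self) -> dict:
        return {
            "converged": bool(self.converged),
            "hebbian_steps_total": int(self.hebbian_steps_total),
            "final_delta_gamma": float(self.final_delta_gamma),
            "final_report": (self.final_report.to_dict()
                             if self.final_report is not None else None),
            "episode_log": [
                {"kind": k, "length": int(n), "summary": s}
                for (k, n, s) in self.episode_log
            ],
            "avalanche_sizes_path": self.avalanche_sizes_path,
        }


class AvalancheSimulator:
    """Stateful handle bundling network state, couplings and mechanism.

    ``mode`` selects what happens while avalanches run:

    - ``"static"``/``"pure_memory"``: frozen couplings;
    - ``"homeostatic"``: the homeostatic rule runs during every avalanche
      (transients, learning episodes and recorded batches alike);
    - ``"dynamical"``: depression and recovery are always active.
    """

    def __init__(self, config: RunConfig, rng: np.random.Generator,
                 J: np.ndarray | None = None,
                 T: np.ndarray | None = None,
                 T_max: np.ndarray | None = None):
        self.config = config
        self.N = config.N
        self.mode = "static" if config.mode == "pure_memory" else config.mode
        self.rng = rng
        self.I_ext = config.resolved_I_ext()
        state = init_network(config.N, config.theta, rng)
        self.h = state.h
        self.t = 0.0
        if self.mode == "dynamical":
            if T_max is None:
                raise ValueError("dynamical mode requires T_max")
            self.T_max = T_max
            self.T = T_max.copy() if T is None else T
            self.t_sync = np.zeros(config.N)
            self.J = None
        else:
            if J is None:
                raise ValueError("static/homeostatic modes require J")
            self.J = J
            self.T = self.T_max = self.t_sync = None

    def _seed(self) -> int:
        return int(self.rng.integers(2**31 - 1))

    def _run(self, n: int, *, learn: bool, record: bool) -> np.ndarray:
        cfg = self.config
        if self.mode == "dynamical":
            sizes, self.t = engine.run_dynamical(
                self.h, self.T, self.T_max, cfg.u, cfg.tau_J, cfg.theta,
                self.I_ext, cfg.tau, self.t, self.t_sync, 0, n, self._seed(),
            )
            return sizes if record else sizes[:0]
        if self.mode == "homeostatic" and learn:
            return engine.run_homeostatic(
                self.h, self.J, cfg.theta, self.I_ext, cfg.tau, n,
                cfg.eps_hom, cfg.homeostatic_scope == "global", record,
                self._seed(),
            )
        return engine.record_static(
            self.h, self.J, cfg.theta, self.I_ext, cfg.tau,
            0 if record else n, n if record else 0, self._seed(),
        )

    def discard(self, n: int) -> None:
        """Transient avalanches; the criticalization mechanism stays active."""
        if n > 0:
            self._run(n, learn=True, record=False)

    def learn(self, n: int) -> None:
        """A homeostatic learning episode (alias of discard for other modes)."""
        if n > 0:
            self._run(n, learn=True, record=False)

    def record(self, n: int) -> np.ndarray:
        """Record a batch of avalanche sizes.

        The active criticalization mechanism keeps running while the batch
        is recorded (homeostatic learning, or depression/recovery); in
        static mode the couplings are frozen.
        """
        return self._run(n, learn=True, record=True)

    def criticalize_more(self) -> None:
        """Between-batch mechanism activity when a batch failed the Δγ test.

        The mechanisms already run while recording, so no extra work is
        needed; the hook exists for static networks (where it is a no-op,
        making non-convergence detectable)."""

    def instantaneous_couplings(self) -> np.ndarray:
        """J, or u*T synced to the current time (used for convergence checks)."""
        if self.mode == "dynamical":
            engine.sync_resources(self.T, self.T_max, self.t_sync, self.t,
                                  self.config.tau_J)
            return self.config.u * self.T
        return self.J

    def ceiling_couplings(self) -> np.ndarray:
        """J, or u*T_max (used for Hebbian-phase quality checks)."""
        if self.mode == "dynamical":
            return self.config.u * self.T_max
        return self.J


# --------------------------------------------------------------------------- #
# pure memory networks
# --------------------------------------------------------------------------- #


# Critical branching ratio of the uniform fixed-weight network at the
# reference conditions (N = 300, theta = 1, I_ext = 0.0067), i.e. the
# uniform coupling minimizing Δγ in units of theta, as measured by
# criticality.find_critical_coupling.  Close to the finite-size estimate
# 1 - N**-0.5 ≈ 0.94 that the homeostatic rule regulates toward.
CRITICAL_BRANCHING_RATIO = 0.92


def coupling_from_memory(
    W: MemoryMatrix, N: int, theta: float = 1.0,
    branching: float = CRITICAL_BRANCHING_RATIO,
) -> np.ndarray:
    """Install the memory matrix as couplings on the membrane-equation scale.

    ``J = N * W`` (delivery ``J_ij/N``) would give a mean branching ratio
    of exactly 1 — marginally supercritical for a finite network; the
    installed couplings are scaled so that the *mean* coupling sits at the
    critical value of the uniform fixed-weight model (the Δγ-minimizing
    uniform coupling, ``branching`` in units of theta).
    """
    return branching * N * theta * W.W


def run_pure_memory(
    config: RunConfig,
    alphas,
    *,
    retrieval: bool = True,
    criticality: bool = True,
) -> pd.DataFrame:
    """Assess fixed-coupling memory networks (J = W) over a load grid.

    For each load ``alpha`` and trial: generate patterns, build the memory
    matrix, optionally assess retrieval of ``n_p`` perturbations per
    pattern, and optionally record an avalanche ensemble with frozen
    weights to measure Δγ.  Returns one row per load value with
    trial-averaged columns.
    """
    rows = []
    for a_idx, alpha in enumerate(alphas):
        per_trial = []
        for trial in range(config.trials):
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, a_idx, trial])
            )
            M = int(round(alpha * config.N))
            ps = generate_patterns(M, config.N, config.sparseness, rng)
            Wm = build_memory_matrix(ps)
            J = coupling_from_memory(Wm, config.N)
            entry = {}
            if retrieval:
                report = assess_retrieval(J, ps, config.n_p, rng)
                entry["mean_overlap_retrieved"] = report.mean_overlap_retrieved
                entry["mean_overlap_perturbed"] = report.mean_overlap_perturbed
                entry["frac_within_one_digit"] = report.fraction_within_digits[1]
            if criticality:
                cfg = config.replace(mode="pure_memory", alpha=alpha)
                sim = AvalancheSimulator(cfg, rng, J=J)
                sim.discard(config.A_0)
                fit = fit_sizes(sim.record(config.A_ava), config.N)
                entry["delta_gamma"] = fit.delta_gamma
                entry["gamma"] = fit.gamma
            per_trial.append(entry)
        mean = pd.DataFrame(per_trial).mean().to_dict()
        rows.append({"alpha": float(alpha), "n_trials": config.trials, **mean})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------- #
# dual optimization
# --------------------------------------------------------------------------- #


class _HebbianPhase:
    """Stochastic relaxation of couplings toward a target, with an
    incrementally maintained field matrix for the per-step quality check."""

    def __init__(self, mat: np.ndarray, target: np.ndarray,
                 patterns: PatternSet, eps: float, p_update: float,
                 rng: np.random.Generator):
        self.mat = mat          # updated in place
        self.target = target
        self.ps = patterns
        self.eps = eps
        self.p = p_update
        self.rng = rng
        self.xi_f = patterns.patterns.astype(np.float64)
        self.base = self.xi_f @ mat.T  # (M, N) fields of the unperturbed patterns
        self._steps_since_rebuild = 0

    def step(self) -> None:
        mask = self.rng.random(self.mat.shape) < self.p
        np.fill_diagonal(mask, False)
        rows, cols = np.nonzero(mask)
        delta = self.eps * (self.target[rows, cols] - self.mat[rows, cols])
        self.mat[rows, cols] += delta
        # base[m, i] = sum_j mat[i, j] xi[m, j]; only (rows, cols) changed
        self.base[:, rows] += delta[None, :] * self.xi_f[:, cols]
        self._steps_since_rebuild += 1
        if self._steps_since_rebuild >= 2000:  # wash out float drift
            self.base = self.xi_f @ self.mat.T
            self._steps_since_rebuild = 0

    def quality(self) -> float:
        """Mean retrieved overlap over one fresh perturbation per pattern,
        at the overlap-maximizing threshold.

        Returns ``-inf`` while the couplings are still too unstructured for
        any admissible threshold to exist (e.g. uniform resource ceilings
        at the start of dynamical-mode learning)."""
        _, removed, added = perturb_many(self.ps, 1, self.rng)
        fields = self.base - self.mat[:, removed].T + self.mat[:, added].T
        try:
            _, objective, _ = _threshold_sweep(fields, self.ps.patterns)
        except UndefinedOverlapError:
            return -np.inf
        return objective


def run_dual_optimization(
    config: RunConfig, patterns: PatternSet | None = None
) -> RunResult:
    """Alternate critical episodes and Hebbian learning (the dual loop).

    Returns a :class:`RunResult`; ``converged`` is True when, after a
    critical episode, retrieval of ``n_p`` perturbations per pattern
    improves the mean overlap by more than ``Δ_conv``.
    """
    if config.mode not in ("homeostatic", "dynamical"):
        raise ValueError("run_dual_optimization requires homeostatic or dynamical mode")
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    if patterns is None:
        patterns = generate_patterns(cfg.M, cfg.N, cfg.sparseness, rng)
    Wm = build_memory_matrix(patterns)

    if cfg.mode == "homeostatic":
        # Hebbian target: the memory matrix with its own ΣW = N
        # normalization, which on the membrane-equation scale is deeply
        # subcritical.  Hebbian relaxation therefore pulls the network
        # *away* from criticality and the homeostatic rule pulls it back;
        # the alternation settles on couplings that carry the W structure
        # as a small additive tilt on a critical background (the global
        # homeostatic shift preserves the tilt exactly).
        W_target = Wm.W
        J = W_target.copy()
        sim = AvalancheSimulator(cfg, rng, J=J)
        learn_mat, learn_target = sim.J, W_target
    else:
        # Uniform ceilings: per-spike transfer u*T_max = t_max_factor/N.
        # The ceilings relax toward the memory matrix scaled so that its
        # mean is the critical coupling: short-term depression tames the
        # resulting heterogeneous (locally dense) structure, which is
        # precisely why this mechanism tolerates strong maximal-efficacy
        # structure where a static network would not.
        T_max = np.full((cfg.N, cfg.N), cfg.t_max_factor * cfg.theta / cfg.u)
        np.fill_diagonal(T_max, 0.0)
        W_target = coupling_from_memory(Wm, cfg.N, cfg.theta)
        sim = AvalancheSimulator(cfg, rng, T_max=T_max)
        learn_mat, learn_target = sim.T_max, W_target / cfg.u

    perturbed_ref = two_digit_reference_overlap(cfg.N, patterns.n_active)
    episode_log: list = []
    hebb_total = 0
    converged = False
    saturated = False
    last_fit: PowerLawFit | None = None
    last_sizes: np.ndarray | None = None
    report: RetrievalReport | None = None

    for round_idx in range(cfg.max_rounds):
        # ----- critical episode -------------------------------------- #
        if cfg.mode == "homeostatic":
            sim.learn(cfg.T_L)
        try:
            ensemble, fit = sample_until_critical(
                sim, cfg.A_0, cfg.A_ava, cfg.delta_gamma_max, cfg.max_rounds
            )
        except NonConvergenceError as exc:
            # criticalization failed within the round budget (e.g. the
            # learned structure overwhelms the mechanism beyond capacity):
            # report the final state instead of aborting
            episode_log.append(
                ("critical", cfg.max_rounds * cfg.A_ava,
                 {"delta_gamma": exc.last_delta_gamma, "failed": True})
            )
            final_dg = exc.last_delta_gamma
            try:
                report = assess_retrieval(
                    sim.instantaneous_couplings(), patterns, cfg.n_p, rng
                )
            except UndefinedOverlapError:
                report = None
            return RunResult(
                converged=False,
                hebbian_steps_total=hebb_total,
                final_delta_gamma=float(final_dg) if final_dg is not None else np.nan,
                final_report=report,
                episode_log=episode_log,
                final_sizes=last_sizes,
                final_couplings=sim.instantaneous_couplings().copy(),
            )
        last_fit, last_sizes = fit, ensemble.sizes
        episode_log.append(
            ("critical", ensemble.n_recorded,
             {"delta_gamma": fit.delta_gamma, "gamma": fit.gamma})
        )
        # ----- convergence check ------------------------------------- #
        try:
            report = assess_retrieval(
                sim.instantaneous_couplings(), patterns, cfg.n_p, rng
            )
        except UndefinedOverlapError:
            report = None  # couplings carry no usable structure yet
        if report is not None and improvement_criterion(report, cfg.Delta_conv):
            converged = True
            break
        if saturated or hebb_total >= cfg.max_hebbian_steps:
            # this critical episode was the "one last excursion"
            break
        # ----- Hebbian learning phase -------------------------------- #
        # homeostatic mode relaxes J itself; dynamical mode relaxes the
        # resource ceilings T_max (the quality check is scale-free, so the
        # ceilings can stand in for u*T_max directly)
        phase = _HebbianPhase(learn_mat, learn_target, patterns,
                              cfg.eps_hebb, 1.0 / cfg.N, rng)
        steps = 0
        window: list[float] = []
        best_window = -np.inf
        best_window_step = 0
        q = -np.inf
        while True:
            phase.step()
            steps += 1
            hebb_total += 1
            q = phase.quality()
            if q - perturbed_ref > cfg.Delta_hebb:
                break
            if np.isfinite(q):  # -inf: no admissible threshold yet
                window.append(q)
            if len(window) > SAT_WINDOW:
                window.pop(0)
            if len(window) == SAT_WINDOW:
                wmean = float(np.mean(window))
                if wmean > best_window + SAT_MIN_DELTA:
                    best_window = wmean
                    best_window_step = steps
                elif steps - best_window_step >= SAT_PATIENCE:
                    saturated = True
                    break
            if hebb_total >= cfg.max_hebbian_steps:
                saturated = True
                break
        if cfg.mode == "dynamical":
            np.minimum(sim.T, sim.T_max, out=sim.T)
        episode_log.append(
            ("hebbian", steps, {"last_quality": q, "saturated": saturated})
        )
    return RunResult(
        converged=converged,
        hebbian_steps_total=hebb_total,
        final_delta_gamma=last_fit.delta_gamma if last_fit else np.nan,
        final_report=report,
        episode_log=episode_log,
        final_sizes=last_sizes,
        final_couplings=sim.instantaneous_couplings().copy(),
    )


def hebbian_step_count_vs_alpha(config: RunConfig, alphas) -> pd.DataFrame:
    """Trial-averaged total Hebbian step counts of converged runs per load."""
    rows = []
    for a_idx, alpha in enumerate(alphas):
        steps_conv: list[int] = []
        n_converged = 0
        results = []
        for trial in range(config.trials):
            cfg = config.replace(
                alpha=alpha,
                seed=int(np.random.SeedSequence([config.seed, a_idx, trial])
                         .generate_state(1)[0] % (2**31 - 1)),
            )
            res = run_dual_optimization(cfg)
            results.append(res)
            if res.converged:
                n_converged += 1
                steps_conv.append(res.hebbian_steps_total)
        rows.append({
            "alpha": float(alpha),
            "hebbian_steps": float(np.mean(steps_conv)) if steps_conv else np.nan,
            "converged_fraction": n_converged / config.trials,
            "n_trials": config.trials,
        })
    return pd.DataFrame(rows)
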
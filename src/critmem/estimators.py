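"""Scikit-learn style estimators over the associative-memory machinery.

``AssociativeMemory`` is the fixed-coupling Hopfield-style memory: ``fit``
stores a set of sparse binary patterns in the correlational matrix and
calibrates the retrieval threshold on random single-swap perturbations;
``predict`` performs one synchronous retrieval step on arbitrary binary
cues.

``CriticalMemoryNetwork`` additionally runs the dual optimization during
``fit`` so that the fitted couplings are simultaneously critical (power-law
avalanche statistics) and an associative memory of the training patterns.
Note that ``fit`` runs an event-driven network simulation; with the
full-scale reference parameters this is a long computation — pass
scaled-down episode sizes (``A_ava``, ``A_0``, ``n_p``) for interactive
use.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .config import RunConfig
from .memory import (
    PatternSet,
    assess_retrieval,
    build_memory_matrix,
    overlap,
    retrieve,
)
from .orchestrate import run_dual_optimization


def _as_pattern_set(X: np.ndarray) -> PatternSet:
    X = np.asarray(X)
    if X.ndim != 2 or not np.isin(X, (0, 1)).all():
        raise ValueError("X must be a 2-D binary pattern matrix")
    M, N = X.shape
    counts = X.sum(axis=1)
    if len(set(counts.tolist())) != 1:
        raise ValueError("all patterns must have the same number of active units")
    p = counts[0] / N
    return PatternSet(patterns=X.astype(np.uint8), sparseness=float(p), M=M, N=N)


class AssociativeMemory(BaseEstimator):
    """Correlational (Hopfield-style) memory for sparse binary patterns.

    Parameters
    ----------
    n_perturbations : int
        Single-swap perturbations per pattern used to calibrate the
        retrieval threshold and to report retrieval quality.
    random_state : int or None
        Seed for the perturbation draws.

    Attributes
    ----------
    W_ : ndarray of shape (N, N)
        Correlational memory matrix (symmetric, zero diagonal, sum = N).
    threshold_ : float
        Overlap-maximizing retrieval threshold.
    report_ : RetrievalReport
        Retrieval-quality summary on the calibration perturbations.
    """

    def __init__(self, n_perturbations: int = 100, random_state: int | None = None):
        self.n_perturbations = n_perturbations
        self.random_state = random_state

    def fit(self, X, y=None):
        ps = _as_pattern_set(X)
        rng = np.random.default_rng(self.random_state)
        self.patterns_ = ps
        self.W_ = build_memory_matrix(ps).W
        self.report_ = assess_retrieval(self.W_, ps, self.n_perturbations, rng)
        self.threshold_ = self.report_.threshold_used
        self.n_features_in_ = ps.N
        return self

    def predict(self, X) -> np.ndarray:
        """One-step retrieval of each binary cue row."""
        check_is_fitted(self, "W_")
        X = np.atleast_2d(np.asarray(X))
        return np.stack([retrieve(self.W_, cue, self.threshold_) for cue in X])

    def score(self, X, y=None) -> float:
        """Mean overlap of retrieved states with their best-matching
        stored pattern."""
        check_is_fitted(self, "W_")
        retrieved = self.predict(X)
        scores = []
        for s in retrieved:
            scores.append(
                max(overlap(s, xi) for xi in self.patterns_.patterns)
            )
        return float(np.mean(scores))


class CriticalMemoryNetwork(BaseEstimator):
    """Associative memory driven to criticality by the dual optimization.

    Parameters mirror the run configuration; any keyword accepted by
    :class:`critmem.config.RunConfig` can be overridden through
    ``config_overrides``.

    Attributes
    ----------
    J_ : ndarray of shape (N, N)
        Converged couplings (``u*T`` in dynamical mode).
    converged_ : bool
        Whether the dual loop reached a simultaneously critical and
        associative state.
    delta_gamma_ : float
        Δγ of the final critical episode.
    hebbian_steps_ : int
        Total Hebbian learning steps.
    threshold_ : float
        Retrieval threshold of the final assessment.
    """

    def __init__(self, mode: str = "homeostatic", A_ava: int = 100_000,
                 A_0: int = 1_000, n_p: int = 100, max_rounds: int = 50,
                 random_state: int = 0, config_overrides: dict | None = None):
        self.mode = mode
        self.A_ava = A_ava
        self.A_0 = A_0
        self.n_p = n_p
        self.max_rounds = max_rounds
        self.random_state = random_state
        self.config_overrides = config_overrides

    def fit(self, X, y=None):
        ps = _as_pattern_set(X)
        overrides = dict(self.config_overrides or {})
        cfg = RunConfig(
            N=ps.N, sparseness=ps.sparseness, alpha=ps.M / ps.N,
            mode=self.mode, A_ava=self.A_ava, A_0=self.A_0, n_p=self.n_p,
            max_rounds=self.max_rounds, seed=self.random_state, **overrides,
        )
        result = run_dual_optimization(cfg, patterns=ps)
        self.patterns_ = ps
        self.result_ = result
        self.J_ = result.final_couplings
        self.converged_ = result.converged
        self.delta_gamma_ = result.final_delta_gamma
        self.hebbian_steps_ = result.hebbian_steps_total
        self.report_ = result.final_report
        self.threshold_ = result.final_report.threshold_used
        self.episode_log_ = result.episode_log
        self.n_features_in_ = ps.N
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "J_")
        X = np.atleast_2d(np.asarray(X))
        return np.stack([retrieve(self.J_, cue, self.threshold_) for cue in X])
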
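"""Sparse binary patterns, the correlational memory matrix, one-step
retrieval with an optimized threshold, and retrieval-quality criteria.

Overlap measure
---------------
The overlap between two binary activity vectors is the Pearson-type
correlation

    o(xi, kappa) = (1/N) sum_i (xi_i - m_xi)(kappa_i - m_kappa) / (s_xi s_kappa)

with per-vector means and *population* standard deviations, so that
``o(xi, xi) = 1`` exactly.  For binary vectors the overlap depends only on
the counts (number of active units in each vector and number of shared
active units), which this module exploits for closed-form reference values
and for a fast exact threshold search.

Threshold search
----------------
Retrieval is a single synchronous step ``S_i = [sum_j J_ij kappa_j > Theta]``.
The mean retrieved overlap is piecewise constant in ``Theta`` with
breakpoints at the pooled input-field values, so the global maximum can be
located exactly by sweeping the sorted pooled fields and updating each
cue's overlap incrementally as its retrieved state gains one unit at a
time.  Ties are broken toward the smallest maximizing threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import NormalizationError, UndefinedOverlapError


@dataclass
class PatternSet:
    """M sparse binary patterns of length N, each with exactly round(p*N) ones."""

    patterns: np.ndarray
    sparseness: float
    M: int
    N: int

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=np.uint8)
        if self.patterns.shape != (self.M, self.N):
            raise ValueError(f"patterns must have shape ({self.M}, {self.N})")
        k = int(round(self.sparseness * self.N))
        if np.any(self.patterns.sum(axis=1) != k):
            raise ValueError(f"every pattern must have exactly {k} active units")

    @property
    def n_active(self) -> int:
        return int(round(self.sparseness * self.N))


@dataclass
class MemoryMatrix:
    """Correlational coupling matrix W (symmetric, zero diagonal, sum = N)."""

    W: np.ndarray
    C: float

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)


@dataclass
class RetrievalReport:
    """Summary of a perturbation-retrieval assessment."""

    mean_overlap_retrieved: float
    mean_overlap_perturbed: float
    per_pattern_overlaps: np.ndarray
    fraction_within_digits: dict
    threshold_used: float

    def to_dict(self) -> dict:
        return {
            "mean_overlap_retrieved": float(self.mean_overlap_retrieved),
            "mean_overlap_perturbed": float(self.mean_overlap_perturbed),
            "per_pattern_overlaps": [float(x) for x in self.per_pattern_overlaps],
            "fraction_within_digits": {
                str(k): float(v) for k, v in self.fraction_within_digits.items()
            },
            "threshold_used": float(self.threshold_used),
        }


# --------------------------------------------------------------------------- #
# patterns and memory matrix
# --------------------------------------------------------------------------- #


def generate_patterns(M: int, N: int, p: float, rng: np.random.Generator) -> PatternSet:
    """Draw M independent patterns, each uniform over the k-subsets of N units."""
    if not 0 < p < 1:
        raise ValueError("sparseness p must be in (0, 1)")
    k = int(round(p * N))
    if k < 1 or k >= N:
        raise ValueError(f"degenerate sparseness: round(p*N) = {k} for N = {N}")
    if M < 1:
        raise ValueError("M must be >= 1")
    # argsort of iid uniforms gives a uniform random permutation per row
    idx = np.argsort(rng.random((M, N)), axis=1)[:, :k]
    patterns = np.zeros((M, N), dtype=np.uint8)
    np.put_along_axis(patterns, idx, 1, axis=1)
    return PatternSet(patterns=patterns, sparseness=p, M=M, N=N)


def build_memory_matrix(patterns: PatternSet) -> MemoryMatrix:
    """Correlational matrix W_ij ∝ Σ_η ξ_i ξ_j (i ≠ j), scaled so ΣW = N.

    The scaling constant C is solved so that the normalization holds
    exactly; if no pair of units is co-active in any pattern the raw sum is
    zero and no normalization exists.
    """
    xi = patterns.patterns.astype(np.float64)
    p, N = patterns.sparseness, patterns.N
    raw = (xi.T @ xi) / (p * (1.0 - p) * N)
    np.fill_diagonal(raw, 0.0)
    total = raw.sum()
    if total <= 0.0:
        raise NormalizationError("no co-active unit pairs; memory matrix is zero")
    C = total / N
    return MemoryMatrix(W=raw / C, C=C)


def perturb(pattern: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Swap one random active and one random inactive unit (operator Q)."""
    pattern = np.asarray(pattern)
    active = np.flatnonzero(pattern)
    inactive = np.flatnonzero(pattern == 0)
    if active.size == 0 or inactive.size == 0:
        raise ValueError("pattern must have at least one active and one inactive unit")
    out = pattern.copy()
    out[active[rng.integers(active.size)]] = 0
    out[inactive[rng.integers(inactive.size)]] = 1
    return out


def perturb_many(
    patterns: PatternSet, n_p: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw ``n_p`` single-swap perturbations of every pattern.

    Returns ``(cues, removed, added)`` where ``cues`` has shape
    ``(M * n_p, N)`` (cues of pattern η occupy rows ``η*n_p ... (η+1)*n_p``)
    and ``removed`` / ``added`` give the swapped unit index per cue.
    """
    xi = patterns.patterns
    M, N = patterns.M, patterns.N
    k = patterns.n_active
    removed = np.empty((M, n_p), dtype=np.int64)
    added = np.empty((M, n_p), dtype=np.int64)
    for m in range(M):
        act = np.flatnonzero(xi[m])
        inact = np.flatnonzero(xi[m] == 0)
        removed[m] = act[rng.integers(k, size=n_p)]
        added[m] = inact[rng.integers(N - k, size=n_p)]
    cues = np.repeat(xi, n_p, axis=0)
    rows = np.arange(M * n_p)
    cues[rows, removed.ravel()] = 0
    cues[rows, added.ravel()] = 1
    return cues, removed.ravel(), added.ravel()


# --------------------------------------------------------------------------- #
# overlap
# --------------------------------------------------------------------------- #


def overlap(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson-type correlation of two equal-length binary vectors."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("overlap requires two equal-length vectors")
    sa, sb = a.std(), b.std()  # population standard deviations
    if sa == 0.0 or sb == 0.0:
        raise UndefinedOverlapError("overlap undefined for a constant vector")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def overlap_from_counts(n11: float, a: int, b: int, N: int) -> float:
    """Overlap of binary vectors with ``a`` and ``b`` active units sharing ``n11``."""
    if a in (0, N) or b in (0, N):
        raise UndefinedOverlapError("overlap undefined for a constant vector")
    return (n11 - a * b / N) * N / np.sqrt(a * (N - a) * b * (N - b))


def one_digit_reference_overlap(N: int, k: int) -> float:
    """Expected overlap of a pattern with a version deviating in one digit.

    A one-digit deviation either removes one active unit (k-1 active, k-1
    shared) or adds one (k+1 active, k shared); the reference is the mean
    of the two cases.
    """
    drop = overlap_from_counts(k - 1, k, k - 1, N)
    add = overlap_from_counts(k, k, k + 1, N)
    return 0.5 * (drop + add)


def two_digit_reference_overlap(N: int, k: int) -> float:
    """Overlap of a pattern with a single-swap (two-digit) perturbation."""
    return overlap_from_counts(k - 1, k, k, N)


# --------------------------------------------------------------------------- #
# retrieval
# --------------------------------------------------------------------------- #


def retrieve(J: np.ndarray, cue: np.ndarray, Theta: float) -> np.ndarray:
    """One synchronous retrieval step: S_i = 1 iff the input field exceeds Theta."""
    J = np.asarray(J, dtype=np.float64)
    cue = np.asarray(cue, dtype=np.float64)
    if J.shape[1] != cue.shape[0]:
        raise ValueError("dimension mismatch between J and cue")
    return (J @ cue > Theta).astype(np.uint8)


def _threshold_sweep(
    fields: np.ndarray, xi: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Exact maximization of the mean retrieved overlap over the threshold.

    ``fields[r]`` is the input-field vector of cue instance ``r`` and
    ``xi[r]`` its source pattern.  Returns ``(theta, objective, o_per_cue)``
    where ``objective`` is the maximal mean overlap and ``o_per_cue`` the
    per-cue overlaps at the returned threshold.  A constant retrieved
    state (all-zero or all-one) has undefined correlation and carries no
    pattern information; such cues score overlap 0, so a single weak cue
    cannot force the shared threshold away from the optimum for all
    others.  If no candidate threshold exists at all (e.g. all fields
    identical) an :class:`UndefinedOverlapError` is raised.
    """
    fields = np.asarray(fields, dtype=np.float64)
    xi = np.asarray(xi, dtype=np.uint8)
    R, N = fields.shape
    a = xi.sum(axis=1).astype(np.int64)
    if np.any(a == 0) or np.any(a == N):
        raise UndefinedOverlapError("source patterns must be non-constant")

    # Candidate thresholds are swept over the top-K fields of every cue:
    # any threshold that would activate more than K units in some
    # retrieved state is excluded as non-competitive (K is several times
    # the pattern activity, where the overlap objective of that cue has
    # already decayed far below the retrieval regime).  Small problems are
    # swept in full.
    K = int(min(N, max(4 * a.max(), 120)))

    if K < N:
        top = np.argpartition(-fields, K - 1, axis=1)[:, :K]
        top_fields = np.take_along_axis(fields, top, axis=1)
        inner = np.argsort(-top_fields, axis=1)
        order_within = np.take_along_axis(top, inner, axis=1)
        Fs = np.take_along_axis(top_fields, inner, axis=1)
    else:
        order_within = np.argsort(-fields, axis=1)
        Fs = np.take_along_axis(fields, order_within, axis=1)
    xs = np.take_along_axis(xi, order_within, axis=1)
    n11 = np.cumsum(xs, axis=1, dtype=np.int64)

    # overlap of each cue's retrieved state as it gains its s-th unit
    s = np.arange(1, K + 1, dtype=np.float64)
    af = a[:, None].astype(np.float64)
    denom = np.sqrt(af * (N - af) * s[None, :] * (N - s[None, :]))
    if K == N:
        denom[:, -1] = np.inf  # s = N: constant state, scores 0
    O = (n11 - af * s[None, :] / N) * N / denom

    # per-flip contribution to the summed objective (s = 0 scores 0)
    A = np.empty_like(O)
    A[:, 0] = O[:, 0]
    A[:, 1:] = O[:, 1:] - O[:, :-1]

    flat = Fs.ravel()
    order = np.argsort(-flat, kind="stable")
    v = flat[order]
    cum = np.cumsum(A.ravel()[order])

    # candidates end where the first cue runs past its K-th field (beyond
    # that its incremental overlap would be stale); with a full sweep the
    # s = N transition is already scored as 0
    if K < N:
        col = order % K
        k_max = int(np.flatnonzero(col == K - 1)[0])  # exclusive
    else:
        k_max = R * K - 1

    # Candidate boundaries must separate genuinely distinct field values:
    # fields that are conceptually equal (the same sum accumulated in a
    # different order) differ by a few ulps, and a "threshold" between
    # them is not realizable — treating them as separable inflates the
    # objective with physically meaningless splits of tied groups.
    tol = 1e-9 * max(1.0, float(np.abs(v[0])))
    g = np.arange(R * K - 1)
    valid = (g < k_max) & (v[:-1] - v[1:] > tol)
    if not np.any(valid):
        raise UndefinedOverlapError("no admissible retrieval threshold")

    objective = np.where(valid, cum[:-1], -np.inf)
    best = objective.max()
    # smallest maximizing theta == last index attaining the maximum
    g_star = int(np.flatnonzero(objective == best)[-1])
    theta = 0.5 * (v[g_star] + v[g_star + 1])

    s_at = (fields > theta).sum(axis=1)
    o_per_cue = np.zeros(R)
    hit = (s_at > 0) & (s_at < N)
    o_per_cue[hit] = O[np.flatnonzero(hit), s_at[hit] - 1]
    return float(theta), float(best / R), o_per_cue


def optimal_threshold(
    J: np.ndarray,
    patterns: PatternSet,
    cues: np.ndarray,
    pattern_index: np.ndarray | None = None,
) -> float:
    """Threshold maximizing the mean overlap of retrieved states with their
    source patterns, searched exactly over the pooled field breakpoints.

    ``pattern_index[r]`` maps cue ``r`` to its source pattern; by default
    cue ``r`` belongs to pattern ``r % M``.
    """
    J = np.asarray(J, dtype=np.float64)
    cues = np.atleast_2d(np.asarray(cues))
    if cues.shape[0] < 1:
        raise ValueError("at least one cue is required")
    if pattern_index is None:
        pattern_index = np.arange(cues.shape[0]) % patterns.M
    fields = cues.astype(np.float64) @ J.T
    xi = patterns.patterns[np.asarray(pattern_index)]
    theta, _, _ = _threshold_sweep(fields, xi)
    return theta


def assess_retrieval(
    J: np.ndarray,
    patterns: PatternSet,
    n_p: int,
    rng: np.random.Generator,
) -> RetrievalReport:
    """Retrieve ``n_p`` single-swap perturbations of every pattern with the
    overlap-maximizing threshold and summarize the retrieval quality."""
    if n_p < 1:
        raise ValueError("n_p must be >= 1")
    J = np.asarray(J, dtype=np.float64)
    M, N, k = patterns.M, patterns.N, patterns.n_active
    _, removed, added = perturb_many(patterns, n_p, rng)

    base = patterns.patterns.astype(np.float64) @ J.T   # (M, N)
    fields = np.repeat(base, n_p, axis=0)
    fields -= J[:, removed].T
    fields += J[:, added].T
    xi = np.repeat(patterns.patterns, n_p, axis=0)

    theta, _, o_per_cue = _threshold_sweep(fields, xi)
    per_pattern = o_per_cue.reshape(M, n_p).mean(axis=1)
    perturbed = two_digit_reference_overlap(N, k)  # Q always swaps one pair

    one_digit = one_digit_reference_overlap(N, k)
    fractions = {
        1: float(np.mean(per_pattern > one_digit)),
        2: float(np.mean(per_pattern > perturbed)),
    }
    return RetrievalReport(
        mean_overlap_retrieved=float(per_pattern.mean()),
        mean_overlap_perturbed=float(perturbed),
        per_pattern_overlaps=per_pattern,
        fraction_within_digits=fractions,
        threshold_used=theta,
    )


def improvement_criterion(report: RetrievalReport, Delta: float) -> bool:
    """True iff retrieval improves on the perturbed cues by more than Delta."""
    return bool(report.mean_overlap_retrieved - report.mean_overlap_perturbed > Delta)
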
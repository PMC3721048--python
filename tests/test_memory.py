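"""Patterns, memory matrix, overlap measure, retrieval and its criteria."""

import numpy as np
import pytest

from critmem.errors import NormalizationError, UndefinedOverlapError
from critmem.memory import (
    PatternSet,
    RetrievalReport,
    _threshold_sweep,
    assess_retrieval,
    build_memory_matrix,
    generate_patterns,
    improvement_criterion,
    one_digit_reference_overlap,
    optimal_threshold,
    overlap,
    overlap_from_counts,
    perturb,
    perturb_many,
    retrieve,
    two_digit_reference_overlap,
)


class TestGeneratePatterns:
    def test_reference_setting(self, rng):
        ps = generate_patterns(30, 300, 0.1, rng)
        assert ps.patterns.shape == (30, 300)
        assert np.all(ps.patterns.sum(axis=1) == 30)

    def test_single_pattern(self, rng):
        ps = generate_patterns(1, 10, 0.5, rng)
        assert ps.patterns.sum() == 5

    @pytest.mark.parametrize("p", [0.001, 0.999])
    def test_degenerate_sparseness_rejected(self, p, rng):
        with pytest.raises(ValueError):
            generate_patterns(3, 10, p, rng)

    def test_independent_patterns_uncorrelated(self, rng):
        """Mean pairwise overlap of independent patterns is ~0."""
        ps = generate_patterns(2000, 300, 0.1, rng)
        a, b = ps.patterns[::2].astype(float), ps.patterns[1::2].astype(float)
        n11 = (a * b).sum(axis=1)
        o = (n11 - 3.0) * 300 / (30 * 270)  # overlap_from_counts, a=b=30
        assert abs(o.mean()) < 0.01


class TestMemoryMatrix:
    def test_normalization_sums_to_n(self, rng):
        for M, N in [(3, 50), (30, 300)]:
            ps = generate_patterns(M, N, 0.1, rng)
            Wm = build_memory_matrix(ps)
            assert Wm.W.sum() == pytest.approx(N, rel=1e-9)

    def test_hand_solved_single_pattern(self):
        ps = PatternSet(np.array([[1, 1, 0, 0]], dtype=np.uint8), 0.5, 1, 4)
        Wm = build_memory_matrix(ps)
        expected = np.zeros((4, 4))
        expected[0, 1] = expected[1, 0] = 2.0
        np.testing.assert_allclose(Wm.W, expected)

    def test_symmetric_zero_diagonal(self, rng):
        ps = generate_patterns(10, 60, 0.1, rng)
        W = build_memory_matrix(ps).W
        np.testing.assert_allclose(W, W.T)
        assert np.all(np.diag(W) == 0)

    def test_no_coactive_pairs_raises(self):
        # single active unit per pattern -> no co-active pairs anywhere
        ps = PatternSet(np.eye(8, dtype=np.uint8)[:3], 1 / 8, 3, 8)
        with pytest.raises(NormalizationError):
            build_memory_matrix(ps)


class TestPerturb:
    def test_two_unit_pattern_swaps(self):
        out = perturb(np.array([1, 0], dtype=np.uint8), np.random.default_rng(0))
        np.testing.assert_array_equal(out, [0, 1])

    def test_hamming_distance_exactly_two(self, rng):
        ps = generate_patterns(1, 300, 0.1, rng)
        kappa = perturb(ps.patterns[0], rng)
        assert (kappa != ps.patterns[0]).sum() == 2
        assert kappa.sum() == 30

    def test_constant_pattern_rejected(self, rng):
        with pytest.raises(ValueError):
            perturb(np.ones(5, dtype=np.uint8), rng)

    def test_swap_overlap_is_26_over_27(self, rng):
        ps = generate_patterns(1, 300, 0.1, rng)
        kappa = perturb(ps.patterns[0], rng)
        assert overlap(ps.patterns[0], kappa) == pytest.approx(26 / 27, abs=1e-12)

    def test_perturb_many_layout(self, rng):
        ps = generate_patterns(4, 50, 0.2, rng)
        cues, removed, added = perturb_many(ps, 7, rng)
        assert cues.shape == (28, 50)
        assert np.all(cues.sum(axis=1) == 10)
        xi = np.repeat(ps.patterns, 7, axis=0)
        assert np.all((xi != cues).sum(axis=1) == 2)


class TestOverlap:
    def test_identical_is_one(self, rng):
        ps = generate_patterns(1, 40, 0.25, rng)
        assert overlap(ps.patterns[0], ps.patterns[0]) == pytest.approx(1.0, abs=1e-15)

    def test_complement_is_minus_one(self):
        a = np.array([1, 1, 0, 0])
        assert overlap(a, 1 - a) == pytest.approx(-1.0, abs=1e-15)

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedOverlapError):
            overlap(np.ones(4), np.array([1, 0, 1, 0]))

    def test_one_digit_reference_rounds_to_0982(self):
        assert round(one_digit_reference_overlap(300, 30), 3) == 0.982

    def test_one_digit_reference_matches_brute_force(self, rng):
        """Average the overlap over all single-digit changes of one pattern
        (independent enumeration oracle for the closed form)."""
        ps = generate_patterns(1, 300, 0.1, rng)
        xi = ps.patterns[0]
        drops = [overlap(xi, _flip(xi, i)) for i in np.flatnonzero(xi)]
        adds = [overlap(xi, _flip(xi, i)) for i in np.flatnonzero(xi == 0)]
        brute = 0.5 * (np.mean(drops) + np.mean(adds))
        assert one_digit_reference_overlap(300, 30) == pytest.approx(brute, abs=1e-12)

    def test_two_digit_reference_value(self):
        assert two_digit_reference_overlap(300, 30) == pytest.approx(26 / 27, abs=1e-15)

    def test_counts_formula_matches_direct(self, rng):
        for _ in range(20):
            a = (rng.random(50) < 0.3).astype(np.uint8)
            b = (rng.random(50) < 0.5).astype(np.uint8)
            if a.std() == 0 or b.std() == 0:
                continue
            via_counts = overlap_from_counts(
                int((a & b).sum()), int(a.sum()), int(b.sum()), 50
            )
            assert via_counts == pytest.approx(overlap(a, b), abs=1e-12)

    def test_symmetry_and_bounds(self, rng):
        for _ in range(20):
            a = (rng.random(30) < 0.4).astype(float)
            b = (rng.random(30) < 0.4).astype(float)
            if a.std() == 0 or b.std() == 0:
                continue
            assert overlap(a, b) == pytest.approx(overlap(b, a), abs=1e-14)
            assert -1 - 1e-12 <= overlap(a, b) <= 1 + 1e-12

    def test_permutation_invariance(self, rng):
        a = (rng.random(40) < 0.3).astype(float)
        b = (rng.random(40) < 0.3).astype(float)
        perm = rng.permutation(40)
        assert overlap(a, b) == pytest.approx(overlap(a[perm], b[perm]), abs=1e-14)


def _flip(xi, i):
    out = xi.copy()
    out[i] = 1 - out[i]
    return out


class TestRetrieve:
    def test_threshold_above_all_fields(self, rng):
        J = rng.random((10, 10))
        cue = (rng.random(10) < 0.5).astype(np.uint8)
        assert retrieve(J, cue, 1e9).sum() == 0

    def test_threshold_below_all_fields(self, rng):
        J = rng.random((10, 10)) + 0.1
        cue = np.ones(10, dtype=np.uint8)
        assert retrieve(J, cue, -1.0).sum() == 10

    def test_single_stored_pattern_retrieved_exactly(self, rng):
        """With one stored pattern, active units receive strictly larger
        fields, so a threshold in the gap reconstructs the pattern."""
        ps = generate_patterns(1, 60, 0.2, rng)
        W = build_memory_matrix(ps).W
        xi = ps.patterns[0]
        fields = W @ xi
        theta = 0.5 * (fields[xi == 1].min() + fields[xi == 0].max())
        np.testing.assert_array_equal(retrieve(W, xi, theta), xi)


class TestOptimalThreshold:
    def test_single_pattern_reaches_overlap_one(self, rng):
        ps = generate_patterns(1, 60, 0.2, rng)
        W = build_memory_matrix(ps).W
        theta = optimal_threshold(W, ps, ps.patterns)
        np.testing.assert_array_equal(retrieve(W, ps.patterns[0], theta),
                                      ps.patterns[0])

    def test_matches_brute_force_midpoint_search(self, rng):
        """Exact sweep equals exhaustive evaluation at every pooled-field
        midpoint on small random instances."""
        for trial in range(5):
            M, N = 3, 20
            ps = generate_patterns(M, N, 0.25, rng)
            J = rng.random((N, N))
            cues, _, _ = perturb_many(ps, 2, rng)
            idx = np.repeat(np.arange(M), 2)
            fields = cues.astype(float) @ J.T
            xi = ps.patterns[idx]
            theta, best, _ = _threshold_sweep(fields, xi)
            # brute force over midpoints of consecutive distinct pooled values
            vals = np.unique(fields.ravel())
            brute_best, brute_theta = -np.inf, None
            for t in 0.5 * (vals[1:] + vals[:-1]):
                objs = []
                for r in range(len(cues)):
                    s = retrieve(J, cues[r], t)
                    # constant retrieved states carry no information
                    objs.append(0.0 if s.std() == 0 else overlap(s, xi[r]))
                if np.mean(objs) > brute_best + 1e-12:
                    brute_best, brute_theta = np.mean(objs), t
            assert best == pytest.approx(brute_best, abs=1e-10)
            assert theta == pytest.approx(brute_theta, abs=1e-10)

    def test_objective_beats_random_probes(self, rng):
        M, N = 4, 40
        ps = generate_patterns(M, N, 0.2, rng)
        W = build_memory_matrix(ps).W
        cues, _, _ = perturb_many(ps, 3, rng)
        idx = np.repeat(np.arange(M), 3)
        fields = cues.astype(float) @ W.T
        theta, best, _ = _threshold_sweep(fields, ps.patterns[idx])
        lo, hi = fields.min(), fields.max()
        for t in rng.uniform(lo, hi, size=100):
            objs = []
            for r in range(len(cues)):
                s = retrieve(W, cues[r], t)
                objs.append(0.0 if s.std() == 0
                            else overlap(s, ps.patterns[idx[r]]))
            assert best >= np.mean(objs) - 1e-10

    def test_degenerate_couplings_raise(self, rng):
        ps = generate_patterns(2, 30, 0.2, rng)
        with pytest.raises(UndefinedOverlapError):
            optimal_threshold(np.zeros((30, 30)), ps, ps.patterns)


class TestAssessRetrieval:
    def test_low_load_retrieval_beats_perturbation(self, rng):
        """Pure memory network at small load: the single swapped pair is
        corrected almost always."""
        ps = generate_patterns(15, 300, 0.1, rng)  # alpha = 0.05
        W = build_memory_matrix(ps).W
        report = assess_retrieval(W, ps, 200, rng)
        assert report.mean_overlap_retrieved > report.mean_overlap_perturbed
        assert report.mean_overlap_retrieved > 0.99

    def test_perturbed_baseline_constant(self, rng):
        ps = generate_patterns(5, 300, 0.1, rng)
        W = build_memory_matrix(ps).W
        report = assess_retrieval(W, ps, 20, rng)
        assert report.mean_overlap_perturbed == pytest.approx(26 / 27, abs=1e-12)

    def test_zero_couplings_raise(self, rng):
        ps = generate_patterns(3, 50, 0.2, rng)
        with pytest.raises(UndefinedOverlapError):
            assess_retrieval(np.zeros((50, 50)), ps, 5, rng)

    def test_fraction_ordering(self, rng):
        ps = generate_patterns(10, 300, 0.1, rng)
        W = build_memory_matrix(ps).W
        report = assess_retrieval(W, ps, 50, rng)
        assert 0 <= report.fraction_within_digits[1] <= report.fraction_within_digits[2] <= 1

    def test_small_load_corrects_single_swaps(self, rng):
        """At alpha = 0.01 nearly every perturbation is mapped back."""
        ps = generate_patterns(3, 300, 0.1, rng)
        W = build_memory_matrix(ps).W
        report = assess_retrieval(W, ps, 300, rng)
        frac_perfect = np.mean(report.per_pattern_overlaps > 0.9999)
        assert report.mean_overlap_retrieved > 0.995
        assert frac_perfect >= 0.95

    def test_capacity_decay_monotone(self, rng):
        """Retrieval quality degrades monotonically with load."""
        means = []
        for alpha in (0.05, 0.12, 0.2):
            vals = []
            for trial in range(3):
                trng = np.random.default_rng([trial, int(alpha * 100)])
                ps = generate_patterns(round(alpha * 300), 300, 0.1, trng)
                W = build_memory_matrix(ps).W
                vals.append(assess_retrieval(W, ps, 50, trng).mean_overlap_retrieved)
            means.append(np.mean(vals))
        assert means[0] >= means[1] >= means[2]


class TestImprovementCriterion:
    @pytest.mark.parametrize(
        "retrieved,perturbed,delta,expected",
        [
            (0.99, 0.963, 0.03, False),   # 0.027 improvement falls short
            (0.999, 0.963, 0.035, True),  # 0.036 beats the Hebbian margin
            (0.8, 0.8, 0.0, False),       # strict inequality
        ],
    )
    def test_direct_arithmetic(self, retrieved, perturbed, delta, expected):
        report = RetrievalReport(retrieved, perturbed, np.array([retrieved]),
                                 {1: 0.0, 2: 0.0}, 0.0)
        assert improvement_criterion(report, delta) is expected
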
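import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import affbound as ab
from affbound import boundary, core_io


def _aff_with_ranks(probs, ranks, sizes=None):
    probs = np.asarray(probs, dtype=float)
    O, A = probs.shape
    if sizes is None:
        sizes = [20.0 * (i + 1) for i in range(O)]
    objects = [ab.ObjectItem(f"o{i}", sizes[i], ranks[i]) for i in range(O)]
    actions = [ab.ActionItem(f"a{i}",
                             "manipulation" if i % 2 == 0 else "whole_body")
               for i in range(A)]
    return ab.AffordanceMatrix(objects, actions, probs, n_participants=10)


def _curve(r_values, first_rank=2, n_actions=14):
    r = np.asarray(r_values, dtype=float)
    pairs = tuple((first_rank + i, first_rank + i + 1) for i in range(len(r)))
    se = np.sqrt(np.clip(1 - r ** 2, 0, None) / (n_actions - 2))
    return ab.RankCurve(pairs=pairs, r=r, se=se, n_actions=n_actions)


class TestRankMeans:
    def test_hand_computed_average(self):
        X = np.array([[0.2, 0.4, 0.6], [0.4, 0.8, 0.0], [1.0, 0.5, 0.3]])
        means = ab.rank_mean_vectors(_aff_with_ranks(X, [2, 2, 3]))
        np.testing.assert_allclose(means.vector_for(2),
                                   [0.3, 0.6, 0.3], atol=1e-12)
        np.testing.assert_allclose(means.vector_for(3), X[2], atol=1e-12)

    def test_singleton_rank_identity(self):
        X = np.array([[0.1, 0.9, 0.5], [0.7, 0.2, 0.8]])
        means = ab.rank_mean_vectors(_aff_with_ranks(X, [4, 5]))
        np.testing.assert_array_equal(means.vector_for(4), X[0])

    def test_duplicate_objects_idempotent(self):
        X = np.array([[0.1, 0.9, 0.5], [0.1, 0.9, 0.5]])
        means = ab.rank_mean_vectors(_aff_with_ranks(X, [4, 4]))
        np.testing.assert_allclose(means.vector_for(4), X[0], atol=1e-12)

    def test_rank_gap_is_coverage_error(self):
        X = np.random.default_rng(0).random((2, 3))
        with pytest.raises(core_io.CoverageError, match="rank 4"):
            ab.rank_mean_vectors(_aff_with_ranks(X, [3, 5]))


class TestNeighborCurve:
    def test_identical_means_give_unit_curve(self):
        v = np.array([0.1, 0.4, 0.9, 0.2])
        means = boundary.RankMeans(np.arange(2, 6),
                                   np.tile(v, (4, 1)))
        curve = ab.neighbor_similarity_curve(means)
        np.testing.assert_allclose(curve.r, 1.0, atol=1e-12)

    def test_reflection_alternates_minus_one(self):
        v = np.array([0.1, 0.4, 0.9, 0.2])
        vectors = np.array([v, 1.0 - v, v, 1.0 - v])
        curve = ab.neighbor_similarity_curve(
            boundary.RankMeans(np.arange(2, 6), vectors))
        np.testing.assert_allclose(curve.r, -1.0, atol=1e-12)

    def test_se_closed_form(self):
        # se = sqrt((1 - r^2)/(n - 2)); at r=0, n=14: sqrt(1/12)
        from affbound.stats import correlation_se
        assert correlation_se(0.0, 14) == pytest.approx(
            np.sqrt(1 / 12), abs=1e-12)
        curve = _curve([0.5, -0.2, 0.9])
        np.testing.assert_allclose(
            curve.se, np.sqrt((1 - curve.r ** 2) / 12), atol=1e-12)

    def test_constant_rank_mean_masked_with_warning(self):
        vectors = np.array([[0.1, 0.4, 0.9, 0.2],
                            [0.5, 0.5, 0.5, 0.5],
                            [0.3, 0.1, 0.8, 0.6]])
        with pytest.warns(UserWarning, match="constant"):
            curve = ab.neighbor_similarity_curve(
                boundary.RankMeans(np.arange(2, 5), vectors))
        assert np.isnan(curve.r).all()


class TestTroughValue:
    def test_direct_arithmetic(self):
        curve = _curve([0.46, 0.02, 0.52])
        assert ab.trough_value(curve, (3, 4)) == pytest.approx(0.47, abs=1e-12)

    def test_flat_curve_zero(self):
        assert ab.trough_value(_curve([0.5, 0.5, 0.5]), (3, 4)) == 0.0

    def test_peak_gives_negative_value(self):
        assert ab.trough_value(_curve([0.1, 0.9, 0.2]), (3, 4)) < 0

    def test_no_banks_error(self):
        with pytest.raises(core_io.InsufficientDataError):
            ab.trough_value(_curve([0.1, 0.9, 0.2]), (2, 3))

    @given(scale=st.floats(-3, 3), shift=st.floats(-1, 1))
    def test_linearity_in_curve(self, scale, shift):
        base = np.array([0.8, 0.1, 0.7, 0.6])
        t0 = ab.trough_value(_curve(base), (3, 4))
        t1 = ab.trough_value(_curve(base * scale + shift), (3, 4))
        assert t1 == pytest.approx(scale * t0, abs=1e-9)


class TestDetectTrough:
    def test_unique_dip(self):
        # deepest dip is the second point (pair 3-4)
        site = ab.detect_trough(_curve([0.8, 0.1, 0.7, 0.75, 0.8, 0.78]))
        assert site == (3, 4)

    def test_tie_breaks_to_smaller_rank(self):
        site = ab.detect_trough(_curve([0.8, 0.1, 0.8, 0.1, 0.8]))
        assert site == (3, 4)

    def test_too_short_curve(self):
        with pytest.raises(core_io.InsufficientDataError):
            ab.detect_trough(_curve([0.5, 0.6]))

    def test_recovers_generative_boundary(self, human_aff):
        curve = ab.neighbor_similarity_curve(ab.rank_mean_vectors(human_aff))
        assert ab.detect_trough(curve) == (4, 5)


class TestPermutationP:
    def test_counting_formula(self):
        assert ab.permutation_p(0.5, [0.1, 0.2, 0.6, 0.5, 0.3]) == \
            pytest.approx(0.4)

    def test_extreme_observation_gives_zero(self):
        assert ab.permutation_p(0.9, [0.1, 0.2, 0.3]) == 0.0

    def test_smoothed_variant(self):
        assert ab.permutation_p(0.9, [0.1, 0.2, 0.3], smoothed=True) == \
            pytest.approx(1 / 4)


def _brute_force_null(probs, ranks, site):
    """Independent enumeration oracle: every distinct object->rank
    assignment, rank means via plain loops, correlations via np.corrcoef."""
    ranks = np.asarray(ranks)
    uniq = sorted(set(ranks.tolist()))
    seen, t_values = set(), []
    for perm in itertools.permutations(range(len(ranks))):
        labels = tuple(ranks[list(perm)])
        if labels in seen:
            continue
        seen.add(labels)
        means = {r: probs[[i for i, l in enumerate(labels) if l == r]].mean(0)
                 for r in uniq}
        rs = [np.corrcoef(means[a], means[b])[0, 1]
              for a, b in zip(uniq[:-1], uniq[1:])]
        k = uniq.index(site[0])
        t_values.append((rs[k - 1] + rs[k + 1]) / 2 - rs[k])
    return np.array(t_values)


class TestPermutationTest:
    def test_exhaustive_matches_brute_force(self):
        rng = np.random.default_rng(7)
        ranks = [2, 2, 3, 4, 5, 5]
        probs = rng.random((6, 5))
        aff = _aff_with_ranks(probs, ranks)
        res = ab.permutation_test_trough(aff, site=(3, 4), exhaustive=True)
        oracle_t = _brute_force_null(probs, ranks, (3, 4))
        assert res.n_permutations == len(oracle_t) == 180
        np.testing.assert_allclose(np.sort(res.null_values),
                                   np.sort(oracle_t), atol=1e-12)
        oracle_p = np.mean(oracle_t >= res.t_obs)
        assert res.p_value == pytest.approx(oracle_p, abs=1e-12)

    def test_exhaustive_invariant_to_object_relabeling(self):
        rng = np.random.default_rng(8)
        ranks = np.array([2, 2, 3, 4, 5, 5])
        probs = rng.random((6, 5))
        perm = rng.permutation(6)
        a = ab.permutation_test_trough(
            _aff_with_ranks(probs, ranks), site=(3, 4), exhaustive=True)
        b = ab.permutation_test_trough(
            _aff_with_ranks(probs[perm], ranks[perm]), site=(3, 4),
            exhaustive=True)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)
        assert a.t_obs == pytest.approx(b.t_obs, abs=1e-12)

    def test_sampled_null_approximates_exhaustive(self):
        rng = np.random.default_rng(9)
        ranks = [2, 2, 3, 4, 5, 5]
        probs = rng.random((6, 5))
        aff = _aff_with_ranks(probs, ranks)
        exact = ab.permutation_test_trough(aff, site=(3, 4), exhaustive=True)
        sampled = ab.permutation_test_trough(
            aff, site=(3, 4),
            config=ab.AnalysisConfig(n_permutations=4000, seed=0))
        assert sampled.p_value == pytest.approx(exact.p_value, abs=0.05)

    def test_deterministic_given_seed(self, human_aff):
        cfg = ab.AnalysisConfig(n_permutations=200, seed=3)
        a = ab.permutation_test_trough(human_aff, site=(4, 5), config=cfg)
        b = ab.permutation_test_trough(human_aff, site=(4, 5), config=cfg)
        np.testing.assert_array_equal(a.null_values, b.null_values)
        assert a.p_value == b.p_value

    def test_action_permutation_mode_runs(self, human_aff):
        cfg = ab.AnalysisConfig(n_permutations=100, seed=3, permute="actions")
        res = ab.permutation_test_trough(human_aff, site=(4, 5), config=cfg)
        assert 0 <= res.p_value <= 1
        assert res.n_permutations == 100


class TestCompareNeighborCorrelations:
    def test_equal_correlations_give_zero_z(self):
        # m_j and m_h differ but correlate equally with the shared m_k:
        # both are m_k plus equal-norm components orthogonal to it
        m_k = np.array([1.0, 2.0, 3.0, 4.0])
        u1 = np.array([1.0, -1.0, -1.0, 1.0])
        u2 = np.array([-1.0, 3.0, -3.0, 1.0]) / np.sqrt(5.0)
        means = boundary.RankMeans(np.arange(3, 6),
                                   np.array([m_k + u1, m_k, m_k + u2]))
        cmp = ab.compare_neighbor_correlations(means, (3, 4), (4, 5))
        assert cmp.r_a == pytest.approx(cmp.r_b, abs=1e-12)
        assert cmp.z == pytest.approx(0.0, abs=1e-10)
        assert cmp.p_one_tailed == pytest.approx(0.5, abs=1e-10)
        lo, hi = cmp.zou_interval
        assert lo < 0 < hi

    def test_pairs_must_share_middle_rank(self):
        rng = np.random.default_rng(0)
        means = boundary.RankMeans(np.arange(2, 6), rng.random((4, 8)))
        with pytest.raises(ValueError, match="share"):
            ab.compare_neighbor_correlations(means, (2, 3), (4, 5))

    def test_trough_contrast_is_significant_on_synthetic_run(self, human_aff):
        means = ab.rank_mean_vectors(human_aff)
        cmp = ab.compare_neighbor_correlations(means, (3, 4), (4, 5))
        assert cmp.r_a > cmp.r_b
        assert cmp.z > 0 and cmp.p_one_tailed < 0.05
        assert cmp.bf10 > 10


class TestPairScan:
    def test_two_objects_same_rank_single_record(self):
        X = np.random.default_rng(1).random((2, 6))
        scan = ab.pairwise_boundary_scan(
            _aff_with_ranks(X, [4, 4], sizes=[70.0, 90.0]),
            rank_window=(3, 6))
        assert len(scan.pairs) == 1
        rec = scan.pairs.iloc[0]
        assert (rec["rank_a"], rec["rank_b"]) == (4, 4)
        assert rec["mean_size_cm"] == pytest.approx(80.0)

    def test_composition_list_and_counts(self, human_aff):
        scan = ab.pairwise_boundary_scan(human_aff, rank_window=(3, 6))
        comps = list(zip(scan.compositions["rank_a"],
                         scan.compositions["rank_b"]))
        assert comps == [(3, 3), (3, 4), (4, 4), (4, 5), (5, 5), (5, 6),
                         (6, 6)]
        # closed-form pair count: within-rank C(m,2) + adjacent m_i*m_{i+1}
        m = {r: sum(o.rank == r for o in human_aff.objects
                    if 3 <= o.rank <= 6) for r in range(3, 7)}
        expected = sum(v * (v - 1) // 2 for v in m.values()) + \
            sum(m[r] * m[r + 1] for r in range(3, 6))
        assert len(scan.pairs) == expected
        assert scan.compositions["n_pairs"].sum() == expected

    def test_minimum_composition_straddles_boundary(self, human_aff):
        scan = ab.pairwise_boundary_scan(human_aff, rank_window=(3, 6))
        assert scan.boundary_composition == (4, 5)
        # within one octave bin of the 150 cm generative boundary
        assert 64 <= scan.boundary_estimate_cm <= 256
        lo, hi = scan.boundary_ci_cm
        assert lo <= scan.boundary_estimate_cm <= hi

    def test_sparse_composition_keeps_record_with_masked_ci(self):
        X = np.random.default_rng(2).random((3, 6))
        scan = ab.pairwise_boundary_scan(
            _aff_with_ranks(X, [4, 4, 5], sizes=[70.0, 90.0, 160.0]),
            rank_window=(3, 6))
        comp45 = scan.compositions.query("rank_a == 4 and rank_b == 5")
        assert len(comp45) == 1
        assert np.isnan(comp45["size_ci_lo"]).all() or \
            comp45["n_pairs"].iloc[0] >= 2
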
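import numpy as np
import pytest
from scipy import stats

from oracles import optimal_assignment_total
from hetspan import matching as mt
from hetspan import synthetic_data as sd
from hetspan.io_formats import GenotypeMatrix


def _pca_from_scores(scores, weights, ids):
    scores = np.asarray(scores, dtype=float)
    return mt.PcaResult(scores=scores, var_explained=np.asarray(weights),
                        k=scores.shape[1], sample_ids=list(ids))


class TestMatchDistance:
    def test_identity_gives_zero(self):
        a = np.arange(6.0)
        assert mt.match_distance(a, a, np.full(6, 0.1)) == 0.0

    def test_single_component_difference(self):
        a = np.zeros(6)
        b = np.zeros(6)
        b[0] = -1.0
        w = np.array([0.1, 0.05, 0.04, 0.03, 0.02, 0.01])
        assert mt.match_distance(a, b, w) == pytest.approx(0.1)

    def test_matches_hand_computed_weighted_l1(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=8)
        w = rng.uniform(0, 1, 8)
        want = sum(abs(a[j] - b[j]) * w[j] for j in range(6))
        assert mt.match_distance(a, b, w) == pytest.approx(want)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            mt.match_distance(np.zeros(3), np.zeros(6), np.ones(6))


class TestGreedyMatch:
    def test_identical_cohorts_pair_at_zero_distance(self, rng):
        scores = rng.normal(size=(5, 6))
        perm = rng.permutation(5)
        pca = _pca_from_scores(
            np.vstack([scores, scores[perm]]), np.full(6, 1 / 6.0),
            [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)])
        pairs = mt.greedy_match(pca, [f"a{i}" for i in range(5)],
                                [f"b{i}" for i in range(5)], seed=0)
        assert pairs.total_distance == pytest.approx(0.0)
        assert all(d == 0 for _, _, d in pairs.pairs)

    def test_single_sample_takes_global_nearest(self, rng):
        scores = np.array([[0.0] * 6, [1.0] * 6, [0.2] * 6, [3.0] * 6])
        pca = _pca_from_scores(scores, np.full(6, 1 / 6.0), ["a0", "b0", "b1", "b2"])
        for seed in range(3):
            pairs = mt.greedy_match(pca, ["a0"], ["b0", "b1", "b2"], seed=seed)
            assert pairs.pairs[0][1] == "b1"

    def test_greedy_total_bounded_below_by_optimal(self, rng):
        for _ in range(10):
            scores = rng.normal(size=(12, 6))
            ids = [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)]
            w = np.sort(rng.uniform(0, 1, 6))[::-1]
            pca = _pca_from_scores(scores, w, ids)
            pairs = mt.greedy_match(pca, ids[:6], ids[6:], n_restarts=3, seed=1)
            dist = [[mt.match_distance(scores[i], scores[6 + j], w)
                     for j in range(6)] for i in range(6)]
            assert pairs.total_distance >= optimal_assignment_total(dist) - 1e-9

    def test_deterministic_and_monotone_in_restarts(self, rng):
        scores = rng.normal(size=(40, 6))
        ids = [f"a{i}" for i in range(15)] + [f"b{i}" for i in range(25)]
        pca = _pca_from_scores(scores, np.full(6, 1 / 6.0), ids)
        one = mt.greedy_match(pca, ids[:15], ids[15:], n_restarts=5, seed=9)
        two = mt.greedy_match(pca, ids[:15], ids[15:], n_restarts=5, seed=9)
        assert one.pairs == two.pairs
        totals = [mt.greedy_match(pca, ids[:15], ids[15:], n_restarts=r,
                                  seed=9).total_distance for r in (1, 3, 5, 10)]
        assert all(t2 <= t1 + 1e-12 for t1, t2 in zip(totals, totals[1:]))

    def test_larger_first_cohort_rejected(self, rng):
        scores = rng.normal(size=(3, 6))
        pca = _pca_from_scores(scores, np.full(6, 1 / 6.0), ["a0", "a1", "b0"])
        with pytest.raises(ValueError):
            mt.greedy_match(pca, ["a0", "a1"], ["b0"])


def test_filter_pairs_threshold_behaviour():
    pairs = mt.MatchedPairs([("a0", "b0", 1.0), ("a1", "b1", 5.0),
                             ("a2", "b2", 2.0)], 8.0)
    assert len(mt.filter_pairs(pairs, 0.5)) == 0
    assert mt.filter_pairs(pairs, np.inf).pairs == pairs.pairs
    kept = mt.filter_pairs(pairs, 2.0)
    assert len(kept) == 2 and kept.total_distance == pytest.approx(3.0)


class TestGenomicInflation:
    def test_definition_and_linearity(self):
        stats_at_median = np.full(11, mt.CHI2_1DF_MEDIAN)
        assert mt.genomic_inflation(stats_at_median).lambda_gc == pytest.approx(1.0)
        assert mt.genomic_inflation(2 * stats_at_median).lambda_gc == pytest.approx(2.0)

    def test_monte_carlo_null_is_one(self, rng):
        draws = rng.chisquare(1, size=100_000)
        assert mt.genomic_inflation(draws).lambda_gc == pytest.approx(1.0, abs=0.02)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mt.genomic_inflation([])


class TestRunPca:
    def test_identical_samples_get_identical_scores(self, rng):
        base = rng.integers(0, 3, size=(10, 50)).astype(np.int8)
        base[0] = base[1]
        genos = GenotypeMatrix(base, [f"s{i}" for i in range(10)],
                               np.array(["A"] * 10, dtype=object),
                               [f"m{j}" for j in range(50)])
        res = mt.run_pca(genos, k=3)
        assert np.allclose(res.scores[0], res.scores[1])

    def test_rank_one_data_concentrates_variance(self):
        col = np.array([0, 0, 1, 1, 2, 2], dtype=np.int8)
        dosage = np.stack([col, 2 - col, col], axis=1)
        genos = GenotypeMatrix(dosage, [f"s{i}" for i in range(6)],
                               np.array(["A"] * 6, dtype=object), ["a", "b", "c"])
        res = mt.run_pca(genos, k=1)
        assert res.var_explained[0] == pytest.approx(1.0)

    def test_k_beyond_rank_rejected(self, rng):
        dosage = rng.integers(0, 3, size=(4, 10)).astype(np.int8)
        genos = GenotypeMatrix(dosage, [f"s{i}" for i in range(4)],
                               np.array(["A"] * 4, dtype=object),
                               [f"m{j}" for j in range(10)])
        with pytest.raises(ValueError, match="rank"):
            mt.run_pca(genos, k=5)

    def test_pc1_separates_balding_nichols_populations(self):
        cfg = sd.SimConfig(n_per_cohort=120, n_snps=600, fst=0.1,
                           subpop_fractions={"A": (1.0, 0.0), "B": (0.0, 1.0)},
                           seed=21)
        genos, _, _ = sd.simulate_cohort_pair(cfg)
        poly = [s for s, v in zip(genos.snp_ids, genos.dosage.std(axis=0)) if v > 0]
        res = mt.run_pca(genos, k=2, panel=poly)
        pc1 = res.scores[:, 0]
        groups = [pc1[genos.cohort_mask(c)] for c in ("A", "B")]
        between = (groups[0].mean() - groups[1].mean()) ** 2
        within = np.var(groups[0]) + np.var(groups[1])
        assert between > within
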
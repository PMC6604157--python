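import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import binomial_two_sided, fet_two_sided, signed_rank_two_sided
from hetspan import het_stats as hs


class TestSnpHet:
    def test_exact_hwe_gives_zero_excess(self):
        row = hs.snp_het({"A": (25, 50, 25)})
        assert row["maf_A"] == pytest.approx(0.5)
        assert row["het_o_A"] == pytest.approx(0.5)
        assert row["het_e_A"] == pytest.approx(0.5)
        assert row["f_A"] == pytest.approx(0.0)

    def test_direct_formula_arithmetic(self):
        row = hs.snp_het({"A": (10, 80, 10)})
        assert row["het_o_A"] == pytest.approx(0.8)
        assert row["f_A"] == pytest.approx(0.6)
        rare = hs.snp_het({"A": (0, 2, 98)})
        assert rare["maf_A"] == pytest.approx(0.01)
        assert rare["het_e_A"] == pytest.approx(0.0198)
        assert rare["f_A"] == pytest.approx((0.02 - 0.0198) / 0.0198)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            hs.snp_het({"A": (0, 0, 50)})

    def test_table_matches_recomputation_from_raw_matrix(self, excess_pair):
        genos, _, _ = excess_pair
        table = hs.het_stats_table(genos)
        pick = table.sample(20, random_state=1)
        for _, row in pick.iterrows():
            j = genos.snp_ids.index(row["snp_id"])
            for c in ("A", "B"):
                d = genos.dosage[genos.cohort_mask(c), j]
                counts = ((d == 2).sum(), (d == 1).sum(), (d == 0).sum())
                again = hs.snp_het({c: counts})
                assert row[f"f_{c}"] == pytest.approx(again[f"f_{c}"])
                assert row[f"het_o_{c}"] == pytest.approx(again[f"het_o_{c}"])


class TestPairedCohortTest:
    def test_identical_vectors_give_p_one(self):
        v = np.linspace(0, 1, 30)
        res = hs.paired_cohort_test(v, v)
        assert res.p == 1.0 and res.direction == "none"

    def test_uniform_shift_is_detected_with_direction(self, rng):
        a = rng.normal(size=100)
        res = hs.paired_cohort_test(a, a + 1)
        assert res.p < 1e-10 and res.direction == "B-higher"

    def test_swap_flips_direction_not_p(self, rng):
        a, b = rng.normal(size=50), rng.normal(size=50)
        r1 = hs.paired_cohort_test(a, b)
        r2 = hs.paired_cohort_test(b, a)
        assert r1.p == pytest.approx(r2.p)
        assert {r1.direction, r2.direction} == {"A-higher", "B-higher"}

    def test_exact_small_sample_matches_sign_flip_enumeration(self, rng):
        for n in (6, 9, 12):
            for _ in range(5):
                a = rng.normal(size=n)
                b = a + rng.normal(size=n)
                res = hs.paired_cohort_test(a, b)
                want = signed_rank_two_sided(list(b - a))
                assert res.p == pytest.approx(want, abs=1e-10)


class TestGenotypeRatioTest:
    def test_separated_table_matches_enumeration(self):
        res = hs.genotype_ratio_test((0, 5, 10), (5, 0, 10))
        assert res.p == pytest.approx(2 / 252)
        assert res.direction == "A-higher"

    def test_identical_odds_give_p_one(self):
        res = hs.genotype_ratio_test((10, 10, 5), (10, 10, 5))
        assert res.p == pytest.approx(1.0) and res.direction == "none"

    def test_cohort_transpose_symmetry(self):
        r1 = hs.genotype_ratio_test((4, 9, 3), (7, 5, 2))
        r2 = hs.genotype_ratio_test((7, 5, 2), (4, 9, 3))
        assert r1.p == pytest.approx(r2.p)

    def test_degenerate_margin_flagged(self):
        res = hs.genotype_ratio_test((0, 5, 10), (0, 7, 12))
        assert res.p == 1.0 and res.direction == "none" and res.note
        with pytest.raises(ValueError, match="empty"):
            hs.genotype_ratio_test((5, 0, 0), (3, 0, 0), mode="het_vs_hom_major")


class TestVectorisedFisher:
    def test_agrees_with_scipy_and_oracle_on_random_tables(self, rng):
        tables = rng.integers(0, 15, size=(300, 4))
        got = hs.fisher_exact_minlike(*tables.T)
        for (a, b, c, d), p in zip(tables, got):
            assert p == pytest.approx(fet_two_sided(a, b, c, d), abs=1e-9)

    def test_large_counts_match_scipy(self, rng):
        tables = rng.integers(50, 400, size=(50, 4))
        got = hs.fisher_exact_minlike(*tables.T)
        for (a, b, c, d), p in zip(tables, got):
            want = stats.fisher_exact([[a, b], [c, d]])[1]
            assert p == pytest.approx(want, rel=1e-8)


class TestAllelicTest:
    def test_equal_frequencies_give_p_one(self):
        res = hs.allelic_test((30, 70), (30, 70))
        assert res.p == pytest.approx(1.0)

    def test_chi2_statistic_matches_formula(self):
        res = hs.allelic_test((40, 60), (20, 80))
        want = 200 * (40 * 80 - 60 * 20) ** 2 / (100 * 100 * 60 * 140)
        assert res.statistic == pytest.approx(want)

    def test_constant_dosage_with_covariates_flagged(self, rng):
        res = hs.allelic_test_logistic(
            np.ones(40), np.array(["A"] * 20 + ["B"] * 20),
            covariate_pcs=rng.normal(size=(40, 2)))
        assert res.p == 1.0 and res.note


class TestBinomialMetaTest:
    def test_symmetric_counts_give_p_one(self):
        for k in (1, 10, 500):
            assert hs.binomial_direction_test(k, k).p == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        for n_a, n_b in [(8, 2), (15, 5), (30, 11), (3, 17)]:
            got = hs.binomial_direction_test(n_a, n_b).p
            assert got == pytest.approx(binomial_two_sided(n_a, n_a + n_b), abs=1e-12)

    def test_label_swap_invariance(self):
        assert (hs.binomial_direction_test(728, 581).p
                == pytest.approx(hs.binomial_direction_test(581, 728).p))

    def test_count_comparison_over_scan_frame(self):
        scan = pd.DataFrame({
            "snp_id": [f"s{i}" for i in range(6)],
            "p": [0.001, 0.02, 0.2, 0.04, 0.5, 0.009],
            "direction": ["A-higher", "B-higher", "A-higher", "B-higher",
                          "none", "B-higher"]})
        out = hs.significant_count_comparison(scan)
        at_05 = out[out["alpha"] == 0.05].iloc[0]
        assert at_05["n_A_higher"] == 1 and at_05["n_B_higher"] == 3
        at_001 = out[out["alpha"] == 0.001].iloc[0]
        assert at_001["n_A_higher"] == 0 and at_001["n_B_higher"] == 0
        assert at_001["p_binomial"] == 1.0


class TestStratifiedComparison:
    def test_excess_flagged_only_in_top_maf_bin(self, excess_pair):
        genos, _, _ = excess_pair
        table = hs.het_stats_table(genos)
        out = hs.stratified_comparison(
            table, hs.StratificationScheme(maf_edges=hs.DEFAULT_MAF_EDGES),
            measure="F")
        top = out[out["stratum"] == "[0.25,0.5]"].iloc[0]
        assert top["significant"] and top["direction"] == "B-higher"

    def test_null_panel_has_no_significant_stratum(self, null_pair):
        genos, _, _ = null_pair
        table = hs.het_stats_table(genos)
        out = hs.stratified_comparison(
            table, hs.StratificationScheme(maf_edges=hs.DEFAULT_MAF_EDGES),
            measure="MAF")
        assert not out["significant"].any()

    def test_annotation_stratification_and_degenerate_stratum(self, null_pair):
        genos, snps, _ = null_pair
        table = hs.het_stats_table(genos)
        out = hs.stratified_comparison(
            table, hs.StratificationScheme(column="association_category"),
            measure="HET_O", snp_table=snps)
        assert set(out["stratum"]) <= {"none", "disease", "trait"}
        single = table.head(1)
        deg = hs.stratified_comparison(
            single, hs.StratificationScheme(maf_edges=(0.0, 0.5)), measure="F")
        assert bool(deg["degenerate"].iloc[0])

    def test_scheme_validation(self):
        with pytest.raises(ValueError):
            hs.StratificationScheme()
        with pytest.raises(ValueError):
            hs.StratificationScheme(maf_edges=(0.5, 0.1))
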
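import numpy as np
import pandas as pd
import pytest

from oracles import fet_two_sided, hwe_exact
from hetspan import variant_qc as vq
from hetspan.io_formats import GenotypeMatrix


class TestHweExactTest:
    def test_modal_configurations_have_p_one(self):
        # (1,2,1): support {0,2,4} hets given 4 rare alleles; 2 is modal
        assert vq.hwe_exact_test(1, 2, 1) == pytest.approx(1.0)
        assert vq.hwe_exact_test(0, 2, 0) == pytest.approx(1.0)

    def test_large_exact_hwe_sample(self):
        assert vq.hwe_exact_test(2500, 5000, 2500) > 0.9

    def test_extreme_excess_is_significant(self):
        assert vq.hwe_exact_test(0, 100, 0) < 1e-10

    def test_agrees_with_enumeration_oracle_all_small_n(self):
        for n in range(1, 21):
            for nmm in range(n + 1):
                for nhet in range(n - nmm + 1):
                    nmaj = n - nmm - nhet
                    got = vq.hwe_exact_test(nmm, nhet, nmaj)
                    want = hwe_exact(nmm, nhet, nmaj)
                    assert got == pytest.approx(want, abs=1e-10), (nmm, nhet, nmaj)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            vq.hwe_exact_test(0, 0, 0)


def _make_genos(columns, cohorts, snp_meta=None):
    """columns: list of (dosages_A, dosages_B) per SNP."""
    n_a, n_b = cohorts
    dosage = np.array([list(a) + list(b) for a, b in columns], dtype=np.int8).T
    ids = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    labels = np.array(["A"] * n_a + ["B"] * n_b, dtype=object)
    snp_ids = [f"s{j}" for j in range(len(columns))]
    genos = GenotypeMatrix(dosage, ids, labels, snp_ids)
    meta = pd.DataFrame({
        "snp_id": snp_ids, "chrom": "1",
        "pos": np.arange(1, len(columns) + 1) * 10,
        "ref": "A", "alt": "C", "annotation_class": "noncoding",
        "gene": "", "association_category": "none", "gene_lists": "",
    })
    if snp_meta:
        for col, values in snp_meta.items():
            meta[col] = values
    return genos, meta


class TestQcFilter:
    def test_first_failing_criterion_attribution(self):
        ok = ([0, 1, 2, 1] * 4, [0, 1, 2, 1] * 4)
        mono_b = ([0, 1, 2, 1] * 4, [0] * 16)             # criterion 2
        missing = ([0, 1, 2, -1] * 4, [0, 1, 2, 1] * 4)   # criterion 3
        chrx = (list(ok[0]), list(ok[1]))                 # criterion 4
        hwe_bad = ([1] * 16, [1] * 16)                    # all-het, criterion 5
        rare = ([0] * 15 + [1], [0] * 15 + [1])           # MAF 2/64, criterion 6
        genos, meta = _make_genos(
            [ok, mono_b, missing, chrx, hwe_bad, rare], (16, 16),
            snp_meta={"chrom": ["1", "1", "1", "X", "1", "1"]})
        panel, report = vq.qc_filter(
            genos, meta,
            vq.QcConfig(excluded_interval=None, combined_maf_min=0.05))
        assert panel == ["s0"]
        assert report.exclusions == {
            "allele_mismatch": 0, "monomorphic_in_a_cohort": 1,
            "missing_genotypes": 1, "non_autosomal_or_excluded_interval": 1,
            "hwe_failure": 1, "low_maf": 1}
        assert report.n_retained == 1

    def test_excluded_interval_is_inclusive(self):
        ok = ([0, 1, 2, 1] * 2, [0, 1, 2, 1] * 2)
        genos, meta = _make_genos([ok, ok, ok], (8, 8), snp_meta={
            "chrom": ["6", "6", "6"], "pos": [24_999_999, 25_000_000, 35_000_000]})
        panel, report = vq.qc_filter(genos, meta, vq.QcConfig())
        assert panel == ["s0"]
        assert report.exclusions["non_autosomal_or_excluded_interval"] == 2

    def test_exact_hwe_common_snp_retained(self):
        counts = ([2] * 25 + [1] * 50 + [0] * 25,) * 2
        genos, meta = _make_genos([counts], (100, 100))
        panel, _ = vq.qc_filter(genos, meta, vq.QcConfig(excluded_interval=None))
        assert panel == ["s0"]

    def test_idempotent(self, excess_pair):
        genos, snps, _ = excess_pair
        cfg = vq.QcConfig(excluded_interval=None)
        panel, _ = vq.qc_filter(genos, snps, cfg)
        again, report = vq.qc_filter(
            genos.subset_snps(panel), snps[snps["snp_id"].isin(panel)], cfg)
        assert again == panel
        assert sum(report.exclusions.values()) == 0

    def test_empty_panel_is_an_error(self):
        mono = ([0] * 8, [0] * 8)
        genos, meta = _make_genos([mono], (8, 8))
        with pytest.raises(ValueError, match="no SNP passed"):
            vq.qc_filter(genos, meta, vq.QcConfig(excluded_interval=None))


class TestLdPrune:
    def _config(self):
        return vq.QcConfig(excluded_interval=None, ld_window_snps=10,
                           ld_step_snps=2)

    def test_duplicated_adjacent_columns_keep_one(self, rng):
        col = rng.integers(0, 3, size=40)
        noise = rng.integers(0, 3, size=40)
        genos, meta = _make_genos(
            [(col[:20], col[20:]), (col[:20], col[20:]), (noise[:20], noise[20:])],
            (20, 20))
        kept = vq.ld_prune(genos, ["s0", "s1", "s2"], meta, self._config())
        assert "s2" in kept
        assert len([s for s in kept if s in ("s0", "s1")]) == 1
        # deterministic tie-break: the later-positioned duplicate is dropped
        assert "s0" in kept

    def test_independent_snps_all_retained(self, rng):
        cols = [(rng.integers(0, 3, 200), rng.integers(0, 3, 200))
                for _ in range(30)]
        genos, meta = _make_genos(cols, (200, 200))
        panel = [f"s{j}" for j in range(30)]
        assert vq.ld_prune(genos, panel, meta, self._config()) == panel

    def test_empty_panel_gives_empty_output(self, rng):
        genos, meta = _make_genos([(rng.integers(0, 3, 5), rng.integers(0, 3, 5))],
                                  (5, 5))
        assert vq.ld_prune(genos, [], meta, self._config()) == []

    def test_no_retained_pair_exceeds_threshold(self, rng):
        # blocks of correlated SNPs: verify the post-condition directly
        base = [rng.integers(0, 3, 120) for _ in range(8)]
        cols = []
        for b in base:
            for _ in range(3):
                noisy = b.copy()
                flips = rng.random(120) < 0.15
                noisy[flips] = rng.integers(0, 3, flips.sum())
                cols.append((noisy[:60], noisy[60:]))
        genos, meta = _make_genos(cols, (60, 60))
        cfg = self._config()
        kept = vq.ld_prune(genos, [f"s{j}" for j in range(len(cols))], meta, cfg)
        sub = genos.subset_snps(kept)
        x = sub.dosage.astype(float)
        order = {s: j for j, s in enumerate(kept)}
        for w_start in range(0, len(kept), cfg.ld_step_snps):
            window = kept[w_start:w_start + cfg.ld_window_snps]
            if len(window) < 2:
                continue
            block = x[:, [order[s] for s in window]]
            r = np.corrcoef(block.T)
            np.fill_diagonal(r, 0.0)
            assert (r ** 2).max() < cfg.ld_r2_max


def test_qc_config_validation():
    with pytest.raises(ValueError):
        vq.QcConfig(hwe_p_threshold=0.0)
    with pytest.raises(ValueError):
        vq.QcConfig(ld_window_snps=2, ld_step_snps=5)


def test_pruner_collapses_generated_ld_blocks():
    from hetspan import synthetic_data as sd

    cfg = sd.SimConfig(n_per_cohort=150, n_snps=400, ld_copy_fraction=0.3,
                       ld_copy_noise=0.02, seed=13)
    genos, snps, _ = sd.simulate_cohort_pair(cfg)
    panel, _ = vq.qc_filter(genos, snps, vq.QcConfig(excluded_interval=None))
    pruned = vq.ld_prune(genos, panel, snps, vq.QcConfig(excluded_interval=None))
    # noisy neighbour copies have r^2 near 1 and must be removed
    assert len(pruned) < len(panel) - 0.15 * len(panel)
    sub = genos.subset_snps(pruned)
    x = sub.dosage.astype(float)
    r = np.corrcoef(x.T)
    np.fill_diagonal(r, 0.0)
    # adjacent retained pairs are below the threshold
    adjacent = np.array([r[i, i + 1] ** 2 for i in range(len(pruned) - 1)])
    assert (adjacent < 0.5).all()
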
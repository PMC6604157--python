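"""SNP inclusion filters and LD pruning for the analysis panel.

A SNP enters the analysis panel only if, in order: both cohorts carry the
same allele pair at the site; each cohort holds at least one minor allele;
no genotype is missing; the site is autosomal and outside the excluded
interval (an MHC-like region, excluded because its extreme diversity would
dominate any heterozygosity comparison); the combined genotype counts are
compatible with Hardy-Weinberg equilibrium (exact test p > 0.001); and the
combined minor-allele frequency exceeds 1%.  The exclusion report attributes
every dropped SNP to the first criterion it fails, so the per-criterion
counts always sum to the number removed.

The HWE test is the exact conditional test: given the observed minor-allele
count, the number of heterozygotes under random mating follows a known
discrete law, and the two-sided p is the total probability of heterozygote
counts no more likely than the observed one (computed by enumeration with a
stable recurrence, not a chi-square approximation, so rare-allele sites are
handled correctly).

LD pruning slides a window of 50 SNPs advancing 5 SNPs at a time; within a
window, while any retained pair of SNPs has squared dosage correlation at or
above the threshold, the later-positioned SNP of the worst pair is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix

AUTOSOMES = {str(i) for i in range(1, 23)} | {f"chr{i}" for i in range(1, 23)}

QC_CRITERIA = [
    "allele_mismatch", "monomorphic_in_a_cohort", "missing_genotypes",
    "non_autosomal_or_excluded_interval", "hwe_failure", "low_maf",
]


@dataclass
class QcConfig:
    hwe_p_threshold: float = 0.001
    combined_maf_min: float = 0.01
    excluded_interval: tuple[str, int, int] | None = ("6", 25_000_000, 35_000_000)
    ld_window_snps: int = 50
    ld_step_snps: int = 5
    ld_r2_max: float = 0.5
    hwe_scope: str = "combined"  # or "per_cohort"

    def __post_init__(self) -> None:
        if not (0 < self.hwe_p_threshold < 1 and 0 < self.combined_maf_min < 1
                and 0 < self.ld_r2_max < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        if not self.ld_window_snps >= self.ld_step_snps >= 1:
            raise ValueError("require window >= step >= 1")
        if self.hwe_scope not in ("combined", "per_cohort"):
            raise ValueError("hwe_scope must be 'combined' or 'per_cohort'")


def hwe_exact_test(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Two-sided exact HWE p from the conditional heterozygote distribution."""
    return float(hwe_exact_test_many(np.array([[n_hom_minor, n_het, n_hom_major]]))[0])


def hwe_exact_test_many(counts: np.ndarray) -> np.ndarray:
    """Vector of exact HWE p-values for rows of (hom-minor, het, hom-major).

    Conditional on n diploids and n_rare minor alleles, P(het = k) follows
    the exact law with support k = n_rare, n_rare-2, ...; probabilities are
    built by the ratio recurrence

        P(k+2)/P(k) = (n_rare-k)(n_major-k) / ((k+2)(k+1) ... )

    normalised over the support; p is the summed probability of outcomes no
    more likely than the observed heterozygote count.
    """
    counts = np.asarray(counts, dtype=np.int64)
    pvals = np.empty(len(counts), dtype=float)
    for i, (nmm, nhet, nmaj) in enumerate(counts):
        if min(nmm, nhet, nmaj) < 0 or nmm + nhet + nmaj == 0:
            raise ValueError("genotype counts must be non-negative, n >= 1")
        n = nmm + nhet + nmaj
        rare = 2 * nmm + nhet
        rare = min(rare, 2 * n - rare)
        obs_het = nhet
        if rare == 0:
            pvals[i] = 1.0
            continue
        ks = np.arange(rare % 2, rare + 1, 2)
        logp = np.empty(len(ks))
        logp[0] = 0.0
        for j in range(len(ks) - 1):
            k = ks[j]
            # hom-rare = (rare-k)/2, hom-common = n - (rare+k)/2 at het count k
            logp[j + 1] = logp[j] + np.log(rare - k) + np.log(2 * n - rare - k) \
                - np.log(k + 2.0) - np.log(k + 1.0)
        probs = np.exp(logp - logp.max())
        probs /= probs.sum()
        p_obs = probs[(obs_het - ks[0]) // 2]
        pvals[i] = min(probs[probs <= p_obs * (1 + 1e-12)].sum(), 1.0)
    return pvals


@dataclass
class QcReport:
    n_input: int
    exclusions: dict[str, int] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return self.n_input - sum(self.exclusions.values())

    def as_frame(self) -> pd.DataFrame:
        rows = [{"criterion": c, "n_excluded": self.exclusions.get(c, 0)}
                for c in QC_CRITERIA]
        rows.append({"criterion": "retained", "n_excluded": self.n_retained})
        return pd.DataFrame(rows)


def qc_filter(genos: GenotypeMatrix, snps: pd.DataFrame, cfg: QcConfig,
              allele_mismatch_ids=()) -> tuple[list[str], QcReport]:
    """Apply the inclusion filters; returns (panel snp ids, exclusion report).

    ``allele_mismatch_ids`` carries sites already found to disagree between
    separately-read cohort files (criterion 1); with a merged matrix the
    alleles agree by construction.
    """
    cohorts = genos.cohorts
    if len(cohorts) != 2:
        raise ValueError(f"QC requires exactly two cohorts, found {cohorts}")
    snps = snps.set_index("snp_id").loc[genos.snp_ids].reset_index()

    fail = np.zeros(genos.n_snps, dtype=np.int8)  # 0 = pass, else criterion no.
    mism = np.isin(np.asarray(genos.snp_ids, dtype=object),
                   np.asarray(list(allele_mismatch_ids), dtype=object))
    fail[mism] = 1

    counts = {c: genos.genotype_counts(c) for c in cohorts}
    for c in cohorts:
        minor = 2 * counts[c][:, 0] + counts[c][:, 1]
        total = 2 * counts[c].sum(axis=1)
        mono = (minor == 0) | (minor == total)
        fail[(fail == 0) & mono] = 2

    missing = (genos.dosage == MISSING).any(axis=0)
    fail[(fail == 0) & missing] = 3

    chrom = snps["chrom"].astype(str).to_numpy()
    pos = snps["pos"].to_numpy()
    bad_region = ~np.isin(chrom, list(AUTOSOMES))
    if cfg.excluded_interval is not None:
        xc, xs, xe = cfg.excluded_interval
        bad_region |= (chrom == str(xc)) & (pos >= xs) & (pos <= xe)
    fail[(fail == 0) & bad_region] = 4

    todo = fail == 0
    if cfg.hwe_scope == "combined":
        combined = counts[cohorts[0]] + counts[cohorts[1]]
        hwe_p = np.ones(genos.n_snps)
        hwe_p[todo] = hwe_exact_test_many(combined[todo])
        hwe_bad = hwe_p <= cfg.hwe_p_threshold
    else:
        hwe_bad = np.zeros(genos.n_snps, dtype=bool)
        for c in cohorts:
            p_c = np.ones(genos.n_snps)
            p_c[todo] = hwe_exact_test_many(counts[c][todo])
            hwe_bad |= p_c <= cfg.hwe_p_threshold
    fail[(fail == 0) & hwe_bad] = 5

    combined = counts[cohorts[0]] + counts[cohorts[1]]
    total_alleles = 2 * combined.sum(axis=1)
    minor = 2 * combined[:, 0] + combined[:, 1]
    maf = np.minimum(minor, total_alleles - minor) / total_alleles
    fail[(fail == 0) & (maf <= cfg.combined_maf_min)] = 6

    report = QcReport(n_input=genos.n_snps)
    for num, name in enumerate(QC_CRITERIA, start=1):
        report.exclusions[name] = int((fail == num).sum())
    panel = [s for s, f in zip(genos.snp_ids, fail) if f == 0]
    if not panel:
        raise ValueError("no SNP passed quality control")
    return panel, report


def ld_prune(genos: GenotypeMatrix, panel, snps: pd.DataFrame,
             cfg: QcConfig) -> list[str]:
    """Sliding-window LD pruning on combined-cohort dosage correlation.

    Returns the subset of ``panel`` with no within-window pair at
    r^2 >= ``cfg.ld_r2_max``.  Ties on the worst r^2 drop the SNP with the
    larger position (then larger id) for determinism.
    """
    panel = list(panel)
    if not panel:
        return []
    order = (snps.set_index("snp_id").loc[panel]
             .reset_index()
             .sort_values(["chrom", "pos", "snp_id"], kind="mergesort"))
    ordered_ids = list(order["snp_id"])
    positions = order["pos"].to_numpy()
    sub = genos.subset_snps(ordered_ids)
    dosage = sub.dosage.astype(np.float64)
    centred = dosage - dosage.mean(axis=0)
    norms = np.sqrt((centred ** 2).sum(axis=0))
    norms[norms == 0] = np.inf  # constant column: define r = 0 against anything

    keep = np.ones(len(ordered_ids), dtype=bool)
    w, step = cfg.ld_window_snps, cfg.ld_step_snps
    start = 0
    while start < len(ordered_ids):
        window = np.arange(start, min(start + w, len(ordered_ids)))
        while True:
            active = window[keep[window]]
            if len(active) < 2:
                break
            block = centred[:, active]
            denom = np.outer(norms[active], norms[active])
            r2 = (block.T @ block / denom) ** 2
            np.fill_diagonal(r2, 0.0)
            worst = np.max(r2)
            if worst < cfg.ld_r2_max:
                break
            ii, jj = np.where(r2 >= worst - 1e-12)
            # later SNP of the worst pair; ties on r^2 break by (pos, id)
            cand = set()
            for x, y in zip(active[ii], active[jj]):
                if x < y:
                    cand.add((positions[y], ordered_ids[y], y))
            drop = max(cand)[2]
            keep[drop] = False
        if start + w >= len(ordered_ids):
            break
        start += step
    return [s for s, k in zip(ordered_ids, keep) if k]
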
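"""Per-individual heterozygosity rate and its pseudo-individual permutation null.

The individual heterozygosity rate is the proportion of heterozygous sites an
individual carries on a fixed common-SNP panel (default: noncoding SNPs with
combined MAF > 0.1).  Because every individual is scored on exactly the same
panel with no missing calls, the raw proportion is directly comparable across
individuals and needs no standardisation.

The permutation null asks whether the two cohorts' mean rates could arise if
genotypes were exchangeable between cohorts: for each SNP independently, the
combined column of genotypes is redistributed at random and the first nA
entries form a pseudo-cohort, whose mean heterozygosity rate is recorded.
Only the pseudo-cohort mean enters the null, and the number of heterozygotes
landing in a random nA-subset of a column with h heterozygotes is exactly
Hypergeometric(nA + nB, h, nA); the implementation samples that law directly,
which is identical in distribution to permuting the full column and far
cheaper.  Empirical p-values use the add-one convention
(1 + #{null >= observed}) / (n_perm + 1), so a mean outside the whole null
range reports the smallest achievable value 1/(n_perm + 1), never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix


@dataclass
class HetRateResult:
    rates: pd.Series          # indexed by sample id
    panel_size: int
    maf_min: float | None = None

    def by_cohort(self, genos: GenotypeMatrix) -> dict[str, pd.Series]:
        labels = pd.Series(genos.cohort_labels, index=genos.sample_ids)
        return {c: self.rates[labels[labels == c].index] for c in genos.cohorts}


@dataclass
class PermutationResult:
    observed_means: dict[str, float]
    null_means: np.ndarray
    p_greater: dict[str, float]   # P(null mean >= observed), one-sided
    p_less: dict[str, float]      # P(null mean <= observed), one-sided
    n_perm: int
    seed: int


def select_rate_panel(stats_table: pd.DataFrame, snp_table: pd.DataFrame | None = None,
                      maf_min: float = 0.1,
                      annotation_class: str | None = "noncoding") -> list[str]:
    """Panel for the rate: combined MAF above ``maf_min``, one annotation class."""
    keep = stats_table["maf_combined"] > maf_min
    if annotation_class is not None and snp_table is not None:
        ann = snp_table.set_index("snp_id")["annotation_class"]
        keep &= stats_table["snp_id"].map(ann).eq(annotation_class).to_numpy()
    return list(stats_table.loc[keep, "snp_id"])


def het_rate(genos: GenotypeMatrix, panel) -> HetRateResult:
    """Proportion of heterozygous panel sites per sample."""
    panel = list(panel)
    if not panel:
        raise ValueError("empty SNP panel")
    sub = genos.subset_snps(panel)
    if (sub.dosage < 0).any():
        raise ValueError("missing genotypes on the rate panel")
    rates = (sub.dosage == 1).mean(axis=1)
    return HetRateResult(
        rates=pd.Series(rates, index=genos.sample_ids, name="het_rate"),
        panel_size=len(panel))


def permutation_null(genos: GenotypeMatrix, panel, n_perm: int = 10_000,
                     seed: int = 0) -> PermutationResult:
    """Null distribution of pseudo-cohort mean heterozygosity rates.

    ``genos`` must hold both cohorts; the pseudo-cohort size is the size of
    the first cohort (nA).  Each permutation draws, per SNP independently,
    the heterozygote count of a random nA-subset of the combined genotype
    column, and records the implied pseudo-cohort mean rate.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    cohorts = genos.cohorts
    if len(cohorts) != 2:
        raise ValueError(f"two cohorts required, found {cohorts}")
    sub = genos.subset_snps(list(panel))
    n_a = int((genos.cohort_labels == cohorts[0]).sum())
    n_total = genos.n_samples
    het_counts = (sub.dosage == 1).sum(axis=0)

    rng = np.random.default_rng(seed)
    draws = rng.hypergeometric(het_counts[None, :],
                               n_total - het_counts[None, :],
                               n_a, size=(n_perm, sub.n_snps))
    null_means = draws.mean(axis=1) / n_a

    rates = het_rate(genos, list(panel))
    observed = {c: float(r.mean()) for c, r in rates.by_cohort(genos).items()}
    p_greater = {c: float((1 + (null_means >= m).sum()) / (n_perm + 1))
                 for c, m in observed.items()}
    p_less = {c: float((1 + (null_means <= m).sum()) / (n_perm + 1))
              for c, m in observed.items()}
    return PermutationResult(observed_means=observed, null_means=null_means,
                             p_greater=p_greater, p_less=p_less,
                             n_perm=n_perm, seed=seed)
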
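"""Top-decile excess-heterozygosity SNP sets and gene-set over-representation.

For each cohort the SNPs in the top decile of excess of heterozygosity (F)
are selected; SNPs topping the decile in both cohorts are removed from both,
leaving mutually exclusive, cohort-specific sets whose genes are tested for
over-representation in user-supplied gene-set collections (GMT).  The test is
the one-sided hypergeometric tail: with N background genes, K of them in a
gene set, and n query genes, the enrichment p is P(X >= k) for the observed
overlap k.  Gene sets are intersected with the background before testing and
Benjamini-Hochberg q-values are computed within each collection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection


@dataclass
class TopSnpSets:
    top: dict[str, set[str]]        # raw per-cohort top-decile SNP ids
    shared: set[str]
    exclusive: dict[str, set[str]]  # top minus shared
    genes: dict[str, set[str]]      # genes of the exclusive sets
    n_unannotated: dict[str, int]   # exclusive SNPs without a gene symbol


def select_top_decile(stats_table: pd.DataFrame, cohort: str,
                      q: float = 0.10) -> set[str]:
    """SNPs at or above the (1 - q) empirical quantile of F in one cohort.

    The threshold is the order statistic at rank ceil(q * n) from the top
    (type-1 / inverse-ECDF quantile); every SNP tied with the threshold is
    included, so the set may exceed ceil(q * n) under ties.
    """
    if stats_table.empty:
        raise ValueError("empty HetStats table")
    f = stats_table[f"f_{cohort}"].to_numpy(dtype=float)
    k = max(1, int(np.ceil(q * len(f))))
    threshold = np.sort(f)[len(f) - k]
    return set(stats_table.loc[f >= threshold, "snp_id"])


def exclusive_sets(top_a: set[str], top_b: set[str],
                   snp_to_gene: pd.Series | dict,
                   cohorts: tuple[str, str] = ("A", "B")) -> TopSnpSets:
    """Remove the shared top SNPs and map each exclusive set to genes."""
    mapping = pd.Series(snp_to_gene) if isinstance(snp_to_gene, dict) else snp_to_gene
    shared = top_a & top_b
    out_top = {cohorts[0]: set(top_a), cohorts[1]: set(top_b)}
    exclusive = {cohorts[0]: top_a - shared, cohorts[1]: top_b - shared}
    genes, unannotated = {}, {}
    for cohort, snp_set in exclusive.items():
        symbols = mapping.reindex(list(snp_set))
        present = symbols[symbols.notna() & (symbols != "")]
        genes[cohort] = set(present)
        unannotated[cohort] = len(snp_set) - len(present)
    return TopSnpSets(top=out_top, shared=shared, exclusive=exclusive,
                      genes=genes, n_unannotated=unannotated)


def hypergeom_enrichment(query_genes, background_genes,
                         collection: GeneSetCollection) -> pd.DataFrame:
    """One-sided hypergeometric over-representation with BH q per collection.

    ``query_genes`` must be contained in ``background_genes``; each gene set
    is intersected with the background first and skipped when the
    intersection is empty.  Rows are sorted by p.
    """
    query = set(query_genes)
    background = set(background_genes)
    if not query:
        raise ValueError("empty query gene set")
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    n_bg, n_query = len(background), len(query)
    rows = []
    for set_name, genes in collection.sets.items():
        in_bg = set(genes) & background
        if not in_bg:
            continue
        k = len(in_bg & query)
        p = float(stats.hypergeom.sf(k - 1, n_bg, len(in_bg), n_query))
        rows.append({"collection": collection.name, "set_name": set_name,
                     "k_overlap": k, "set_size": len(in_bg),
                     "query_size": n_query, "background_size": n_bg,
                     "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    return out


def score_set_comparison(scores: pd.Series, set_a, set_b,
                         names: tuple[str, str] = ("set_A", "set_B")):
    """Two-sided Mann-Whitney U between per-SNP score distributions.

    Generic mechanism for comparing a numeric SNP annotation (e.g. an
    evolutionary-permissibility or deleteriousness score) between two SNP
    sets, or between a set and the rest of the panel.
    """
    from .het_stats import TestResult

    a = scores.reindex(list(set_a)).dropna().to_numpy(dtype=float)
    b = scores.reindex(list(set_b)).dropna().to_numpy(dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both SNP sets need scored members")
    if np.ptp(np.concatenate([a, b])) == 0:
        return TestResult("mannwhitney_scores", np.nan, 1.0, "none",
                          note="all scores tied")
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    direction = (f"{names[0]}-higher" if np.median(a) > np.median(b)
                 else f"{names[1]}-higher" if np.median(b) > np.median(a)
                 else "none")
    return TestResult("mannwhitney_scores", float(stat), float(p), direction)
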
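"""Per-SNP heterozygosity statistics and cohort-comparison scans.

For a biallelic SNP with minor-allele frequency p, the expected heterozygote
frequency under Hardy-Weinberg equilibrium is HET_E = 2p(1-p).  The excess of
heterozygosity is

    F = (HET_O - HET_E) / HET_E

which is 0 at exact HWE, positive when heterozygotes are over-represented and
bounded below by -1.  Unlike HET_O, F is essentially decoupled from allele
frequency, which is what makes it comparable across SNPs and cohorts.

The scans compare two cohorts SNP by SNP with Fisher's exact test on genotype
ratios (het vs minor-allele homozygote "Dd/DD", het vs major-allele homozygote
"Dd/dd") and on allele counts ("D/d"), then summarise the direction counts of
nominally significant SNPs with a two-sided exact binomial meta-test: under
the null of no heterozygosity difference, a SNP that clears a nominal cutoff
is equally likely to favour either cohort.

All two-sided exact p-values (Fisher, binomial) follow the minlike
convention - the sum of outcome probabilities not exceeding that of the
observed outcome - matching the mainstream R/scipy implementations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .io_formats import GenotypeMatrix

#: Default combined-MAF bin edges; bins are [lo, hi) except the last, [0.25, 0.5].
DEFAULT_MAF_EDGES = (0.01, 0.05, 0.1, 0.25, 0.5)


@dataclass
class TestResult:
    name: str
    statistic: float
    p: float
    direction: str
    note: str = ""


@dataclass
class StratificationScheme:
    """Either MAF bins over combined frequency or a SNP-table annotation key."""
    maf_edges: tuple[float, ...] | None = None
    column: str | None = None

    def __post_init__(self) -> None:
        if (self.maf_edges is None) == (self.column is None):
            raise ValueError("specify exactly one of maf_edges / column")
        if self.maf_edges is not None and list(self.maf_edges) != sorted(self.maf_edges):
            raise ValueError("MAF bin edges must be increasing")


# ---------------------------------------------------------------------------
# per-SNP statistics

def het_stats_from_counts(n_hom_minor, n_het, n_hom_major):
    """Vectorised (MAF, HET_O, HET_E, F) from genotype counts.

    The designated allele may drift above frequency 0.5 within one cohort even
    though it is minor on the combined cohorts; MAF is folded to <= 0.5 while
    HET_E = 2p(1-p) is unchanged by the folding.
    """
    nmm = np.asarray(n_hom_minor, dtype=float)
    nhet = np.asarray(n_het, dtype=float)
    nmaj = np.asarray(n_hom_major, dtype=float)
    n = nmm + nhet + nmaj
    if np.any(n < 1):
        raise ValueError("empty genotype counts")
    p = (2 * nmm + nhet) / (2 * n)
    if np.any((p == 0) | (p == 1)):
        raise ValueError("monomorphic SNP: heterozygosity statistics undefined")
    het_o = nhet / n
    het_e = 2 * p * (1 - p)
    return np.minimum(p, 1 - p), het_o, het_e, (het_o - het_e) / het_e


def snp_het(counts_by_cohort: dict[str, tuple[int, int, int]]) -> pd.Series:
    """HetStats for one SNP from per-cohort (hom-minor, het, hom-major) counts."""
    out: dict[str, float] = {}
    total = np.zeros(3)
    for cohort, counts in counts_by_cohort.items():
        maf, het_o, het_e, f = het_stats_from_counts(*counts)
        out[f"maf_{cohort}"] = float(maf)
        out[f"het_o_{cohort}"] = float(het_o)
        out[f"het_e_{cohort}"] = float(het_e)
        out[f"f_{cohort}"] = float(f)
        total += counts
    maf, _, _, _ = het_stats_from_counts(*total)
    out["maf_combined"] = float(maf)
    return pd.Series(out)


def het_stats_table(genos: GenotypeMatrix, panel=None) -> pd.DataFrame:
    """Per-SNP HetStats for every cohort plus the combined MAF."""
    g = genos if panel is None else genos.subset_snps(list(panel))
    table = pd.DataFrame({"snp_id": g.snp_ids})
    for cohort in g.cohorts:
        counts = g.genotype_counts(cohort)
        maf, het_o, het_e, f = het_stats_from_counts(
            counts[:, 0], counts[:, 1], counts[:, 2])
        table[f"maf_{cohort}"] = maf
        table[f"het_o_{cohort}"] = het_o
        table[f"het_e_{cohort}"] = het_e
        table[f"f_{cohort}"] = f
    combined = g.genotype_counts(None)
    maf, _, _, _ = het_stats_from_counts(
        combined[:, 0], combined[:, 1], combined[:, 2])
    table["maf_combined"] = maf
    return table


# ---------------------------------------------------------------------------
# exact tests

_MINLIKE_RTOL = 1.0 + 1e-7


def fisher_exact_minlike(a, b, c, d, chunk: int = 4096) -> np.ndarray:
    """Two-sided (minlike) Fisher exact p for arrays of 2x2 tables [[a,b],[c,d]].

    Vectorised over tables via the conditional hypergeometric likelihood;
    agrees with ``scipy.stats.fisher_exact`` per table.  Tables with a zero
    margin carry no information and get p = 1.
    """
    a = np.atleast_1d(np.asarray(a, dtype=np.int64))
    b = np.broadcast_to(np.asarray(b, dtype=np.int64), a.shape).copy()
    c = np.broadcast_to(np.asarray(c, dtype=np.int64), a.shape).copy()
    d = np.broadcast_to(np.asarray(d, dtype=np.int64), a.shape).copy()
    n_tot = a + b + c + d
    col1 = a + c
    row1 = a + b
    p = np.ones(a.shape, dtype=float)
    ok = (col1 > 0) & (col1 < n_tot) & (row1 > 0) & (row1 < n_tot)
    idx = np.where(ok)[0]
    if idx.size == 0:
        return p

    def logpmf(k, n_, k1, r1):
        return (gammaln(k1 + 1) - gammaln(k + 1) - gammaln(k1 - k + 1)
                + gammaln(n_ - k1 + 1) - gammaln(r1 - k + 1)
                - gammaln(n_ - k1 - r1 + k + 1)
                - (gammaln(n_ + 1) - gammaln(r1 + 1) - gammaln(n_ - r1 + 1)))

    kmin = np.maximum(0, col1 + row1 - n_tot)
    kmax = np.minimum(col1, row1)
    for start in range(0, idx.size, chunk):
        rows = idx[start:start + chunk]
        lo, hi = kmin[rows], kmax[rows]
        width = int((hi - lo).max()) + 1
        ks = lo[:, None] + np.arange(width)[None, :]
        valid = ks <= hi[:, None]
        ks = np.minimum(ks, hi[:, None])
        lp = logpmf(ks, n_tot[rows, None], col1[rows, None], row1[rows, None])
        pmf = np.where(valid, np.exp(lp), 0.0)
        p_obs = np.exp(logpmf(a[rows], n_tot[rows], col1[rows], row1[rows]))
        p[rows] = np.minimum(
            (pmf * (pmf <= p_obs[:, None] * _MINLIKE_RTOL)).sum(axis=1), 1.0)
    return p


def allelic_chi2(a, b, c, d) -> np.ndarray:
    """Pearson 1-df chi-square statistic (no continuity correction) per table."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, n * (a * d - b * c) ** 2 / denom, 0.0)
    return chi2


def genotype_ratio_test(counts_a, counts_b, mode: str = "het_vs_hom_minor",
                        cohorts: tuple[str, str] = ("A", "B")) -> TestResult:
    """FET comparing the het:hom genotype ratio between the two cohorts.

    ``counts_*`` are (n_hom_minor, n_het, n_hom_major).  ``mode`` selects the
    homozygote class: ``het_vs_hom_minor`` is the Dd/DD comparison,
    ``het_vs_hom_major`` the Dd/dd one.
    """
    hom_idx = {"het_vs_hom_minor": 0, "het_vs_hom_major": 2}[mode]
    a, b = int(counts_a[1]), int(counts_a[hom_idx])
    c, d = int(counts_b[1]), int(counts_b[hom_idx])
    if (a + b == 0) and (c + d == 0):
        raise ValueError("both cohorts have empty genotype classes")
    if min(a + b, c + d, a + c, b + d) == 0:
        return TestResult(f"fet_{mode}", np.nan, 1.0, "none", note="degenerate margin")
    _, p = stats.fisher_exact([[a, b], [c, d]])
    cross_a, cross_b = a * d, c * b
    direction = (f"{cohorts[0]}-higher" if cross_a > cross_b
                 else f"{cohorts[1]}-higher" if cross_b > cross_a else "none")
    return TestResult(f"fet_{mode}", float(a * d / (b * c)) if b * c else np.inf,
                      float(p), direction)


def allelic_test(allele_counts_a, allele_counts_b,
                 cohorts: tuple[str, str] = ("A", "B")) -> TestResult:
    """FET on the allele-count 2x2 table (minor, major) x cohort.

    The ``statistic`` field carries the 1-df Pearson chi-square used for the
    genomic-inflation diagnostic.
    """
    a, b = (int(x) for x in allele_counts_a)
    c, d = (int(x) for x in allele_counts_b)
    chi2 = float(allelic_chi2(a, b, c, d))
    if min(a + b, c + d, a + c, b + d) == 0:
        return TestResult("fet_allelic", chi2, 1.0, "none", note="degenerate margin")
    _, p = stats.fisher_exact([[a, b], [c, d]])
    direction = (f"{cohorts[0]}-higher" if a * d > c * b
                 else f"{cohorts[1]}-higher" if c * b > a * d else "none")
    return TestResult("fet_allelic", chi2, float(p), direction)


def allelic_test_logistic(dosages: np.ndarray, cohort_labels: np.ndarray,
                          covariate_pcs: np.ndarray | None = None) -> TestResult:
    """Logistic model of cohort label on per-sample dosage plus PC covariates.

    Returns the Wald p for the dosage term; a constant dosage column is
    reported as no-signal with a degeneracy note.
    """
    import statsmodels.api as sm

    dosages = np.asarray(dosages, dtype=float)
    if np.ptp(dosages) == 0:
        return TestResult("logistic_allelic", np.nan, 1.0, "none",
                          note="constant dosage; Wald test undefined")
    y = (np.asarray(cohort_labels) == np.asarray(cohort_labels)[0]).astype(float)
    x = dosages[:, None] if covariate_pcs is None else np.column_stack(
        [dosages, covariate_pcs])
    fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0, maxiter=200)
    coef, p = fit.params[1], fit.pvalues[1]
    first = str(np.asarray(cohort_labels)[0])
    direction = f"{first}-higher" if coef > 0 else (f"not-{first}-higher" if coef < 0 else "none")
    return TestResult("logistic_allelic", float(coef), float(p), direction)


# ---------------------------------------------------------------------------
# genome scans

def _scan_frame(genos: GenotypeMatrix, panel):
    g = genos if panel is None else genos.subset_snps(list(panel))
    cohorts = g.cohorts
    if len(cohorts) != 2:
        raise ValueError(f"scan requires exactly two cohorts, found {cohorts}")
    return g, cohorts


def genotype_scan(genos: GenotypeMatrix, panel=None,
                  mode: str = "het_vs_hom_minor") -> pd.DataFrame:
    """Per-SNP FET of the het:hom ratio between cohorts, vectorised.

    Returns a frame with the four table cells, the minlike FET p and the
    direction (which cohort has the larger het:hom odds).
    """
    g, (ca, cb) = _scan_frame(genos, panel)
    hom_idx = {"het_vs_hom_minor": 0, "het_vs_hom_major": 2}[mode]
    counts_a = g.genotype_counts(ca)
    counts_b = g.genotype_counts(cb)
    a, b = counts_a[:, 1], counts_a[:, hom_idx]
    c, d = counts_b[:, 1], counts_b[:, hom_idx]
    p = fisher_exact_minlike(a, b, c, d)
    cross_a, cross_b = a.astype(np.int64) * d, c.astype(np.int64) * b
    direction = np.where(cross_a > cross_b, f"{ca}-higher",
                         np.where(cross_b > cross_a, f"{cb}-higher", "none"))
    return pd.DataFrame({
        "snp_id": g.snp_ids, f"het_{ca}": a, f"hom_{ca}": b,
        f"het_{cb}": c, f"hom_{cb}": d, "p": p, "direction": direction,
    })


def allelic_scan(genos: GenotypeMatrix, panel=None) -> pd.DataFrame:
    """Per-SNP allelic FET plus the 1-df chi-square feeding lambda_gc."""
    g, (ca, cb) = _scan_frame(genos, panel)
    counts_a = g.genotype_counts(ca)
    counts_b = g.genotype_counts(cb)
    na = counts_a.sum(axis=1)
    nb = counts_b.sum(axis=1)
    minor_a = 2 * counts_a[:, 0] + counts_a[:, 1]
    minor_b = 2 * counts_b[:, 0] + counts_b[:, 1]
    a, b = minor_a, 2 * na - minor_a
    c, d = minor_b, 2 * nb - minor_b
    p = fisher_exact_minlike(a, b, c, d)
    chi2 = allelic_chi2(a, b, c, d)
    cross_a = a.astype(np.int64) * d
    cross_b = c.astype(np.int64) * b
    direction = np.where(cross_a > cross_b, f"{ca}-higher",
                         np.where(cross_b > cross_a, f"{cb}-higher", "none"))
    return pd.DataFrame({"snp_id": g.snp_ids, "p": p, "chi2": chi2,
                         "direction": direction})


def significant_count_comparison(scan: pd.DataFrame,
                                 alpha_grid=(0.05, 0.01, 0.001),
                                 cohorts: tuple[str, str] = ("A", "B")) -> pd.DataFrame:
    """Direction counts of nominally significant SNPs with a binomial meta-test.

    For each nominal cutoff, counts SNPs whose FET p clears it by direction
    and tests the split against Binomial(n, 1/2), two-sided exact.
    """
    if scan.empty:
        raise ValueError("empty scan")
    rows = []
    for alpha in alpha_grid:
        sig = scan[scan["p"] < alpha]
        n_a = int((sig["direction"] == f"{cohorts[0]}-higher").sum())
        n_b = int((sig["direction"] == f"{cohorts[1]}-higher").sum())
        rows.append({"alpha": alpha, f"n_{cohorts[0]}_higher": n_a,
                     f"n_{cohorts[1]}_higher": n_b,
                     "p_binomial": binomial_direction_test(n_a, n_b).p})
    return pd.DataFrame(rows)


def binomial_direction_test(n_a: int, n_b: int) -> TestResult:
    """Two-sided exact binomial test of a direction-count split against 1:1."""
    n = n_a + n_b
    if n == 0:
        return TestResult("binomial_direction", np.nan, 1.0, "none",
                          note="no significant SNPs")
    p = stats.binomtest(n_a, n, 0.5).pvalue
    direction = "A-higher" if n_a > n_b else ("B-higher" if n_b > n_a else "none")
    return TestResult("binomial_direction", float(n_a), float(p), direction)


# ---------------------------------------------------------------------------
# paired and stratified comparisons

def paired_cohort_test(values_a, values_b,
                       cohorts: tuple[str, str] = ("A", "B")) -> TestResult:
    """Wilcoxon signed-rank test on per-SNP paired differences.

    Zero differences are dropped (classic Wilcoxon convention); the exact
    null is enumerated for <= 25 untied differences, otherwise the normal
    approximation with continuity correction is used.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    diff = b - a
    diff = diff[diff != 0]
    if diff.size == 0:
        return TestResult("wilcoxon_signed_rank", 0.0, 1.0, "none",
                          note="all paired differences zero")
    ranks = stats.rankdata(np.abs(diff))
    w_pos = float(ranks[diff > 0].sum())
    w_neg = float(ranks[diff < 0].sum())
    has_ties = np.unique(np.abs(diff)).size < diff.size
    method = "exact" if (diff.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(diff, zero_method="wilcox", correction=True,
                         method=method)
    direction = (f"{cohorts[1]}-higher" if w_pos > w_neg
                 else f"{cohorts[0]}-higher" if w_neg > w_pos else "none")
    return TestResult("wilcoxon_signed_rank", float(res.statistic),
                      float(res.pvalue), direction)


_MEASURE_PREFIX = {"MAF": "maf", "HET_O": "het_o", "F": "f"}


def stratified_comparison(stats_table: pd.DataFrame,
                          scheme: StratificationScheme,
                          measure: str = "F",
                          snp_table: pd.DataFrame | None = None,
                          cohorts: tuple[str, str] = ("A", "B"),
                          fdr_alpha: float = 0.05) -> pd.DataFrame:
    """Per-stratum paired cohort comparison of a HetStats measure.

    Strata are combined-MAF bins or the levels of a SNP-annotation column.
    Each stratum gets cohort means with standard errors (SNPs as units), the
    paired signed-rank p, and a Benjamini-Hochberg q across strata.  Strata
    with fewer than two SNPs are flagged degenerate and excluded from the
    FDR family.
    """
    prefix = _MEASURE_PREFIX[measure]
    col_a, col_b = f"{prefix}_{cohorts[0]}", f"{prefix}_{cohorts[1]}"
    table = stats_table
    if scheme.maf_edges is not None:
        edges = list(scheme.maf_edges)
        labels = [f"[{lo},{hi})" for lo, hi in zip(edges[:-1], edges[1:])]
        labels[-1] = f"[{edges[-2]},{edges[-1]}]"
        strata = pd.cut(table["maf_combined"], bins=edges, labels=labels,
                        right=False, include_lowest=True)
        # close the last bin on the right so MAF == 0.5 is kept
        strata = strata.astype(object)
        strata[table["maf_combined"] == edges[-1]] = labels[-1]
    else:
        if snp_table is None:
            raise ValueError("annotation stratification needs a SNP table")
        ann = snp_table.set_index("snp_id")[scheme.column]
        strata = table["snp_id"].map(ann).astype(object)
    n_excluded = int(pd.isna(strata).sum())

    rows = []
    for stratum in [s for s in pd.unique(strata) if not pd.isna(s)]:
        sub = table[np.asarray(strata == stratum)]
        row = {"stratum": str(stratum), "n_snps": len(sub),
               f"mean_{cohorts[0]}": sub[col_a].mean(),
               f"se_{cohorts[0]}": sub[col_a].sem(),
               f"mean_{cohorts[1]}": sub[col_b].mean(),
               f"se_{cohorts[1]}": sub[col_b].sem()}
        if len(sub) < 2:
            row.update({"statistic": np.nan, "p": np.nan, "direction": "none",
                        "degenerate": True})
        else:
            res = paired_cohort_test(sub[col_a], sub[col_b], cohorts)
            row.update({"statistic": res.statistic, "p": res.p,
                        "direction": res.direction, "degenerate": False})
        rows.append(row)
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    testable = ~out["degenerate"]
    if testable.any():
        out.loc[testable, "q"] = multipletests(
            out.loc[testable, "p"], method="fdr_bh")[1]
    out["significant"] = (out["q"] < fdr_alpha).fillna(False)
    out.attrs["n_excluded"] = n_excluded
    out.attrs["measure"] = measure
    return out
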
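# Methods

## Scientific question and overall design

`hetspan` tests whether one cohort carries systematically more heterozygous
genotypes than another — the pattern expected if heterozygote advantage
(overdominance) contributes to health and survival — and whether an
individual's genome-wide heterozygosity rate predicts an EHR-derived
10-year survival estimate.  The pipeline is built around the comparison of a
healthy-aged cohort against a general-population biobank cohort, but every
stage is cohort-agnostic: any two groups typed on a shared biallelic SNP
panel can be compared.

The unit statistic is the per-SNP **excess of heterozygosity**

    F = (HET_O − HET_E) / HET_E,        HET_E = 2p(1−p),

with `p` the minor-allele frequency (minor defined on the cohorts combined)
and `HET_O` the observed heterozygote frequency in one cohort.  `F` is zero
at Hardy–Weinberg equilibrium (HWE), positive under heterozygote excess, and
— unlike `HET_O` — essentially decoupled from allele frequency, which is what
makes it comparable across SNPs and MAF strata.  `F` is the sample analogue
of `−f` for an inbreeding-like coefficient `f` in the genotype law

    P(het) = 2p(1−p)(1−f),  P(hom minor) = p² + p(1−p)f,
    P(hom major) = (1−p)² + p(1−p)f,

which is also exactly the law the synthetic generator simulates from.

## Stages and their statistics

**QC (variant_qc).**  A SNP enters the analysis panel when, in order: both
cohorts carry the same allele pair; each cohort holds at least one minor
allele; no genotype is missing; the site is autosomal and outside the
excluded MHC-like interval (default chr6:25,000,000–35,000,000, 1-based
inclusive); the exact HWE test on combined genotypes gives p > 0.001; and
combined MAF > 1%.  Exclusions are attributed to the first failing
criterion, so the report's counts always sum to the number removed.  The HWE
test is the exact conditional test (enumeration of the heterozygote-count
distribution given the allele count, in log space for numerical stability);
a per-cohort scope is available behind `QcConfig.hwe_scope`.  LD pruning
slides a 50-SNP window advancing 5 SNPs, dropping the later SNP of the worst
pair while any retained pair has dosage r² ≥ 0.5; ties on r² break by
position then id, making the output deterministic.

**Matching (matching).**  PCA is run on per-SNP standardised dosages;
component signs are fixed (largest-magnitude loading positive) so scores are
reproducible across linear-algebra backends.  The pairing distance is the
variance-weighted L1 distance over the first six PCs,
`d(a,b) = Σ_j |a_j − b_j|·w_j` with `w_j` the variance-explained fractions;
"score differences" rather than eigenvalue differences are used because
eigenvalues are per-component constants and carry no per-individual
information.  An L2 option exists behind a flag.  Matching is greedy — the
smaller cohort is visited in random order, each individual taking the
nearest unmatched partner — restarted 10 times with the best total kept.
Optimal bipartite assignment is deliberately *not* the default; it serves
only as a test oracle.  A pair-distance cutoff is available but has no
default: its scale depends on score units and is dataset-specific.
Residual stratification is quantified by λ_gc = median(χ²)/0.4549 over
per-SNP allelic 1-df chi-square statistics.  Because subsetting to matched
pairs can leave panel SNPs monomorphic within a cohort, the pipeline
re-applies the SNP filters to the matched pairs before any scan.

**Scans and meta-test (het_stats).**  Each SNP is tested with Fisher's exact
test (FET) on the het vs minor-hom table ("Dd/DD"), the het vs major-hom
table ("Dd/dd"), and the allele-count table ("D/d"); a logistic-regression
variant with PC covariates is available for the allelic test.  The scan
engine is a vectorised minlike FET (conditional hypergeometric likelihood
via log-gamma, chunked); it is verified against `scipy.stats.fisher_exact`
and an exact-rational enumeration oracle.  Direction counts of nominally
significant SNPs at α ∈ {0.05, 0.01, 0.001} are compared to a fair coin with
the two-sided *exact* binomial test.  The exact (rather than
normal-approximate) convention was fixed because it reproduces the published
worked examples to their printed precision: (3855, 3547) → 3.6e-04,
(728, 581) → 5.4e-05, (458, 362) → 9.0e-04.  Whole-distribution cohort
comparisons use the Wilcoxon signed-rank test on per-SNP paired differences
(the standard paired analogue of the rank-sum test): zero differences
dropped, exact enumeration for ≤ 25 untied differences, otherwise the
normal approximation with continuity correction.  Stratified comparisons
(default MAF bins [0.01,0.05), [0.05,0.1), [0.1,0.25), [0.25,0.5]; or an
annotation key) report cohort means ± SE with SNPs as units and apply
Benjamini–Hochberg FDR across the strata of one analysis.

**Individual heterozygosity (individual_het).**  The rate is the proportion
of heterozygous sites on a fixed panel (default noncoding, combined
MAF > 0.1; a MAF > 0.25 panel mirrors the robustness variant).  With no
missing calls and a shared panel no standardisation is needed.  The
permutation null redistributes each SNP column across the combined cohorts
and records the pseudo-cohort mean rate.  Since only the mean enters the
null, the heterozygote count landing in a random nA-subset of a column with
h heterozygotes is exactly Hypergeometric(nA+nB, h, nA); the implementation
samples that law directly — identical in distribution to permuting the full
column, and orders of magnitude cheaper.  Empirical p-values use the
add-one convention (1 + #{null ≥ obs})/(n_perm + 1), so the smallest
achievable value at 10,000 permutations is ~1e-4 and p is never zero.  Both
one-sided p's are reported per cohort.

**Survival (survival).**  The Charlson 10-year survival probability is
`Z = 0.983^exp(0.9(A+C))` with age points A (≤40 → 0; then one point per
decade band to 71–80 → 4; undefined above 80, such records are excluded) and
comorbidity points C summed over the fixed 16-family condition catalogue
(severity variants — diabetes with end-organ damage, metastatic solid
tumor, moderate/severe liver disease — are distinct, mutually exclusive
ids).  Fractional ages are floored before banding since the bands are
stated in whole years.  `Z` underflows double precision beyond A+C ≈ 12;
`charlson_log_probability` provides the log-scale value, on which the
strict monotone decrease is representable over the whole grid.  The
association model is OLS: `10ySP ~ HetRate + age + comorbidity + gender +
PC1..PC5`, pooled and per gender (the gender indicator is dropped in
single-gender fits).  Comorbidity C is kept as its own predictor even
though Z is a function of A and C — the literal model specification — and
the resulting collinearity is reported, not resolved.  Classical OLS
t-test p-values are used, no robust errors.

**Enrichment (enrichment).**  Per cohort, the SNPs at or above the
0.90 empirical quantile of F (type-1/inverse-ECDF; ties at the threshold all
included) form the top set; SNPs topping both cohorts are removed from
both; the exclusive sets are mapped to genes (multi-gene SNPs contribute
each gene once; unannotated SNPs counted and dropped).  Over-representation
is the one-sided hypergeometric tail P(X ≥ k) against the background of all
genes harboring panel SNPs, with each gene set intersected with the
background first and BH q-values computed within each collection.  The
headline significance call is FDR < 0.1.  Ranked (GSEA-style) enrichment is
out of scope; the published analysis is plain over-representation.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical* structure the analysis assumes:
a shared panel of biallelic autosomal SNPs with MAF uniform on [0.01, 0.5]
(covering all four MAF bins evenly), per-cohort genotype laws controlled by
f (scalar or rules keyed on MAF range × annotation class, which reproduces
the "excess only at common SNPs of one cohort" pattern), optional
Balding–Nichols subpopulation structure with per-cohort mixing fractions,
annotation labels (noncoding/nonsynonymous, disease/trait association,
recessive/dominant gene lists), genes tiling the panel in fixed-size blocks,
gene sets with a plantable enrichment, and linked EHR records.  Infeasible
(p, f) combinations — f < −p/(1−p) makes the minor-homozygote probability
negative — are rejected, which is why strong excess can only be injected at
common SNPs.

It deliberately does **not** emulate: realistic LD (only a block-copy option
exists, enough to exercise the pruner), realistic site-frequency spectra,
genotyping-platform error, relatedness, or real comorbidity co-occurrence.
Passing tests therefore demonstrate that the *statistics* behave as claimed
under their assumed sampling models, not that the biological conclusions
transfer to any particular real dataset.

The EHR linkage: an "effect of heterozygosity on survival" is
implemented on the response scale — the observed survival outcome is
`Z(age, conditions) + β_gender · het_rate + ε`, with conditions drawn
independently of genotype.  This makes the true partial regression
coefficient of the het rate exactly β (the het rate is independent of every
other predictor), so parameter recovery is a well-posed check.  A
burden-mediated linkage (conditions depending on het rate) would be
absorbed by the comorbidity predictor and admit no closed-form true slope.

## Numerical and convention choices

- Two-sided exact p-values (Fisher, binomial) use the minlike convention —
  total probability of outcomes no more likely than the observed one — with
  a 1+1e-7 relative tolerance on the pmf comparison, matching mainstream
  implementations.
- Minor-allele ties at combined frequency exactly 0.5 designate the
  lexicographically smaller allele string as minor (order-independent).
- HWE enumeration and the vectorised FET work in log space; the FET scan is
  chunked to bound memory.
- Greedy matching, LD pruning and top-decile selection all carry explicit
  deterministic tie-break rules (documented at the function level).
- Per-stage seeds derive from the global seed keyed by stage *name*, so
  enabling or disabling one stage never reshuffles another's randomness.

## Study conditions used by the test suite and acceptance script

Replicated checks run at these fixed sizes (the package's own replication
choices): null-panel calibration at 426 per cohort × 5,000 SNPs across 200
replicates (60 in the acceptance script); signal recovery (f = −0.03 at
MAF ≥ 0.25 in cohort B) at 426 × 4,000 across 100 replicates; permutation
recovery with 1,000 permutations across 50 replicates; matching efficacy at
150 vs 450 individuals (cohort B an even two-subpopulation mixture,
F_ST = 0.01) × 6,000 SNPs across 50 replicates; survival recovery at
n = 359 (β = 11.92 pooled; 21.78 male-only) across 200 replicates.

Two calibration facts are worth stating plainly.  First, the exact FET is
conservative on discrete tables: the measured null rejection rate at
α = 0.05 is ≈ 0.035–0.039 for this design, so a check demanding the nominal
0.05 within binomial error fails by construction for any exact conditional
test (a mid-p variant would be closer to nominal but is intentionally not
used).  The binomial direction meta-test, by contrast, holds its level.
Second, with BH-FDR across four MAF strata of which three are true nulls,
the probability that *no* null stratum is flagged is ≈ 0.93, so demanding
"only the signal stratum flagged" in ≥ 90% of replicates operates close to
its theoretical ceiling.

## Known limitations

- The pipeline consumes user-supplied annotation tables and GMT files; it
  does not fetch GWAS catalogues, Mendelian-gene lists, pathogenicity
  scores or pathway databases, and performs no variant calling or admixture
  estimation.
- Hard-call dosages only; no imputation uncertainty, no indels, no
  haplotype-phase information (LD r² is composite/dosage r²).
- Sample-level QC (call rate, relatedness, sex checks) is assumed done
  upstream.
- The Charlson catalogue is frozen to one published variant of the index;
  other published revisions weight renal/liver disease differently and are
  intentionally not merged.
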
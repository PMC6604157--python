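"""Two-cohort genotype, annotation, gene-set and EHR simulator.

The generator emulates the study design every downstream stage assumes: two
cohorts of equal size (default 426 individuals each, matching a 1:1
genetically matched design) typed on a shared biallelic autosomal SNP panel,
with per-SNP genotype frequencies controlled by an inbreeding-like
coefficient f.  For minor-allele frequency p the genotype law is

    P(het)       = 2p(1-p)(1-f)
    P(hom minor) = p^2     + p(1-p) f
    P(hom major) = (1-p)^2 + p(1-p) f

so f = 0 is exact Hardy-Weinberg equilibrium and f < 0 produces the
heterozygote excess the analysis is designed to detect.  f may be a single
scalar per cohort or a set of rules keyed on MAF range and annotation class,
which lets a simulation inject excess only at, say, common SNPs of one
cohort.

Ancestry structure is optional: with ``fst`` set, subpopulation allele
frequencies are drawn around the ancestral frequency under the
Balding-Nichols model (a Beta law with mean p and variance fst * p(1-p)),
and each cohort may mix subpopulations in different proportions - the
scenario that inflates association statistics and that genetic matching is
meant to repair.

Linked EHR records carry age, gender and Charlson-catalogue conditions.  A
nonzero linkage coefficient adds beta * het_rate (plus Gaussian noise) to
the Charlson survival response so that regression recovery is testable
against a known slope; conditions themselves are drawn independently of the
genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, GeneSetCollection, _minor_recode
from . import survival as _survival


@dataclass
class FRule:
    """Inbreeding-like coefficient for SNPs in a MAF range / annotation class."""
    f: float
    maf_min: float = 0.0
    maf_max: float = 0.5
    annotation_class: str | None = None


@dataclass
class AnnotationFractions:
    nonsynonymous: float = 0.05      # remainder is noncoding
    disease_associated: float = 0.03
    trait_associated: float = 0.03
    recessive_genes: float = 0.05    # fractions of genes on each Mendelian list
    dominant_genes: float = 0.05


@dataclass
class EhrParams:
    age_range: tuple[int, int] = (51, 80)
    female_fraction: float = 0.5
    condition_prevalence: float = 0.08   # per condition family
    severe_variant_fraction: float = 0.3
    het_linkage_beta: float | dict[str, float] = 0.0
    noise_sd: float = 0.03


@dataclass
class SimConfig:
    n_per_cohort: int = 426
    n_snps: int = 20_000
    maf_range: tuple[float, float] = (0.01, 0.5)
    f_cohort: dict[str, float | list[FRule]] = field(
        default_factory=lambda: {"A": 0.0, "B": 0.0})
    fst: float | None = None
    subpop_fractions: dict[str, tuple[float, float]] | None = None
    annotation_fractions: AnnotationFractions = field(default_factory=AnnotationFractions)
    gene_size: int = 5                    # SNPs per synthetic gene tile
    chrom: str = "6"
    pos_start: int = 1
    pos_spacing: int = 1000
    mhc_like_interval: tuple[int, int] | None = None
    #: fraction of SNPs whose right neighbour becomes a noisy copy — a crude
    #: stand-in for linkage disequilibrium, just enough to exercise pruning
    ld_copy_fraction: float = 0.0
    ld_copy_noise: float = 0.05
    ehr: EhrParams = field(default_factory=EhrParams)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("MAF range must lie within (0, 0.5]")
        if self.n_per_cohort < 1 or self.n_snps < 1:
            raise ValueError("cohort and panel sizes must be positive")
        if len(self.f_cohort) != 2:
            raise ValueError("exactly two cohorts required")
        if self.fst is not None and not 0 < self.fst < 1:
            raise ValueError("fst must lie in (0, 1)")
        if self.subpop_fractions is not None and self.fst is None:
            raise ValueError("subpopulation structure requires fst")


def _f_values(rules, maf: np.ndarray, annotation: np.ndarray) -> np.ndarray:
    if np.isscalar(rules):
        return np.full(maf.shape, float(rules))
    f = np.zeros(maf.shape)
    for rule in rules:
        sel = (maf >= rule.maf_min) & (maf <= rule.maf_max)
        if rule.annotation_class is not None:
            sel &= annotation == rule.annotation_class
        f[sel] = rule.f
    return f


def _genotype_probs(p: np.ndarray, f: np.ndarray):
    het = 2 * p * (1 - p) * (1 - f)
    hom_minor = p ** 2 + p * (1 - p) * f
    hom_major = (1 - p) ** 2 + p * (1 - p) * f
    bad = (het < 0) | (het > 1) | (hom_minor < 0) | (hom_major < 0)
    if bad.any():
        j = int(np.argmax(bad))
        raise ValueError(
            f"invalid genotype law at SNP {j}: p={p.flat[j]:.4f}, f={f.flat[j]:.4f}")
    return hom_minor, het


def _balding_nichols(rng, p: np.ndarray, fst: float) -> np.ndarray:
    shape = (1 - fst) / fst
    draw = rng.beta(p * shape, (1 - p) * shape)
    return np.clip(draw, 1e-4, 1 - 1e-4)


def simulate_cohort_pair(config: SimConfig):
    """Simulate the two-cohort design; returns (GenotypeMatrix, SnpTable, SampleTable).

    Deterministic given ``config.seed``.  Dosages are recoded to count the
    combined-cohort minor allele, so the returned matrix already satisfies
    the package-wide convention.
    """
    rng = np.random.default_rng(config.seed)
    cohorts = list(config.f_cohort)
    n, m = config.n_per_cohort, config.n_snps
    af = config.annotation_fractions

    maf = rng.uniform(*config.maf_range, size=m)
    annotation = np.where(rng.random(m) < af.nonsynonymous,
                          "nonsynonymous", "noncoding").astype(object)
    assoc = rng.random(m)
    category = np.where(assoc < af.disease_associated, "disease",
                        np.where(assoc < af.disease_associated + af.trait_associated,
                                 "trait", "none")).astype(object)
    n_genes = int(np.ceil(m / config.gene_size))
    gene_of_snp = np.repeat([f"GENE{i + 1:05d}" for i in range(n_genes)],
                            config.gene_size)[:m]
    gene_names = pd.unique(gene_of_snp)
    lists = rng.random(len(gene_names))
    gene_list = np.where(lists < af.recessive_genes, "recessive",
                         np.where(lists < af.recessive_genes + af.dominant_genes,
                                  "dominant", "")).astype(object)
    gene_list_of_snp = pd.Series(gene_list, index=gene_names)[gene_of_snp].to_numpy()

    positions = config.pos_start + config.pos_spacing * np.arange(m)
    snps = pd.DataFrame({
        "snp_id": [f"snp{j + 1:06d}" for j in range(m)],
        "chrom": config.chrom, "pos": positions,
        "ref": "A", "alt": "C",
        "annotation_class": annotation, "gene": gene_of_snp,
        "association_category": category, "gene_lists": gene_list_of_snp,
    })

    if config.subpop_fractions is not None:
        subpop_freqs = [_balding_nichols(rng, maf, config.fst) for _ in range(2)]
    dosage_blocks, sample_ids, labels, subpops = [], [], [], []
    for cohort in cohorts:
        if config.subpop_fractions is not None:
            frac = config.subpop_fractions[cohort]
            membership = rng.choice(2, size=n, p=np.asarray(frac) / np.sum(frac))
        elif config.fst is not None:
            membership = np.zeros(n, dtype=int)
        else:
            membership = None
        if config.fst is not None and config.subpop_fractions is None:
            p_cohort = _balding_nichols(rng, maf, config.fst)
        else:
            p_cohort = maf
        f = _f_values(config.f_cohort[cohort], maf, annotation)
        block = np.empty((n, m), dtype=np.int8)
        if membership is None or config.subpop_fractions is None:
            hom_minor, het = _genotype_probs(p_cohort, f)
            u = rng.random((n, m))
            block[:] = np.where(u < hom_minor, 2,
                                np.where(u < hom_minor + het, 1, 0))
        else:
            for s in (0, 1):
                rows = membership == s
                hom_minor, het = _genotype_probs(subpop_freqs[s], f)
                u = rng.random((int(rows.sum()), m))
                block[rows] = np.where(u < hom_minor, 2,
                                       np.where(u < hom_minor + het, 1, 0))
        dosage_blocks.append(block)
        sample_ids += [f"{cohort}{i + 1:04d}" for i in range(n)]
        labels += [cohort] * n
        subpops += (list(membership) if membership is not None else [0] * n)

    dosage = np.concatenate(dosage_blocks, axis=0)
    if config.ld_copy_fraction > 0:
        sources = np.where(rng.random(m - 1) < config.ld_copy_fraction)[0]
        for j in sources:
            copy = dosage[:, j].copy()
            flips = rng.random(len(copy)) < config.ld_copy_noise
            copy[flips] = rng.integers(0, 3, int(flips.sum()))
            dosage[:, j + 1] = copy
    dosage, snps = _minor_recode(dosage, snps)
    genos = GenotypeMatrix(dosage, sample_ids,
                           np.array(labels, dtype=object), list(snps["snp_id"]))
    samples = pd.DataFrame({"sample_id": sample_ids, "cohort": labels,
                            "subpop": subpops})
    return genos, snps, samples


def simulate_gene_sets(snp_table: pd.DataFrame, n_sets: int = 20,
                       set_size: int = 30, enriched_genes=(),
                       enrichment: float = 0.0, seed: int = 0) -> GeneSetCollection:
    """Random gene sets over the synthetic gene universe.

    The first set draws a fraction ``enrichment`` of its members from
    ``enriched_genes`` (e.g. genes tiling heterozygote-excess SNPs), giving
    the over-representation test a planted positive.
    """
    rng = np.random.default_rng(seed)
    universe = list(pd.unique(snp_table["gene"]))
    enriched = [g for g in enriched_genes if g in set(universe)]
    sets: dict[str, list[str]] = {}
    for i in range(n_sets):
        if i == 0 and enrichment > 0 and enriched:
            n_hit = min(int(round(enrichment * set_size)), len(enriched))
            hits = list(rng.choice(enriched, size=n_hit, replace=False))
            rest_pool = [g for g in universe if g not in set(hits)]
            rest = list(rng.choice(rest_pool, size=set_size - n_hit, replace=False))
            sets[f"GS{i + 1:03d}"] = hits + rest
        else:
            sets[f"GS{i + 1:03d}"] = list(
                rng.choice(universe, size=min(set_size, len(universe)),
                           replace=False))
    return GeneSetCollection("synthetic", sets)


def simulate_ehr(samples: pd.DataFrame, het_rates: pd.Series,
                 config: SimConfig) -> pd.DataFrame:
    """EHR-like records (age, gender, Charlson conditions) linked to het rates.

    Returns a frame with ``sample_id``, ``age``, ``gender``, ``conditions``
    (semicolon-joined catalogue ids) and ``ten_year_survival``, the Charlson
    survival probability plus the linkage term
    ``beta[gender] * het_rate`` and Gaussian noise.
    """
    p = config.ehr
    lo, hi = p.age_range
    if not 41 <= lo <= hi <= 80:
        raise ValueError("EHR ages must lie within [41, 80]")
    rng = np.random.default_rng(config.seed + 104729)
    ids = list(samples["sample_id"])
    n = len(ids)
    ages = rng.integers(lo, hi + 1, size=n)
    genders = np.where(rng.random(n) < p.female_fraction, "female", "male")

    conditions = []
    for _ in range(n):
        present = [fam for fam in _survival.CONDITION_FAMILIES
                   if rng.random() < p.condition_prevalence]
        record = []
        for fam in present:
            variants = next((v for v in _survival.SEVERITY_FAMILIES.values()
                             if fam in v), (fam,))
            if len(variants) > 1 and rng.random() < p.severe_variant_fraction:
                record.append(variants[1])
            else:
                record.append(fam)
        conditions.append(";".join(record))

    ehr = pd.DataFrame({"sample_id": ids, "age": ages, "gender": genders,
                        "conditions": conditions})
    scored = _survival.score_ehr(ehr)
    beta = (p.het_linkage_beta if isinstance(p.het_linkage_beta, dict)
            else {"male": p.het_linkage_beta, "female": p.het_linkage_beta})
    rate = het_rates.reindex(ids).to_numpy(dtype=float)
    if np.isnan(rate).any():
        raise ValueError("missing heterozygosity rate for some samples")
    slope = np.array([beta.get(g, 0.0) for g in genders])
    ehr["ten_year_survival"] = (scored["charlson_z"].to_numpy()
                                + slope * rate
                                + rng.normal(0, p.noise_sd, size=n))
    return ehr
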
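"""Readers and writers for the file formats the pipeline touches.

Genotypes travel as hard-call minor-allele dosages in {0, 1, 2}.  Two on-disk
dialects are supported: a minimal VCF v4.x subset (GT field only, biallelic
SNPs) and a TSV dialect with one SNP per row and one column per sample.
Gene sets use the standard GMT layout; stage outputs are plain TSV.

The in-memory convention is fixed here once and shared by every stage: the
stored dosage counts copies of the *minor* allele, where "minor" is decided on
the cohorts combined.  A site whose designated allele ends up with combined
frequency above 0.5 is recoded (alleles swapped, dosages complemented); an
exact 0.5 tie designates the lexicographically smaller allele string as minor
so the outcome does not depend on input order.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

SNP_TABLE_COLUMNS = [
    "snp_id", "chrom", "pos", "ref", "alt",
    "annotation_class", "gene", "association_category", "gene_lists",
]


class ParseError(ValueError):
    """Raised when an input file does not conform to its declared dialect."""


@dataclass
class GenotypeMatrix:
    """Samples x SNPs hard-call minor-allele dosage matrix with cohort labels.

    ``dosage[i, j]`` is the number of minor-allele copies sample ``i`` carries
    at SNP ``j`` (``MISSING`` = -1 marks a missing hard call; QC removes
    those sites).  ``cohort_labels`` holds one of at most two cohort names per
    sample.
    """

    dosage: np.ndarray
    sample_ids: list[str]
    cohort_labels: np.ndarray
    snp_ids: list[str]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.cohort_labels = np.asarray(self.cohort_labels, dtype=object)
        if self.dosage.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        if len(self.cohort_labels) != len(self.sample_ids):
            raise ValueError("one cohort label required per sample")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def cohorts(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.cohort_labels:
            seen.setdefault(str(c))
        return list(seen)

    def cohort_mask(self, cohort: str) -> np.ndarray:
        mask = self.cohort_labels == cohort
        if not mask.any():
            raise KeyError(f"no samples labelled {cohort!r}")
        return mask

    def genotype_counts(self, cohort: str | None = None) -> np.ndarray:
        """Per-SNP (n_hom_minor, n_het, n_hom_major) counts, shape (n_snps, 3).

        Missing calls are not counted in any class.
        """
        d = self.dosage if cohort is None else self.dosage[self.cohort_mask(cohort)]
        return np.stack(
            [(d == 2).sum(axis=0), (d == 1).sum(axis=0), (d == 0).sum(axis=0)],
            axis=1,
        )

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        index = {s: j for j, s in enumerate(self.snp_ids)}
        cols = [index[s] for s in snp_ids]
        return GenotypeMatrix(
            self.dosage[:, cols], list(self.sample_ids),
            self.cohort_labels.copy(), list(snp_ids),
        )

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return GenotypeMatrix(
            self.dosage[rows], list(sample_ids),
            self.cohort_labels[rows].copy(), list(self.snp_ids),
        )


@dataclass
class GeneSetCollection:
    name: str
    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for set_name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {set_name!r} is empty")


def _minor_recode(dosage: np.ndarray, snps: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Recode dosages so they count the combined-cohort minor allele.

    ``dosage`` counts ALT on entry.  Ties at frequency exactly 0.5 keep the
    lexicographically smaller allele string as the designated minor allele.
    """
    snps = snps.reset_index(drop=True).copy()
    valid = dosage != MISSING
    with np.errstate(invalid="ignore"):
        alt_freq = np.where(
            valid.sum(axis=0) > 0,
            np.where(valid, dosage, 0).sum(axis=0) / (2.0 * np.maximum(valid.sum(axis=0), 1)),
            0.0,
        )
    ref = snps["ref"].to_numpy()
    alt = snps["alt"].to_numpy()
    flip = (alt_freq > 0.5) | ((alt_freq == 0.5) & (ref < alt))
    if flip.any():
        cols = np.where(flip)[0]
        block = dosage[:, cols]
        block[block != MISSING] = 2 - block[block != MISSING]
        dosage[:, cols] = block
        snps.loc[flip, ["ref", "alt"]] = snps.loc[flip, ["alt", "ref"]].to_numpy()
    return dosage, snps


def _normalise_cohorts(sample_ids: list[str], cohorts) -> np.ndarray:
    if cohorts is None:
        return np.array(["A"] * len(sample_ids), dtype=object)
    if isinstance(cohorts, (str, os.PathLike)):
        table = pd.read_csv(cohorts, sep="\t", dtype=str)
        cohorts = dict(zip(table.iloc[:, 0], table.iloc[:, 1]))
    missing = [s for s in sample_ids if s not in cohorts]
    if missing:
        raise ParseError(f"no cohort label for samples: {missing[:5]}")
    return np.array([cohorts[s] for s in sample_ids], dtype=object)


def read_genotypes(path, dialect: str = "vcf", cohorts=None):
    """Read a genotype file into (GenotypeMatrix, SnpTable).

    Parameters
    ----------
    dialect
        ``"vcf"`` (GT-only VCF v4.x subset, plain or bgzipped) or ``"tsv"``
        (header row of sample ids, one SNP per row).
    cohorts
        Mapping sample id -> cohort name, or path to a two-column TSV with a
        header.  ``None`` labels every sample cohort ``"A"``.

    Multiallelic or non-SNP records are rejected; their count is returned in
    the SnpTable's ``attrs["n_rejected"]``.
    """
    if dialect == "vcf":
        genos, snps = _read_vcf(os.fspath(path))
    elif dialect == "tsv":
        genos, snps = _read_tsv_genotypes(os.fspath(path))
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    genos.cohort_labels = _normalise_cohorts(genos.sample_ids, cohorts)
    return genos, snps


def _read_vcf(path: str):
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise ParseError(f"{path}: VCF has no sample columns")
    rows, records, n_rejected = [], [], 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_rejected += 1
            continue
        gt = np.asarray(var.gt_types, dtype=np.int8)  # 0 hom-ref, 1 het, 2 hom-alt, 3 missing
        gt[gt == 3] = MISSING
        rows.append(gt)
        records.append((var.ID or f"{var.CHROM}:{var.POS}", str(var.CHROM),
                        int(var.POS), var.REF, var.ALT[0]))
    if not rows:
        raise ParseError(f"{path}: no biallelic SNP records")
    dosage = np.stack(rows, axis=1)
    snps = pd.DataFrame(records, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    for col in ("annotation_class", "gene", "association_category", "gene_lists"):
        snps[col] = ""
    dosage, snps = _minor_recode(dosage, snps)
    snps.attrs["n_rejected"] = n_rejected
    genos = GenotypeMatrix(dosage, sample_ids,
                           np.array(["A"] * len(sample_ids), dtype=object),
                           list(snps["snp_id"]))
    return genos, snps


_TSV_FIXED = ["snp_id", "chrom", "pos", "ref", "alt"]


def _read_tsv_genotypes(path: str):
    table = pd.read_csv(path, sep="\t", dtype=str)
    if list(table.columns[:5]) != _TSV_FIXED:
        raise ParseError(
            f"{path}: TSV genotype header must start with {_TSV_FIXED}, "
            f"got {list(table.columns[:5])}"
        )
    annotation_cols = [c for c in ("annotation_class", "gene",
                                   "association_category", "gene_lists")
                       if c in table.columns]
    sample_ids = [c for c in table.columns[5:] if c not in annotation_cols]
    if not sample_ids:
        raise ParseError(f"{path}: no sample columns")
    keep = (table["ref"].str.len() == 1) & (table["alt"].str.len() == 1)
    n_rejected = int((~keep).sum())
    table = table[keep].reset_index(drop=True)
    if table.empty:
        raise ParseError(f"{path}: no biallelic SNP records")
    try:
        dosage = table[sample_ids].apply(pd.to_numeric).to_numpy(dtype=np.int8).T
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric dosage entry ({exc})") from exc
    if not np.isin(dosage, [MISSING, 0, 1, 2]).all():
        raise ParseError(f"{path}: dosages must be in {{0,1,2}} or {MISSING}")
    snps = table[_TSV_FIXED].copy()
    snps["pos"] = snps["pos"].astype(int)
    for col in ("annotation_class", "gene", "association_category", "gene_lists"):
        snps[col] = table[col].fillna("") if col in table else ""
    dosage, snps = _minor_recode(dosage, snps)
    snps.attrs["n_rejected"] = n_rejected
    genos = GenotypeMatrix(dosage, sample_ids,
                           np.array(["A"] * len(sample_ids), dtype=object),
                           list(snps["snp_id"]))
    return genos, snps


def write_genotypes(genos: GenotypeMatrix, snps: pd.DataFrame, path,
                    dialect: str = "vcf") -> None:
    """Write genotypes in the named dialect (inverse of :func:`read_genotypes`)."""
    path = os.fspath(path)
    snps = snps.reset_index(drop=True)
    if dialect == "tsv":
        out = snps[_TSV_FIXED].copy()
        for col in ("annotation_class", "gene", "association_category", "gene_lists"):
            if col in snps:
                out[col] = snps[col]
        body = pd.DataFrame(genos.dosage.T, columns=genos.sample_ids)
        pd.concat([out, body], axis=1).to_csv(path, sep="\t", index=False)
        return
    if dialect != "vcf":
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genos.sample_ids) + "\n")
        for j, row in snps.iterrows():
            # on disk ALT is the minor allele, so stored dosage == ALT count
            calls = "\t".join(gt_map[int(d)] for d in genos.dosage[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.ref}\t{row.alt}"
                     f"\t.\tPASS\t.\tGT\t{calls}\n")


def write_cohorts(genos: GenotypeMatrix, path) -> None:
    pd.DataFrame({"sample_id": genos.sample_ids,
                  "cohort": genos.cohort_labels}).to_csv(path, sep="\t", index=False)


def read_gene_sets(path, name: str | None = None) -> GeneSetCollection:
    """Read a GMT file (set name, description, gene symbols per line)."""
    path = os.fspath(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has no genes")
            set_name, genes = fields[0], [g for g in fields[2:] if g]
            if not genes:
                raise ParseError(f"{path}:{lineno}: gene set {set_name!r} is empty")
            if set_name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {set_name!r}")
            sets[set_name] = genes
    if not sets:
        raise ParseError(f"{path}: empty GMT file")
    return GeneSetCollection(name or os.path.basename(path), sets)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(os.fspath(path), "w") as fh:
        for set_name, genes in collection.sets.items():
            fh.write("\t".join([set_name, "na", *genes]) + "\n")


def write_results(tables: dict[str, pd.DataFrame], out_dir) -> dict[str, str]:
    """Write each stage-output table as ``<name>.tsv`` under ``out_dir``."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    written = {}
    for table_name, table in tables.items():
        dest = os.path.join(out_dir, f"{table_name}.tsv")
        table.to_csv(dest, sep="\t", index=False)
        written[table_name] = dest
    return written
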
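"""Config-driven orchestration of the full heterozygosity analysis.

Stage order follows the analysis narrative: obtain genotypes (simulate or
ingest) -> QC -> optional LD pruning -> PCA + genetic matching -> per-SNP
heterozygosity statistics and genotype-ratio / allelic scans with the
binomial meta-test -> stratified comparisons -> individual heterozygosity
rate and its permutation null -> Charlson survival regression (when EHR data
is present) -> top-decile gene-set enrichment (when gene sets are present).

Every stage writes its tables as TSV under the output directory and records
(stage name, parameters, seed, output file hashes) in ``manifest.json``;
identical config + seed reproduces identical hashes.  Per-stage seeds are
derived from the global seed keyed by the stage *name*, so enabling or
disabling one stage never reshuffles the randomness of another.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
import zlib
from dataclasses import asdict, dataclass, field, is_dataclass

import numpy as np
import pandas as pd

from . import enrichment as _enrichment
from . import het_stats as _het_stats
from . import individual_het as _individual_het
from . import io_formats as _io
from . import matching as _matching
from . import survival as _survival
from . import synthetic_data as _synthetic
from .variant_qc import QcConfig, ld_prune, qc_filter

log = logging.getLogger("hetspan")


@dataclass
class RunConfig:
    out_dir: str
    seed: int
    sim: _synthetic.SimConfig | None = None
    geno_path: str | None = None
    geno_dialect: str = "vcf"
    cohort_path: str | None = None
    ehr_path: str | None = None
    gmt_path: str | None = None
    qc: QcConfig = field(default_factory=QcConfig)
    run_ld_prune: bool = False
    run_matching: bool = False
    pca_k: int = 10
    match_components: int = 6
    match_restarts: int = 10
    match_max_distance: float | None = None
    maf_edges: tuple[float, ...] = _het_stats.DEFAULT_MAF_EDGES
    rate_maf_min: float = 0.1
    n_perm: int = 10_000
    run_survival: bool = False
    top_decile_q: float = 0.10
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.geno_path is None):
            raise ValueError("exactly one of simulation config / genotype path required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "sim" in raw and raw["sim"] is not None:
            sim = dict(raw["sim"])
            if "annotation_fractions" in sim:
                sim["annotation_fractions"] = _synthetic.AnnotationFractions(
                    **sim["annotation_fractions"])
            if "ehr" in sim:
                sim["ehr"] = _synthetic.EhrParams(**sim["ehr"])
            if "f_cohort" in sim:
                sim["f_cohort"] = {
                    c: (v if np.isscalar(v)
                        else [_synthetic.FRule(**r) for r in v])
                    for c, v in sim["f_cohort"].items()}
            raw["sim"] = _synthetic.SimConfig(**sim)
        if "qc" in raw and raw["qc"] is not None:
            raw["qc"] = QcConfig(**raw["qc"])
        return cls(**raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage child seed keyed by stage name (stable under stage insertion)."""
    return int((global_seed * 2_654_435_761 + zlib.crc32(stage.encode())) % (2 ** 31))


def _sha256(path: str) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            digest.update(block)
    return digest.hexdigest()


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


class _Manifest:
    def __init__(self, out_dir: str, config: RunConfig):
        self.out_dir = out_dir
        self.entries: list[dict] = []
        self.config = config

    def record(self, stage: str, params: dict, files: dict[str, str],
               t0: float) -> None:
        self.entries.append({
            "stage": stage, "params": _jsonable(params),
            "outputs": {name: {"path": os.path.relpath(p, self.out_dir),
                               "sha256": _sha256(p)} for name, p in files.items()},
            "wall_seconds": round(time.time() - t0, 3),
        })
        self.flush()

    def flush(self) -> None:
        with open(os.path.join(self.out_dir, "manifest.json"), "w") as fh:
            json.dump({"config": _jsonable(self.config),
                       "stages": self.entries}, fh, indent=2)


def run_pipeline(config: RunConfig) -> dict:
    """Run every enabled stage; returns a result bundle of key objects."""
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), 20),
                        format="%(levelname)s %(name)s: %(message)s")
    os.makedirs(config.out_dir, exist_ok=True)
    manifest = _Manifest(config.out_dir, config)
    bundle: dict = {}
    try:
        _run_stages(config, manifest, bundle)
    except Exception as exc:
        manifest.entries.append({"stage": "ABORTED", "error": str(exc)})
        manifest.flush()
        raise
    return bundle


def _run_stages(config: RunConfig, manifest: _Manifest, bundle: dict) -> None:
    out = config.out_dir

    t0 = time.time()
    if config.sim is not None:
        sim = _synthetic.replace(config.sim, seed=stage_seed(config.seed, "simulate"))
        genos, snps, samples = _synthetic.simulate_cohort_pair(sim)
        files = _io.write_results({"snp_table": snps, "sample_table": samples}, out)
        _io.write_genotypes(genos, snps, os.path.join(out, "genotypes.tsv"), "tsv")
        files["genotypes"] = os.path.join(out, "genotypes.tsv")
        manifest.record("simulate", {"sim": sim}, files, t0)
    else:
        genos, snps = _io.read_genotypes(config.geno_path, config.geno_dialect,
                                         cohorts=config.cohort_path)
        samples = pd.DataFrame({"sample_id": genos.sample_ids,
                                "cohort": genos.cohort_labels})
        manifest.record("ingest", {"path": config.geno_path}, {}, t0)
    log.info("genotypes: %d samples x %d SNPs", genos.n_samples, genos.n_snps)

    t0 = time.time()
    panel, report = qc_filter(genos, snps, config.qc)
    files = _io.write_results({"qc_report": report.as_frame(),
                               "qc_panel": pd.DataFrame({"snp_id": panel})}, out)
    manifest.record("qc", {"qc": config.qc}, files, t0)
    log.info("qc: %d of %d SNPs retained", len(panel), genos.n_snps)

    if config.run_ld_prune:
        t0 = time.time()
        panel = ld_prune(genos, panel, snps, config.qc)
        files = _io.write_results(
            {"ld_panel": pd.DataFrame({"snp_id": panel})}, out)
        manifest.record("ld_prune", {"qc": config.qc}, files, t0)
        log.info("ld_prune: %d SNPs retained", len(panel))

    cohorts = genos.cohorts
    pca = None
    if config.run_matching or config.run_survival:
        t0 = time.time()
        pca = _matching.run_pca(genos, k=config.pca_k, panel=panel)
        scores = pd.DataFrame(pca.scores, index=pca.sample_ids,
                              columns=[f"PC{j + 1}" for j in range(pca.k)])
        files = _io.write_results(
            {"pc_scores": scores.rename_axis("sample_id").reset_index()}, out)
        manifest.record("pca", {"k": config.pca_k}, files, t0)

    if config.run_matching:
        t0 = time.time()
        ids = {c: [s for s, l in zip(genos.sample_ids, genos.cohort_labels)
                   if l == c] for c in cohorts}
        small, large = sorted(cohorts, key=lambda c: len(ids[c]))
        before = _matching.genomic_inflation(
            _het_stats.allelic_scan(genos, panel)["chi2"])
        pairs = _matching.greedy_match(
            pca, ids[small], ids[large], n_restarts=config.match_restarts,
            seed=stage_seed(config.seed, "match"),
            n_components=config.match_components)
        if config.match_max_distance is not None:
            pairs = _matching.filter_pairs(pairs, config.match_max_distance)
        matched_ids = pairs.ids(0) + pairs.ids(1)
        genos = genos.subset_samples(matched_ids)
        after = _matching.genomic_inflation(
            _het_stats.allelic_scan(genos, panel)["chi2"])
        pair_table = pd.DataFrame(pairs.pairs,
                                  columns=[small, large, "distance"])
        inflation = pd.DataFrame([
            {"stage": "before_matching", "lambda_gc": before.lambda_gc,
             "n_tests": before.n_tests},
            {"stage": "after_matching", "lambda_gc": after.lambda_gc,
             "n_tests": after.n_tests}])
        files = _io.write_results({"matched_pairs": pair_table,
                                   "inflation": inflation}, out)
        manifest.record("match", {"restarts": config.match_restarts,
                                  "components": config.match_components,
                                  "max_distance": config.match_max_distance},
                        files, t0)
        bundle["inflation"] = inflation
        log.info("match: %d pairs, lambda %0.3f -> %0.3f",
                 len(pairs), before.lambda_gc, after.lambda_gc)
        # SNP filters are re-applied to the matched pairs: subsetting samples
        # can leave panel SNPs monomorphic within a matched cohort
        t0 = time.time()
        panel, report = qc_filter(genos, snps, config.qc)
        files = _io.write_results(
            {"qc_report_matched": report.as_frame(),
             "qc_panel_matched": pd.DataFrame({"snp_id": panel})}, out)
        manifest.record("qc_matched", {"qc": config.qc}, files, t0)

    t0 = time.time()
    stats_table = _het_stats.het_stats_table(genos, panel)
    scans = {}
    tables = {"het_stats": stats_table}
    for mode in ("het_vs_hom_minor", "het_vs_hom_major"):
        scan = _het_stats.genotype_scan(genos, panel, mode=mode)
        scans[mode] = scan
        tables[f"scan_{mode}"] = scan
        tables[f"meta_{mode}"] = _het_stats.significant_count_comparison(
            scan, cohorts=tuple(cohorts))
    scan_allelic = _het_stats.allelic_scan(genos, panel)
    scans["allelic"] = scan_allelic
    tables["scan_allelic"] = scan_allelic
    tables["meta_allelic"] = _het_stats.significant_count_comparison(
        scan_allelic, cohorts=tuple(cohorts))
    for measure in ("MAF", "HET_O", "F"):
        strat = _het_stats.stratified_comparison(
            stats_table, _het_stats.StratificationScheme(maf_edges=config.maf_edges),
            measure=measure, cohorts=tuple(cohorts))
        tables[f"stratified_maf_{measure}"] = strat
    files = _io.write_results(tables, out)
    manifest.record("scan", {"maf_edges": config.maf_edges}, files, t0)
    bundle.update(stats_table=stats_table, scans=scans)

    t0 = time.time()
    rate_panel = _individual_het.select_rate_panel(
        stats_table, snps, maf_min=config.rate_maf_min)
    if rate_panel:
        rates = _individual_het.het_rate(genos, rate_panel)
        perm = _individual_het.permutation_null(
            genos, rate_panel, n_perm=config.n_perm,
            seed=stage_seed(config.seed, "permutation"))
        perm_table = pd.DataFrame([
            {"cohort": c, "observed_mean": perm.observed_means[c],
             "p_greater": perm.p_greater[c], "p_less": perm.p_less[c]}
            for c in perm.observed_means])
        files = _io.write_results(
            {"het_rates": rates.rates.rename_axis("sample_id").reset_index(),
             "permutation": perm_table}, out)
        manifest.record("hetrate", {"maf_min": config.rate_maf_min,
                                    "n_perm": config.n_perm}, files, t0)
        bundle.update(het_rates=rates, permutation=perm)
    else:
        log.warning("hetrate: empty panel at MAF > %.2f; stage skipped",
                    config.rate_maf_min)

    if config.run_survival:
        t0 = time.time()
        if config.ehr_path is not None:
            ehr = pd.read_csv(config.ehr_path, sep="\t", dtype={"conditions": str})
        elif config.sim is not None:
            ehr_seed = stage_seed(config.seed, "ehr")
            ehr = _synthetic.simulate_ehr(
                samples, bundle["het_rates"].rates,
                _synthetic.replace(config.sim, seed=ehr_seed))
        else:
            raise ValueError("survival stage needs an EHR table or simulation")
        pc_frame = None
        if pca is not None:
            pc_frame = pd.DataFrame(pca.scores[:, :5], index=pca.sample_ids,
                                    columns=[f"PC{j}" for j in range(1, 6)])
        reports = {s: _survival.regress_survival(
            ehr, bundle["het_rates"].rates, pc_frame, subset=s)
            for s in ("all", "male", "female")}
        rows = []
        for s, rep in reports.items():
            for predictor, row in rep.coefficients.iterrows():
                rows.append({"subset": s, "n": rep.n, "predictor": predictor,
                             "coef": row["coef"], "se": row["se"], "p": row["p"]})
        files = _io.write_results({"survival_regression": pd.DataFrame(rows)}, out)
        manifest.record("survival", {"ehr": config.ehr_path or "simulated"},
                        files, t0)
        bundle["survival"] = reports

    if config.gmt_path is not None:
        t0 = time.time()
        collection = _io.read_gene_sets(config.gmt_path)
        nonsyn = snps.loc[snps["annotation_class"] == "nonsynonymous", "snp_id"]
        coding = stats_table[stats_table["snp_id"].isin(set(nonsyn))]
        target = coding if len(coding) >= 10 else stats_table
        snp_to_gene = snps.set_index("snp_id")["gene"]
        tops = {c: _enrichment.select_top_decile(target, c, q=config.top_decile_q)
                for c in cohorts}
        sets = _enrichment.exclusive_sets(tops[cohorts[0]], tops[cohorts[1]],
                                          snp_to_gene, cohorts=tuple(cohorts))
        background = set(snp_to_gene.reindex(target["snp_id"]).dropna())
        tables = {}
        for c in cohorts:
            if sets.genes[c]:
                tables[f"enrichment_{c}"] = _enrichment.hypergeom_enrichment(
                    sets.genes[c], background, collection)
        files = _io.write_results(tables, out)
        manifest.record("enrich", {"q": config.top_decile_q}, files, t0)
        bundle["enrichment"] = tables


def main_from_yaml(path) -> dict:
    return run_pipeline(RunConfig.from_yaml(path))
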
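"""End-to-end orchestration: QC -> traits -> GWAS -> p-gain -> loci.

A single PipelineConfig carries every stage parameter (all defaulting to
the study protocol: inclusion at >= 5 detected metabolites, MAF >= 5%,
call rate >= 90%, HWE p >= 1e-6, LD pruning at r^2 = 0.5, 10 PCs, OLS
engine, suggestive screen at p < 1e-5, clumping at r^2 < 0.1). Every run
emits a provenance manifest sufficient to reproduce it byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io
from .association import run_gwas
from .loci import candidate_crossref, clump, count_independent_loci, loci_table, nearest_gene
from .pgain import classify, compute_thresholds
from .phenotypes import assemble_covariates, build_traits, detection_report, select_samples
from .qc import compute_grm, compute_pcs, compute_variant_stats, filter_variants, ld_prune
from .simulate import CANDIDATE_PATHWAY_GENES

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    vcf: str = ""
    metabolites: str = ""
    covariates: str = ""
    genes: str = ""
    outdir: str = "ratiogwas_out"
    min_detected: int = 5
    maf_min: float = 0.05
    call_rate_min: float = 0.90
    hwe_p_min: float = 1e-6
    prune_r2: float = 0.5
    prune_window: int = 50
    prune_step: int = 5
    n_pcs: int = 10
    engine: str = "ols"  # ols | lmm
    suggestive_p: float = 1e-5
    clump_r2: float = 0.1
    candidate_genes: list[str] = field(default_factory=lambda: list(CANDIDATE_PATHWAY_GENES))
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; emit TSVs, a manifest, and a summary table.

    Returns a dict bundle with the key in-memory objects and output
    paths. A stage failure propagates with the stage name attached.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        genotypes = io.read_vcf(config.vcf)
        panel = io.read_metabolites_tsv(config.metabolites)
        covariates_raw = io.read_covariates_tsv(config.covariates)
        gene_track = io.read_gene_track(config.genes) if config.genes else None

        stage = "sample_selection"
        panel = select_samples(panel, min_detected=config.min_detected)
        detection_report(panel).to_csv(outdir / "inclusion_report.tsv", sep="\t")
        shared = [s for s in genotypes.sample_ids if s in set(panel.sample_ids)]
        genotypes = genotypes.subset_samples(shared)
        panel = type(panel)(abundances=panel.abundances.loc[shared], meta=panel.meta)

        stage = "qc"
        stats = compute_variant_stats(genotypes)
        stats.to_csv(outdir / "variant_stats.tsv", sep="\t", index=False)
        genotypes_qc, qc_report = filter_variants(
            genotypes,
            stats,
            maf_min=config.maf_min,
            call_rate_min=config.call_rate_min,
            hwe_p_min=config.hwe_p_min,
        )
        logger.info("variant QC: %s", qc_report)
        no_indel, _ = filter_variants(
            genotypes_qc, maf_min=0, call_rate_min=0, hwe_p_min=0, drop_indels=True
        )
        pruned_idx = ld_prune(
            no_indel, r2_max=config.prune_r2,
            window=config.prune_window, step=config.prune_step,
        )
        pruned = no_indel.take_variants(pruned_idx)
        pruned.variants[["chrom", "pos", "id"]].to_csv(
            outdir / "pruned_variants.tsv", sep="\t", index=False
        )

        stage = "pcs_grm"
        pcs = compute_pcs(pruned, k=config.n_pcs)
        pcs.to_csv(outdir / "pcs.tsv", sep="\t")
        grm = None
        if config.engine == "lmm":
            grm = compute_grm(pruned)
            io.write_grm(grm, outdir / "cohort")

        stage = "traits"
        traits = build_traits(panel)
        covariates = assemble_covariates(covariates_raw.loc[shared], pcs)

        stage = "gwas"
        results = run_gwas(
            traits, genotypes_qc, covariates, mode=config.engine, grm=grm
        )
        io.write_summary_stats(results, genotypes_qc, outdir / "summary_stats.tsv")

        stage = "pgain"
        thresholds = compute_thresholds(len(traits.trait_ids))
        pgain_table = classify(results, thresholds, traits.descriptors)
        pgain_table.to_csv(
            outdir / "pgain.tsv", sep="\t", index=False, float_format="%.6g"
        )

        stage = "clump"
        loci = clump(
            pgain_table,
            genotypes_qc,
            r2_independence=config.clump_r2,
            suggestive_p=config.suggestive_p,
        )
        if gene_track is not None:
            loci = [nearest_gene(l, gene_track) for l in loci]
            loci = candidate_crossref(loci, config.candidate_genes)
        table = loci_table(loci)
        table.to_csv(outdir / "loci.tsv", sep="\t", index=False, float_format="%.6g")

        stage = "report"
        summary = _summary_table(table, results, genotypes_qc)
        summary.to_csv(outdir / "summary.tsv", sep="\t", index=False, float_format="%.4g")
        manifest = {
            "ratiogwas_version": __version__,
            "parameters": dataclasses.asdict(config),
            "thresholds": dataclasses.asdict(thresholds),
            "inputs": {
                k: {"path": str(p), "sha256": _sha256(p)}
                for k, p in {
                    "vcf": config.vcf,
                    "metabolites": config.metabolites,
                    "covariates": config.covariates,
                    "genes": config.genes,
                }.items()
                if p
            },
            "qc_report": qc_report,
            "n_samples": genotypes_qc.n_samples,
            "n_traits": len(traits.trait_ids),
            "n_pruned_variants": int(len(pruned_idx)),
            "n_associations": int(len(results)),
            "n_suggestive": int(pgain_table["suggestive"].sum()),
            "n_loci": len(loci),
            "n_independent_loci": count_independent_loci(loci),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err

    return {
        "genotypes": genotypes_qc,
        "traits": traits,
        "covariates": covariates,
        "results": results,
        "pgain": pgain_table,
        "loci": loci,
        "thresholds": thresholds,
        "manifest": manifest,
        "outdir": outdir,
    }


def _summary_table(
    loci: pd.DataFrame, results: pd.DataFrame, genotypes
) -> pd.DataFrame:
    """Human-readable per-locus summary: locus gene, trait, SNP, chr,
    pos, MAF, beta, p, p-gain (one row per clumped association)."""
    if loci.empty:
        return pd.DataFrame(
            columns=["locus", "trait", "snp", "chr", "pos", "maf", "beta", "p", "pgain"]
        )
    stats = compute_variant_stats(genotypes).set_index("id")
    betas = results.set_index(["trait", "variant"])["beta"]
    rows = []
    for _, l in loci.iterrows():
        rows.append(
            {
                "locus": l["nearest_genes"] or l["index_variant"],
                "trait": l["trait"],
                "snp": l["index_variant"],
                "chr": l["chrom"],
                "pos": l["pos"],
                "maf": stats.at[l["index_variant"], "maf"],
                "beta": betas.get((l["trait"], l["index_variant"]), float("nan")),
                "p": l["p"],
                "pgain": l["pgain"],
            }
        )
    return pd.DataFrame(rows).sort_values("p").reset_index(drop=True)
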
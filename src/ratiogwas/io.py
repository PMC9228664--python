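"""Readers and writers for the pipeline's file formats.

Genotypes travel as VCF v4.2 (GT field only; read through cyvcf2,
multi-allelic records skipped with a warning, half/unknown calls treated
as missing). Metabolite abundances and covariates are TSV with the
sample id in the first column; an empty metabolite cell means "not
detected", never zero. Gene tracks are BED (0-based half-open) or GFF3
("gene" features only, converted to BED coordinates by pyranges).
Summary statistics, variant stats and the GRM are whitespace TSV.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .loci import GeneTrack
from .phenotypes import MetabolitePanel
from .qc import GenotypeMatrix, RelationshipMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- VCF

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Load biallelic variants from a VCF into a dosage matrix.

    Multi-allelic records are skipped with a warning; genotypes other
    than diploid 0/0, 0/1, 1/1 are missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    rows = []
    dosage_cols = []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        alt = rec.ALT[0]
        gt = rec.gt_types.astype(float)
        gt[gt == 3] = np.nan
        dosage_cols.append(gt)
        rows.append(
            {
                "chrom": str(rec.CHROM),
                "pos": int(rec.POS),
                "id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                "ref": rec.REF,
                "alt": alt,
                "is_indel": len(rec.REF) != 1 or len(alt) != 1,
            }
        )
    if n_multi:
        warnings.warn(f"skipped {n_multi} multi-allelic records", stacklevel=2)
    if not rows:
        raise ValueError(f"no biallelic variants in {path}")
    return GenotypeMatrix(
        dosages=np.column_stack(dosage_cols),
        variants=pd.DataFrame(rows),
        sample_ids=sample_ids,
    )


_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Emit a minimal VCF v4.2 with GT only, one record per variant,
    positions in file order (caller guarantees sorted input)."""
    path = Path(path)
    contigs = list(dict.fromkeys(g.variants["chrom"].astype(str)))
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in contigs:
            length = int(g.variants.loc[g.variants["chrom"].astype(str) == c, "pos"].max()) + 1
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        for j, var in g.variants.iterrows():
            calls = [
                _GT_CODE.get(d, "./.") if np.isfinite(d) else "./."
                for d in g.dosages[:, j]
            ]
            fh.write(
                f"{var['chrom']}\t{var['pos']}\t{var['id']}\t{var['ref']}\t"
                f"{var['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


# ---------------------------------------------------------------- TSV

def read_metabolites_tsv(path: str | Path) -> MetabolitePanel:
    """Metabolite TSV: first column sample id, header of metabolite
    names; empty cells are non-detections."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[""])
    df = df.astype(float)
    df.index = df.index.astype(str)
    df.index.name = "sample"
    return MetabolitePanel(abundances=df)


def write_metabolites_tsv(panel: MetabolitePanel, path: str | Path) -> None:
    panel.abundances.to_csv(path, sep="\t", na_rep="", index_label="sample")


def read_covariates_tsv(path: str | Path) -> pd.DataFrame:
    """Covariates TSV: sample, age, sex (0/1)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "sample"
    return df


def write_covariates_tsv(covariates: pd.DataFrame, path: str | Path) -> None:
    covariates.to_csv(path, sep="\t", index_label="sample")


# ----------------------------------------------------------- gene tracks

def read_bed(path: str | Path) -> GeneTrack:
    """BED gene track (0-based half-open); needs at least 4 columns."""
    import pyranges as pr

    df = pr.read_bed(str(path)).df
    out = pd.DataFrame(
        {
            "name": df["Name"].astype(str),
            "chrom": df["Chromosome"].astype(str),
            "start": df["Start"].astype(int),
            "end": df["End"].astype(int),
            "strand": df["Strand"].astype(str) if "Strand" in df.columns else ".",
        }
    )
    return GeneTrack(genes=out)


def write_bed(track: GeneTrack, path: str | Path) -> None:
    bed = track.genes[["chrom", "start", "end", "name"]].copy()
    bed["score"] = 0
    bed["strand"] = track.genes["strand"]
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_gff3(path: str | Path) -> GeneTrack:
    """GFF3 gene track; only features of type 'gene' are used, with the
    Name (falling back to ID) attribute as the gene name. pyranges
    converts GFF3's 1-based closed intervals to BED convention."""
    import pyranges as pr

    df = pr.read_gff3(str(path)).df
    genes = df[df["Feature"] == "gene"]
    if genes.empty:
        raise ValueError(f"no 'gene' features in {path}")
    names = genes["Name"] if "Name" in genes.columns else pd.Series(np.nan, index=genes.index)
    if "ID" in genes.columns:
        names = names.fillna(genes["ID"])
    out = pd.DataFrame(
        {
            "name": names.astype(str),
            "chrom": genes["Chromosome"].astype(str),
            "start": genes["Start"].astype(int),
            "end": genes["End"].astype(int),
            "strand": genes["Strand"].astype(str) if "Strand" in genes.columns else ".",
        }
    )
    return GeneTrack(genes=out)


def read_gene_track(path: str | Path) -> GeneTrack:
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        return read_gff3(path)
    return read_bed(path)


# --------------------------------------------------------------- outputs

def write_grm(grm: RelationshipMatrix, prefix: str | Path) -> None:
    """GRM as whitespace TSV plus a sample-id list (``<prefix>.grm.tsv``,
    ``<prefix>.grm.ids``)."""
    prefix = Path(prefix)
    np.savetxt(f"{prefix}.grm.tsv", grm.values, delimiter="\t")
    Path(f"{prefix}.grm.ids").write_text("\n".join(grm.sample_ids) + "\n")


def read_grm(prefix: str | Path) -> RelationshipMatrix:
    values = np.loadtxt(f"{prefix}.grm.tsv", delimiter="\t", ndmin=2)
    ids = Path(f"{prefix}.grm.ids").read_text().splitlines()
    return RelationshipMatrix(values=values, sample_ids=ids, n_variants_used=-1)


def write_summary_stats(
    results: pd.DataFrame, genotypes: GenotypeMatrix, path: str | Path
) -> None:
    """Summary-statistics TSV: chrom, pos, id, ref, alt, trait, n, beta,
    se, p — fixed columns, one header line, p in scientific notation."""
    meta = genotypes.variants.set_index("id")
    out = results.copy()
    out["ref"] = out["variant"].map(meta["ref"])
    out["alt"] = out["variant"].map(meta["alt"])
    out = out.rename(columns={"variant": "id", "n_used": "n"})
    out[["chrom", "pos", "id", "ref", "alt", "trait", "n", "beta", "se", "p"]].to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def write_locuszoom(results: pd.DataFrame, trait: str, path: str | Path) -> None:
    """Two-column (id, p) export per trait for regional-plot tools."""
    sub = results[results["trait"] == trait]
    sub[["variant", "p"]].rename(columns={"variant": "MarkerName", "p": "P-value"}).to_csv(
        path, sep="\t", index=False
    )


def write_cohort(cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated cohort as VCF + TSVs + BED + config YAML.

    Round-trips losslessly through this module's readers (hard genotype
    calls, float-precision abundances, blank = missing).
    """
    from .simulate import config_to_yaml

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out_dir / "genotypes.vcf",
        "metabolites": out_dir / "metabolites.tsv",
        "covariates": out_dir / "covariates.tsv",
        "genes": out_dir / "genes.bed",
        "config": out_dir / "config.yaml",
    }
    write_vcf(cohort.genotypes, paths["vcf"])
    write_metabolites_tsv(cohort.panel, paths["metabolites"])
    write_covariates_tsv(cohort.covariates, paths["covariates"])
    write_bed(cohort.gene_track, paths["genes"])
    config_to_yaml(cohort.config, paths["config"])
    return paths
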
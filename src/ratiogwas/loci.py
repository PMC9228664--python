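"""Collapse suggestive associations into independent loci and annotate.

Clumping is the usual greedy index-variant scheme: repeatedly take the
smallest-p unassigned suggestive variant as an index and absorb every
unassigned variant correlated with it at r^2 at or above the
independence threshold (default 0.1, so index variants are mutually
independent at r^2 < 0.1). Clumps are formed per trait; a variant
suggestive for two traits yields two association records, while reported
locus counts union the index variants.

Annotation is purely local: nearest gene by distance to the interval
edge (strand-agnostic, distance 0 inside the gene, both genes on an
exact tie), then a case-insensitive cross-reference against a candidate
pathway gene list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qc import GenotypeMatrix, _r2_vectors

logger = logging.getLogger(__name__)


@dataclass
class GeneTrack:
    """Gene intervals in BED convention (0-based, half-open), sorted."""

    genes: pd.DataFrame  # columns: name, chrom, start, end, strand

    def __post_init__(self) -> None:
        required = {"name", "chrom", "start", "end"}
        missing = required - set(self.genes.columns)
        if missing:
            raise ValueError(f"gene track missing columns: {missing}")
        if "strand" not in self.genes.columns:
            self.genes = self.genes.assign(strand=".")
        if self.genes["name"].duplicated().any():
            raise ValueError("gene names must be unique")
        self.genes = self.genes.sort_values(["chrom", "start", "end"]).reset_index(
            drop=True
        )


@dataclass
class Locus:
    """One clumped association region for one trait."""

    index_variant: str
    trait: str
    chrom: str
    pos: int
    p: float
    members: list[str] = field(default_factory=list)
    pgain: float = float("nan")
    nearest_genes: list[str] = field(default_factory=list)
    gene_distance: int | None = None
    candidate_gene_hit: bool = False


def clump(
    results: pd.DataFrame,
    genotypes: GenotypeMatrix,
    r2_independence: float = 0.1,
    suggestive_p: float = 1e-5,
) -> list[Locus]:
    """Greedy clumping of suggestive associations into independent loci.

    ``results`` must carry trait, variant, chrom, pos and a p column
    (p_ratio accepted as an alias). Only rows with p < suggestive_p
    enter. Ties in p are broken by (chromosome, position). Every
    suggestive variant of a trait ends up in exactly one locus.
    """
    df = results.copy()
    if "p" not in df.columns and "p_ratio" in df.columns:
        df = df.rename(columns={"p_ratio": "p"})
    df = df[np.isfinite(df["p"]) & (df["p"] < suggestive_p)]
    var_index = {v: i for i, v in enumerate(genotypes.variants["id"])}

    loci: list[Locus] = []
    for trait, sub in df.groupby("trait", sort=True):
        sub = sub.sort_values(
            ["p", "chrom", "pos"], kind="stable"
        ).reset_index(drop=True)
        unassigned = list(sub.index)
        while unassigned:
            head = unassigned[0]
            index_row = sub.loc[head]
            idx_col = var_index[index_row["variant"]]
            members = [head]
            rest = []
            for k in unassigned[1:]:
                other = var_index[sub.loc[k, "variant"]]
                r2 = _r2_vectors(
                    genotypes.dosages[:, idx_col], genotypes.dosages[:, other]
                )
                if not np.isnan(r2) and r2 >= r2_independence:
                    members.append(k)
                else:
                    rest.append(k)
            unassigned = rest
            loci.append(
                Locus(
                    index_variant=str(index_row["variant"]),
                    trait=str(trait),
                    chrom=str(index_row["chrom"]),
                    pos=int(index_row["pos"]),
                    p=float(index_row["p"]),
                    pgain=float(index_row["pgain"]) if "pgain" in sub.columns else float("nan"),
                    members=[str(sub.loc[k, "variant"]) for k in members],
                )
            )
    return loci


def count_independent_loci(loci: list[Locus]) -> int:
    """Number of distinct index variants across traits (locus union)."""
    return len({locus.index_variant for locus in loci})


def _interval_distance(pos_1based: int, start0: int, end0: int) -> int:
    """Distance in bp from a 1-based variant position to a BED interval.

    The interval covers 1-based positions start0+1 .. end0; distance 0
    inside, otherwise the gap to the nearest edge.
    """
    first = start0 + 1
    last = end0
    if pos_1based < first:
        return first - pos_1based
    if pos_1based > last:
        return pos_1based - last
    return 0


def nearest_gene(locus: Locus, track: GeneTrack) -> Locus:
    """Annotate a locus with the gene(s) minimizing edge distance.

    Only genes on the index variant's chromosome are considered; exact
    distance ties report every tied gene. An empty chromosome leaves the
    locus unannotated with a warning.
    """
    sub = track.genes[track.genes["chrom"].astype(str) == str(locus.chrom)]
    if sub.empty:
        logger.warning(
            "no genes on chromosome %s; locus %s unannotated",
            locus.chrom,
            locus.index_variant,
        )
        locus.nearest_genes = []
        locus.gene_distance = None
        return locus
    dists = np.array(
        [
            _interval_distance(locus.pos, int(s), int(e))
            for s, e in zip(sub["start"], sub["end"])
        ]
    )
    best = int(dists.min())
    locus.nearest_genes = list(sub.loc[dists == best, "name"].astype(str))
    locus.gene_distance = best
    return locus


def candidate_crossref(loci: list[Locus], candidate_genes: list[str]) -> list[Locus]:
    """Flag loci whose nearest gene matches the candidate pathway list.

    Matching is case-insensitive exact name equality; an empty candidate
    list flags nothing.
    """
    wanted = {g.lower() for g in candidate_genes}
    for locus in loci:
        locus.candidate_gene_hit = any(
            g.lower() in wanted for g in locus.nearest_genes
        )
    return loci


def loci_table(loci: list[Locus]) -> pd.DataFrame:
    """Tidy per-locus summary for reporting."""
    return pd.DataFrame(
        [
            {
                "index_variant": l.index_variant,
                "trait": l.trait,
                "chrom": l.chrom,
                "pos": l.pos,
                "p": l.p,
                "pgain": l.pgain,
                "n_members": len(l.members),
                "members": ",".join(l.members),
                "nearest_genes": ",".join(l.nearest_genes),
                "gene_distance": l.gene_distance,
                "candidate_gene_hit": l.candidate_gene_hit,
            }
            for l in loci
        ]
    )
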
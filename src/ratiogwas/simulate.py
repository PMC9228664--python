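"""Synthetic cohort generator for ratio-trait metabolite GWAS.

Emulates the statistical structure of a drug-metabolite panel measured
on a non-targeted LC-MS platform in a genotyped population cohort:

* genotypes drawn under Hardy-Weinberg proportions on one synthetic
  autosome, with optional LD blocks induced by copy-with-mutation
  between adjacent variants;
* metabolite log-abundances built from a generative model
  ``log m_ij = mu_j + sum(genetic effects) + dilution_i + batch + eps``,
  where the per-sample dilution term absorbs dose and time-since-dose
  variability shared by every metabolite of a sample;
* run-day batch distortion followed by the platform's median-to-one
  normalization within each run-day block;
* limit-of-detection censoring: the lowest fraction of each metabolite's
  latent abundances is set missing (missing-not-at-random), with an MCAR
  mode for null-calibration experiments.

Default panel and detection fractions mirror a nine-metabolite
acetaminophen panel in which between 363 and 514 of 520 participants had
each metabolite detected.

Genetic effect archetypes
-------------------------
``direct``      adds beta * dosage to one metabolite.
``branch``      shifts the partition of a branching reaction: +beta to
                the first target and -beta to the second per alternate
                allele, so the log-ratio moves by 2*beta per allele
                (e.g. glucuronidation vs sulfation efficiency).
``conversion``  shifts a substrate->product step: -beta to the substrate
                (first target) and +beta to the product (second).
``dilution``    adds beta * dosage to every metabolite — a shared factor
                that cancels exactly in every pairwise ratio.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .phenotypes import MetabolitePanel
from .qc import GenotypeMatrix
from .loci import GeneTrack

logger = logging.getLogger(__name__)

#: Nine-metabolite acetaminophen panel with per-metabolite detection
#: counts out of 520 participants; CAS, LC/MS mode, retention index and
#: monoisotopic mass carried as descriptor metadata.
ACETAMINOPHEN_PANEL = pd.DataFrame(
    [
        ("4-acetamidophenol (paracetamol)", "103-90-2", "Neg", 2173.7, 150.05605, 497),
        ("4-acetamidophenyl glucuronide", "120595-80-4", "Neg", 1400.0, 326.08814, 510),
        ("2-methoxyacetaminophen glucuronide*", "53446-12-1", "Neg", 1633.0, 356.09870, 416),
        ("2-hydroxyacetaminophen sulfate*", "53446-14-3", "Neg", 1674.0, 246.00778, 497),
        ("2-methoxyacetaminophen sulfate*", "53446-13-2", "Neg", 1949.0, 260.02343, 405),
        ("4-acetaminophen sulfate", "10066-90-7", "Neg", 1792.0, 230.01287, 514),
        ("3-(N-acetyl-L-cystein-S-yl) acetaminophen", "52372-86-8", "Neg", 2094.0, 311.07072, 363),
        ("3-(methylthio) acetaminophen sulfate*", "78194-51-1", "Neg", 2265.0, 276.00059, 475),
        ("3-(cystein-S-yl) acetaminophen*", "53446-10-9", "Pos Early", 2420.0, 271.07471, 363),
    ],
    columns=["name", "cas", "lcms_mode", "retention_index", "mass", "n_detected_of_520"],
)

PANEL_COHORT_SIZE = 520

#: Genes of the acetaminophen metabolism pathway (UGT / SULT / CYP / GST
#: conjugation and oxidation families plus COMT) used as the default
#: candidate list for locus cross-referencing.
CANDIDATE_PATHWAY_GENES = [
    "UGT1A1", "UGT1A6", "UGT1A9", "UGT2B15", "UGT2B11", "UGT2B7",
    "SULT1A1", "SULT1A3", "SULT1E1", "SULT2A1",
    "CYP1A2", "CYP2E1", "CYP3A4", "CYP2D6", "CYP2C9", "CYP2C8",
    "CYP4B1", "CYP4A11",
    "GSTP1", "GSTM1", "GSTT1", "COMT", "NAT2", "ABCC2", "ABCG2",
]


@dataclass
class PlantedEffect:
    """A per-allele genetic effect on the natural-log abundance scale."""

    variant_index: int
    kind: str  # direct | branch | conversion | dilution
    target_metabolites: list[str] = field(default_factory=list)
    beta: float = 0.0

    def __post_init__(self) -> None:
        kinds = {"direct", "branch", "conversion", "dilution"}
        if self.kind not in kinds:
            raise ValueError(f"unknown effect kind {self.kind!r}; one of {kinds}")
        n = len(self.target_metabolites)
        if self.kind == "direct" and n != 1:
            raise ValueError("direct effect names exactly one metabolite")
        if self.kind in {"branch", "conversion"} and n != 2:
            raise ValueError(f"{self.kind} effect names exactly two metabolites")
        if self.kind == "dilution" and n != 0:
            raise ValueError("dilution affects all metabolites; leave targets empty")


@dataclass
class CovariateSpec:
    age_range: tuple[int, int] = (18, 76)
    female_fraction: float = 0.592


@dataclass
class SimulationConfig:
    """Cohort-level parameters; defaults reproduce the study conditions
    of the nine-metabolite panel (520 samples, run-day batches,
    detection fractions between 363/520 and 514/520)."""

    n_samples: int = PANEL_COHORT_SIZE
    n_variants: int = 200
    maf_spec: float | list[float] | None = None  # None: uniform(0.05, 0.5)
    seed: int = 0
    metabolite_names: list[str] = field(
        default_factory=lambda: list(ACETAMINOPHEN_PANEL["name"])
    )
    batch_count: int = 10
    batch_sd: float = 0.5
    lod_quantile: float | list[float] | None = None  # None: panel detection fractions
    effect_plan: list[PlantedEffect] = field(default_factory=list)
    covariate_spec: CovariateSpec = field(default_factory=CovariateSpec)
    # generative-model nuisance scales (natural-log units)
    residual_sd: float = 0.5
    dilution_sd: float = 1.0
    baseline_log_mean: float = 0.0
    # optional structure
    ld_block_size: int = 1  # 1 = independent variants
    ld_mutation_rate: float = 0.1
    genotype_missing_rate: float = 0.0
    missing_mechanism: str = "lod"  # lod (MNAR) | mcar
    position_spacing: int = 50_000
    chrom: str = "1"

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.n_variants <= 0:
            raise ValueError("n_variants must be positive")
        if self.missing_mechanism not in {"lod", "mcar"}:
            raise ValueError("missing_mechanism must be 'lod' or 'mcar'")
        mafs = self.resolved_mafs()
        if np.any((mafs <= 0) | (mafs > 0.5)):
            raise ValueError("allele frequencies must lie in (0, 0.5]")
        lod = self.resolved_lod_quantiles()
        if np.any((lod < 0) | (lod >= 1)):
            raise ValueError("lod_quantile must lie in [0, 1)")
        for eff in self.effect_plan:
            if not 0 <= eff.variant_index < self.n_variants:
                raise ValueError(f"effect references unknown variant {eff.variant_index}")
            unknown = set(eff.target_metabolites) - set(self.metabolite_names)
            if unknown:
                raise ValueError(f"effect references unknown metabolites {unknown}")

    def resolved_mafs(self) -> np.ndarray:
        if self.maf_spec is None:
            rng = np.random.default_rng([self.seed % (2**31), 101])
            return rng.uniform(0.05, 0.5, size=self.n_variants)
        arr = np.broadcast_to(
            np.asarray(self.maf_spec, dtype=float), (self.n_variants,)
        ).copy()
        return arr

    def resolved_lod_quantiles(self) -> np.ndarray:
        m = len(self.metabolite_names)
        if self.lod_quantile is None:
            table = ACETAMINOPHEN_PANEL.set_index("name")
            out = np.zeros(m)
            for j, name in enumerate(self.metabolite_names):
                if name in table.index:
                    out[j] = 1.0 - table.at[name, "n_detected_of_520"] / PANEL_COHORT_SIZE
            return out
        return np.broadcast_to(
            np.asarray(self.lod_quantile, dtype=float), (m,)
        ).copy()


@dataclass
class Cohort:
    """A complete simulated study: genotypes, metabolites, covariates,
    run-day batches, a toy gene track, and the pre-censoring latent
    abundances retained for validation."""

    config: SimulationConfig
    genotypes: GenotypeMatrix
    panel: MetabolitePanel
    covariates: pd.DataFrame
    batches: pd.Series
    gene_track: GeneTrack
    latent_abundances: pd.DataFrame


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed % (2**31), stream])


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw a samples x variants dosage matrix under HWE.

    Each variant's two alleles are independent Bernoulli(maf) draws, so
    genotype frequencies follow Hardy-Weinberg proportions exactly in
    expectation. When ``ld_block_size`` > 1, variants inside a block copy
    the previous variant's alleles and re-draw each allele with
    probability ``ld_mutation_rate``, preserving the marginal frequency
    while inducing correlation ~(1 - rate) per step. Positions are
    strictly increasing on a single synthetic autosome.
    """
    rng = _rng(config.seed, 0)
    n, v = config.n_samples, config.n_variants
    mafs = config.resolved_mafs()

    alleles = np.empty((n, 2, v), dtype=np.int8)
    for j in range(v):
        fresh = rng.random((n, 2)) < mafs[j]
        if config.ld_block_size > 1 and j % config.ld_block_size != 0:
            keep = rng.random((n, 2)) >= config.ld_mutation_rate
            alleles[:, :, j] = np.where(keep, alleles[:, :, j - 1], fresh)
        else:
            alleles[:, :, j] = fresh
    dosages = alleles.sum(axis=1).astype(float)

    if config.genotype_missing_rate > 0:
        mask = rng.random((n, v)) < config.genotype_missing_rate
        dosages[mask] = np.nan

    positions = config.position_spacing * np.arange(1, v + 1)
    width = len(str(v))
    variants = pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": positions,
            "id": [f"snp{j + 1:0{width}d}" for j in range(v)],
            "ref": "A",
            "alt": "G",
            "is_indel": False,
        }
    )
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(dosages=dosages, variants=variants, sample_ids=sample_ids)


def _apply_effects(
    config: SimulationConfig, genotypes: GenotypeMatrix, log_abund: np.ndarray
) -> None:
    """Add the planted per-allele genetic effects in place."""
    name_to_col = {m: j for j, m in enumerate(config.metabolite_names)}
    for eff in config.effect_plan:
        dosage = genotypes.dosages[:, eff.variant_index]
        dosage = np.nan_to_num(dosage, nan=float(np.nanmean(dosage)))
        term = eff.beta * dosage
        if eff.kind == "dilution":
            log_abund += term[:, None]
        elif eff.kind == "direct":
            log_abund[:, name_to_col[eff.target_metabolites[0]]] += term
        elif eff.kind == "branch":
            log_abund[:, name_to_col[eff.target_metabolites[0]]] += term
            log_abund[:, name_to_col[eff.target_metabolites[1]]] -= term
        elif eff.kind == "conversion":
            log_abund[:, name_to_col[eff.target_metabolites[0]]] -= term
            log_abund[:, name_to_col[eff.target_metabolites[1]]] += term


def _batch_assignment(config: SimulationConfig) -> np.ndarray:
    """Contiguous run-day blocks of near-equal size."""
    return np.minimum(
        np.arange(config.n_samples) * config.batch_count // config.n_samples,
        config.batch_count - 1,
    )


def simulate_metabolites(
    config: SimulationConfig, genotypes: GenotypeMatrix
) -> tuple[MetabolitePanel, pd.DataFrame]:
    """Generate the metabolite panel from the genotype matrix.

    Pipeline per the generative model: baseline + genetic effects +
    shared per-sample dilution + per-(run-day, metabolite) batch factor +
    Gaussian noise, all on the natural-log scale. Detection is then
    decided against the per-metabolite limit of detection (the lowest
    ``lod_quantile`` fraction of latent abundances is not detected), and
    finally each run-day block of detected values is registered so its
    median equals one — the order in which a real platform measures,
    detects, and normalizes.

    Returns the censored, normalized panel and the latent (pre-censoring,
    raw-scale) abundance table for validation.
    """
    if genotypes.n_samples != config.n_samples:
        raise ValueError("genotype and config sample counts differ")
    rng = _rng(config.seed, 1)
    n = config.n_samples
    m = len(config.metabolite_names)

    log_abund = np.full((n, m), config.baseline_log_mean, dtype=float)
    _apply_effects(config, genotypes, log_abund)
    if config.dilution_sd > 0:
        log_abund += rng.normal(0.0, config.dilution_sd, size=n)[:, None]
    batches = _batch_assignment(config)
    if config.batch_sd > 0:
        batch_factors = rng.normal(0.0, config.batch_sd, size=(config.batch_count, m))
        log_abund += batch_factors[batches]
    log_abund += rng.normal(0.0, config.residual_sd, size=(n, m))
    latent = np.exp(log_abund)

    lod = config.resolved_lod_quantiles()
    detected = np.ones((n, m), dtype=bool)
    if config.missing_mechanism == "lod":
        for j in range(m):
            if lod[j] > 0:
                detected[:, j] = latent[:, j] >= np.quantile(latent[:, j], lod[j])
    else:
        detected = rng.random((n, m)) >= lod[None, :]

    observed = np.where(detected, latent, np.nan)
    for b in range(config.batch_count):
        rows = batches == b
        if not rows.any():
            continue
        with warnings.catch_warnings():
            # a tiny block can have a metabolite entirely undetected
            warnings.simplefilter("ignore", category=RuntimeWarning)
            med = np.nanmedian(observed[rows], axis=0)
        observed[rows] /= np.where(np.isnan(med) | (med == 0), 1.0, med)

    index = pd.Index(genotypes.sample_ids, name="sample")
    panel = MetabolitePanel(
        abundances=pd.DataFrame(observed, index=index, columns=config.metabolite_names),
        meta=ACETAMINOPHEN_PANEL.copy(),
    )
    latent_df = pd.DataFrame(latent, index=index, columns=config.metabolite_names)
    return panel, latent_df


def simulate_covariates(config: SimulationConfig) -> pd.DataFrame:
    """Age (uniform over the configured range) and sex (1 = female)."""
    rng = _rng(config.seed, 2)
    lo, hi = config.covariate_spec.age_range
    return pd.DataFrame(
        {
            "age": rng.integers(lo, hi + 1, size=config.n_samples),
            "sex": (rng.random(config.n_samples) < config.covariate_spec.female_fraction).astype(int),
        },
        index=pd.Index([f"S{i + 1:04d}" for i in range(config.n_samples)], name="sample"),
    )


def toy_gene_track(config: SimulationConfig) -> GeneTrack:
    """A small gene track on the synthetic autosome.

    One candidate pathway gene is placed over each planted-effect
    variant (so candidate cross-referencing has true positives), and
    filler genes tile the rest of the chromosome.
    """
    archetype_gene = {
        "branch": "UGT2B15",
        "conversion": "COMT",
        "direct": "SULT1A1",
        "dilution": "CYP1A2",
    }
    genes: list[dict] = []
    used_names: set[str] = set()
    span = config.position_spacing
    for k, eff in enumerate(config.effect_plan):
        name = archetype_gene[eff.kind]
        if name in used_names:
            name = f"{name}_{k}"
        used_names.add(name)
        pos = span * (eff.variant_index + 1)
        genes.append(
            {
                "name": name,
                "chrom": config.chrom,
                "start": max(pos - span // 4, 0),
                "end": pos + span // 4,
                "strand": "+",
            }
        )
    chrom_len = span * (config.n_variants + 1)
    n_filler = max(4, config.n_variants // 25)
    for k in range(n_filler):
        start = int(chrom_len * (k + 0.5) / n_filler)
        genes.append(
            {
                "name": f"GENE{k + 1}",
                "chrom": config.chrom,
                "start": start,
                "end": start + span // 2,
                "strand": "-",
            }
        )
    return GeneTrack(genes=pd.DataFrame(genes))


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate every artifact of a study: fully deterministic per seed."""
    genotypes = simulate_genotypes(config)
    panel, latent = simulate_metabolites(config, genotypes)
    covariates = simulate_covariates(config)
    return Cohort(
        config=config,
        genotypes=genotypes,
        panel=panel,
        covariates=covariates,
        batches=pd.Series(_batch_assignment(config), index=panel.abundances.index, name="batch"),
        gene_track=toy_gene_track(config),
        latent_abundances=latent,
    )


def demo_config(seed: int = 0, n_samples: int = PANEL_COHORT_SIZE, n_variants: int = 200) -> SimulationConfig:
    """A compact end-to-end demonstration cohort.

    Plants the two headline pharmacogenetic archetypes: a branch effect
    (glucuronidation vs sulfation partition, UGT-like) and a conversion
    effect (catechol methylation, COMT-like), inside modest LD blocks so
    pruning and clumping have structure to work on.
    """
    names = list(ACETAMINOPHEN_PANEL["name"])
    return SimulationConfig(
        n_samples=n_samples,
        n_variants=n_variants,
        seed=seed,
        ld_block_size=5,
        ld_mutation_rate=0.1,
        effect_plan=[
            PlantedEffect(
                variant_index=n_variants // 4,
                kind="branch",
                target_metabolites=[names[2], names[4]],  # methoxy glucuronide vs sulfate
                beta=0.15,
            ),
            PlantedEffect(
                variant_index=3 * n_variants // 4,
                kind="conversion",
                target_metabolites=[names[3], names[4]],  # hydroxy sulfate -> methoxy sulfate
                beta=0.12,
            ),
        ],
    )


def config_to_yaml(config: SimulationConfig, path: str | Path) -> None:
    data = asdict(config)
    data["covariate_spec"]["age_range"] = list(config.covariate_spec.age_range)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def config_from_yaml(path: str | Path) -> SimulationConfig:
    data = yaml.safe_load(Path(path).read_text())
    if "effect_plan" in data:
        data["effect_plan"] = [PlantedEffect(**e) for e in data["effect_plan"]]
    if "covariate_spec" in data:
        spec = dict(data["covariate_spec"])
        spec["age_range"] = tuple(spec["age_range"])
        data["covariate_spec"] = CovariateSpec(**spec)
    return SimulationConfig(**data)
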
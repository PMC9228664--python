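"""Variant-level quality control for genotype matrices.

Implements the standard pre-association QC ladder for a WGS-derived
biallelic SNV panel: per-variant summary statistics (MAF, call rate,
Hardy-Weinberg exact test), threshold filtering, greedy sliding-window
LD pruning, principal components of the standardized dosage matrix,
and the genomic relationship matrix (GRM) used as the random-effect
covariance in mixed-model association.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "is_indel"]


@dataclass
class GenotypeMatrix:
    """Samples x variants additive dosage matrix.

    dosages holds 0/1/2 alt-allele counts as float, with NaN for missing
    calls. ``variants`` is a DataFrame with columns chrom, pos (1-based,
    VCF convention), id, ref, alt, is_indel; variant ids must be unique.
    Sample order is the canonical ordering for every derived object
    (traits, covariates, GRM, PCs).
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("variant metadata does not match dosage columns")
        if self.dosages.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids does not match dosage rows")
        if self.variants["id"].duplicated().any():
            raise ValueError("variant ids must be unique")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def take_variants(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            variants=self.variants.iloc[index].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
        )

    def take_samples(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[index, :],
            variants=self.variants.copy(),
            sample_ids=[self.sample_ids[i] for i in index],
        )

    def subset_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"samples absent from genotype matrix: {missing[:5]}")
        return self.take_samples([lookup[s] for s in ids])


@dataclass
class RelationshipMatrix:
    """Symmetric samples x samples genomic relationship matrix."""

    values: np.ndarray
    sample_ids: list[str]
    n_variants_used: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("relationship matrix must be symmetric")


def _hwe_weights(n: int, n_alt: int) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalized integer weights of the conditional heterozygote-count
    distribution given ``n`` diploid samples carrying ``n_alt`` alt alleles.

    The weight of h heterozygotes is the number of ways to realize the
    genotype configuration: multinomial(n; n_aa, h, n_bb) * 2**h.
    Exact integers so that ties in probability are resolved exactly.
    """
    n_ref = 2 * n - n_alt
    rare = min(n_alt, n_ref)
    h_values = np.arange(rare % 2, rare + 1, 2)
    weights = []
    for h in h_values:
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        weights.append(comb(n, hom_rare) * comb(n - hom_rare, h) * (2 ** int(h)))
    return h_values, np.array(weights, dtype=object)


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed count. Monomorphic variants return 1.0. Weights
    are exact integers, so equal-probability configurations are genuine
    ties, not float accidents.
    """
    for c in (n_hom_ref, n_het, n_hom_alt):
        if c < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no called genotypes")
    n_alt = n_het + 2 * n_hom_alt
    if n_alt == 0 or n_alt == 2 * n:
        return 1.0
    h_values, weights = _hwe_weights(n, n_alt)
    obs = int(np.where(h_values == n_het)[0][0])
    w_obs = weights[obs]
    selected = sum(int(w) for w in weights if w <= w_obs)
    total = sum(int(w) for w in weights)
    return selected / total


def compute_variant_stats(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-variant MAF, call rate, and HWE exact-test p-value.

    MAF and HWE use non-missing genotypes only. All-missing variants get
    NaN stats and are dropped by any downstream filter. Dosages are
    expected to be hard calls in {0, 1, 2}; fractional dosages are
    rounded for genotype counting.
    """
    d = g.dosages
    n_samples = d.shape[0]
    called = ~np.isnan(d)
    n_called = called.sum(axis=0)
    call_rate = n_called / n_samples

    rounded = np.where(called, np.round(d), np.nan)
    n_hom_ref = np.nansum(rounded == 0, axis=0).astype(int)
    n_het = np.nansum(rounded == 1, axis=0).astype(int)
    n_hom_alt = np.nansum(rounded == 2, axis=0).astype(int)

    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = (n_het + 2 * n_hom_alt) / (2 * n_called)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)

    hwe_p = np.full(d.shape[1], np.nan)
    for j in range(d.shape[1]):
        if n_called[j] > 0:
            hwe_p[j] = hwe_exact_p(n_hom_ref[j], n_het[j], n_hom_alt[j])
    maf = np.where(n_called > 0, maf, np.nan)

    return pd.DataFrame(
        {
            "id": g.variants["id"].to_numpy(),
            "maf": maf,
            "call_rate": call_rate,
            "hwe_p": hwe_p,
            "n_called": n_called,
        }
    )


AUTOSOMES = {str(c) for c in range(1, 23)} | {f"chr{c}" for c in range(1, 23)}


def filter_variants(
    g: GenotypeMatrix,
    stats: pd.DataFrame | None = None,
    maf_min: float = 0.05,
    call_rate_min: float = 0.90,
    hwe_p_min: float = 1e-6,
    autosomes_only: bool = True,
    drop_indels: bool = False,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Threshold filter on variant statistics.

    Removals are strict violations: a variant exactly at a threshold
    survives (MAF below 5%, call rate below 90%, HWE p below 1e-6 are
    removed). Returns the filtered matrix and per-criterion removal
    counts (a variant may be counted under several criteria).
    """
    if stats is None:
        stats = compute_variant_stats(g)
    maf = stats["maf"].to_numpy()
    cr = stats["call_rate"].to_numpy()
    hp = stats["hwe_p"].to_numpy()

    undefined = np.isnan(maf) | np.isnan(hp)
    fail_maf = ~undefined & (maf < maf_min)
    fail_cr = cr < call_rate_min
    fail_hwe = ~undefined & (hp < hwe_p_min)
    fail_auto = np.zeros(g.n_variants, dtype=bool)
    if autosomes_only:
        fail_auto = ~g.variants["chrom"].astype(str).isin(AUTOSOMES).to_numpy()
    fail_indel = np.zeros(g.n_variants, dtype=bool)
    if drop_indels:
        fail_indel = g.variants["is_indel"].to_numpy().astype(bool)

    keep = ~(undefined | fail_maf | fail_cr | fail_hwe | fail_auto | fail_indel)
    report = {
        "input": g.n_variants,
        "removed_undefined": int(undefined.sum()),
        "removed_maf": int(fail_maf.sum()),
        "removed_call_rate": int(fail_cr.sum()),
        "removed_hwe": int(fail_hwe.sum()),
        "removed_non_autosomal": int(fail_auto.sum()),
        "removed_indel": int(fail_indel.sum()),
        "retained": int(keep.sum()),
    }
    if report["retained"] == 0:
        warnings.warn("all variants removed by QC filters", stacklevel=2)
    return g.take_variants(np.flatnonzero(keep)), report


def ld_r2(g: GenotypeMatrix, i: int, j: int) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over pairwise-complete samples (composite/genotype r^2, not
    haplotype-EM r^2). A zero-variance vector makes the correlation
    undefined; NaN is returned and callers treat the pair as unlinked.
    """
    x = g.dosages[:, i]
    y = g.dosages[:, j]
    return _r2_vectors(x, y)


def _r2_vectors(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        return np.nan
    xc = x[ok] - x[ok].mean()
    yc = y[ok] - y[ok].mean()
    vx = xc @ xc
    vy = yc @ yc
    if vx == 0 or vy == 0:
        return np.nan
    return float((xc @ yc) ** 2 / (vx * vy))


def ld_prune(
    g: GenotypeMatrix,
    r2_max: float = 0.5,
    window: int = 50,
    step: int = 5,
) -> np.ndarray:
    """Greedy sliding-window LD pruning; returns retained variant indices.

    Within each window of ``window`` consecutive variants, offending pairs
    (r^2 > r2_max) are resolved by removing the later-positioned variant;
    the window then slides by ``step``. Deterministic given the variant
    order.
    """
    n = g.n_variants
    keep = np.ones(n, dtype=bool)
    if n == 0:
        return np.array([], dtype=int)
    for start in range(0, max(n - 1, 1), step):
        idx = [k for k in range(start, min(start + window, n)) if keep[k]]
        for a in range(len(idx)):
            i = idx[a]
            if not keep[i]:
                continue
            for b in range(a + 1, len(idx)):
                j = idx[b]
                if not keep[j]:
                    continue
                r2 = ld_r2(g, i, j)
                if not np.isnan(r2) and r2 > r2_max:
                    keep[j] = False
        if start + window >= n:
            break
    return np.flatnonzero(keep)


def _standardized_dosages(
    g: GenotypeMatrix, impute: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardized dosages; returns (matrix, polymorphic mask).

    Missing dosages are replaced with the per-variant mean when
    ``impute`` is set (the PCA policy); monomorphic columns are flagged.
    """
    d = g.dosages.copy()
    col_mean = np.nanmean(d, axis=0)
    if impute:
        nan_idx = np.where(np.isnan(d))
        d[nan_idx] = np.take(col_mean, nan_idx[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        col_sd = np.nanstd(d, axis=0)
    poly = col_sd > 0
    z = (d - col_mean) / np.where(poly, col_sd, 1.0)
    return z, poly


def compute_pcs(g: GenotypeMatrix, k: int = 10) -> pd.DataFrame:
    """Top-k principal component scores of the standardized dosage matrix.

    Missing dosages are mean-imputed per variant before standardization.
    Sign convention: each component is flipped so that its
    largest-magnitude variant loading is positive, which makes scores
    reproducible across runs and platforms.
    """
    z, poly = _standardized_dosages(g, impute=True)
    z = z[:, poly]
    if z.shape[1] == 0:
        raise ValueError("no polymorphic variants for PCA")
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if k > rank:
        warnings.warn(
            f"requested {k} PCs but matrix rank is {rank}; truncating",
            stacklevel=2,
        )
        k = rank
    scores = u[:, :k] * s[:k]
    for c in range(k):
        lead = np.argmax(np.abs(vt[c]))
        if vt[c, lead] < 0:
            scores[:, c] *= -1
    return pd.DataFrame(
        scores,
        index=pd.Index(g.sample_ids, name="sample"),
        columns=[f"PC{c + 1}" for c in range(k)],
    )


def compute_grm(g: GenotypeMatrix) -> RelationshipMatrix:
    """Genomic relationship matrix from a pruned, filtered panel.

    Entry (j, k) = mean over variants i of
    (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),
    with p_i the sample alt-allele frequency. Missing dosages contribute
    zero to the numerator and the average is taken over the variants
    jointly called in both samples (pairwise-complete averaging).
    Monomorphic variants are excluded.
    """
    d = g.dosages
    called = ~np.isnan(d)
    with np.errstate(invalid="ignore"):
        p = np.nansum(d, axis=0) / (2 * called.sum(axis=0))
    poly = (p > 0) & (p < 1) & (called.sum(axis=0) > 0)
    if not poly.any():
        raise ValueError("no polymorphic variants for GRM")
    d = d[:, poly]
    p = p[poly]
    called = called[:, poly]

    z = (d - 2 * p) / np.sqrt(2 * p * (1 - p))
    z = np.where(called, z, 0.0)
    numer = z @ z.T
    pair_counts = called.astype(float) @ called.astype(float).T
    with np.errstate(invalid="ignore", divide="ignore"):
        values = numer / pair_counts
    values[pair_counts == 0] = np.nan
    return RelationshipMatrix(
        values=values,
        sample_ids=list(g.sample_ids),
        n_variants_used=int(poly.sum()),
    )
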
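"""The p-gain statistic and trait-wide significance classification.

The p-gain of a ratio association quantifies how much evidence the ratio
adds over its two component metabolites at the same variant:

    p-gain = min(p_numerator, p_denominator) / p_ratio

A p-gain of 10 corresponds to a single-test alpha of 0.05; with T traits
tested the trait-wide critical value is 10 * T, and the genome- and
trait-wide p-value threshold is the Bonferroni-scaled 5e-8 / T. Large
p-gains flag metabolite pairs linked through a shared normalizing factor
or a common pathway step whose balance is under genetic control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phenotypes import RATIO_SEP

GENOME_WIDE_P = 5e-8
PGAIN_SINGLE_TEST = 10.0
SUGGESTIVE_P = 1e-5


@dataclass(frozen=True)
class SignificanceThresholds:
    """Multiple-testing thresholds for a panel of ``n_traits`` phenotypes."""

    n_traits: int
    p_bonf: float
    pgain_bonf: float
    suggestive_p: float = SUGGESTIVE_P


def compute_thresholds(n_traits: int) -> SignificanceThresholds:
    """Trait-wide thresholds: p_bonf = 5e-8 / T, pgain_bonf = 10 * T.

    T counts every tested phenotype (singles plus ratios); for the
    canonical nine-metabolite panel T = 45, giving p_bonf = 1.1e-9 and
    pgain_bonf = 450.
    """
    if n_traits < 1:
        raise ValueError("need at least one trait")
    return SignificanceThresholds(
        n_traits=n_traits,
        p_bonf=GENOME_WIDE_P / n_traits,
        pgain_bonf=PGAIN_SINGLE_TEST * n_traits,
    )


def compute_pgain(p_num, p_den, p_ratio):
    """min(p_num, p_den) / p_ratio; accepts scalars or arrays.

    All three p-values must lie in (0, 1]. Symmetric in the two
    component p-values, hence invariant under flipping the ratio's
    orientation.
    """
    p_num = np.asarray(p_num, dtype=float)
    p_den = np.asarray(p_den, dtype=float)
    p_ratio = np.asarray(p_ratio, dtype=float)
    for name, arr in (("p_num", p_num), ("p_den", p_den), ("p_ratio", p_ratio)):
        if np.any((arr <= 0) | (arr > 1)):
            raise ValueError(f"{name} must lie in (0, 1]")
    out = np.minimum(p_num, p_den) / p_ratio
    return float(out) if out.ndim == 0 else out


def classify(
    results: pd.DataFrame,
    thresholds: SignificanceThresholds,
    descriptors: pd.DataFrame,
) -> pd.DataFrame:
    """Join ratio and component associations per variant; flag significance.

    ``results`` is a run_gwas output covering both single and ratio
    traits; ``descriptors`` maps each ratio trait to its numerator and
    denominator metabolites. Component p-values come from each single
    trait's own complete-case analysis. Flags (all strict comparisons):

    * bonferroni_significant — p_ratio < p_bonf
    * pgain_significant      — pgain > pgain_bonf
    * suggestive             — p_ratio < suggestive_p

    Rows whose component result is missing or untestable keep NaN pgain
    and are flagged ``incomplete``. Pure function of its inputs:
    identical input tables give identical output.
    """
    ratios = descriptors[descriptors["kind"] == "ratio"]
    singles = results[results["trait"].isin(descriptors[descriptors["kind"] == "single"]["trait"])]
    p_single = singles.pivot_table(
        index="variant", columns="trait", values="p", aggfunc="first"
    )

    ratio_rows = results[results["trait"].isin(ratios["trait"])].copy()
    num = ratio_rows["trait"].map(ratios.set_index("trait")["numerator"])
    den = ratio_rows["trait"].map(ratios.set_index("trait")["denominator"])

    def lookup(variant: pd.Series, trait: pd.Series) -> np.ndarray:
        out = np.full(len(variant), np.nan)
        for k, (v, t) in enumerate(zip(variant, trait)):
            if t in p_single.columns and v in p_single.index:
                out[k] = p_single.at[v, t]
        return out

    p_num = lookup(ratio_rows["variant"], num)
    p_den = lookup(ratio_rows["variant"], den)
    p_ratio = ratio_rows["p"].to_numpy()

    ok = np.isfinite(p_num) & np.isfinite(p_den) & np.isfinite(p_ratio)
    pgain = np.full(len(ratio_rows), np.nan)
    pgain[ok] = np.minimum(p_num[ok], p_den[ok]) / p_ratio[ok]

    out = ratio_rows.assign(
        p_num=p_num,
        p_den=p_den,
        p_ratio=p_ratio,
        pgain=pgain,
        incomplete=~ok,
        bonferroni_significant=ok & (p_ratio < thresholds.p_bonf),
        pgain_significant=ok & (pgain > thresholds.pgain_bonf),
        suggestive=np.isfinite(p_ratio) & (p_ratio < thresholds.suggestive_p),
    )
    return out.drop(columns=["p"]).reset_index(drop=True)


def _simple_regression_p(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Two-sided p for the slope of y on x, row-wise over replicates.

    y, x are (replicates, n) arrays; covariate-free simple regression
    with intercept, vectorized across replicates.
    """
    n = y.shape[1]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sxx = np.einsum("ij,ij->i", xc, xc)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.einsum("ij,ij->i", xc, yc) / sxx
        rss = np.einsum("ij,ij->i", yc, yc) - beta**2 * sxx
        sigma2 = np.maximum(rss, 0.0) / (n - 2)
        tstat = beta / np.sqrt(sigma2 / sxx)
    p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    p[~np.isfinite(tstat)] = np.nan
    return np.maximum(p, np.finfo(float).tiny)


def null_calibration(
    n_samples: int = 500,
    maf: float = 0.3,
    n_replicates: int = 10_000,
    critical_value: float = PGAIN_SINGLE_TEST,
    seed: int = 0,
    log_sd: float = 1.0,
    confidence: float = 0.95,
) -> dict:
    """Empirical exceedance of the p-gain under a genetic null.

    Per replicate: one SNP at the given MAF under Hardy-Weinberg
    proportions and two independent log-normal metabolites with no
    genetic effect. The two single-trait p-values and the ratio p-value
    come from covariate-free regression on dosage; the replicate's p-gain
    is formed and the fraction exceeding ``critical_value`` is returned
    with a Clopper-Pearson binomial confidence interval.

    A critical value of 10 is the single-test alpha = 0.05 calibration
    point; for independent metabolites the exceedance should sit at or
    below 0.05.
    """
    rng = np.random.default_rng(seed)
    x = rng.binomial(2, maf, size=(n_replicates, n_samples)).astype(float)
    t1 = rng.normal(0.0, log_sd, size=(n_replicates, n_samples))
    t2 = rng.normal(0.0, log_sd, size=(n_replicates, n_samples))

    p1 = _simple_regression_p(t1, x)
    p2 = _simple_regression_p(t2, x)
    p_ratio = _simple_regression_p(t1 - t2, x)
    pgain = np.minimum(p1, p2) / p_ratio

    exceed = int(np.sum(pgain >= critical_value))
    frac = exceed / n_replicates
    alpha = 1.0 - confidence
    lo = stats.beta.ppf(alpha / 2, exceed, n_replicates - exceed + 1) if exceed > 0 else 0.0
    hi = (
        stats.beta.ppf(1 - alpha / 2, exceed + 1, n_replicates - exceed)
        if exceed < n_replicates
        else 1.0
    )
    return {
        "critical_value": critical_value,
        "n_replicates": n_replicates,
        "n_exceed": exceed,
        "fraction": frac,
        "ci_low": float(lo),
        "ci_high": float(hi),
    }


def ratio_components(trait_id: str) -> tuple[str, str]:
    """Split a canonical ratio trait id into (numerator, denominator)."""
    num, _, den = trait_id.partition(RATIO_SEP)
    if not den:
        raise ValueError(f"not a ratio trait id: {trait_id!r}")
    return num, den
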
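"""Per variant-trait association testing.

Two engines share one result schema:

* ``ols`` — ordinary least squares of the trait on additive dosage plus
  covariates and an intercept, two-sided t test on the dosage
  coefficient. Deterministic and fast; the default.
* ``lmm`` — one-variance-component linear mixed model
  y = Xb + g + e, g ~ N(0, s_g^2 A), e ~ N(0, s_e^2 I), with A a genomic
  relationship matrix. Variance components are fit once per trait by
  REML on the covariate-only model via the eigendecomposition of A, then
  each variant is tested by generalized least squares under the fitted
  covariance (the MLMA scheme). With A = I this reduces exactly to OLS.

Genotypes enter as unstandardized 0/1/2 dosages, so betas are per-allele
effects on the trait (log) scale. Samples with a missing trait value,
covariate, or dosage are dropped per test; nothing is imputed in the OLS
path. The LMM path mean-imputes the rare missing dosage within the
analysis subset because re-fitting the eigendecomposition per variant
would defeat the MLMA factorization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .phenotypes import TraitMatrix
from .qc import GenotypeMatrix, RelationshipMatrix

logger = logging.getLogger(__name__)

#: smallest reportable p-value; avoids literal zeros in output tables
P_FLOOR = np.finfo(float).tiny

RESULT_COLUMNS = [
    "trait",
    "variant",
    "chrom",
    "pos",
    "n_used",
    "beta",
    "se",
    "p",
    "status",
]


@dataclass
class AssociationResult:
    trait: str
    variant: str
    n_used: int
    beta: float
    se: float
    p: float
    status: str = "ok"  # ok | untestable | insufficient_n | lmm_fallback_ols


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    converged: bool = True

    @property
    def heritability(self) -> float:
        total = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / total if total > 0 else 0.0


def _design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    """Covariate block with intercept prepended."""
    if covariates is None:
        return np.ones((n, 1))
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covariates.shape[0] != n:
        covariates = covariates.T
    return np.column_stack([np.ones(n), covariates])


def _t_pvalue(tstat: np.ndarray, df: int) -> np.ndarray:
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    return np.maximum(p, P_FLOOR)


def ols_association(
    trait: np.ndarray,
    dosage: np.ndarray,
    covariates: np.ndarray | None = None,
    trait_id: str = "trait",
    variant_id: str = "variant",
) -> AssociationResult:
    """OLS of trait on dosage + covariates + intercept.

    Complete-case: samples with NaN in the trait, the dosage, or any
    covariate are dropped. A variant monomorphic in the analysis subset
    is flagged untestable rather than raising.
    """
    y = np.asarray(trait, dtype=float)
    x = np.asarray(dosage, dtype=float)
    c = _design(covariates, len(y))
    ok = np.isfinite(y) & np.isfinite(x) & np.all(np.isfinite(c), axis=1)
    y, x, c = y[ok], x[ok], c[ok]
    n = len(y)
    p_cov = c.shape[1]
    if n < p_cov + 3:
        return AssociationResult(trait_id, variant_id, n, np.nan, np.nan, np.nan, "insufficient_n")
    if np.ptp(x) == 0:
        return AssociationResult(trait_id, variant_id, n, np.nan, np.nan, np.nan, "untestable")

    design = np.column_stack([x, c])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    df = n - design.shape[1]
    if df <= 0 or rank < design.shape[1]:
        return AssociationResult(trait_id, variant_id, n, np.nan, np.nan, np.nan, "untestable")
    sigma2 = resid @ resid / df
    xtx_inv = np.linalg.inv(design.T @ design)
    se = float(np.sqrt(sigma2 * xtx_inv[0, 0]))
    beta = float(coef[0])
    if se == 0:
        p = P_FLOOR
    else:
        p = float(_t_pvalue(np.array(beta / se), df))
    return AssociationResult(trait_id, variant_id, n, beta, se, p, "ok")


def _ols_scan(
    y: np.ndarray,
    dosages: np.ndarray,
    covariates: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized OLS of one trait against every variant column.

    Uses the Frisch-Waugh-Lovell decomposition: the trait and each dosage
    vector are residualized on the covariates (with intercept), then the
    per-variant coefficient is a simple regression of residual on
    residual. The t statistic carries the full-model residual degrees of
    freedom, so results are identical to the joint fit. Requires
    complete trait/covariate rows; variants with missing dosages inside
    the subset are returned as NaN and handled by the per-variant
    fallback.

    Returns (beta, se, p, n_used) arrays over variants.
    """
    n = len(y)
    c = _design(covariates, n)
    q, _ = np.linalg.qr(c)
    y_r = y - q @ (q.T @ y)
    g_r = dosages - q @ (q.T @ dosages)
    gg = np.einsum("ij,ij->j", g_r, g_r)
    df = n - c.shape[1] - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = (g_r.T @ y_r) / gg
        rss = y_r @ y_r - beta**2 * gg
        rss = np.maximum(rss, 0.0)
        sigma2 = rss / df
        se = np.sqrt(sigma2 / gg)
        tstat = beta / se
    p = _t_pvalue(tstat, df)
    bad = ~np.isfinite(se) | (gg <= 0)
    beta[bad] = np.nan
    se[bad] = np.nan
    p[bad] = np.nan
    return beta, se, p, np.full(dosages.shape[1], n)


def reml_variance_components(
    y: np.ndarray,
    covariates: np.ndarray | None,
    eigvals: np.ndarray,
    eigvecs: np.ndarray,
) -> VarianceComponents:
    """REML fit of (sigma_g^2, sigma_e^2) for y = Xb + g + e.

    Works in the eigenbasis of the relationship matrix A = U S U', where
    the marginal covariance is diagonal: sigma_total^2 (h S + (1-h) I).
    The heritability-like ratio h is profiled by bounded scalar
    optimization of the REML log-likelihood; the total variance has a
    closed form given h. h is allowed to hit the zero boundary.
    """
    n = len(y)
    x = _design(covariates, n)
    p = x.shape[1]
    ystar = eigvecs.T @ y
    xstar = eigvecs.T @ x
    s = np.maximum(eigvals, 0.0)

    def neg_reml(h: float) -> float:
        w = h * s + (1.0 - h)
        if np.any(w <= 0):
            return np.inf
        xw = xstar / w[:, None]
        xtx = xstar.T @ xw
        sign, logdet_xtx = np.linalg.slogdet(xtx)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(xtx, xw.T @ ystar)
        resid = ystar - xstar @ beta
        rss = resid @ (resid / w)
        if rss <= 0:
            return np.inf
        sigma2 = rss / (n - p)
        return 0.5 * (
            (n - p) * np.log(sigma2) + np.sum(np.log(w)) + logdet_xtx + (n - p)
        )

    res = optimize.minimize_scalar(
        neg_reml, bounds=(0.0, 1.0 - 1e-6), method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success or not np.isfinite(res.fun):
        return VarianceComponents(np.nan, np.nan, converged=False)
    h = float(res.x)
    # boundary snap: the bounded optimizer cannot land exactly on 0
    if neg_reml(0.0) <= res.fun + 1e-10:
        h = 0.0
    w = h * s + (1.0 - h)
    xw = xstar / w[:, None]
    beta = np.linalg.solve(xstar.T @ xw, xw.T @ ystar)
    resid = ystar - xstar @ beta
    sigma2 = float(resid @ (resid / w) / (n - p))
    return VarianceComponents(sigma_g2=h * sigma2, sigma_e2=(1.0 - h) * sigma2)


def lmm_association(
    trait: np.ndarray,
    dosages: np.ndarray,
    covariates: np.ndarray | None,
    grm: RelationshipMatrix,
    trait_id: str = "trait",
    variant_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, VarianceComponents]:
    """Mixed-model association of one trait against a dosage matrix.

    Variance components are estimated once under the covariate-only
    model, then every variant is tested by GLS with the fitted weights
    (equivalently, OLS after whitening by W^{-1/2} in the eigenbasis of
    the GRM). Missing dosages are mean-imputed within the analysis
    subset. If REML fails to converge the engine falls back to OLS and
    flags every row.
    """
    y = np.asarray(trait, dtype=float)
    d = np.asarray(dosages, dtype=float)
    if d.ndim == 1:
        d = d[:, None]
    c_block = None if covariates is None else np.asarray(covariates, dtype=float)
    ok = np.isfinite(y)
    if c_block is not None:
        ok &= np.all(np.isfinite(c_block), axis=1)
    y = y[ok]
    d = d[ok]
    c_sub = None if c_block is None else c_block[ok]
    a_sub = grm.values[np.ix_(ok.nonzero()[0], ok.nonzero()[0])]

    col_mean = np.nanmean(d, axis=0)
    nan_idx = np.where(np.isnan(d))
    d[nan_idx] = np.take(col_mean, nan_idx[1])

    eigvals, eigvecs = np.linalg.eigh(a_sub)
    vc = reml_variance_components(y, c_sub, eigvals, eigvecs)

    if variant_ids is None:
        variant_ids = [f"v{j}" for j in range(d.shape[1])]

    status = "ok"
    if not vc.converged:
        logger.warning("REML did not converge for trait %s; using OLS", trait_id)
        status = "lmm_fallback_ols"
        beta, se, p, n_used = _ols_scan(y, d, c_sub)
    else:
        h = vc.heritability
        w = h * np.maximum(eigvals, 0.0) + (1.0 - h)
        scale = 1.0 / np.sqrt(w)
        yw = (eigvecs.T @ y) * scale
        dw = (eigvecs.T @ d) * scale[:, None]
        cw = None
        if c_sub is not None:
            cw = (eigvecs.T @ c_sub) * scale[:, None]
        # the whitened intercept is no longer constant; fold it into the
        # covariate block explicitly
        ones_w = (eigvecs.T @ np.ones(len(y))) * scale
        cw_full = ones_w[:, None] if cw is None else np.column_stack([ones_w, cw])
        beta, se, p, n_used = _ols_scan_precentered(yw, dw, cw_full)

    mono = np.array([np.ptp(d[:, j]) == 0 for j in range(d.shape[1])])
    rows = pd.DataFrame(
        {
            "trait": trait_id,
            "variant": variant_ids,
            "n_used": len(y),
            "beta": beta,
            "se": se,
            "p": p,
            "status": np.where(mono, "untestable", status),
        }
    )
    rows.loc[mono, ["beta", "se", "p"]] = np.nan
    return rows, vc


def _ols_scan_precentered(
    y: np.ndarray, dosages: np.ndarray, covariate_block: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """FWL scan where the covariate block already includes any intercept."""
    n = len(y)
    q, _ = np.linalg.qr(covariate_block)
    y_r = y - q @ (q.T @ y)
    g_r = dosages - q @ (q.T @ dosages)
    gg = np.einsum("ij,ij->j", g_r, g_r)
    df = n - covariate_block.shape[1] - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = (g_r.T @ y_r) / gg
        rss = np.maximum(y_r @ y_r - beta**2 * gg, 0.0)
        se = np.sqrt(rss / df / gg)
        tstat = beta / se
    p = _t_pvalue(tstat, df)
    bad = ~np.isfinite(se) | (gg <= 0)
    beta[bad], se[bad], p[bad] = np.nan, np.nan, np.nan
    return beta, se, p, np.full(dosages.shape[1], n)


def run_gwas(
    traits: TraitMatrix,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | None = None,
    mode: str = "ols",
    grm: RelationshipMatrix | None = None,
) -> pd.DataFrame:
    """Full scan: one association result per testable (trait, variant) pair.

    Samples are aligned on the genotype matrix ordering; traits and
    covariates are reindexed onto it. Untestable pairs (monomorphic in
    subset, insufficient complete cases) are reported with NaN statistics
    and a status flag — the scan never aborts on a single pair. Returns a
    tidy DataFrame sorted by (trait, chrom, pos).
    """
    if mode not in {"ols", "lmm"}:
        raise ValueError(f"unknown association mode: {mode}")
    if mode == "lmm" and grm is None:
        raise ValueError("lmm mode requires a relationship matrix")

    sample_index = pd.Index(genotypes.sample_ids)
    trait_values = traits.values.reindex(sample_index)
    cov_arr = None
    if covariates is not None:
        cov = covariates.reindex(sample_index)
        cov_arr = cov.to_numpy(dtype=float)

    variant_meta = genotypes.variants
    out: list[pd.DataFrame] = []
    n_untestable = 0
    for trait_id in traits.trait_ids:
        y_full = trait_values[trait_id].to_numpy(dtype=float)
        if mode == "lmm":
            rows, _ = lmm_association(
                y_full,
                genotypes.dosages,
                cov_arr,
                grm,
                trait_id=trait_id,
                variant_ids=list(variant_meta["id"]),
            )
        else:
            rows = _ols_trait_scan(
                y_full, genotypes.dosages, cov_arr, trait_id, variant_meta
            )
        rows = rows.assign(
            chrom=variant_meta["chrom"].to_numpy(),
            pos=variant_meta["pos"].to_numpy(),
        )
        n_untestable += int((rows["status"] != "ok").sum())
        out.append(rows)
    result = pd.concat(out, ignore_index=True)[RESULT_COLUMNS]
    if n_untestable:
        logger.info("%d (trait, variant) pairs untestable", n_untestable)
    return result.sort_values(["trait", "chrom", "pos"], kind="stable").reset_index(
        drop=True
    )


def _ols_trait_scan(
    y_full: np.ndarray,
    dosages: np.ndarray,
    cov_arr: np.ndarray | None,
    trait_id: str,
    variant_meta: pd.DataFrame,
) -> pd.DataFrame:
    """One trait against all variants: vectorized fast path for variants
    fully called in the trait's complete-case subset, per-variant
    complete-case fallback for the rest."""
    ok = np.isfinite(y_full)
    if cov_arr is not None:
        ok &= np.all(np.isfinite(cov_arr), axis=1)
    y = y_full[ok]
    c_sub = None if cov_arr is None else cov_arr[ok]
    d_sub = dosages[ok]
    n = len(y)
    n_var = d_sub.shape[1]
    n_cov = 1 if c_sub is None else 1 + c_sub.shape[1]

    beta = np.full(n_var, np.nan)
    se = np.full(n_var, np.nan)
    p = np.full(n_var, np.nan)
    n_used = np.zeros(n_var, dtype=int)
    status = np.full(n_var, "ok", dtype=object)

    if n < n_cov + 3:
        status[:] = "insufficient_n"
    else:
        complete = ~np.isnan(d_sub).any(axis=0)
        mono = np.zeros(n_var, dtype=bool)
        mono[complete] = np.ptp(d_sub[:, complete], axis=0) == 0
        fast = complete & ~mono
        if fast.any():
            b, s, pv, nu = _ols_scan(y, d_sub[:, fast], c_sub)
            beta[fast], se[fast], p[fast], n_used[fast] = b, s, pv, nu
        status[mono] = "untestable"
        for j in np.flatnonzero(~complete):
            res = ols_association(
                y, d_sub[:, j], c_sub, trait_id, str(variant_meta["id"].iloc[j])
            )
            beta[j], se[j], p[j] = res.beta, res.se, res.p
            n_used[j], status[j] = res.n_used, res.status
        n_used[complete] = n

    return pd.DataFrame(
        {
            "trait": trait_id,
            "variant": variant_meta["id"].to_numpy(),
            "n_used": n_used,
            "beta": beta,
            "se": se,
            "p": p,
            "status": status,
        }
    )
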
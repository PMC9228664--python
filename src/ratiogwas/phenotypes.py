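"""Sample inclusion and construction of log / log-ratio metabolite traits.

A panel of M metabolites yields M single traits (natural log of the
median-normalized relative abundance) plus M(M-1)/2 pairwise ratio
traits (difference of the two logs). Ratios proxy the substrate/product
balance of an enzymatic step and implicitly cancel any multiplicative
factor shared by the pair — dosing, dilution, platform drift — which is
what makes them powerful phenotypes for drug-metabolite GWAS where
missingness is high and batch effects are large.

Non-detected metabolites are never imputed: each trait carries its own
complete-case mask and every downstream test uses only the samples for
which the trait is defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RATIO_SEP = "/"


@dataclass
class MetabolitePanel:
    """Samples x metabolites relative abundances with a detection mask.

    ``abundances`` is a DataFrame (rows = samples, columns = metabolite
    names); NaN means not detected. All present values must be positive
    (relative, median-normalized abundances). Optional per-metabolite
    descriptors (CAS, LC/MS mode, retention index, mass) ride along in
    ``meta``.
    """

    abundances: pd.DataFrame
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.abundances.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise ValueError("detected abundances must be strictly positive")

    @property
    def detected(self) -> pd.DataFrame:
        return self.abundances.notna()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundances.index)

    @property
    def metabolites(self) -> list[str]:
        return list(self.abundances.columns)


@dataclass
class TraitMatrix:
    """Derived phenotypes: single log traits and pairwise log-ratios.

    ``values`` rows are samples; NaN marks samples where the trait is
    undefined (a component not detected). ``descriptors`` has one row per
    trait: kind ('single' or 'ratio'), numerator, denominator (NaN for
    singles).
    """

    values: pd.DataFrame
    descriptors: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def trait_ids(self) -> list[str]:
        return list(self.values.columns)

    def complete_cases(self, trait: str) -> pd.Index:
        col = self.values[trait]
        return col.index[col.notna()]


def expected_trait_count(n_metabolites: int) -> int:
    """M single traits plus M(M-1)/2 unordered pairwise ratios."""
    return n_metabolites + n_metabolites * (n_metabolites - 1) // 2


def select_samples(panel: MetabolitePanel, min_detected: int = 5) -> MetabolitePanel:
    """Retain samples with at least ``min_detected`` detected metabolites.

    The default of 5 (out of a 9-metabolite panel) is the inclusion rule
    used to define the analysis cohort.
    """
    counts = panel.detected.sum(axis=1)
    keep = counts >= min_detected
    logger.info(
        "sample inclusion: %d of %d samples have >= %d detected metabolites",
        int(keep.sum()),
        len(keep),
        min_detected,
    )
    return MetabolitePanel(
        abundances=panel.abundances.loc[keep],
        meta=panel.meta,
    )


def detection_report(panel: MetabolitePanel) -> pd.DataFrame:
    """Per-sample detected-metabolite counts (inclusion report)."""
    return pd.DataFrame(
        {"n_detected": panel.detected.sum(axis=1)},
        index=panel.abundances.index,
    )


def ratio_trait_id(numerator: str, denominator: str) -> str:
    return f"{numerator}{RATIO_SEP}{denominator}"


def build_traits(panel: MetabolitePanel) -> TraitMatrix:
    """Construct all single log traits and pairwise log-ratio traits.

    Ratio orientation is canonicalized by panel column order (the earlier
    column is the numerator); association p-values are invariant to
    orientation, and betas just flip sign. A ratio trait is defined for a
    sample iff both components were detected.
    """
    names = panel.metabolites
    logs = np.log(panel.abundances.to_numpy(dtype=float))
    columns: dict[str, np.ndarray] = {}
    rows = []
    for j, name in enumerate(names):
        columns[name] = logs[:, j]
        rows.append({"trait": name, "kind": "single", "numerator": name, "denominator": None})
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            tid = ratio_trait_id(names[a], names[b])
            columns[tid] = logs[:, a] - logs[:, b]
            rows.append(
                {
                    "trait": tid,
                    "kind": "ratio",
                    "numerator": names[a],
                    "denominator": names[b],
                }
            )
    values = pd.DataFrame(columns, index=panel.abundances.index)
    descriptors = pd.DataFrame(rows).set_index("trait", drop=False)
    assert len(values.columns) == expected_trait_count(len(names))
    return TraitMatrix(values=values, descriptors=descriptors)


def rank_inverse_normal(values: pd.Series) -> pd.Series:
    """Rank-based inverse-normal transform (Blom offset), NaN-preserving.

    Off by default in the pipeline: traits stay on the natural-log scale
    so betas are per-allele log-fold changes.
    """
    from scipy import stats

    out = pd.Series(np.nan, index=values.index, dtype=float)
    ok = values.notna()
    n = int(ok.sum())
    if n == 0:
        return out
    ranks = stats.rankdata(values[ok])
    out[ok] = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    return out


def assemble_covariates(
    covariates: pd.DataFrame,
    pcs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join raw covariates (age, sex) with genomic PCs on sample id.

    Samples missing any covariate are dropped with a warning; an empty
    intersection between the covariate and PC sample sets is an error
    (it indicates an id mismatch between genotype and phenotype files).
    """
    table = covariates.copy()
    if pcs is not None:
        overlap = table.index.intersection(pcs.index)
        if len(overlap) == 0:
            raise ValueError(
                "no shared sample ids between covariates and genomic PCs"
            )
        dropped = table.index.difference(pcs.index)
        if len(dropped):
            logger.warning(
                "dropping %d samples absent from the genotype-derived PCs: %s%s",
                len(dropped),
                list(dropped[:5]),
                "..." if len(dropped) > 5 else "",
            )
        table = table.loc[overlap].join(pcs.loc[overlap])
    incomplete = table.isna().any(axis=1)
    if incomplete.any():
        logger.warning(
            "dropping %d samples with incomplete covariates", int(incomplete.sum())
        )
        table = table.loc[~incomplete]
    return table
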
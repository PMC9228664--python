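"""Variant QC: HWE exact test, filters, LD, PCA, GRM."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ratiogwas.qc import (
    compute_grm,
    compute_pcs,
    compute_variant_stats,
    filter_variants,
    hwe_exact_p,
    ld_prune,
    ld_r2,
)

from conftest import make_genotypes


def hwe_enumeration_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """First-principles exact-fraction enumeration of the conditional
    heterozygote-count distribution given allele totals."""
    n = n_hom_ref + n_het + n_hom_alt
    na = n_het + 2 * n_hom_alt  # alt allele count
    if na == 0 or na == 2 * n:
        return 1.0
    rare = min(na, 2 * n - na)
    total = comb(2 * n, rare)
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        ways = (
            Fraction(
                comb(n, hom_rare) * comb(n - hom_rare, h) * 2**h,
                total,
            )
        )
        probs[h] = ways
    obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= obs))


class TestHWEExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact_p(100, 0, 0) == 1.0
        assert hwe_exact_p(0, 0, 50) == 1.0

    @pytest.mark.parametrize(
        "counts",
        [(57, 14, 50), (10, 20, 10), (3, 1, 0), (0, 2, 0), (25, 50, 25), (40, 5, 1)],
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_p(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), rel=1e-12
        )

    def test_allele_relabeling_symmetry(self):
        for a, b, c in [(57, 14, 50), (3, 10, 40), (1, 1, 1)]:
            assert hwe_exact_p(a, b, c) == hwe_exact_p(c, b, a)

    @given(
        st.integers(0, 60), st.integers(0, 60), st.integers(0, 60)
    )
    @settings(max_examples=200, deadline=None)
    def test_p_in_unit_interval(self, a, b, c):
        if a + b + c == 0:
            return
        p = hwe_exact_p(a, b, c)
        assert 0 < p <= 1


class TestVariantStats:
    def test_maf_call_rate_and_undefined(self):
        g = make_genotypes(
            [
                [0, 2, np.nan],
                [1, 2, np.nan],
                [1, 2, np.nan],
                [2, 2, np.nan],
            ]
        )
        stats = compute_variant_stats(g)
        assert stats.loc[0, "maf"] == pytest.approx(0.5)
        assert stats.loc[1, "maf"] == 0.0  # monomorphic alt: min(f, 1-f)
        assert stats.loc[1, "hwe_p"] == 1.0
        assert stats.loc[0, "call_rate"] == 1.0
        assert np.isnan(stats.loc[2, "maf"])  # all missing -> undefined

    def test_relabeling_leaves_maf_and_hwe(self):
        d = np.array([[0, 2], [1, 1], [2, 0], [1, 1], [0, 2]], dtype=float)
        stats = compute_variant_stats(make_genotypes(d))
        assert stats.loc[0, "maf"] == stats.loc[1, "maf"]
        assert stats.loc[0, "hwe_p"] == stats.loc[1, "hwe_p"]


class TestFilterVariants:
    def _toy(self):
        # five variants engineered to straddle each threshold:
        # v1 good, v2 low MAF, v3 low call rate, v4 HWE violation, v5 exactly at MAF 5%
        n = 40
        rng = np.random.default_rng(5)
        good = rng.binomial(2, 0.4, n).astype(float)
        low_maf = np.zeros(n)
        low_maf[0] = 1  # maf 1/80 < 0.05
        low_cr = good.copy()
        low_cr[: n // 2] = np.nan  # call rate 0.5
        hwe_bad = np.ones(n)  # all heterozygous: extreme HWE violation
        at_boundary = np.zeros(n)
        at_boundary[:4] = 1.0  # maf = 4/80 = 0.05 exactly
        return make_genotypes(
            np.column_stack([good, low_maf, low_cr, hwe_bad, at_boundary])
        )

    def test_manual_rule_application(self):
        g = self._toy()
        stats = compute_variant_stats(g)
        assert stats.loc[3, "hwe_p"] < 1e-6
        filtered, report = filter_variants(g)
        assert list(filtered.variants["id"]) == ["v1", "v5"]
        assert report["removed_maf"] == 1
        assert report["removed_call_rate"] == 1
        assert report["removed_hwe"] == 1

    def test_boundary_maf_retained(self):
        g = self._toy()
        filtered, _ = filter_variants(g)
        assert "v5" in set(filtered.variants["id"])  # strict "<" removal

    def test_zero_thresholds_identity(self):
        g = self._toy()
        filtered, _ = filter_variants(g, maf_min=0, call_rate_min=0, hwe_p_min=0)
        assert filtered.n_variants == g.n_variants

    def test_idempotent(self):
        g = self._toy()
        once, _ = filter_variants(g)
        twice, report = filter_variants(once)
        assert list(twice.variants["id"]) == list(once.variants["id"])
        assert report["retained"] == once.n_variants

    def test_non_autosomal_removed(self):
        g = make_genotypes([[0, 0], [1, 1], [2, 2], [1, 1]], chrom="X")
        filtered, report = filter_variants(g, maf_min=0, call_rate_min=0, hwe_p_min=0)
        assert filtered.n_variants == 0
        assert report["removed_non_autosomal"] == 2


class TestLD:
    def test_self_r2_is_one(self):
        g = make_genotypes(np.array([[0, 0], [1, 1], [2, 2], [1, 1], [0, 0]]))
        assert ld_r2(g, 0, 0) == pytest.approx(1.0)

    def test_mirrored_dosages_r2_one(self):
        g = make_genotypes(np.column_stack([[0, 1, 2, 1, 0], [2, 1, 0, 1, 2]]))
        assert ld_r2(g, 0, 1) == pytest.approx(1.0)

    def test_matches_pearson_oracle_and_symmetry(self, rng):
        d = rng.binomial(2, 0.3, size=(30, 2)).astype(float)
        g = make_genotypes(d)
        expected = np.corrcoef(d[:, 0], d[:, 1])[0, 1] ** 2
        assert ld_r2(g, 0, 1) == pytest.approx(expected)
        assert ld_r2(g, 0, 1) == ld_r2(g, 1, 0)

    def test_zero_variance_undefined(self):
        g = make_genotypes(np.column_stack([[1, 1, 1, 1], [0, 1, 2, 1]]))
        assert np.isnan(ld_r2(g, 0, 1))

    def test_prune_duplicates_keeps_one(self, rng):
        col = rng.binomial(2, 0.4, 50).astype(float)
        g = make_genotypes(np.column_stack([col, col]))
        kept = ld_prune(g, r2_max=0.5)
        assert list(kept) == [0]

    def test_prune_uncorrelated_identity(self, rng):
        d = rng.binomial(2, 0.4, size=(500, 8)).astype(float)
        g = make_genotypes(d)
        r2s = [ld_r2(g, i, j) for i in range(8) for j in range(i + 1, 8)]
        assert max(r2s) < 0.5  # construction check at this n and seed
        assert list(ld_prune(g, r2_max=0.5)) == list(range(8))

    def test_prune_matches_exhaustive_greedy_oracle(self, rng):
        # 10-variant block with strong serial correlation
        n = 200
        base = rng.binomial(1, 0.4, (n, 2, 10)).astype(float)
        for j in range(1, 10):
            keep = rng.random((n, 2)) >= 0.15
            base[:, :, j] = np.where(keep, base[:, :, j - 1], base[:, :, j])
        g = make_genotypes(base.sum(axis=1))

        def oracle(g, r2_max, window, step):
            nv = g.n_variants
            keep = [True] * nv
            start = 0
            while True:
                idx = [k for k in range(start, min(start + window, nv)) if keep[k]]
                for a in range(len(idx)):
                    for b in range(a + 1, len(idx)):
                        i, j = idx[a], idx[b]
                        if keep[i] and keep[j]:
                            r2 = ld_r2(g, i, j)
                            if not np.isnan(r2) and r2 > r2_max:
                                keep[j] = False
                if start + window >= nv:
                    break
                start += step
            return [k for k in range(nv) if keep[k]]

        assert list(ld_prune(g, r2_max=0.5, window=5, step=2)) == oracle(
            g, 0.5, 5, 2
        )

    def test_no_retained_pair_exceeds_threshold_within_window(self, demo_cohort):
        g = demo_cohort.genotypes
        kept = ld_prune(g, r2_max=0.5, window=50, step=5)
        sub = g.take_variants(kept)
        for i in range(sub.n_variants):
            for j in range(i + 1, min(i + 50, sub.n_variants)):
                r2 = ld_r2(sub, i, j)
                if not np.isnan(r2):
                    assert r2 <= 0.5 + 1e-12


class TestPCA:
    def test_identical_samples_identical_scores(self, rng):
        d = rng.binomial(2, 0.4, size=(20, 40)).astype(float)
        d[1] = d[0]
        scores = compute_pcs(make_genotypes(d), k=3)
        assert np.allclose(scores.iloc[0], scores.iloc[1])

    def test_scores_orthogonal(self, rng):
        d = rng.binomial(2, 0.3, size=(60, 100)).astype(float)
        scores = compute_pcs(make_genotypes(d), k=5).to_numpy()
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(gram))

    def test_two_population_separation(self, rng):
        # allele-frequency divergence between two subpopulations
        n_pop, nv = 60, 150
        p1 = rng.uniform(0.1, 0.5, nv)
        shift = rng.choice([-0.15, 0.15], nv)
        p2 = np.clip(p1 + shift, 0.02, 0.98)
        d = np.vstack(
            [rng.binomial(2, p1, (n_pop, nv)), rng.binomial(2, p2, (n_pop, nv))]
        ).astype(float)
        pc1 = compute_pcs(make_genotypes(d), k=2)["PC1"].to_numpy()
        assert (
            np.median(pc1[:n_pop]) < np.min(pc1[n_pop:])
            or np.median(pc1[:n_pop]) > np.max(pc1[n_pop:])
        )

    def test_rank_truncation_warns(self, rng):
        d = rng.binomial(2, 0.4, size=(4, 30)).astype(float)
        with pytest.warns(UserWarning, match="rank"):
            scores = compute_pcs(make_genotypes(d), k=10)
        assert scores.shape[1] < 10


class TestGRM:
    def test_symmetric(self, demo_cohort):
        grm = compute_grm(demo_cohort.genotypes)
        assert np.allclose(grm.values, grm.values.T)

    def test_hand_computed_toy(self):
        # 3 samples x 2 variants, no missingness
        d = np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]])
        grm = compute_grm(make_genotypes(d))
        p = d.mean(axis=0) / 2
        z = (d - 2 * p) / np.sqrt(2 * p * (1 - p))
        expected = z @ z.T / 2
        assert np.allclose(grm.values, expected)
        assert grm.n_variants_used == 2

    def test_mean_diagonal_near_one(self, rng):
        n, nv = 500, 5000
        p = rng.uniform(0.1, 0.5, nv)
        d = rng.binomial(2, p, (n, nv)).astype(float)
        grm = compute_grm(make_genotypes(d))
        diag = np.diag(grm.values)
        se = diag.std(ddof=1) / np.sqrt(n)
        assert abs(diag.mean() - 1.0) < 3 * max(se, 1e-3)

    def test_duplicated_sample_off_diagonal(self, rng):
        d = rng.binomial(2, 0.3, size=(40, 400)).astype(float)
        d[1] = d[0]
        grm = compute_grm(make_genotypes(d))
        assert grm.values[0, 1] == pytest.approx(grm.values[0, 0], rel=1e-9)

    def test_monomorphic_excluded(self, rng):
        d = rng.binomial(2, 0.3, size=(30, 5)).astype(float)
        d[:, 2] = 0.0
        grm = compute_grm(make_genotypes(d))
        assert grm.n_variants_used == 4
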
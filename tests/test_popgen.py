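"""Genotype QC, kinship, PCA, LD, blocks, Nei distance, concordance."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sunlipid.genotypes import GenotypeMatrix
from sunlipid.popgen import (
    LDBlock,
    block_bonferroni_threshold,
    concordance_test,
    detect_ld_blocks,
    filter_snps,
    kinship_centered_ibs,
    ld_decay,
    ld_r2,
    maf,
    nei_distance,
    pca_genotypes,
)
from sunlipid.synthetic import SimConfig, simulate_genotypes
from tests.conftest import block_layout


def make_geno(dosage, dp=None, pos=None, chrom=None):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    if dp is None:
        dp = np.full((n, m), 30)
    if pos is None:
        pos = np.arange(1, m + 1) * 1000
    if chrom is None:
        chrom = np.array(["chr1"] * m, dtype=object)
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n)],
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.array(["A"] * m, dtype=object),
        alt=np.array(["T"] * m, dtype=object),
        dosage=dosage,
        dp=np.asarray(dp),
    )


class TestMaf:
    def test_examples(self):
        assert maf([0, 1, 2]) == 0.5
        assert maf([2, 2, 2]) == 0.0
        assert maf([0, 0, 1, np.nan]) == pytest.approx(1 / 6)

    def test_all_missing(self):
        with pytest.raises(ValueError):
            maf([np.nan, np.nan])


class TestFilterSnps:
    def test_maf_boundaries(self):
        g = make_geno(np.array([[0, 0], [0, 0], [0, 0], [1, 1]]))
        kept, counts = filter_snps(g, min_maf=0.01)
        assert kept.n_snps == 2  # MAF 0.125 retained
        kept2, _ = filter_snps(g, min_maf=0.2)
        assert kept2.n_snps == 0

    def test_missing_rate_boundary(self):
        d = np.array([[0.0, 0], [np.nan, 0], [np.nan, 1], [1, 1]])
        g = make_geno(d)
        kept, counts = filter_snps(g, min_maf=0.01)
        # SNP 0 has missing rate 0.5 >= 0.3 -> removed
        assert kept.n_snps == 1
        assert counts["snps_removed_missing"] == 1

    def test_dp_boundary_masks_dp4(self):
        d = np.array([[0.0, 0], [1, 0], [2, 1], [1, 1]])
        dp = np.array([[4, 30], [30, 30], [30, 30], [30, 30]])
        g = make_geno(d, dp=dp)
        kept, counts = filter_snps(g, min_maf=0.01, max_missing=0.6)
        assert counts["calls_masked_low_dp"] == 1
        assert np.isnan(kept.dosage[0, 0])

    def test_idempotent(self, small_geno):
        once, _ = filter_snps(small_geno, min_maf=0.03)
        twice, counts = filter_snps(once, min_maf=0.03)
        assert twice.n_snps == once.n_snps
        np.testing.assert_array_equal(
            np.nan_to_num(once.dosage, nan=-1),
            np.nan_to_num(twice.dosage, nan=-1),
        )

    def test_empty_result_warns(self):
        g = make_geno(np.zeros((4, 3)))  # monomorphic everywhere
        with pytest.warns(UserWarning, match="no SNPs"):
            kept, _ = filter_snps(g)
        assert kept.n_snps == 0


class TestKinship:
    def test_brute_force_oracle(self, small_geno):
        K = kinship_centered_ibs(small_geno).to_numpy()
        d = small_geno.dosage.copy()
        mean = np.nanmean(d, axis=0)
        filled = np.where(np.isnan(d), mean[None, :], d)
        p = mean / 2.0
        poly = (p > 0) & (p < 1)
        denom = 2.0 * np.sum(p[poly] * (1 - p[poly]))
        n = small_geno.n_samples
        expect = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                acc = 0.0
                for s in np.flatnonzero(poly):
                    acc += (filled[i, s] - 2 * p[s]) * (filled[j, s] - 2 * p[s])
                expect[i, j] = acc / denom
        np.testing.assert_allclose(K, expect, atol=1e-10)

    def test_identical_samples(self):
        base = np.array([[0, 1, 2, 1, 0], [0, 1, 2, 1, 0], [2, 1, 0, 0, 2]])
        K = kinship_centered_ibs(make_geno(base)).to_numpy()
        assert K[0, 1] == pytest.approx(K[0, 0])
        np.testing.assert_allclose(K[0], K[1])

    def test_symmetric_and_psd(self, small_geno):
        K = kinship_centered_ibs(small_geno).to_numpy()
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        assert np.linalg.eigvalsh(K).min() > -1e-8

    def test_unrelated_offdiagonal_near_zero(self):
        """Centering at sample frequencies forces every row of W to sum to
        zero, so sum(K) = 0 exactly and the off-diagonal mean for unrelated
        samples is -tr(K)/(n(n-1)) = O(1/n), vanishing with panel size."""
        n = 80
        means = []
        for seed in range(10):
            cfg = SimConfig(n_lines=n, n_snps=300, n_chroms=3, subpop_count=1,
                            snp_spacing_bp=10_000_000, missing_rate=0.0,
                            seed=seed)
            K = kinship_centered_ibs(simulate_genotypes(cfg)).to_numpy()
            assert abs(K.sum()) < 1e-8
            iu = np.triu_indices_from(K, 1)
            means.append(K[iu].mean())
        assert abs(np.mean(means)) < 2.0 / n

    def test_monomorphic_only_rejected(self):
        with pytest.raises(ValueError):
            kinship_centered_ibs(make_geno(np.full((4, 3), 2.0)))


class TestPca:
    def test_subpopulations_separate(self):
        cfg = SimConfig(n_lines=100, n_snps=300, n_chroms=3, subpop_count=2,
                        fst=0.25, missing_rate=0.05, seed=7)
        g = simulate_genotypes(cfg)
        coords, fractions = pca_genotypes(g, n_pcs=3)
        labels = g.metadata["subpop"].to_numpy()
        a = coords.loc[labels == 0, "PC1"]
        b = coords.loc[labels == 1, "PC1"]
        pooled = np.sqrt((a.var() + b.var()) / 2)
        assert abs(a.mean() - b.mean()) > 2 * pooled
        assert (np.diff(fractions) <= 1e-12).all()
        assert fractions.sum() <= 1.0 + 1e-12

    def test_duplicate_sample_identical_coords(self):
        base = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 0],
                         [1, 0, 1, 2]])
        coords, _ = pca_genotypes(make_geno(base), n_pcs=2)
        np.testing.assert_allclose(coords.iloc[0], coords.iloc[1], atol=1e-10)

    def test_too_many_pcs(self, small_geno):
        with pytest.raises(ValueError):
            pca_genotypes(small_geno, n_pcs=1000)


class TestLdR2:
    def test_identical_snps_r2_one(self):
        d = np.array([[0, 0], [1, 1], [2, 2], [1, 1], [0, 0], [2, 2]])
        pairs = ld_r2(make_geno(d), min_maf=0.01)
        assert pairs["r2"].iloc[0] == pytest.approx(1.0)

    def test_allele_relabeling_invariance(self, small_geno):
        pairs = ld_r2(small_geno, min_maf=0.03)
        flipped = GenotypeMatrix(
            samples=small_geno.samples,
            chrom=small_geno.chrom, pos=small_geno.pos,
            ref=small_geno.alt, alt=small_geno.ref,
            dosage=2.0 - small_geno.dosage, dp=small_geno.dp,
        )
        pairs_f = ld_r2(flipped, min_maf=0.03)
        merged = pairs.merge(pairs_f, on=["chrom", "pos_a", "pos_b"])
        np.testing.assert_allclose(merged["r2_x"], merged["r2_y"], atol=1e-12)

    def test_independent_snps_low_r2(self):
        cfg = SimConfig(n_lines=500, n_snps=60, n_chroms=1, subpop_count=1,
                        snp_spacing_bp=50_000, ld_decay_bp=1.0,
                        missing_rate=0.0, maf_range=(0.2, 0.5), seed=5)
        pairs = ld_r2(simulate_genotypes(cfg), min_maf=0.03)
        assert pairs["r2"].mean() < 0.01

    def test_matches_naive_oracle(self, small_geno):
        pairs = ld_r2(small_geno, min_maf=0.03)
        filt, _ = filter_snps(small_geno, max_missing=0.4 + 1e-12,
                              min_dp=4, min_maf=0.03)
        posmap = {(c, p): i for i, (c, p) in
                  enumerate(zip(filt.chrom, filt.pos))}
        rng = np.random.default_rng(1)
        take = rng.choice(len(pairs), size=min(100, len(pairs)),
                          replace=False)
        for row in pairs.iloc[take].itertuples():
            x = filt.dosage[:, posmap[(row.chrom, row.pos_a)]]
            y = filt.dosage[:, posmap[(row.chrom, row.pos_b)]]
            ok = ~(np.isnan(x) | np.isnan(y))
            expected = np.corrcoef(x[ok], y[ok])[0, 1] ** 2
            assert row.r2 == pytest.approx(expected, abs=1e-12)


class TestLdDecay:
    def test_flat_curve_not_reached(self):
        rng = np.random.default_rng(0)
        pairs = pd.DataFrame(
            {"distance": rng.uniform(1e3, 1e6, 500), "r2": 0.4}
        )
        _, half = ld_decay(pairs)
        assert half is None

    def test_curve_maximum_at_origin_and_recovery(self):
        cfg = SimConfig(n_lines=300, n_snps=400, n_chroms=1, subpop_count=1,
                        ld_decay_bp=500_000, snp_spacing_bp=100_000,
                        maf_range=(0.1, 0.5), missing_rate=0.0, seed=4)
        pairs = ld_r2(simulate_genotypes(cfg), min_maf=0.03)
        curve, half = ld_decay(pairs)
        peak_at = curve.loc[curve["r2_smooth"].idxmax(), "distance"]
        assert peak_at <= np.quantile(curve["distance"], 0.05)
        assert half is not None and 250_000 <= half <= 1_000_000

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            ld_decay(pd.DataFrame({"distance": [1.0], "r2": [0.5]}))


class TestLdBlocks:
    def test_perfect_ld_single_block(self):
        rng = np.random.default_rng(3)
        n = 120
        core = rng.integers(0, 2, n) + rng.integers(0, 2, n)
        flank1 = rng.integers(0, 2, n) + rng.integers(0, 2, n)
        flank2 = rng.integers(0, 2, n) + rng.integers(0, 2, n)
        cols = [flank1] + [core] * 5 + [flank2]
        d = np.column_stack(cols).astype(float)
        pos = np.array([1_000, 5_000_000, 5_000_100, 5_000_200, 5_000_300,
                        5_000_400, 10_000_000], dtype=np.int64)
        blocks = detect_ld_blocks(make_geno(d, pos=pos))
        assert len(blocks) == 1
        assert blocks[0].members == [1, 2, 3, 4, 5]
        assert blocks[0].start == 5_000_000 and blocks[0].end == 5_000_400

    def test_two_planted_blocks_recovered(self):
        pos, (a1, b1), (a2, b2) = block_layout()
        hits = 0
        for seed in range(3):
            cfg = SimConfig(n_lines=150, n_snps=len(pos), n_chroms=1,
                            subpop_count=1, ld_decay_bp=100_000,
                            maf_range=(0.2, 0.5), missing_rate=0.0,
                            seed=100 + seed)
            g = simulate_genotypes(cfg, positions={"chr1": pos})
            found = sorted(
                (min(b.members), max(b.members)) for b in detect_ld_blocks(g)
            )
            ok = (
                len(found) == 2
                and abs(found[0][0] - a1) <= 1 and abs(found[0][1] - b1) <= 1
                and abs(found[1][0] - a2) <= 1 and abs(found[1][1] - b2) <= 1
            )
            hits += ok
        assert hits == 3

    def test_printed_block_length_arithmetic(self):
        blk = LDBlock("chr3", 44_696_624, 46_188_263, [])
        assert blk.length_kb == 1491

    def test_region_with_too_few_snps(self, small_geno):
        with pytest.raises(ValueError, match="< 2 SNPs"):
            detect_ld_blocks(small_geno, region="chr1:1-2")


class TestBonferroniThreshold:
    @pytest.mark.parametrize(
        "n,alpha,expected",
        [(5000, 0.05, 1e-5), (1, 0.05, 0.05), (100, 0.01, 1e-4)],
    )
    def test_values(self, n, alpha, expected):
        assert block_bonferroni_threshold(n, alpha) == pytest.approx(expected)

    def test_invalid(self):
        with pytest.raises(ValueError):
            block_bonferroni_threshold(0)


class TestNeiDistance:
    def test_identical_zero(self):
        d = np.array([[0, 1, 2, 1], [0, 1, 2, 1]])
        D = nei_distance(make_geno(d)).to_numpy()
        assert D[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_opposite_homozygotes_flagged_infinite(self):
        d = np.array([[0, 0, 0], [2, 2, 2]])
        D = nei_distance(make_geno(d)).to_numpy()
        assert np.isinf(D[0, 1])

    def test_brute_force_oracle(self, small_geno):
        g = small_geno.take_samples(np.arange(8))
        D = nei_distance(g).to_numpy()
        X = g.dosage / 2.0
        for i in range(8):
            for j in range(8):
                if i == j:
                    continue
                ok = ~(np.isnan(X[i]) | np.isnan(X[j]))
                jxy = jx = jy = 0.0
                for s in np.flatnonzero(ok):
                    x, y = X[i, s], X[j, s]
                    jxy += x * y + (1 - x) * (1 - y)
                    jx += x * x + (1 - x) * (1 - x)
                    jy += y * y + (1 - y) * (1 - y)
                expected = -np.log(jxy / np.sqrt(jx * jy))
                assert D[i, j] == pytest.approx(expected, abs=1e-10)

    def test_symmetry(self, small_geno):
        D = nei_distance(small_geno.take_samples(np.arange(10))).to_numpy()
        np.testing.assert_allclose(D, D.T, atol=1e-12)
        assert (np.diag(D) == 0).all()


class TestConcordance:
    def test_identical_vectors(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, (3, 75)).astype(object)
        res = concordance_test(calls, calls.copy(), n_perm=99, seed=1)
        assert (res["concordance"] == 1.0).all()

    def test_partial_agreement(self):
        a = np.array([["AA", "AB", "AA"]], dtype=object)
        b = np.array([["AA", "AB", "BB"]], dtype=object)
        res = concordance_test(a, b, n_perm=99, seed=1)
        assert res["concordance"].iloc[0] == pytest.approx(2 / 3)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, (500, 400)).astype(object)
        b = rng.integers(0, 3, (500, 400)).astype(object)
        res = concordance_test(a, b, n_perm=199, seed=1)
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01

    def test_no_joint_calls_rejected(self):
        a = np.array([[np.nan, 1]], dtype=object)
        b = np.array([[1, np.nan]], dtype=object)
        with pytest.raises(ValueError, match="jointly"):
            concordance_test(a, b, n_perm=9)
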
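"""Population-genetics statistics for GBS dosage data.

Genotype QC (depth masking, missingness and MAF filters), centered-IBS
kinship, PCA on dosages, pairwise LD r-squared with decay smoothing,
confidence-interval haplotype blocks on unphased dosages, the LD-block
Bonferroni threshold, Nei's standard genetic distance, and a permutation
test for cross-platform genotyping concordance.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix

__all__ = [
    "LDBlock",
    "maf",
    "filter_snps",
    "kinship_centered_ibs",
    "pca_genotypes",
    "ld_r2",
    "ld_decay",
    "detect_ld_blocks",
    "block_bonferroni_threshold",
    "nei_distance",
    "concordance_test",
]


@dataclasses.dataclass
class LDBlock:
    """A haplotype block: 1-based inclusive coordinates plus member SNPs."""

    chrom: str
    start: int
    end: int
    members: list[int]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("block start > end")

    @property
    def length_kb(self) -> int:
        """Block span in kb, floor((end - start + 1) / 1000)."""
        return int((self.end - self.start + 1) // 1000)


def maf(dosages: np.ndarray) -> float:
    """Minor allele frequency of one SNP from diploid dosages (nan = missing)."""
    d = np.asarray(dosages, dtype=float)
    called = ~np.isnan(d)
    if not called.any():
        raise ValueError("all calls missing")
    p = d[called].sum() / (2.0 * called.sum())
    return float(min(p, 1.0 - p))


def _maf_vector(dosage: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(dosage, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def filter_snps(
    geno: GenotypeMatrix,
    max_missing: float = 0.3,
    min_dp: int = 4,
    min_maf: float = 0.01,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Depth-mask calls, then drop high-missingness and low-MAF SNPs.

    Calls with DP <= ``min_dp`` are set to missing first (strict DP > 4
    retained); then SNPs with missing fraction >= ``max_missing`` or
    MAF <= ``min_maf`` are removed (strict boundaries throughout).
    Returns the filtered matrix and per-criterion removal counts.
    """
    dosage = geno.dosage.copy()
    low_dp = geno.dp <= min_dp
    masked = int((low_dp & ~np.isnan(dosage)).sum())
    dosage[low_dp] = np.nan

    miss_frac = np.isnan(dosage).mean(axis=0)
    fail_missing = miss_frac >= max_missing
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mafs = _maf_vector(dosage)
    fail_maf = ~(mafs > min_maf)  # nan (all-missing) also fails
    keep = ~(fail_missing | fail_maf)
    counts = {
        "calls_masked_low_dp": masked,
        "snps_removed_missing": int(fail_missing.sum()),
        "snps_removed_maf": int((fail_maf & ~fail_missing).sum()),
        "snps_kept": int(keep.sum()),
    }
    if counts["snps_kept"] == 0:
        warnings.warn("no SNPs pass the filters", stacklevel=2)
    out = geno.take_snps(np.flatnonzero(keep))
    out = dataclasses.replace(out, dosage=dosage[:, keep])
    return out, counts


def _mean_impute(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fill missing dosages with the per-SNP mean; also return freqs p."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(dosage, axis=0)
    filled = np.where(np.isnan(dosage), mean[None, :], dosage)
    return filled, mean / 2.0


def kinship_centered_ibs(geno: GenotypeMatrix) -> pd.DataFrame:
    """Centered-IBS genomic relationship matrix.

    K = W W' / (2 sum_j p_j (1 - p_j)) with W the per-SNP centered dosage
    matrix (dosage - 2p), missing calls mean-imputed. The centering makes
    the expected off-diagonal zero for unrelated individuals.
    """
    filled, p = _mean_impute(geno.dosage)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all SNPs monomorphic: kinship undefined")
    W = filled[:, poly] - 2.0 * p[poly][None, :]
    denom = 2.0 * float(np.sum(p[poly] * (1.0 - p[poly])))
    K = W @ W.T / denom
    K = (K + K.T) / 2.0
    return pd.DataFrame(K, index=geno.samples, columns=geno.samples)


def pca_genotypes(
    geno: GenotypeMatrix, n_pcs: int = 3
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the mean-imputed, centered dosage matrix.

    Returns per-sample coordinates (columns PC1..PCn) and the explained
    variance fractions (non-increasing, summing to <= 1).
    """
    if n_pcs > min(geno.n_samples, geno.n_snps):
        raise ValueError("n_pcs exceeds matrix rank bound")
    from sklearn.decomposition import PCA

    filled, _ = _mean_impute(geno.dosage)
    pca = PCA(n_components=n_pcs, svd_solver="full")
    coords = pca.fit_transform(filled - filled.mean(axis=0))
    df = pd.DataFrame(
        coords, index=geno.samples, columns=[f"PC{i + 1}" for i in range(n_pcs)]
    )
    return df, pca.explained_variance_ratio_.copy()


def ld_r2(
    geno: GenotypeMatrix,
    max_dist_bp: int = 5_000_000,
    min_maf: float = 0.03,
    min_dp: int = 4,
    min_called: float = 0.6,
) -> pd.DataFrame:
    """Pairwise r-squared vs distance for intra-chromosomal SNP pairs.

    SNPs are first re-filtered (DP-masked calls, called fraction >=
    ``min_called``, MAF > ``min_maf``); r-squared is the squared Pearson
    correlation of dosages over jointly called samples. Monomorphic pairs
    are skipped.
    """
    filtered, _ = filter_snps(
        geno, max_missing=1.0 - min_called + 1e-12, min_dp=min_dp, min_maf=min_maf
    )
    dosage = filtered.dosage
    rows = []
    for c in pd.unique(filtered.chrom):
        idx = np.flatnonzero(filtered.chrom == c)
        pos = filtered.pos[idx]
        D = dosage[:, idx]
        called = ~np.isnan(D)
        Z = np.nan_to_num(D, nan=0.0)
        Z2 = Z * Z
        for a in range(len(idx)):
            hi = int(np.searchsorted(pos, pos[a] + max_dist_bp, side="right"))
            if hi <= a + 1:
                continue
            win = slice(a + 1, hi)
            # masked Pearson correlation via joint sufficient statistics
            m = called[:, a : a + 1] & called[:, win]
            x = Z[:, a : a + 1]
            n = m.sum(axis=0).astype(float)
            sx = (x * m).sum(axis=0)
            sy = (Z[:, win] * m).sum(axis=0)
            sxx = (Z2[:, a : a + 1] * m).sum(axis=0)
            syy = (Z2[:, win] * m).sum(axis=0)
            sxy = (x * Z[:, win] * m).sum(axis=0)
            var_x = n * sxx - sx * sx
            var_y = n * syy - sy * sy
            denom = var_x * var_y
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                r2 = np.where(denom > 0, (n * sxy - sx * sy) ** 2 / denom, np.nan)
            valid = (n >= 3) & np.isfinite(r2)
            for off in np.flatnonzero(valid):
                b = a + 1 + off
                rows.append(
                    (c, int(pos[a]), int(pos[b]), int(pos[b] - pos[a]),
                     float(r2[off]))
                )
    return pd.DataFrame(rows, columns=["chrom", "pos_a", "pos_b", "distance", "r2"])


def ld_decay(
    pairs: pd.DataFrame, span: float = 0.3
) -> tuple[pd.DataFrame, float | None]:
    """Local-regression smooth of r2 vs distance and the half-decay distance.

    The half-decay distance is the smallest distance at which the smoothed
    curve drops to half its maximum; ``None`` when the curve never crosses
    half-maximum ("not reached").
    """
    if len(pairs) < 100:
        raise ValueError("need at least 100 pairs for a decay curve")
    import statsmodels.api as sm

    dist = pairs["distance"].to_numpy(dtype=float)
    delta = 0.005 * (dist.max() - dist.min())
    sm_out = sm.nonparametric.lowess(
        pairs["r2"].to_numpy(), dist, frac=span, delta=delta
    )
    curve = pd.DataFrame(sm_out, columns=["distance", "r2_smooth"])
    curve = curve.drop_duplicates("distance").reset_index(drop=True)
    top = curve["r2_smooth"].max()
    below = curve.loc[curve["r2_smooth"] <= top / 2.0, "distance"]
    half = float(below.min()) if len(below) else None
    return curve, half


# ---------------------------------------------------------------------------
# Haplotype blocks: two-locus EM and D' confidence intervals on dosages
# ---------------------------------------------------------------------------

def _pair_counts(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    ok = ~(np.isnan(x) | np.isnan(y))
    n = np.zeros((3, 3))
    for i, j in zip(x[ok].astype(int), y[ok].astype(int)):
        n[i, j] += 1
    return n


def _haplotype_em(n: np.ndarray, n_iter: int = 100, tol: float = 1e-10) -> np.ndarray:
    """EM haplotype frequencies (fAB, fAb, faB, fab) from a 3x3 dosage table.

    Only the double heterozygote is phase-ambiguous; all other cells
    contribute known haplotypes.
    """
    total = 2.0 * n.sum()
    if total == 0:
        raise ValueError("no jointly called samples")
    # fixed contributions (A = alt at locus 1, B = alt at locus 2)
    base_AB = 2 * n[2, 2] + n[2, 1] + n[1, 2]
    base_Ab = 2 * n[2, 0] + n[2, 1] + n[1, 0]
    base_aB = 2 * n[0, 2] + n[0, 1] + n[1, 2]
    base_ab = 2 * n[0, 0] + n[0, 1] + n[1, 0]
    dh = n[1, 1]
    f = np.full(4, 0.25)
    for _ in range(n_iter):
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        c = 0.5 if cis + trans == 0 else cis / (cis + trans)
        new = np.array(
            [base_AB + c * dh, base_Ab + (1 - c) * dh,
             base_aB + (1 - c) * dh, base_ab + c * dh]
        ) / total
        if np.abs(new - f).max() < tol:
            f = new
            break
        f = new
    return f


def _genotype_probs(f: np.ndarray) -> np.ndarray:
    fAB, fAb, faB, fab = np.maximum(f, 1e-12)
    return np.array(
        [
            [fab * fab, 2 * fab * faB, faB * faB],
            [2 * fab * fAb, 2 * (fAB * fab + fAb * faB), 2 * fAB * faB],
            [fAb * fAb, 2 * fAB * fAb, fAB * fAB],
        ]
    )


def _dprime_ci(
    n: np.ndarray, grid: np.ndarray | None = None
) -> tuple[float, float, float]:
    """Point estimate and 90% likelihood interval of |D'| for one SNP pair."""
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    f = _haplotype_em(n)
    pA = f[0] + f[1]
    pB = f[0] + f[2]
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("monomorphic locus in pair")
    d = f[0] - pA * pB
    if d >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
        sign = 1.0
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
        sign = -1.0
    dprime = 0.0 if dmax == 0 else abs(d) / dmax
    ll = np.empty_like(grid)
    for k, g in enumerate(grid):
        D = sign * g * dmax
        fg = np.array(
            [pA * pB + D, pA * (1 - pB) - D, (1 - pA) * pB - D,
             (1 - pA) * (1 - pB) + D]
        )
        probs = _genotype_probs(fg)
        ll[k] = float((n * np.log(probs)).sum())
    w = np.exp(ll - ll.max())
    cdf = np.cumsum(w) / w.sum()
    low = float(grid[int(np.searchsorted(cdf, 0.05))])
    high = float(grid[min(int(np.searchsorted(cdf, 0.95)), len(grid) - 1)])
    return float(dprime), low, high


def _parse_region(region: str) -> tuple[str, int, int]:
    chrom, span = region.rsplit(":", 1)
    start, end = span.replace(",", "").split("-")
    return chrom, int(start), int(end)


def detect_ld_blocks(
    geno: GenotypeMatrix,
    region: str | None = None,
    strong_low: float = 0.70,
    strong_high: float = 0.98,
    recomb_high: float = 0.90,
    min_strong_frac: float = 0.95,
) -> list[LDBlock]:
    """Confidence-interval haplotype blocks from unphased dosages.

    Per SNP pair, D' and its 90% likelihood interval are estimated by
    two-locus haplotype EM. A pair is in *strong LD* when the interval
    lower bound >= ``strong_low`` and upper bound >= ``strong_high``, and
    shows *strong recombination* when the upper bound < ``recomb_high``.
    Any interval of >= 2 SNPs in which at least ``min_strong_frac`` of
    informative pairs are strong-LD is a candidate block; candidates are
    selected greedily, longest (bp span) first, without overlap.
    """
    if region is not None:
        chrom, lo, hi = _parse_region(region)
        idx = np.flatnonzero(
            (geno.chrom == chrom) & (geno.pos >= lo) & (geno.pos <= hi)
        )
        if len(idx) < 2:
            raise ValueError(f"region {region} holds < 2 SNPs")
        groups = [(chrom, idx)]
    else:
        groups = [
            (c, np.flatnonzero(geno.chrom == c)) for c in pd.unique(geno.chrom)
        ]

    blocks: list[LDBlock] = []
    for chrom, idx in groups:
        m = len(idx)
        if m < 2:
            continue
        strong = np.zeros((m, m), dtype=bool)
        informative = np.zeros((m, m), dtype=bool)
        for a in range(m):
            for b in range(a + 1, m):
                n = _pair_counts(geno.dosage[:, idx[a]], geno.dosage[:, idx[b]])
                try:
                    _, low, high = _dprime_ci(n)
                except ValueError:
                    continue
                if low >= strong_low and high >= strong_high:
                    strong[a, b] = informative[a, b] = True
                elif high < recomb_high:
                    informative[a, b] = True
        s_cum = strong.cumsum(0).cumsum(1)
        i_cum = informative.cumsum(0).cumsum(1)

        def _count(cum: np.ndarray, a: int, b: int) -> int:
            # pairs (i, j) with a <= i < j <= b
            total = cum[b, b]
            if a > 0:
                total -= cum[a - 1, b] + cum[b, a - 1] - cum[a - 1, a - 1]
            return int(total)

        candidates = []
        pos = geno.pos[idx]
        for a in range(m):
            for b in range(a + 1, m):
                ni = _count(i_cum, a, b)
                if ni == 0:
                    continue
                if _count(s_cum, a, b) / ni >= min_strong_frac:
                    candidates.append((int(pos[b] - pos[a]), a, b))
        candidates.sort(key=lambda t: (-t[0], t[1]))
        used = np.zeros(m, dtype=bool)
        for _, a, b in candidates:
            if used[a : b + 1].any():
                continue
            used[a : b + 1] = True
            blocks.append(
                LDBlock(
                    chrom=str(chrom),
                    start=int(pos[a]),
                    end=int(pos[b]),
                    members=[int(i) for i in idx[a : b + 1]],
                )
            )
    blocks.sort(key=lambda blk: (blk.chrom, blk.start))
    return blocks


def block_bonferroni_threshold(n_blocks: int = 5000, alpha: float = 0.05) -> float:
    """Genome-wide p-value threshold alpha / number-of-LD-blocks."""
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    return alpha / n_blocks


def nei_distance(geno: GenotypeMatrix, method: str = "nei1972") -> pd.DataFrame:
    """Pairwise Nei (1972) standard genetic distance between samples.

    Each individual is treated as a one-individual population with per-locus
    allele frequencies (x, 1-x), x = dosage/2. D = -ln I with the normalized
    gene identity I = sum(xy) / sqrt(sum(x^2) sum(y^2)) summed over both
    alleles of every jointly called locus. Disjoint profiles (I = 0) are
    flagged with ``inf``. ``method="ibs"`` returns 1 - IBS instead.
    """
    if geno.n_samples < 2:
        raise ValueError("need at least 2 samples")
    X = geno.dosage / 2.0
    n = geno.n_samples
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(np.isnan(X[i]) | np.isnan(X[j]))
            if not ok.any():
                raise ValueError(
                    f"no shared called loci for {geno.samples[i]}, {geno.samples[j]}"
                )
            x, y = X[i, ok], X[j, ok]
            if method == "ibs":
                D[i, j] = D[j, i] = float(np.mean(np.abs(x - y)))
                continue
            jxy = float(np.sum(x * y + (1 - x) * (1 - y)))
            jx = float(np.sum(x * x + (1 - x) * (1 - x)))
            jy = float(np.sum(y * y + (1 - y) * (1 - y)))
            identity = jxy / np.sqrt(jx * jy)
            D[i, j] = D[j, i] = np.inf if identity <= 0 else -np.log(identity)
    return pd.DataFrame(D, index=geno.samples, columns=geno.samples)


def concordance_test(
    calls_a: np.ndarray,
    calls_b: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-SNP concordance between two genotyping platforms, permutation p.

    ``calls_a``/``calls_b``: (n_snps, n_lines) arrays of genotype labels
    (any hashable; nan/None = missing). Concordance is the fraction of
    identical calls over jointly called lines; the null distribution comes
    from permuting the line labels of the second platform, with
    p = (1 + #{permuted >= observed}) / (n_perm + 1), BH-adjusted across
    SNPs.
    """
    a = np.asarray(calls_a, dtype=object)
    b = np.asarray(calls_b, dtype=object)
    if a.shape != b.shape:
        raise ValueError("call matrices must share shape")
    rng = np.random.default_rng(seed)
    n_snps, n_lines = a.shape
    conc = np.empty(n_snps)
    pvals = np.empty(n_snps)
    for s in range(n_snps):
        miss_a = pd.isna(a[s])
        miss_b = pd.isna(b[s])
        joint = ~(miss_a | miss_b)
        if not joint.any():
            raise ValueError(f"no jointly called lines for SNP {s}")
        obs = float(np.mean(a[s, joint] == b[s, joint]))
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n_lines)
            bj = b[s, perm]
            jm = ~(miss_a | pd.isna(bj))
            stat = float(np.mean(a[s, jm] == bj[jm])) if jm.any() else 0.0
            if stat >= obs:
                count += 1
        conc[s] = obs
        pvals[s] = (1 + count) / (n_perm + 1)
    from statsmodels.stats.multitest import multipletests

    bh = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({"concordance": conc, "p": pvals, "bh_p": bh})
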
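"""Mixed-linear-model association scans for lipid traits.

The model is Y = SNP + covariates + u + e with u ~ N(0, sigma_g^2 K) for a
centered-IBS kinship K: the standard single-locus MLM with population
structure captured by principal components (fixed) and relatedness by the
kinship random effect. Variance components are estimated once per trait
under the null by REML on the eigendecomposition of K and then held fixed
for the per-SNP generalized-least-squares scan (the P3D approximation), so
each SNP costs one weighted regression in the rotated space.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import GenotypeMatrix

__all__ = [
    "NullModel",
    "prepare_phenotypes",
    "build_design",
    "fit_null_model",
    "association_scan",
    "qq_and_manhattan_tables",
    "genomic_inflation",
    "variance_explained",
]


def prepare_phenotypes(
    traits: pd.DataFrame, trait_cols: list[str], max_missing: float = 0.10
) -> tuple[pd.DataFrame, list]:
    """Drop samples with >= ``max_missing`` fraction of missing trait values."""
    frac = traits[trait_cols].isna().mean(axis=1)
    removed = list(traits.index[frac >= max_missing])
    kept = traits.loc[frac < max_missing].copy()
    if kept.empty:
        raise ValueError("every sample exceeds the phenotype missingness cap")
    return kept, removed


def build_design(
    table: pd.DataFrame,
    pcs: pd.DataFrame | np.ndarray | None = None,
    factors: tuple[str, ...] = (),
    continuous: tuple[str, ...] = (),
) -> np.ndarray:
    """Fixed-effect design matrix: intercept, PCs, factor dummies, covariates."""
    n = len(table)
    cols = [np.ones((n, 1))]
    if pcs is not None:
        cols.append(np.asarray(pcs, dtype=float))
    for f in factors:
        dummies = pd.get_dummies(table[f].astype(str), drop_first=True)
        if dummies.shape[1]:
            cols.append(dummies.to_numpy(dtype=float))
    for c in continuous:
        v = table[c].to_numpy(dtype=float)
        sd = v.std()
        cols.append(((v - v.mean()) / (sd if sd > 0 else 1.0)).reshape(-1, 1))
    X = np.hstack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear fixed-effect design")
    return X


@dataclasses.dataclass
class NullModel:
    """Null-model fit: variance components plus the eigen-rotation."""

    sigma_g2: float
    sigma_e2: float
    h2: float
    delta: float  # sigma_e2 / sigma_g2
    eigenvalues: np.ndarray
    U: np.ndarray  # eigenvectors of K, rotation matrix
    X_rot: np.ndarray
    y_rot: np.ndarray
    beta: np.ndarray
    reml_loglik: float


def _reml_neg_loglik(log_delta: float, s: np.ndarray, Xr: np.ndarray,
                     yr: np.ndarray) -> float:
    delta = np.exp(log_delta)
    v = s + delta
    w = 1.0 / v
    Xw = Xr * w[:, None]
    A = Xr.T @ Xw
    beta = np.linalg.solve(A, Xw.T @ yr)
    r = yr - Xr @ beta
    n, p = Xr.shape
    sigma = float(r @ (w * r)) / (n - p)
    _, logdet_A = np.linalg.slogdet(A)
    _, logdet_xx = np.linalg.slogdet(Xr.T @ Xr)
    ll = -0.5 * (
        (n - p) * (np.log(2 * np.pi * sigma) + 1)
        + np.log(v).sum()
        + logdet_A
        - logdet_xx
    )
    return -ll


def fit_null_model(
    y: np.ndarray, X: np.ndarray, kinship: pd.DataFrame | np.ndarray
) -> NullModel:
    """REML variance components for y = X beta + u + e, u ~ N(0, sg^2 K).

    Uses the eigendecomposition of K (EMMA parameterization): with
    K = U S U', the rotated model has independent errors with variances
    sigma_g^2 (s_i + delta), delta = sigma_e2/sigma_g2, and the REML
    criterion is maximized over delta by bounded scalar optimization.
    The returned rotation lets the per-SNP scan run as weighted least
    squares without refitting variance components.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    K = np.asarray(kinship, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear fixed-effect design")
    s, U = np.linalg.eigh((K + K.T) / 2.0)
    s = np.maximum(s, 0.0)
    if np.allclose(K, np.eye(len(K)) * K[0, 0], atol=1e-10):
        warnings.warn(
            "kinship proportional to identity: variance split not identifiable",
            stacklevel=2,
        )
    yr = U.T @ y
    Xr = U.T @ X
    res = optimize.minimize_scalar(
        _reml_neg_loglik,
        bounds=(-10.0, 10.0),
        args=(s, Xr, yr),
        method="bounded",
        options={"xatol": 1e-6},
    )
    log_delta = float(res.x)
    # guard against boundary optima
    for cand in (-10.0, 10.0):
        if _reml_neg_loglik(cand, s, Xr, yr) < res.fun:
            log_delta = cand
    delta = float(np.exp(log_delta))
    v = s + delta
    w = 1.0 / v
    Xw = Xr * w[:, None]
    A = Xr.T @ Xw
    beta = np.linalg.solve(A, Xw.T @ yr)
    r = yr - Xr @ beta
    n, p = Xr.shape
    sigma_g2 = float(r @ (w * r)) / (n - p)
    sigma_e2 = sigma_g2 * delta
    mean_diag = float(np.trace(K)) / len(K)
    h2 = sigma_g2 * mean_diag / (sigma_g2 * mean_diag + sigma_e2)
    return NullModel(
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        h2=float(h2),
        delta=delta,
        eigenvalues=s,
        U=U,
        X_rot=Xr,
        y_rot=yr,
        beta=beta,
        reml_loglik=float(-res.fun),
    )


def association_scan(
    geno: GenotypeMatrix,
    y: np.ndarray,
    X: np.ndarray | None = None,
    null_model: NullModel | None = None,
    min_maf: float = 0.0,
) -> pd.DataFrame:
    """Per-SNP effect, standard error and Wald p-value.

    With ``null_model`` supplied the scan is generalized least squares in
    the rotated space at fixed variance components (P3D); without one it is
    ordinary least squares (the naive scan used for comparison). SNPs whose
    within-sample MAF falls at or below ``min_maf`` are skipped; samples
    missing a SNP's call are dropped for that SNP via an exact GLS solve on
    the remaining rows.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    p_cov = X.shape[1]

    if null_model is not None:
        U, s, delta = null_model.U, null_model.eigenvalues, null_model.delta
        w = 1.0 / (s + delta)
        Xr, yr = null_model.X_rot, null_model.y_rot
        G_rot = U.T @ np.nan_to_num(geno.dosage, nan=0.0)  # complete-data path
    else:
        w = np.ones(n)
        Xr, yr = X, y
        G_rot = np.nan_to_num(geno.dosage, nan=0.0)

    Xw = Xr * w[:, None]
    A = Xr.T @ Xw
    A_inv = np.linalg.inv(A)
    bx = Xw.T @ yr
    yy = float(yr @ (w * yr))
    base_rss = yy - float(bx @ (A_inv @ bx))

    rows = []
    dosage = geno.dosage
    for j in range(geno.n_snps):
        g = dosage[:, j]
        called = ~np.isnan(g)
        n_used = int(called.sum())
        if n_used < p_cov + 2:
            continue
        p_allele = g[called].sum() / (2 * n_used)
        snp_maf = min(p_allele, 1 - p_allele)
        if not snp_maf > min_maf:
            continue
        if called.all():
            gr = G_rot[:, j]
            wg = w * gr
            c = Xr.T @ wg
            d = float(gr @ wg)
            e = float(wg @ yr)
            Ac = A_inv @ c
            denom = d - float(c @ Ac)
            if denom <= 1e-12:
                continue
            beta_g = (e - float(c @ (A_inv @ bx))) / denom
            rss = base_rss - beta_g**2 * denom
            dof = n - p_cov - 1
            sigma2 = max(rss, 0.0) / dof
            se = float(np.sqrt(sigma2 / denom))
        else:
            # exact GLS on the called subset at fixed variance components
            gs = g[called]
            Xs = np.column_stack([X[called], gs])
            ys = y[called]
            if null_model is not None:
                K = (null_model.U * null_model.eigenvalues) @ null_model.U.T
                V = null_model.sigma_g2 * K[np.ix_(called, called)] + (
                    null_model.sigma_e2 * np.eye(n_used)
                )
                from scipy.linalg import cholesky, solve_triangular

                L = cholesky(V, lower=True)
                Xt = solve_triangular(L, Xs, lower=True)
                yt = solve_triangular(L, ys, lower=True)
            else:
                Xt, yt = Xs, ys
            q = Xt.shape[1]
            coef, _, _, _ = np.linalg.lstsq(Xt, yt, rcond=None)
            resid = yt - Xt @ coef
            dof = n_used - q
            if dof < 1:
                continue
            sigma2 = float(resid @ resid) / dof  # V already in the whitening
            cov = sigma2 * np.linalg.inv(Xt.T @ Xt)
            beta_g = float(coef[-1])
            se = float(np.sqrt(cov[-1, -1]))
        tstat = beta_g / se
        pval = 2.0 * stats.t.sf(abs(tstat), dof)
        rows.append(
            (geno.chrom[j], int(geno.pos[j]), beta_g, se,
             max(pval, np.finfo(float).tiny), float(snp_maf), n_used)
        )
    out = pd.DataFrame(
        rows, columns=["chrom", "pos", "beta", "se", "p", "maf", "n"]
    )
    return out.sort_values(["chrom", "pos"]).reset_index(drop=True)


def genomic_inflation(pvalues: np.ndarray) -> float:
    """Genomic inflation factor: median observed chi2 over its null median."""
    p = np.asarray(pvalues, dtype=float)
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


def qq_and_manhattan_tables(
    results: pd.DataFrame,
) -> dict[str, pd.DataFrame | float]:
    """QQ and Manhattan plotting tables plus the genomic-inflation factor.

    QQ table: sorted -log10 observed p against expected uniform quantiles.
    Manhattan table: per-SNP -log10 p with a cumulative genome coordinate.
    """
    if results.empty:
        raise ValueError("empty association results")
    p = results["p"].to_numpy()
    m = len(p)
    qq = pd.DataFrame(
        {
            "expected": -np.log10((np.arange(1, m + 1) - 0.5) / m),
            "observed": -np.log10(np.sort(p)),
        }
    )
    man = results.copy()
    offset = 0
    cum = np.empty(m, dtype=float)
    for c in pd.unique(man["chrom"]):
        mask = (man["chrom"] == c).to_numpy()
        cum[mask] = man.loc[mask, "pos"].to_numpy() + offset
        offset = cum[mask].max() + 1
    man["cum_pos"] = cum
    man["neglog10p"] = -np.log10(man["p"])
    return {"qq": qq, "manhattan": man, "lambda_gc": genomic_inflation(p)}


def variance_explained(
    geno_subset: np.ndarray, X: np.ndarray, y: np.ndarray
) -> dict[str, float]:
    """Percent variance explained jointly by a SNP set beyond covariates.

    Ordinary linear model on complete cases: incremental R^2 = R^2 of
    covariates + SNPs minus R^2 of covariates alone, both in percent.
    """
    G = np.asarray(geno_subset, dtype=float)
    if G.ndim == 1:
        G = G.reshape(-1, 1)
    if G.size == 0:
        G = G.reshape(len(y), 0)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rows = ~np.isnan(y)
    if G.shape[1]:
        rows &= ~np.isnan(G).any(axis=1)
    Xc, yc = X[rows], y[rows]
    Gc = G[rows]
    if Xc.shape[1] + Gc.shape[1] >= len(yc):
        raise ValueError("more regressors than samples")

    def _r2(design: np.ndarray) -> float:
        coef, _, _, _ = np.linalg.lstsq(design, yc, rcond=None)
        resid = yc - design @ coef
        tss = float(((yc - yc.mean()) ** 2).sum())
        return 1.0 - float((resid**2).sum()) / tss

    r2_cov = _r2(Xc)
    r2_joint = _r2(np.column_stack([Xc, Gc])) if Gc.shape[1] else r2_cov
    return {
        "incremental_r2_pct": max(r2_joint - r2_cov, 0.0) * 100.0,
        "joint_r2_pct": r2_joint * 100.0,
        "covariate_r2_pct": r2_cov * 100.0,
    }
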
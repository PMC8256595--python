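"""Genotype x environment partitioning of replicated lipid measurements.

A multi-year replication design (lines grown for several seasons with
biological replicates) is analyzed with the two-way fixed-effects model

    abundance ~ line + year + line:year

using sequential (Type I) sums of squares in that term order. Besides the
classical F tests the module reports SS fractions, per-degree-of-freedom
fractions, and method-of-moments variance-component fractions from the
expected mean squares — the latter are the unbiased quantities to compare
with planted simulation fractions. BH correction and a classical MDS
summary of sample lipid profiles complete the stage.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["gxe_anova", "bh_adjust", "mds_profile"]


def gxe_anova(table: pd.DataFrame, trait: str, ss_type: int = 1) -> pd.DataFrame:
    """Two-way ANOVA with interaction for one trait.

    Parameters
    ----------
    table
        Must contain factor columns ``line`` and ``year`` plus the trait.
    trait
        Trait column name.
    ss_type
        1 (sequential, default, term order line -> year -> interaction)
        or 2.

    Returns
    -------
    DataFrame indexed by term (line, year, line:year, residual) with
    columns df, sum_sq, F, p, ss_fraction, ss_fraction_per_df,
    varcomp_fraction. SS fractions sum to 1 over the four rows.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = table[["line", "year", trait]].dropna().copy()
    data["line"] = data["line"].astype(str)
    data["year"] = data["year"].astype(str)
    n_lines = data["line"].nunique()
    n_years = data["year"].nunique()
    if n_lines < 2 or n_years < 2:
        raise ValueError("need >= 2 levels for both line and year")
    cell_sizes = data.groupby(["line", "year"]).size()
    if len(cell_sizes) < n_lines * n_years:
        raise ValueError("every (line, year) cell needs >= 1 observation")
    if (cell_sizes < 2).all():
        raise ValueError(
            "single-replicate design: interaction confounded with residual"
        )

    y = data[trait].to_numpy(dtype=float)
    terms = ["line", "year", "line:year", "residual"]
    if np.allclose(y, y[0]):
        # degenerate: constant response, no variation to partition
        out = pd.DataFrame(
            {
                "df": [n_lines - 1, n_years - 1,
                       (n_lines - 1) * (n_years - 1),
                       len(y) - n_lines * n_years],
                "sum_sq": 0.0,
                "F": [0.0, 0.0, 0.0, np.nan],
                "p": [1.0, 1.0, 1.0, np.nan],
            },
            index=terms,
        )
        out["ss_fraction"] = 0.0
        out["ss_fraction_per_df"] = 0.0
        out["varcomp_fraction"] = 0.0
        return out

    model = smf.ols(
        f"Q('{trait}') ~ C(line) + C(year) + C(line):C(year)", data=data
    ).fit()
    tab = sm.stats.anova_lm(model, typ=ss_type)
    tab = tab.rename(
        index={
            "C(line)": "line",
            "C(year)": "year",
            "C(line):C(year)": "line:year",
            "Residual": "residual",
        }
    )
    out = pd.DataFrame(
        {
            "df": tab["df"].astype(int),
            "sum_sq": tab["sum_sq"],
            "F": tab["F"],
            "p": tab["PR(>F)"],
        }
    ).reindex(terms)
    total_ss = out["sum_sq"].sum()
    out["ss_fraction"] = out["sum_sq"] / total_ss
    per_df = out["sum_sq"] / out["df"]
    out["ss_fraction_per_df"] = per_df / per_df.sum()

    # method-of-moments variance components from expected mean squares
    # (balanced approximation with the mean cell size)
    k_bar = float(cell_sizes.mean())
    ms = per_df  # mean squares
    sigma_e = ms["residual"]
    sigma_gxe = max((ms["line:year"] - sigma_e) / k_bar, 0.0)
    sigma_line = max((ms["line"] - ms["line:year"]) / (n_years * k_bar), 0.0)
    sigma_year = max((ms["year"] - ms["line:year"]) / (n_lines * k_bar), 0.0)
    comps = np.array([sigma_line, sigma_year, sigma_gxe, sigma_e])
    out["varcomp_fraction"] = comps / comps.sum()
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a nonempty 1-D sequence")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def mds_profile(
    table: pd.DataFrame, trait_cols: list[str] | None = None, dims: int = 2
) -> pd.DataFrame:
    """Classical MDS of samples on 1 - Spearman correlation distances.

    ``trait_cols`` defaults to every numeric column other than the design
    columns (line, year, rep). Samples with a constant profile (Spearman
    undefined) raise an error naming the sample.
    """
    design = {"line", "year", "rep", "sample"}
    if trait_cols is None:
        trait_cols = [
            c
            for c in table.columns
            if c not in design and pd.api.types.is_numeric_dtype(table[c])
        ]
    profiles = table[trait_cols].to_numpy(dtype=float)
    n = len(profiles)
    if n < 3 or len(trait_cols) < 3:
        raise ValueError("need >= 3 samples and >= 3 traits")
    for i in range(n):
        if np.nanstd(profiles[i]) == 0:
            label = table.index[i]
            raise ValueError(f"constant trait profile for sample {label!r}")
    rho = stats.spearmanr(profiles, axis=1).statistic
    rho = np.atleast_2d(rho)
    D = 1.0 - rho
    np.fill_diagonal(D, 0.0)
    # Torgerson double centering
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = vecs[:, :dims] * np.sqrt(np.maximum(vals[:dims], 0.0))
    return pd.DataFrame(
        coords, index=table.index, columns=[f"dim{i + 1}" for i in range(dims)]
    )
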
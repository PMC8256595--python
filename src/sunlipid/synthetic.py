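"""Synthetic data with known ground truth for every pipeline stage.

Emulates the study design end-to-end without any downloads: a structured
panel of inbred lines genotyped at biallelic SNPs with local LD, lipid
traits with planted additive QTL on top of a polygenic background, a
multi-year replication experiment with genotype-dominated variance and a
small genotype-by-year interaction, and LC-MS peak tables generated from
known FA/TAG species with adduct multiplicity, ppm-scale mass error, a
retention-time grid linear in chain length and saturation, contaminant
peaks and blank intensities.

Every generator is a pure function of the configuration (including its
seed); planted parameters are returned alongside the data so downstream
estimators can be checked for recovery.
"""
from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, write_vcf
from .lipids import (
    ADDUCT_POLARITY,
    CLASS_ADDUCTS,
    LipidCandidate,
    _formula,
    adduct_mz,
    enumerate_candidates,
    mono_mass,
)

__all__ = [
    "SimConfig",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_replication",
    "simulate_peak_table",
    "write_simulation",
]

# retention-time model: RT = a + b * carbons + c * double_bonds + noise (s).
# Reversed-phase elution follows the equivalent-carbon-number rule
# (ECN = carbons - 2 * double bonds), so the double-bond coefficient is
# minus twice the per-carbon coefficient.
RT_INTERCEPT = 60.0
RT_PER_CARBON = 10.0
RT_PER_DOUBLE_BOND = -20.0

#: relative ion yield per adduct (ammoniated TAGs dominate on C8 columns)
ADDUCT_YIELD = {"-H": 1.0, "+NH4": 1.0, "+H": 0.3, "+Na": 0.2, "+K": 0.1}

def _default_lipids() -> list[tuple[str, int, int, float]]:
    """Default true species: 27 FAs and 42 TAGs, as a seed-oil profile.

    The four major fatty acids (palmitic, stearic, oleic, linoleic) and the
    C52/C54 TAGs carry most of the intensity; minor and very-long-chain
    species sit 2-4 natural-log units lower.
    """
    fas = [
        (12, 0), (14, 0), (15, 0), (16, 0), (16, 1), (16, 2), (17, 0),
        (17, 1), (17, 2), (18, 0), (18, 1), (18, 2), (18, 3), (19, 0),
        (19, 1), (19, 2), (20, 0), (20, 1), (20, 2), (21, 0), (22, 0),
        (22, 1), (23, 0), (24, 0), (24, 1), (26, 0), (28, 0),
    ]
    fa_major = {(16, 0): 15.0, (18, 0): 14.2, (18, 1): 16.0, (18, 2): 16.2}
    tags = [(46, d) for d in range(3)]
    tags += [(c, d) for c in (48, 50, 52, 54, 56) for d in range(7)]
    tags += [(51, 2), (51, 3), (53, 2), (53, 3)]
    tag_major = {
        (52, 2): 15.4, (52, 3): 15.5, (52, 4): 15.3, (54, 3): 16.1,
        (54, 4): 16.0, (54, 5): 15.9, (54, 6): 15.8, (50, 2): 14.6,
    }
    out = [("FA", c, d, fa_major.get((c, d), 11.5)) for c, d in fas]
    out += [("TAG", c, d, tag_major.get((c, d), 12.0)) for c, d in tags]
    return out


_DEFAULT_LIPIDS: list[tuple[str, int, int, float]] = _default_lipids()


@dataclass
class SimConfig:
    """Configuration of the synthetic study.

    Defaults mirror the study design: a 543-line panel genotyped at ~15k
    SNPs across 17 chromosomes from three collections of origin, LD
    decaying on a 0.7 Mb scale, genotype-dominated lipid variance, a
    replication experiment of 6 lines x 3 years x 5 biological replicates,
    and peak tables built from the major seed-oil FA and TAG species.
    """

    n_lines: int = 543
    n_snps: int = 15068
    n_chroms: int = 17
    subpop_count: int = 3
    fst: float = 0.1
    ld_decay_bp: float = 700_000.0
    snp_spacing_bp: float = 200_000.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.05
    dp_mean: float = 20.0
    dp_shape: float = 5.0
    # trait architecture
    qtl_spec: list[tuple[int, str, float]] = field(default_factory=list)
    h2: float = 0.6
    covar_effect_sd: float = 0.2
    # replication experiment
    gxe_frac: float = 0.05
    year_frac: float = 0.05
    years: int = 3
    reps_per_year: int = 5
    rep_lines: int = 6
    drop_points: int = 1
    # mass spectrometry
    true_lipids: list[tuple[str, int, int, float]] = field(
        default_factory=lambda: list(_DEFAULT_LIPIDS)
    )
    ppm_noise_sd: float = 3.0
    rt_noise_sd: float = 1.0
    contaminant_count: int = 50
    blank_rule_violations: int = 0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_lines, self.n_snps, self.n_chroms, self.subpop_count) <= 0:
            raise ValueError("dimensions must be positive")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if not 0.0 <= self.gxe_frac <= 1.0 - self.h2:
            raise ValueError("gxe_frac must lie in [0, 1 - h2]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.ppm_noise_sd < 0:
            raise ValueError("ppm_noise_sd must be >= 0")


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def simulate_genotypes(
    cfg: SimConfig, positions: dict[str, np.ndarray] | None = None
) -> GenotypeMatrix:
    """Structured diploid dosages with distance-decaying local LD.

    Subpopulation allele frequencies diverge by a Balding-Nichols model at
    the configured F_ST; along each chromosome a haplotype copies its state
    from the previous SNP with probability exp(-distance / ld_decay_bp),
    otherwise draws fresh from its subpopulation frequency, giving r^2 that
    decays with distance at the configured scale. Per-call depth is
    negative-binomial; calls go missing completely at random.

    ``positions`` optionally fixes SNP coordinates per chromosome for
    designed layouts (e.g. planted haplotype blocks).
    """
    cfg.validate()
    rng = _rng(cfg, 1)
    n_h = 2 * cfg.n_lines

    if positions is None:
        per_chrom = np.full(cfg.n_chroms, cfg.n_snps // cfg.n_chroms)
        per_chrom[: cfg.n_snps % cfg.n_chroms] += 1
        positions = {}
        for k in range(cfg.n_chroms):
            gaps = np.maximum(
                rng.exponential(cfg.snp_spacing_bp, per_chrom[k]), 1.0
            ).astype(np.int64)
            positions[f"chr{k + 1}"] = np.cumsum(gaps)
    chroms = list(positions)

    subpop = rng.integers(0, cfg.subpop_count, cfg.n_lines)
    hap_subpop = np.repeat(subpop, 2)

    chrom_col, pos_col, dosage_cols = [], [], []
    for chrom in chroms:
        pos = np.asarray(positions[chrom], dtype=np.int64)
        m = len(pos)
        p_anc = rng.uniform(*cfg.maf_range, m)
        if cfg.subpop_count > 1 and cfg.fst > 0:
            a = p_anc * (1 - cfg.fst) / cfg.fst
            b = (1 - p_anc) * (1 - cfg.fst) / cfg.fst
            p_sub = rng.beta(
                np.tile(a, (cfg.subpop_count, 1)), np.tile(b, (cfg.subpop_count, 1))
            )
        else:
            p_sub = np.tile(p_anc, (cfg.subpop_count, 1))
        hap = np.zeros((n_h, m), dtype=np.int8)
        prev = None
        for j in range(m):
            fresh = (rng.random(n_h) < p_sub[hap_subpop, j]).astype(np.int8)
            if prev is None:
                hap[:, j] = fresh
            else:
                rho = np.exp(-(pos[j] - pos[j - 1]) / cfg.ld_decay_bp)
                copy = rng.random(n_h) < rho
                hap[:, j] = np.where(copy, prev, fresh)
            prev = hap[:, j]
        dosage_cols.append((hap[0::2] + hap[1::2]).astype(float))
        chrom_col.append(np.repeat(chrom, m))
        pos_col.append(pos)

    dosage = np.hstack(dosage_cols)
    chrom_arr = np.concatenate(chrom_col).astype(object)
    pos_arr = np.concatenate(pos_col)
    n_total = dosage.shape[1]

    dp = rng.negative_binomial(
        cfg.dp_shape, cfg.dp_shape / (cfg.dp_shape + cfg.dp_mean),
        size=dosage.shape,
    )
    missing = rng.random(dosage.shape) < cfg.missing_rate
    dosage[missing] = np.nan
    dp[missing] = 0

    ref = np.full(n_total, "A", dtype=object)
    alt = np.full(n_total, "T", dtype=object)
    samples = [f"line{i:04d}" for i in range(cfg.n_lines)]
    metadata = pd.DataFrame(
        {"subpop": subpop, "collection": [f"collection{s + 1}" for s in subpop]},
        index=samples,
    )
    return GenotypeMatrix(
        samples=samples,
        chrom=chrom_arr,
        pos=pos_arr,
        ref=ref,
        alt=alt,
        dosage=dosage,
        dp=dp,
        metadata=metadata,
    )


def simulate_phenotypes(
    geno: GenotypeMatrix, cfg: SimConfig
) -> tuple[pd.DataFrame, dict]:
    """Lipid traits with planted QTL, polygenic background and covariates.

    Per trait the variance budget is normalized to 1: the planted QTL
    contribute their squared effects (in trait SD per standardized allele),
    a polygenic component with covariance proportional to the centered-IBS
    kinship fills the genetic fraction up to ``h2``, and iid noise supplies
    the remaining ``1 - h2``. Sample variances are scaled exactly so the
    planted fractions hold in the realized data. Collection, batch, seed
    weight and internal-standard covariates are appended with known
    effects (drawn at scale ``covar_effect_sd``).
    """
    cfg.validate()
    from .popgen import kinship_centered_ibs

    rng = _rng(cfg, 2)
    n = geno.n_samples
    for idx, _, _ in cfg.qtl_spec:
        if not 0 <= idx < geno.n_snps:
            raise ValueError(f"QTL index {idx} out of range")

    trait_names = sorted({t for _, t, _ in cfg.qtl_spec}) or ["trait"]
    K = kinship_centered_ibs(geno).to_numpy()
    L = np.linalg.cholesky(K + 1e-6 * np.eye(n))

    def _scale_to(x: np.ndarray, var: float) -> np.ndarray:
        sd = x.std()
        if sd == 0 or var == 0:
            return np.zeros_like(x)
        return x * np.sqrt(var) / sd

    filled = np.where(
        np.isnan(geno.dosage), np.nanmean(geno.dosage, axis=0)[None, :], geno.dosage
    )
    truth: dict = {"h2": cfg.h2, "qtl": {}, "covariates": {}}
    table = pd.DataFrame(index=geno.samples)
    if geno.metadata is not None and "collection" in geno.metadata:
        table["collection"] = geno.metadata["collection"]
    else:
        table["collection"] = "collection1"
    table["batch"] = rng.integers(1, 5, n)
    table["weight"] = rng.normal(10.0, 1.0, n)
    table["istd"] = rng.normal(1000.0, 100.0, n)

    coll_levels = sorted(table["collection"].unique())
    batch_levels = sorted(table["batch"].unique())
    coll_eff = dict(
        zip(coll_levels, rng.normal(0, cfg.covar_effect_sd, len(coll_levels)))
    )
    beta_weight = cfg.covar_effect_sd
    beta_istd = cfg.covar_effect_sd
    batch_eff = dict(
        zip(batch_levels, rng.normal(0, cfg.covar_effect_sd, len(batch_levels)))
    )
    truth["covariates"] = {
        "collection": coll_eff,
        "batch": batch_eff,
        "weight": beta_weight,
        "istd": beta_istd,
    }
    cov_part = (
        table["collection"].map(coll_eff).to_numpy()
        + table["batch"].map(batch_eff).to_numpy()
        + beta_weight * (table["weight"] - table["weight"].mean()).to_numpy()
        + beta_istd
        * ((table["istd"] - table["istd"].mean()) / table["istd"].std()).to_numpy()
    )

    for trait in trait_names:
        effs = [(i, e) for i, t, e in cfg.qtl_spec if t == trait]
        qtl_comp = np.zeros(n)
        var_qtl = 0.0
        for idx, eff in effs:
            g = filled[:, idx]
            sd = g.std()
            if sd == 0:
                warnings.warn(f"monomorphic QTL SNP {idx}", stacklevel=2)
                continue
            qtl_comp = qtl_comp + eff * (g - g.mean()) / sd
            var_qtl += eff**2
        if var_qtl > cfg.h2:
            warnings.warn(
                "QTL effects exceed h2 budget; rescaling to fit", stacklevel=2
            )
            qtl_comp = _scale_to(qtl_comp, cfg.h2)
            var_qtl = cfg.h2
        elif var_qtl > 0:
            qtl_comp = _scale_to(qtl_comp, var_qtl)
        var_poly = cfg.h2 - var_qtl
        poly = _scale_to(L @ rng.standard_normal(n), var_poly)
        noise = _scale_to(rng.standard_normal(n), 1.0 - cfg.h2)
        table[trait] = qtl_comp + poly + noise + cov_part
        truth["qtl"][trait] = effs
        truth.setdefault("var_poly", {})[trait] = var_poly
    return table, truth


def simulate_replication(cfg: SimConfig) -> tuple[pd.DataFrame, dict]:
    """Replicated line x year lipid abundances with planted variance parts.

    Per trait, line / year / interaction / residual effects are drawn iid
    normal with variances equal to the configured fractions (h2, year_frac,
    gxe_frac, remainder), so a two-way ANOVA recovers them in expectation.
    One observation is dropped at random (``drop_points``) to mirror a
    near-balanced field design.
    """
    cfg.validate()
    if cfg.years < 2 or cfg.reps_per_year < 2:
        raise ValueError("need >= 2 years and >= 2 replicates per year")
    resid_frac = 1.0 - cfg.h2 - cfg.year_frac - cfg.gxe_frac
    if resid_frac < 0:
        raise ValueError("variance fractions exceed 1")
    rng = _rng(cfg, 3)
    traits = [f"{cls} {c}:{d}" for cls, c, d, _ in cfg.true_lipids]
    lines = [f"rep_line{i + 1}" for i in range(cfg.rep_lines)]
    years = [2016 + j for j in range(cfg.years)]

    rows = []
    for i, line in enumerate(lines):
        for j, year in enumerate(years):
            for r in range(cfg.reps_per_year):
                rows.append((line, year, r + 1))
    df = pd.DataFrame(rows, columns=["line", "year", "rep"])
    for trait, (_, _, _, mean_log) in zip(traits, cfg.true_lipids):
        a = rng.normal(0, np.sqrt(cfg.h2), cfg.rep_lines)
        b = rng.normal(0, np.sqrt(cfg.year_frac), cfg.years)
        c = rng.normal(0, np.sqrt(cfg.gxe_frac), (cfg.rep_lines, cfg.years))
        e = rng.normal(0, np.sqrt(resid_frac), len(df))
        li = df["line"].map({l: k for k, l in enumerate(lines)}).to_numpy()
        yi = df["year"].map({y: k for k, y in enumerate(years)}).to_numpy()
        df[trait] = mean_log + a[li] + b[yi] + c[li, yi] + e
    if cfg.drop_points:
        drop = rng.choice(len(df), size=cfg.drop_points, replace=False)
        df = df.drop(index=drop).reset_index(drop=True)
    truth = {
        "line_frac": cfg.h2,
        "year_frac": cfg.year_frac,
        "gxe_frac": cfg.gxe_frac,
        "resid_frac": resid_frac,
        "traits": traits,
    }
    return df, truth


def _min_ion_gap_ppm(mode: str) -> float:
    ions = []
    for cls, adducts in CLASS_ADDUCTS.items():
        for cand in enumerate_candidates(cls):
            for adduct in adducts:
                if ADDUCT_POLARITY[adduct] == mode:
                    ions.append(adduct_mz(cand.mono_mass, adduct))
    mz = np.sort(np.unique(ions))
    gaps = np.diff(mz) / mz[1:] * 1e6
    return float(gaps[gaps > 0].min())


def simulate_peak_table(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """LC-MS peak table from known species, plus its ground-truth table.

    Every true lipid yields one peak per applicable adduct with
    multiplicative mass error of ``ppm_noise_sd`` ppm, a species-level
    retention time on the linear chain-length/saturation grid, and
    log-normal per-sample intensities. Contaminant peaks sit at random
    masses and retention times. Exactly ``blank_rule_violations`` true-lipid
    peaks receive blank intensities that fail the 2x rule; all other peaks
    pass it comfortably. The truth table labels every peak exactly once.
    """
    cfg.validate()
    if not cfg.true_lipids:
        raise ValueError("true_lipids must be nonempty")
    if cfg.ppm_noise_sd > 0:
        gap = _min_ion_gap_ppm("positive")
        if 6.0 * cfg.ppm_noise_sd > gap:
            warnings.warn(
                f"ppm_noise_sd {cfg.ppm_noise_sd} comparable to the minimal "
                f"ion spacing ({gap:.1f} ppm): adduct identities may be "
                "ambiguous",
                stacklevel=2,
            )
    rng = _rng(cfg, 4)
    samples = [f"line{i:04d}" for i in range(cfg.n_lines)]

    peak_rows = []
    truth_rows = []

    def _add_peak(mz, rt, mode, mean_log, label, cls=None, c=None, d=None,
                  adduct=None, mz_theory=None):
        pid = f"p{len(peak_rows):04d}"
        intens = np.exp(rng.normal(mean_log, 0.5, len(samples)))
        row = {"peak_id": pid, "mz": mz, "rt": rt, "mode": mode,
               "blank": float(np.mean(intens)) * rng.uniform(0.05, 0.2)}
        row.update(dict(zip(samples, intens)))
        peak_rows.append(row)
        truth_rows.append(
            {"peak_id": pid, "label": label, "lipid_class": cls, "carbons": c,
             "double_bonds": d, "adduct": adduct,
             "mz_true": mz if mz_theory is None else mz_theory,
             "blank_violation": False}
        )

    for cls, c, d, mean_log in cfg.true_lipids:
        mass = mono_mass(_formula(cls, c, d))
        rt = (
            RT_INTERCEPT
            + RT_PER_CARBON * c
            + RT_PER_DOUBLE_BOND * d
            + rng.normal(0, cfg.rt_noise_sd)
        )
        for adduct in CLASS_ADDUCTS[cls]:
            mz_true = adduct_mz(mass, adduct)
            mz = mz_true * (1.0 + rng.normal(0, cfg.ppm_noise_sd * 1e-6))
            _add_peak(
                mz, rt, ADDUCT_POLARITY[adduct],
                mean_log + np.log(ADDUCT_YIELD[adduct]),
                f"{cls} {c}:{d}", cls, c, d, adduct, mz_theory=mz_true,
            )

    n_true = len(peak_rows)
    rt_lo = RT_INTERCEPT + RT_PER_CARBON * 10 + RT_PER_DOUBLE_BOND * 12
    rt_hi = RT_INTERCEPT + RT_PER_CARBON * 88
    for _ in range(cfg.contaminant_count):
        _add_peak(
            rng.uniform(150.0, 1000.0),
            rng.uniform(rt_lo, rt_hi),
            rng.choice(["positive", "negative"]),
            rng.normal(12.0, 1.0),
            "contaminant",
        )

    peaks = pd.DataFrame(peak_rows)
    truth = pd.DataFrame(truth_rows)

    if cfg.blank_rule_violations:
        if cfg.blank_rule_violations > n_true:
            raise ValueError("more blank-rule violations than true peaks")
        victim = rng.choice(n_true, size=cfg.blank_rule_violations, replace=False)
        means = peaks[samples].mean(axis=1)
        peaks.loc[victim, "blank"] = means.iloc[victim].to_numpy()
        truth.loc[victim, "blank_violation"] = True
    return peaks, truth


def write_simulation(cfg: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write every synthetic table; returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geno = simulate_genotypes(cfg)
    traits, _ = simulate_phenotypes(geno, cfg)
    repl, _ = simulate_replication(cfg)
    peaks, truth = simulate_peak_table(cfg)
    files = {
        "vcf": out / "genotypes.vcf",
        "traits": out / "phenotypes.tsv",
        "replication": out / "replication.tsv",
        "peaks": out / "peaks.tsv",
        "peak_truth": out / "peak_truth.tsv",
    }
    write_vcf(geno, files["vcf"])
    traits.to_csv(files["traits"], sep="\t", index_label="sample")
    repl.to_csv(files["replication"], sep="\t", index=False)
    peaks.to_csv(files["peaks"], sep="\t", index=False)
    truth.to_csv(files["peak_truth"], sep="\t", index=False)
    return files
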
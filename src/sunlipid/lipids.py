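"""Exact-mass annotation of seed-oil LC-MS peak tables.

Implements the untargeted FA/TAG annotation workflow for reversed-phase
UPLC-MS peak lists: blank-sample filtering, sum-composition enumeration,
adduct m/z computation, ppm matching, retention-time grid filtering,
category annotation against a lipid database, and per-class normalization
to relative abundances.

A *sum composition* ``N:D`` gives the total acyl carbon count N and the
total number of double bonds D; isomers (sn-position, individual acyl
chains) are never resolved, matching what exact mass alone can support.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from pyteomics.mass import Composition
from scipy import stats

__all__ = [
    "LipidCandidate",
    "AdductMatch",
    "mono_mass",
    "adduct_mz",
    "ppm_deviation",
    "enumerate_candidates",
    "filter_by_blank",
    "match_peaks",
    "grid_filter",
    "annotate_categories",
    "normalize_by_class",
    "resolve_multimatch",
    "annotate_peaks",
]

#: Monoisotopic atomic masses (Da) of the elements occurring in acyl lipids.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.007825032,
    "O": 15.994914620,
    "N": 14.003074004,
}

#: Mass shift (Th) of each singly charged adduct relative to the neutral
#: monoisotopic mass. Ion-mass convention: the electron mass is included
#: (a proton is 1.007276 Da, not 1.007825).
ADDUCT_MASS_SHIFT: dict[str, float] = {
    "-H": -1.007276,
    "+H": 1.007276,
    "+Na": 22.989218,
    "+K": 38.963158,
    "+NH4": 18.033823,
}

ADDUCT_POLARITY: dict[str, str] = {
    "-H": "negative",
    "+H": "positive",
    "+Na": "positive",
    "+K": "positive",
    "+NH4": "positive",
}

#: Adducts considered per lipid class: deprotonated FAs in negative mode,
#: four cationized/protonated forms for TAGs in positive mode.
CLASS_ADDUCTS: dict[str, tuple[str, ...]] = {
    "FA": ("-H",),
    "TAG": ("+H", "+Na", "+K", "+NH4"),
}

#: Enumeration grid per class: (min carbons, max carbons, min db, max db).
CLASS_GRID: dict[str, tuple[int, int, int, int]] = {
    "FA": (10, 28, 0, 6),
    "TAG": (30, 85, 0, 12),
}

#: Columns of a peak table that are not per-sample intensities.
RESERVED_COLUMNS: tuple[str, ...] = ("peak_id", "mz", "rt", "mode", "blank")

POSITIVE_ADDUCTS: tuple[str, ...] = ("+H", "+Na", "+K", "+NH4")


class LipidCandidate(NamedTuple):
    """An enumerated lipid species identified by class and sum composition."""

    lipid_class: str
    carbons: int
    double_bonds: int
    formula: str
    mono_mass: float

    @property
    def name(self) -> str:
        return f"{self.lipid_class} {self.carbons}:{self.double_bonds}"


@dataclasses.dataclass
class AdductMatch:
    """A (peak, candidate, adduct) assignment within the ppm tolerance."""

    peak_id: str
    candidate: LipidCandidate
    adduct: str
    ppm: float
    mz: float
    grid_pass: bool = True


def sample_columns(peaks: pd.DataFrame) -> list[str]:
    """Names of the per-sample intensity columns of a peak table."""
    return [c for c in peaks.columns if c not in RESERVED_COLUMNS]


def mono_mass(formula: str | Mapping[str, int]) -> float:
    """Monoisotopic neutral mass (Da) of an elemental composition.

    Parameters
    ----------
    formula
        Hill-style formula string (e.g. ``"C57H104O6"``) or a mapping of
        element symbol to atom count. Only C, H, O and N are supported.
    """
    if isinstance(formula, str):
        if not formula:
            raise ValueError("empty formula")
        comp = dict(Composition(formula=formula))
    else:
        comp = dict(formula)
    if not comp:
        raise ValueError("empty formula")
    unknown = set(comp) - set(MONOISOTOPIC_MASS)
    if unknown:
        raise ValueError(f"unknown element(s): {sorted(unknown)}")
    return float(sum(MONOISOTOPIC_MASS[el] * n for el, n in comp.items()))


def adduct_mz(neutral_mass: float, adduct: str) -> float:
    """m/z (Th) of the singly charged ``adduct`` ion of a neutral mass."""
    if adduct not in ADDUCT_MASS_SHIFT:
        raise ValueError(f"unknown adduct {adduct!r}")
    return neutral_mass + ADDUCT_MASS_SHIFT[adduct]


def neutral_mass(mz: float, adduct: str) -> float:
    """Back-calculate the neutral mass from an adduct ion m/z."""
    if adduct not in ADDUCT_MASS_SHIFT:
        raise ValueError(f"unknown adduct {adduct!r}")
    return mz - ADDUCT_MASS_SHIFT[adduct]


def ppm_deviation(m1: float, m2: float) -> float:
    """Relative mass deviation in ppm: ``abs(m1 - m2) / max(m1, m2) * 1e6``."""
    if m1 <= 0 or m2 <= 0:
        raise ValueError("masses must be positive")
    return abs(m1 - m2) / max(m1, m2) * 1e6


def _formula(lipid_class: str, carbons: int, double_bonds: int) -> str:
    if lipid_class == "FA":
        return f"C{carbons}H{2 * carbons - 2 * double_bonds}O2"
    if lipid_class == "TAG":
        # glycerol backbone + three acyls - three waters
        return f"C{carbons + 3}H{2 * carbons - 2 * double_bonds + 2}O6"
    raise ValueError(f"unknown lipid class {lipid_class!r}")


def enumerate_candidates(lipid_class: str) -> list[LipidCandidate]:
    """Full sum-composition grid of a lipid class.

    FAs cover chain lengths 10-28 with 0-6 double bonds (133 species);
    TAGs cover total acyl carbons 30-85 with 0-12 double bonds (728).
    """
    if lipid_class not in CLASS_GRID:
        raise ValueError(f"unknown lipid class {lipid_class!r}")
    c_lo, c_hi, d_lo, d_hi = CLASS_GRID[lipid_class]
    out = []
    for c in range(c_lo, c_hi + 1):
        for d in range(d_lo, d_hi + 1):
            f = _formula(lipid_class, c, d)
            out.append(LipidCandidate(lipid_class, c, d, f, mono_mass(f)))
    return out


def filter_by_blank(
    peaks: pd.DataFrame, factor: float = 2.0, agg: str = "mean"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove peaks not exceeding ``factor`` times their blank intensity.

    A peak is retained when its aggregate sample intensity is *strictly*
    greater than ``factor * blank`` (the strict form of the 2x rule, i.e.
    log2(sample/blank) > 1); peaks with zero blank and any signal pass.

    Returns
    -------
    (kept, removed)
        ``removed`` carries a ``reason`` column.
    """
    if "blank" not in peaks.columns:
        raise ValueError("peak table lacks a 'blank' column")
    samples = sample_columns(peaks)
    if not samples:
        raise ValueError("peak table has no sample columns")
    if agg == "mean":
        level = peaks[samples].mean(axis=1)
    elif agg == "median":
        level = peaks[samples].median(axis=1)
    else:
        raise ValueError(f"unknown aggregate {agg!r}")
    keep = level > factor * peaks["blank"]
    removed = peaks.loc[~keep].copy()
    removed["reason"] = [
        f"{agg} intensity {m:.4g} <= {factor} x blank {b:.4g}"
        for m, b in zip(level[~keep], peaks.loc[~keep, "blank"])
    ]
    kept = peaks.loc[keep].copy()
    if kept.empty:
        warnings.warn("blank filter removed every peak", stacklevel=2)
    return kept, removed


def match_peaks(
    peaks: pd.DataFrame,
    candidates: Sequence[LipidCandidate],
    threshold_ppm: float = 10.0,
) -> list[AdductMatch]:
    """All (peak, candidate, adduct) pairs within the ppm tolerance.

    Adduct polarity must agree with the peak's ionization mode; a peak may
    match several candidates (resolved later by :func:`resolve_multimatch`).
    """
    if len(candidates) == 0:
        raise ValueError("empty candidate list")
    ion_cand: list[LipidCandidate] = []
    ion_adduct: list[str] = []
    ion_mz: list[float] = []
    ion_pol: list[str] = []
    for cand in candidates:
        for adduct in CLASS_ADDUCTS[cand.lipid_class]:
            ion_cand.append(cand)
            ion_adduct.append(adduct)
            ion_mz.append(adduct_mz(cand.mono_mass, adduct))
            ion_pol.append(ADDUCT_POLARITY[adduct])
    ion_mz_arr = np.asarray(ion_mz)
    ion_pol_arr = np.asarray(ion_pol)

    matches: list[AdductMatch] = []
    for row in peaks.itertuples(index=False):
        ok = ion_pol_arr == row.mode
        if not ok.any():
            continue
        mz = float(row.mz)
        ppm = (
            np.abs(mz - ion_mz_arr[ok])
            / np.maximum(mz, ion_mz_arr[ok])
            * 1e6
        )
        for k, p in zip(np.flatnonzero(ok), ppm):
            if p < threshold_ppm:
                matches.append(
                    AdductMatch(row.peak_id, ion_cand[k], ion_adduct[k], float(p), mz)
                )
    return matches


def _robust_scale(resid: np.ndarray, n_params: int) -> float:
    """Residual scale: Huber proposal-2 floored by the normal-scaled MAD,
    inflated for the fitted parameters."""
    import statsmodels.api as sm

    mad = stats.median_abs_deviation(resid, scale="normal")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            scale = max(float(sm.robust.scale.huber(resid)[1]), mad)
        except Exception:
            scale = mad
    return scale * np.sqrt(len(resid) / max(len(resid) - n_params, 1))


def grid_filter(
    matches: Iterable[AdductMatch],
    peaks: pd.DataFrame,
    k: float = 3.5,
    min_group: int = 5,
) -> list[AdductMatch]:
    """Flag matches that fall off the retention-time grid of their class.

    True members of a homologous series lie on a near-planar surface
    RT ~ carbons + double_bonds (the net-like pattern on the RT-m/z plane),
    and all adducts of one species co-elute, so a single plane per lipid
    class constrains every adduct at once. Contaminants and cross-adduct
    mass coincidences (e.g. a sodiated TAG whose mass also fits the
    protonated ion of a species two carbons and three double bonds away)
    sit several noise SDs off the plane.

    The plane is fitted robustly to *anchor* matches — matches whose peak
    has exactly one candidate interpretation, which therefore cannot carry
    a mis-assignment — and every match is then scored against it: absolute
    residuals beyond ``k`` times the robust anchor residual scale get
    ``grid_pass=False``. If a class has too few anchors the fit falls back
    to all of its matches. Classes with fewer than ``min_group`` matches,
    or a degenerate composition design, pass through unfiltered.
    """
    import statsmodels.api as sm

    rt = peaks.set_index("peak_id")["rt"]
    matches = [dataclasses.replace(m) for m in matches]
    multiplicity: dict[str, int] = {}
    for m in matches:
        multiplicity[m.peak_id] = multiplicity.get(m.peak_id, 0) + 1
    groups: dict[str, list[AdductMatch]] = {}
    for m in matches:
        groups.setdefault(m.candidate.lipid_class, []).append(m)

    for cls, group in groups.items():
        if len(group) < min_group:
            continue
        carbons = np.array([m.candidate.carbons for m in group], dtype=float)
        dbs = np.array([m.candidate.double_bonds for m in group], dtype=float)
        y = np.array([rt.loc[m.peak_id] for m in group], dtype=float)
        X = np.column_stack([np.ones(len(group)), carbons, dbs])
        anchor = np.array([multiplicity[m.peak_id] == 1 for m in group])
        if anchor.sum() < min_group or np.unique(carbons[anchor]).size < 2:
            anchor = np.ones(len(group), dtype=bool)
        if np.unique(carbons[anchor]).size < 2:
            warnings.warn(
                f"degenerate RT grid for {cls}: single chain length",
                stacklevel=2,
            )
            continue
        try:
            fit = sm.RLM(y[anchor], X[anchor], M=sm.robust.norms.HuberT()).fit()
            coef = fit.params
        except Exception:  # singular groups: fall back to least squares
            coef = np.linalg.lstsq(X[anchor], y[anchor], rcond=None)[0]
        resid = y - X @ coef
        cut = k * _robust_scale(resid[anchor], X.shape[1]) + 1e-8
        for m, r in zip(group, resid):
            m.grid_pass = bool(abs(r) <= cut)
    return matches


def collapse_isomers(db: pd.DataFrame) -> pd.DataFrame:
    """Collapse a lipid database to one entry per elemental formula."""
    required = {"name", "category", "formula"}
    if not required.issubset(db.columns):
        raise ValueError(f"database needs columns {sorted(required)}")
    out = db.drop_duplicates(subset="formula").copy()
    out["mono_mass"] = [mono_mass(f) for f in out["formula"]]
    return out


def annotate_categories(
    peaks: pd.DataFrame, db: pd.DataFrame, threshold_ppm: float = 10.0
) -> pd.Series:
    """Category label per positive-mode peak from a lipid database.

    Matches each peak against isomer-collapsed database masses under the
    four positive adducts; a peak keeps the category when all its matches
    agree, ``"ambig"`` when more than one category matches, ``"unk"`` when
    nothing matches.
    """
    if db.empty:
        raise ValueError("empty lipid database")
    db = collapse_isomers(db)
    ion_mass = np.concatenate(
        [db["mono_mass"].to_numpy() + ADDUCT_MASS_SHIFT[a] for a in POSITIVE_ADDUCTS]
    )
    ion_cat = np.concatenate([db["category"].to_numpy()] * len(POSITIVE_ADDUCTS))

    pos = peaks.loc[peaks["mode"] == "positive"]
    labels = {}
    for row in pos.itertuples(index=False):
        mz = float(row.mz)
        ppm = np.abs(mz - ion_mass) / np.maximum(mz, ion_mass) * 1e6
        cats = set(ion_cat[ppm < threshold_ppm])
        if not cats:
            labels[row.peak_id] = "unk"
        elif len(cats) == 1:
            labels[row.peak_id] = next(iter(cats))
        else:
            labels[row.peak_id] = "ambig"
    return pd.Series(labels, name="category")


def normalize_by_class(
    intensities: pd.DataFrame, class_assignments: pd.Series
) -> pd.DataFrame:
    """Relative abundance (% of class total) per sample.

    ``intensities`` is species x samples; ``class_assignments`` maps each
    species (row) to its class. Within each sample and class the output
    sums to 100.
    """
    if (intensities.to_numpy() < 0).any():
        raise ValueError("negative intensity")
    missing = set(intensities.index) - set(class_assignments.index)
    if missing:
        raise ValueError(f"species without class assignment: {sorted(missing)[:5]}")
    out = intensities.astype(float).copy()
    classes = class_assignments.loc[intensities.index]
    for cls, idx in intensities.groupby(classes.to_numpy()).groups.items():
        block = intensities.loc[idx]
        totals = block.sum(axis=0)
        zero = totals[totals == 0]
        if len(zero):
            raise ValueError(
                f"zero total intensity for class {cls} in sample(s) "
                f"{list(zero.index)[:5]}"
            )
        out.loc[idx] = block / totals * 100.0
    return out


def resolve_multimatch(matches: Iterable[AdductMatch]) -> dict[str, AdductMatch]:
    """One species per peak: best grid-passing match by lowest ppm.

    Ties are broken toward fewer double bonds, then fewer carbons, so the
    chemically simpler assignment wins when exact mass cannot decide.
    """
    best: dict[str, AdductMatch] = {}

    def key(m: AdductMatch) -> tuple:
        return (m.ppm, abs(m.candidate.double_bonds), m.candidate.carbons)

    for m in matches:
        if not m.grid_pass:
            continue
        cur = best.get(m.peak_id)
        if cur is None or key(m) < key(cur):
            best[m.peak_id] = m
    return best


def annotate_peaks(
    peaks: pd.DataFrame,
    threshold_ppm: float = 10.0,
    blank_factor: float = 2.0,
    grid_k: float = 3.5,
    classes: Sequence[str] = ("FA", "TAG"),
) -> pd.DataFrame:
    """Full annotation pipeline: blank filter, match, grid filter, resolve.

    Returns one row per annotated peak with columns ``lipid_class``,
    ``carbons``, ``double_bonds``, ``species``, ``adduct``, ``ppm``.
    """
    kept, _ = filter_by_blank(peaks, factor=blank_factor)
    if kept.empty:
        return pd.DataFrame(
            columns=["peak_id", "lipid_class", "carbons", "double_bonds",
                     "species", "adduct", "ppm"]
        )
    candidates: list[LipidCandidate] = []
    for cls in classes:
        candidates.extend(enumerate_candidates(cls))
    matches = match_peaks(kept, candidates, threshold_ppm=threshold_ppm)
    matches = grid_filter(matches, kept, k=grid_k)
    resolved = resolve_multimatch(matches)
    rows = [
        {
            "peak_id": pid,
            "lipid_class": m.candidate.lipid_class,
            "carbons": m.candidate.carbons,
            "double_bonds": m.candidate.double_bonds,
            "species": m.candidate.name,
            "adduct": m.adduct,
            "ppm": m.ppm,
        }
        for pid, m in resolved.items()
    ]
    return pd.DataFrame(rows)
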
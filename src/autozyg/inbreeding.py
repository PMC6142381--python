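"""Inbreeding coefficients: F_ROH, F_GRM and Wright's F_PED.

Three estimators of individual inbreeding are computed and compared:

* ``F_ROH`` — the genomic autozygosity proportion: summed ROH length
  divided by the total autosomal extent covered by markers (L_total),
  optionally restricted to one ROH length class.
* ``F_GRM`` — ``G_ii - 1``, where G is the VanRaden genomic relationship
  matrix ``ZZ' / (2 sum p_i (1 - p_i))`` built from allele counts centered
  by twice the allele frequency. Unlike F_ROH it can be negative (animals
  less homozygous than the Hardy-Weinberg expectation).
* ``F_PED`` — Wright's pedigree coefficient, half the additive relationship
  between the animal's parents; unknown parents are treated as unrelated
  founders with F = 0.

The module also provides pairwise Spearman correlations between the
coefficients, per-group (lineage) means, and ordinary least-squares trends
of the annual mean coefficient on birth year.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .io_formats import HET, MISSING, GenotypeMatrix, Pedigree
from .roh import LENGTH_CLASSES

logger = logging.getLogger(__name__)

#: Total autosomal extent (bp) of the UMD3.1 cattle consensus map; usable as
#: a fixed L_total override instead of the extent computed from a loaded map.
UMD31_AUTOSOME_EXTENT_BP = 2_510_605_962

F_ROH_COLUMNS = {
    "C1_2": "f_roh_1_2",
    "C2_4": "f_roh_2_4",
    "C4_8": "f_roh_4_8",
    "C8_plus": "f_roh_gt8",
}
COEFFICIENTS = ["f_ped", "f_grm", "f_roh_total", *F_ROH_COLUMNS.values()]


def f_roh(
    segments: pd.DataFrame, l_total_bp: int, class_filter: str = "ALL"
) -> float:
    """Autozygosity proportion of one animal's segment list.

    ``class_filter`` is one of the length classes or ``ALL`` (every segment
    >= 1 Mb). An empty segment table gives 0.0.
    """
    if l_total_bp <= 0:
        raise DataError("l_total_bp must be > 0")
    if class_filter != "ALL":
        if class_filter not in LENGTH_CLASSES:
            raise DataError(f"unknown length class {class_filter!r}")
        segments = segments[segments["length_class"] == class_filter]
    return float(segments["length_bp"].sum()) / l_total_bp


def f_roh_table(
    segments: pd.DataFrame,
    animal_ids: list[str],
    l_total_bp: int,
    cumulative: bool = False,
) -> pd.DataFrame:
    """Per-animal F_ROH per length class plus the total.

    Classes are disjoint bins by default; ``cumulative=True`` instead uses
    minimum-length thresholds (class column = all segments at least as long
    as the bin's lower edge).
    """
    sums = (
        segments.groupby(["animal_id", "length_class"])["length_bp"]
        .sum()
        .unstack(fill_value=0)
        .reindex(index=animal_ids, columns=LENGTH_CLASSES, fill_value=0)
    )
    out = pd.DataFrame(index=pd.Index(animal_ids, name="animal_id"))
    if cumulative:
        rev = sums[LENGTH_CLASSES[::-1]].cumsum(axis=1)[LENGTH_CLASSES]
        for cls, col in F_ROH_COLUMNS.items():
            out[col] = rev[cls] / l_total_bp
    else:
        for cls, col in F_ROH_COLUMNS.items():
            out[col] = sums[cls] / l_total_bp
    out["f_roh_total"] = sums.sum(axis=1) / l_total_bp
    return out


def build_grm_diagonal(
    gm: GenotypeMatrix, allele_freqs: np.ndarray | None = None
) -> pd.Series:
    """Per-animal ``f_grm = G_ii - 1`` from the VanRaden G matrix diagonal.

    Allele frequencies default to observed frequencies in the input cohort;
    markers monomorphic (p in {0, 1}) or entirely missing are excluded from
    both numerator and denominator. Missing calls are centered to 0 (column
    mean), the standard neutral imputation.
    """
    if gm.n_animals < 2 and allele_freqs is None:
        raise DataError("need >= 2 animals to estimate allele frequencies")
    counts = gm.calls.astype(float)  # codes 0/1/2 are alt-allele counts
    miss = gm.calls == MISSING
    counts[miss] = np.nan
    if allele_freqs is None:
        with np.errstate(invalid="ignore"):
            p = np.nanmean(counts, axis=0) / 2.0
    else:
        p = np.asarray(allele_freqs, dtype=float)
        if p.size != counts.shape[1]:
            raise DataError("allele_freqs length does not match marker count")
    poly = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise DataError("all markers monomorphic: G denominator undefined")
    z = counts[:, poly] - 2.0 * p[poly]
    z[np.isnan(z)] = 0.0
    denom = 2.0 * float(np.sum(p[poly] * (1.0 - p[poly])))
    g_ii = np.einsum("ij,ij->i", z, z) / denom
    return pd.Series(g_ii - 1.0, index=gm.animal_ids, name="f_grm")


# ---------------------------------------------------------------------------
# F_PED
# ---------------------------------------------------------------------------


def f_ped(pedigree: Pedigree) -> pd.Series:
    """Wright's inbreeding coefficient for every pedigree record.

    F_x is the kinship (coancestry) of the parents, computed by the
    classical recursion on the topologically ordered pedigree; any unknown
    parent contributes 0, so founders and half-known animals get F = 0.
    """
    rank = {a: i for i, a in enumerate(pedigree.animals)}
    memo: dict[tuple[str, str], float] = {}

    def kinship(a: str | None, b: str | None) -> float:
        if a is None or b is None:
            return 0.0
        if a == b:
            key = (a, a)
            if key not in memo:
                s, d = pedigree.parents(a)
                memo[key] = 0.5 * (1.0 + kinship(s, d))
            return memo[key]
        if rank[a] > rank[b]:
            a, b = b, a
        key = (a, b)
        if key not in memo:
            s, d = pedigree.parents(b)  # b is the younger of the two
            memo[key] = 0.5 * (kinship(a, s) + kinship(a, d))
        return memo[key]

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * len(pedigree) + 100))
    try:
        vals = {}
        for animal in pedigree.animals:  # topological order fills the memo bottom-up
            s, d = pedigree.parents(animal)
            vals[animal] = kinship(s, d) if (s and d) else 0.0
    finally:
        sys.setrecursionlimit(old)
    return pd.Series(vals, name="f_ped")


# ---------------------------------------------------------------------------
# combined table, correlations, trends, group means
# ---------------------------------------------------------------------------


def build_inbreeding_table(
    segments: pd.DataFrame,
    animal_ids: list[str],
    l_total_bp: int,
    pedigree: Pedigree | None = None,
    gm: GenotypeMatrix | None = None,
    cumulative: bool = False,
) -> pd.DataFrame:
    """Assemble the per-animal coefficient table (F_ROH classes, F_GRM, F_PED).

    Birth year and lineage are carried over from the pedigree when present;
    coefficients unavailable for an animal are left missing.
    """
    table = f_roh_table(segments, animal_ids, l_total_bp, cumulative=cumulative)
    table["f_grm"] = np.nan
    table["f_ped"] = np.nan
    table["birth_year"] = pd.array([pd.NA] * len(table), dtype="Int64")
    table["lineage"] = pd.Series([pd.NA] * len(table), index=table.index, dtype="object")
    if gm is not None:
        table.loc[:, "f_grm"] = build_grm_diagonal(gm).reindex(table.index)
    if pedigree is not None:
        fp = f_ped(pedigree)
        table.loc[:, "f_ped"] = fp.reindex(table.index)
        meta = pedigree.df.set_index("animal")
        common = table.index.intersection(meta.index)
        table.loc[common, "birth_year"] = meta.loc[common, "birth_year"]
        table.loc[common, "lineage"] = meta.loc[common, "lineage"]
    return table.reset_index()


def coefficient_correlations(
    table: pd.DataFrame, coefficients: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rank correlations between inbreeding coefficients.

    Each pair uses the animals non-missing for both coefficients
    (pairwise-complete). Pairs with fewer than 3 complete cases are left
    missing and logged. Returns (correlation matrix, n matrix).
    """
    coefficients = coefficients or [c for c in COEFFICIENTS if c in table.columns]
    k = len(coefficients)
    rho = pd.DataFrame(np.eye(k), index=coefficients, columns=coefficients)
    n = pd.DataFrame(0, index=coefficients, columns=coefficients, dtype=int)
    for i, a in enumerate(coefficients):
        for j, b in enumerate(coefficients):
            if j < i:
                continue
            mask = table[a].notna() & table[b].notna()
            n.loc[a, b] = n.loc[b, a] = int(mask.sum())
            if a == b:
                rho.loc[a, b] = 1.0 if mask.sum() else np.nan
                continue
            if mask.sum() < 3:
                logger.warning(
                    "Spearman %s~%s skipped: %d complete cases", a, b, mask.sum()
                )
                rho.loc[a, b] = rho.loc[b, a] = np.nan
                continue
            xa = table.loc[mask, a].to_numpy(dtype=float)
            xb = table.loc[mask, b].to_numpy(dtype=float)
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                logger.warning("Spearman %s~%s undefined: constant input", a, b)
                rho.loc[a, b] = rho.loc[b, a] = np.nan
                continue
            r = stats.spearmanr(xa, xb).statistic
            rho.loc[a, b] = rho.loc[b, a] = float(r)
    return rho, n


def inbreeding_trend(
    table: pd.DataFrame, coefficient: str, annual_means: bool = True
) -> dict:
    """OLS trend of an inbreeding coefficient on birth year.

    By default each birth year contributes one point, the annual mean of
    the coefficient (animals without birth year are excluded, not imputed);
    ``annual_means=False`` regresses animal-level values instead. Returns
    slope, intercept, two-sided slope p-value, r and the number of points.
    """
    sub = table[["birth_year", coefficient]].dropna()
    if annual_means:
        pts = sub.groupby("birth_year")[coefficient].mean()
        x = pts.index.to_numpy(dtype=float)
        y = pts.to_numpy(dtype=float)
    else:
        x = sub["birth_year"].to_numpy(dtype=float)
        y = sub[coefficient].to_numpy(dtype=float)
    if np.unique(x).size < 3:
        raise DataError(
            f"trend for {coefficient!r} needs >= 3 distinct birth years"
        )
    res = stats.linregress(x, y)
    return {
        "coefficient": coefficient,
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "p_value": float(res.pvalue),
        "r": float(res.rvalue),
        "n_points": int(np.unique(x).size if annual_means else x.size),
    }


def group_means(
    table: pd.DataFrame, group_col: str = "lineage"
) -> pd.DataFrame:
    """Per-group mean and count for each coefficient (empty groups omitted)."""
    coefs = [c for c in COEFFICIENTS if c in table.columns]
    rows = []
    labelled = table[table[group_col].notna()]
    for grp, sub in labelled.groupby(group_col):
        for c in coefs:
            vals = sub[c].dropna()
            if len(vals) == 0:
                continue
            rows.append(
                {
                    "group": grp,
                    "coefficient": c,
                    "mean": float(vals.mean()),
                    "n": int(len(vals)),
                }
            )
    return pd.DataFrame(rows, columns=["group", "coefficient", "mean", "n"])
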
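"""Data model and text-format I/O.

Core containers shared by the whole pipeline:

* :class:`MarkerMap` — ordered autosomal marker positions (1-based bp).
* :class:`GenotypeMatrix` — animals x markers diploid calls coded as
  ``HOM_REF``/``HET``/``HOM_ALT``/``MISSING``; allele identity is dropped at
  load because no downstream computation needs it (homozygosity status and
  alternate-allele counts suffice).
* :class:`Pedigree` — animal/sire/dam records with birth year and optional
  lineage label, held in topological order (parents before offspring).
* :class:`IntervalSet` — 1-based inclusive genomic intervals (islands,
  CNVRs, genes).

File formats: PLINK text PED/MAP, headered pedigree TSV/CSV, BED3+ (0-based
half-open on disk, converted to 1-based inclusive in memory), and plain TSV
for every report table.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DataError, FormatError, PedigreeError

logger = logging.getLogger(__name__)

# genotype codes
MISSING = -1
HOM_REF = 0
HET = 1
HOM_ALT = 2

_NON_AUTOSOME_LABELS = {"X", "Y", "XY", "MT", "M", "0"}


def is_autosome(label: str) -> bool:
    """True for purely numeric chromosome labels >= 1 (sex/mito/unplaced are not)."""
    s = str(label).strip()
    if s.upper() in _NON_AUTOSOME_LABELS:
        return False
    return s.isdigit() and int(s) >= 1


def _chrom_sort_key(label: str):
    s = str(label)
    return (0, int(s)) if s.isdigit() else (1, s)


# ---------------------------------------------------------------------------
# MarkerMap
# ---------------------------------------------------------------------------


@dataclass
class MarkerMap:
    """Ordered autosomal marker positions.

    ``df`` has columns ``chromosome`` (str), ``marker_id`` (str),
    ``position_bp`` (int, 1-based), sorted by (chromosome, position) with
    strictly increasing positions within each chromosome.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["chromosome", "marker_id", "position_bp"]
        if list(self.df.columns[:3]) != required:
            self.df = self.df[required]
        df = self.df.copy()
        df["chromosome"] = df["chromosome"].astype(str)
        df["position_bp"] = df["position_bp"].astype(np.int64)
        bad = [c for c in df["chromosome"].unique() if not is_autosome(c)]
        if bad:
            raise DataError(f"non-autosomal chromosomes in MarkerMap: {bad}")
        df = df.sort_values(
            ["chromosome", "position_bp"],
            key=lambda s: s.map(_chrom_sort_key) if s.name == "chromosome" else s,
            kind="mergesort",
        ).reset_index(drop=True)
        for chrom, grp in df.groupby("chromosome", sort=False):
            pos = grp["position_bp"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise DataError(
                    f"marker positions not strictly increasing on chromosome {chrom}"
                )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.df["chromosome"].unique(), key=_chrom_sort_key)

    def chrom_slice(self, chrom: str) -> slice:
        """Row slice of this chromosome's markers (map is chromosome-contiguous)."""
        idx = np.flatnonzero((self.df["chromosome"] == str(chrom)).to_numpy())
        if idx.size == 0:
            return slice(0, 0)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def positions(self, chrom: str) -> np.ndarray:
        return self.df["position_bp"].to_numpy()[self.chrom_slice(chrom)]

    def chrom_extent_bp(self, chrom: str) -> int:
        """Mapped extent of one chromosome: last - first marker position + 1."""
        pos = self.positions(chrom)
        if pos.size == 0:
            return 0
        return int(pos[-1] - pos[0] + 1)

    def total_extent_bp(self) -> int:
        """Total autosomal extent covered by markers (sum of per-chromosome extents)."""
        return sum(self.chrom_extent_bp(c) for c in self.chromosomes)


# ---------------------------------------------------------------------------
# GenotypeMatrix
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls for a cohort, aligned to a :class:`MarkerMap`.

    ``calls`` is an ``(n_animals, n_markers)`` int8 array holding
    ``HOM_REF``/``HET``/``HOM_ALT``/``MISSING``.
    """

    animal_ids: list[str]
    calls: np.ndarray
    map: MarkerMap

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise DataError("calls must be a 2-D array")
        if self.calls.shape[1] != len(self.map):
            raise DataError(
                f"calls have {self.calls.shape[1]} columns but map has "
                f"{len(self.map)} markers"
            )
        if len(self.animal_ids) != self.calls.shape[0]:
            raise DataError("animal_ids length does not match calls rows")
        if len(set(self.animal_ids)) != len(self.animal_ids):
            raise DataError("duplicate animal ids")

    @property
    def n_animals(self) -> int:
        return self.calls.shape[0]

    def call_rate(self) -> pd.Series:
        """Fraction of non-missing calls per animal."""
        rate = (self.calls != MISSING).mean(axis=1)
        return pd.Series(rate, index=self.animal_ids, name="call_rate")

    def animal_calls(self, animal_id: str) -> np.ndarray:
        return self.calls[self.animal_ids.index(animal_id)]


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


@dataclass
class Pedigree:
    """Pedigree records in topological order (parents before offspring).

    ``df`` columns: ``animal`` (str), ``sire``/``dam`` (str or None for
    unknown), ``birth_year`` (nullable int), ``lineage`` (str or None),
    ``is_founder`` (bool; both parents unknown). Parents referenced without a
    record of their own are treated as unknown founders.
    """

    df: pd.DataFrame
    _parents: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in ("birth_year", "lineage"):
            if col not in df.columns:
                df[col] = pd.NA
        animals = df["animal"].astype(str)
        if animals.duplicated().any():
            dup = animals[animals.duplicated()].iloc[0]
            raise PedigreeError(f"animal appears twice in pedigree: {dup!r}")
        df["animal"] = animals
        known = set(animals)
        for col in ("sire", "dam"):
            df[col] = [
                str(v) if (pd.notna(v) and str(v) not in ("0", "")) else None
                for v in df[col]
            ]
            # a parent with no record of its own is an implicit founder
            df[col] = [v if v in known else None for v in df[col]]

        g = nx.DiGraph()
        g.add_nodes_from(df["animal"])
        for _, r in df.iterrows():
            for p in (r["sire"], r["dam"]):
                if p is not None:
                    g.add_edge(p, r["animal"])
        try:
            order = list(nx.topological_sort(g))
        except nx.NetworkXUnfeasible:
            cycle = nx.find_cycle(g)
            raise PedigreeError(f"pedigree contains a cycle: {cycle}") from None
        rank = {a: i for i, a in enumerate(order)}
        df = df.sort_values("animal", key=lambda s: s.map(rank), kind="mergesort")
        df["is_founder"] = df["sire"].isna() & df["dam"].isna()
        df["birth_year"] = pd.array(df["birth_year"], dtype="Int64")
        self.df = df.reset_index(drop=True)
        self._parents = {
            r.animal: (r.sire, r.dam) for r in self.df.itertuples(index=False)
        }

    def __len__(self) -> int:
        return len(self.df)

    @property
    def animals(self) -> list[str]:
        return list(self.df["animal"])

    def parents(self, animal: str) -> tuple[str | None, str | None]:
        return self._parents.get(str(animal), (None, None))


# ---------------------------------------------------------------------------
# IntervalSet
# ---------------------------------------------------------------------------


@dataclass
class IntervalSet:
    """Genomic intervals, 1-based inclusive, sorted by (chromosome, start)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        if "name" not in df.columns:
            df["name"] = [f"iv{i}" for i in range(len(df))]
        df = df[["chromosome", "start_bp", "end_bp", "name"]]
        df["chromosome"] = df["chromosome"].astype(str)
        if len(df):
            df["start_bp"] = df["start_bp"].astype(np.int64)
            df["end_bp"] = df["end_bp"].astype(np.int64)
            if (df["start_bp"] > df["end_bp"]).any():
                raise DataError("interval with start_bp > end_bp")
            df = df.sort_values(
                ["chromosome", "start_bp"],
                key=lambda s: s.map(_chrom_sort_key) if s.name == "chromosome" else s,
                kind="mergesort",
            )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# PLINK text PED/MAP
# ---------------------------------------------------------------------------

_ALLELE_RE = re.compile(r"^[ACGT12]$")


def read_plink_text(
    ped_path, map_path, min_call_rate: float | None = None
) -> GenotypeMatrix:
    """Read a PLINK text fileset into a :class:`GenotypeMatrix`.

    MAP: 4 whitespace-separated columns (chromosome, marker id, cM, bp).
    PED: 6 leading columns (FID IID PAT MAT SEX PHENO) then two allele
    columns per marker, in MAP file order. ``0 0`` encodes a missing call.

    Non-autosomal and unplaced markers are dropped (count logged); the
    remaining markers are re-ordered by (chromosome, position). Homozygote
    orientation: with numeric alleles, ``1`` is the reference allele; with
    ACGT alleles the alphabetically first allele observed at the marker is
    taken as reference. Orientation is irrelevant downstream.

    ``min_call_rate``, when set (e.g. 0.9), removes animals whose call rate
    falls below it.
    """
    raw_map = pd.read_csv(
        map_path, sep=r"\s+", header=None, dtype=str, comment="#"
    )
    if raw_map.shape[1] != 4:
        raise FormatError(
            f"{map_path}: MAP must have 4 columns, found {raw_map.shape[1]}"
        )
    raw_map.columns = ["chromosome", "marker_id", "cm", "position_bp"]
    n_markers_file = len(raw_map)
    keep = raw_map["chromosome"].map(is_autosome).to_numpy()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "dropped %d non-autosomal/unplaced markers at load", n_dropped
        )

    animal_ids: list[str] = []
    rows: list[np.ndarray] = []
    expected = 6 + 2 * n_markers_file
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            tok = line.split()
            if len(tok) != expected:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {expected} fields "
                    f"(6 + 2x{n_markers_file} markers), found {len(tok)}"
                )
            iid = tok[1]
            if iid in animal_ids:
                raise DataError(f"{ped_path}:{lineno}: duplicate animal id {iid!r}")
            animal_ids.append(iid)
            alleles = np.array(tok[6:], dtype="U1").reshape(-1, 2)
            rows.append(alleles)
    if not rows:
        raise FormatError(f"{ped_path}: no animals")
    alleles = np.stack(rows)  # (n, m_file, 2)

    # encode per marker
    calls = np.full((len(animal_ids), n_markers_file), MISSING, dtype=np.int8)
    a1, a2 = alleles[:, :, 0], alleles[:, :, 1]
    valid = (a1 != "0") & (a2 != "0")
    for j in range(n_markers_file):
        col1, col2, v = a1[:, j], a2[:, j], valid[:, j]
        obs = np.unique(np.concatenate([col1[v], col2[v]]))
        for al in obs:
            if not _ALLELE_RE.match(al):
                raise FormatError(
                    f"{ped_path}: invalid allele code {al!r} at marker "
                    f"{raw_map['marker_id'].iloc[j]!r}"
                )
        if obs.size == 0:
            continue
        ref = "1" if "1" in obs else str(sorted(obs)[0])
        het = v & (col1 != col2)
        hom_ref = v & ~het & (col1 == ref)
        hom_alt = v & ~het & (col1 != ref)
        calls[het, j] = HET
        calls[hom_ref, j] = HOM_REF
        calls[hom_alt, j] = HOM_ALT

    kept_map = raw_map.loc[keep, ["chromosome", "marker_id", "position_bp"]].copy()
    kept_map["position_bp"] = kept_map["position_bp"].astype(np.int64)
    calls = calls[:, keep]
    mm = MarkerMap(kept_map.reset_index(drop=True))
    # MarkerMap sorts by (chrom, pos); mirror that permutation on the columns
    order = (
        kept_map.reset_index(drop=True)
        .sort_values(
            ["chromosome", "position_bp"],
            key=lambda s: s.map(_chrom_sort_key) if s.name == "chromosome" else s,
            kind="mergesort",
        )
        .index.to_numpy()
    )
    gm = GenotypeMatrix(animal_ids, calls[:, order], mm)
    if min_call_rate is not None:
        rate = gm.call_rate()
        keep_animals = rate[rate >= min_call_rate].index
        n_removed = gm.n_animals - len(keep_animals)
        if n_removed:
            logger.info(
                "removed %d animals with call rate < %.2f", n_removed, min_call_rate
            )
            sel = [gm.animal_ids.index(a) for a in keep_animals]
            gm = GenotypeMatrix(list(keep_animals), gm.calls[sel], mm)
    return gm


def write_plink_text(gm: GenotypeMatrix, ped_path, map_path) -> None:
    """Write PLINK text PED/MAP; numeric alleles ``1`` (ref) / ``2`` (alt)."""
    mdf = gm.map.df
    with open(map_path, "w") as fh:
        for r in mdf.itertuples(index=False):
            fh.write(f"{r.chromosome}\t{r.marker_id}\t0\t{r.position_bp}\n")
    pair = {HOM_REF: "1 1", HET: "1 2", HOM_ALT: "2 2", MISSING: "0 0"}
    with open(ped_path, "w") as fh:
        for i, aid in enumerate(gm.animal_ids):
            geno = " ".join(pair[int(c)] for c in gm.calls[i])
            fh.write(f"{aid} {aid} 0 0 0 -9 {geno}\n")


# ---------------------------------------------------------------------------
# Pedigree table
# ---------------------------------------------------------------------------


def read_pedigree_table(path) -> Pedigree:
    """Read a headered, delimited pedigree table.

    Required columns: ``animal``, ``sire``, ``dam``; optional ``birth_year``
    and ``lineage``. Unknown parents are ``0`` or empty.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = {"animal", "sire", "dam"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing pedigree columns {sorted(missing)}")
    if "birth_year" in df.columns:
        df["birth_year"] = pd.to_numeric(df["birth_year"], errors="coerce")
    return Pedigree(df)


def write_pedigree_table(ped: Pedigree, path) -> None:
    out = ped.df[["animal", "sire", "dam", "birth_year", "lineage"]].copy()
    out["sire"] = out["sire"].fillna("0")
    out["dam"] = out["dam"].fillna("0")
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path) -> IntervalSet:
    """Read BED3+ (0-based half-open) into 1-based inclusive intervals."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            tok = line.split()
            if len(tok) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start0, end0 = tok[0], int(tok[1]), int(tok[2])
            if start0 >= end0:
                raise FormatError(
                    f"{path}:{lineno}: BED start >= end ({start0} >= {end0})"
                )
            name = tok[3] if len(tok) > 3 else f"iv{len(rows)}"
            rows.append((chrom, start0 + 1, end0, name))
    return IntervalSet(
        pd.DataFrame(rows, columns=["chromosome", "start_bp", "end_bp", "name"])
    )


def write_bed(intervals: IntervalSet, path) -> None:
    """Write intervals as BED3+ (inverts the 1-based inclusive conversion)."""
    with open(path, "w") as fh:
        for r in intervals.df.itertuples(index=False):
            fh.write(f"{r.chromosome}\t{r.start_bp - 1}\t{r.end_bp}\t{r.name}\n")


def write_tsv(df: pd.DataFrame, path, float_format: str = "%.6f") -> None:
    """Report-table writer: TSV, fixed 6-decimal floats for diffability."""
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
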
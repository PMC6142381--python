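"""Autozygosity islands: high-ROH-incidence regions shared across a cohort.

The island statistic works on the per-SNP ROH incidence track: for each
marker, the number of animals whose ROH cover it. Counts are
log10-transformed (with +1 so zero-count markers stay defined), and a
marker is an outlier when its transformed count exceeds the upper Tukey
fence Q3 + 1.5*IQR of its own autosome's distribution (strict inequality;
quartiles by linear interpolation, numpy's default). Runs of at least
``min_run`` consecutive outlier markers become islands, spanning the
positions of the first and last outlier SNP of the run. "Consecutive"
means adjacent in marker order on one chromosome; no physical-gap limit is
imposed, but the largest inter-marker gap inside each island is reported.

Interval overlap (islands vs CNVRs/genes, islands between lineages) uses
any-overlap (>= 1 bp) counting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import DataError
from .io_formats import IntervalSet, MarkerMap

ISLAND_COLUMNS = [
    "group",
    "chromosome",
    "start_bp",
    "end_bp",
    "length_bp",
    "n_outlier_snps",
    "peak_count",
    "max_gap_bp",
]


def snp_roh_incidence(
    segments: pd.DataFrame, marker_map: MarkerMap, zero_mode: str = "add_one"
) -> pd.DataFrame:
    """Count, per marker, the animals whose ROH cover it.

    Returns the marker map with ``count`` and ``log_count`` columns
    appended. ``zero_mode='add_one'`` (default) transforms log10(count+1);
    ``'drop'`` leaves zero-count markers with log_count = NaN so they are
    ignored by the fence computation.
    """
    if zero_mode not in ("add_one", "drop"):
        raise DataError(f"unknown zero_mode {zero_mode!r}")
    counts = np.zeros(len(marker_map), dtype=np.int64)
    for chrom in marker_map.chromosomes:
        sl = marker_map.chrom_slice(chrom)
        pos = marker_map.positions(chrom)
        sub = segments[segments["chromosome"] == chrom]
        if len(sub) == 0:
            continue
        # merge each animal's intervals so a marker counts an animal once
        # even if the input table carries overlapping segments
        merged = []
        for _, grp in sub.groupby("animal_id", sort=False):
            iv = grp[["start_bp", "end_bp"]].sort_values("start_bp").to_numpy()
            cur_s, cur_e = iv[0]
            for s, e in iv[1:]:
                if s <= cur_e + 1:
                    cur_e = max(cur_e, e)
                else:
                    merged.append((cur_s, cur_e))
                    cur_s, cur_e = s, e
            merged.append((cur_s, cur_e))
        starts = np.array([s for s, _ in merged])
        ends = np.array([e for _, e in merged])
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="right")
        delta = np.zeros(pos.size + 1, dtype=np.int64)
        np.add.at(delta, lo, 1)
        np.add.at(delta, hi, -1)
        counts[sl] += np.cumsum(delta[:-1])
    track = marker_map.df.copy()
    track["count"] = counts
    if zero_mode == "add_one":
        track["log_count"] = np.log10(counts + 1.0)
    else:
        with np.errstate(divide="ignore"):
            track["log_count"] = np.where(counts > 0, np.log10(counts), np.nan)
    return track


def outlier_mask(track: pd.DataFrame) -> np.ndarray:
    """Upper-Tukey-fence outlier flags, computed per autosome.

    A marker is flagged iff log_count > Q3 + 1.5*IQR of its chromosome's
    log_count distribution. With constant counts the IQR is 0 and the
    strict inequality flags nothing.
    """
    mask = np.zeros(len(track), dtype=bool)
    for _, idx in track.groupby("chromosome", sort=False).indices.items():
        vals = track["log_count"].to_numpy()[idx]
        finite = vals[np.isfinite(vals)]
        if finite.size == 0:
            continue
        q1, q3 = np.percentile(finite, [25, 75])
        fence = q3 + 1.5 * (q3 - q1)
        with np.errstate(invalid="ignore"):
            mask[idx] = vals > fence
    return mask


def call_islands(
    mask: np.ndarray,
    marker_map: MarkerMap,
    min_run: int = 100,
    counts: np.ndarray | None = None,
    group: str = "ALL",
) -> pd.DataFrame:
    """Runs of >= ``min_run`` consecutive outlier SNPs, as island intervals.

    Island start/end are the positions of the first/last flagged SNP of the
    run; runs are never bridged across an unflagged SNP.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size != len(marker_map):
        raise DataError("mask not aligned with marker map")
    rows = []
    for chrom in marker_map.chromosomes:
        sl = marker_map.chrom_slice(chrom)
        m = mask[sl]
        pos = marker_map.positions(chrom)
        d = np.diff(np.concatenate([[0], m.astype(np.int8), [0]]))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)  # exclusive
        for s, e in zip(starts, ends):
            if e - s < min_run:
                continue
            c = counts[sl][s:e] if counts is not None else None
            gaps = np.diff(pos[s:e])
            rows.append(
                {
                    "group": group,
                    "chromosome": chrom,
                    "start_bp": int(pos[s]),
                    "end_bp": int(pos[e - 1]),
                    "length_bp": int(pos[e - 1] - pos[s] + 1),
                    "n_outlier_snps": int(e - s),
                    "peak_count": int(c.max()) if c is not None else pd.NA,
                    "max_gap_bp": int(gaps.max()) if gaps.size else 0,
                }
            )
    return pd.DataFrame(rows, columns=ISLAND_COLUMNS)


def islands_from_segments(
    segments: pd.DataFrame,
    marker_map: MarkerMap,
    min_run: int = 100,
    group: str = "ALL",
    zero_mode: str = "add_one",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full island pipeline for one cohort: incidence -> fence -> runs.

    Returns (islands, incidence track with ``outlier`` column).
    """
    track = snp_roh_incidence(segments, marker_map, zero_mode=zero_mode)
    mask = outlier_mask(track)
    track["outlier"] = mask
    isl = call_islands(
        mask, marker_map, min_run=min_run, counts=track["count"].to_numpy(),
        group=group,
    )
    return isl, track


# ---------------------------------------------------------------------------
# interval overlap
# ---------------------------------------------------------------------------


def _relation(a_start, a_end, b_start, b_end) -> str:
    if a_start <= b_start and a_end >= b_end:
        return "contains"
    if b_start <= a_start and b_end >= a_end:
        return "contained"
    return "partial"


def overlap_intervals(a: IntervalSet, b: IntervalSet) -> pd.DataFrame:
    """All pairs of intervals from a and b overlapping by >= 1 bp.

    Identical intervals are reported as ``contains``. Output is sorted by
    (chromosome, a-interval start).
    """
    rows = []
    trees: dict[str, IntervalTree] = {}
    for r in b.df.itertuples(index=False):
        # intervaltree uses half-open ends; +1 converts inclusive ends
        trees.setdefault(r.chromosome, IntervalTree())[
            r.start_bp : r.end_bp + 1
        ] = (r.start_bp, r.end_bp, r.name)
    for r in a.df.itertuples(index=False):
        tree = trees.get(r.chromosome)
        if tree is None:
            continue
        for hit in sorted(tree[r.start_bp : r.end_bp + 1]):
            b_start, b_end, b_name = hit.data
            ov = min(r.end_bp, b_end) - max(r.start_bp, b_start) + 1
            rows.append(
                {
                    "chromosome": r.chromosome,
                    "a_name": r.name,
                    "a_start_bp": r.start_bp,
                    "a_end_bp": r.end_bp,
                    "b_name": b_name,
                    "b_start_bp": b_start,
                    "b_end_bp": b_end,
                    "overlap_bp": int(ov),
                    "relation": _relation(r.start_bp, r.end_bp, b_start, b_end),
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "chromosome",
            "a_name",
            "a_start_bp",
            "a_end_bp",
            "b_name",
            "b_start_bp",
            "b_end_bp",
            "overlap_bp",
            "relation",
        ],
    )
    if len(out):
        from .io_formats import _chrom_sort_key

        out = out.sort_values(
            ["chromosome", "a_start_bp"],
            key=lambda s: s.map(_chrom_sort_key) if s.name == "chromosome" else s,
            kind="mergesort",
        ).reset_index(drop=True)
    return out


def _islands_to_intervalset(islands: pd.DataFrame) -> IntervalSet:
    df = islands[["chromosome", "start_bp", "end_bp"]].copy()
    df["name"] = [
        f"{r.chromosome}:{r.start_bp}-{r.end_bp}"
        for r in islands.itertuples(index=False)
    ]
    return IntervalSet(df)


def compare_groups(group_islands: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Label each group's islands by which other groups they overlap.

    For every island: the set of other groups with >= 1 bp overlapping
    island, whether it is shared by all groups, and whether it is private
    (overlaps none). Requires >= 2 groups.
    """
    if len(group_islands) < 2:
        raise DataError("compare_groups needs >= 2 groups")
    sets = {g: _islands_to_intervalset(df) for g, df in group_islands.items()}
    rows = []
    for g, isl in group_islands.items():
        others = [h for h in group_islands if h != g]
        hit_by: dict[str, set[str]] = {name: set() for name in sets[g].df["name"]}
        for h in others:
            ov = overlap_intervals(sets[g], sets[h])
            for name in ov["a_name"].unique():
                hit_by[name].add(h)
        for r in isl.itertuples(index=False):
            name = f"{r.chromosome}:{r.start_bp}-{r.end_bp}"
            overlapping = sorted(hit_by[name])
            rows.append(
                {
                    "group": g,
                    "chromosome": r.chromosome,
                    "start_bp": r.start_bp,
                    "end_bp": r.end_bp,
                    "overlapping_groups": ",".join(overlapping),
                    "shared_all": len(overlapping) == len(others),
                    "private": len(overlapping) == 0,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "group",
            "chromosome",
            "start_bp",
            "end_bp",
            "overlapping_groups",
            "shared_all",
            "private",
        ],
    )
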
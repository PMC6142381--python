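"""Runs-of-homozygosity (ROH) detection with PLINK-style sliding windows.

A ROH is a contiguous stretch of homozygous genotypes in one individual,
the observable footprint of autozygosity (both chromosome copies identical
by descent). Detection follows the classical sliding-window scheme:

1. Slide a window of ``window_snps`` markers along each chromosome; a window
   is *homozygous* if it contains at most ``max_het`` heterozygous and at
   most ``max_missing_per_window`` missing calls.
2. For every SNP, compute the fraction of the windows spanning it that are
   homozygous; the SNP is ROH-eligible when that fraction reaches
   ``window_threshold``.
3. Maximal runs of consecutive eligible SNPs — split wherever adjacent
   markers are more than ``max_gap_bp`` apart — become candidate segments.
4. Candidates are kept only if they contain at least ``min_snps`` markers,
   span at least ``min_length_bp``, are dense enough
   (``length_bp / n_snps <= density_bp_per_snp``), and (by default) contain
   no more than ``max_het`` heterozygous calls over the whole segment.

Surviving segments are binned into the four conventional length classes
1–2, 2–4, 4–8 and >8 Mb; under 1 cM ~ 1 Mb these correspond to inbreeding
roughly 50, 20, 12.5 and 6 generations back.

Defaults reproduce a widely used livestock parameterisation: 50-SNP window,
>=100 SNPs and >=1 Mb per segment, <=0.5 Mb gap, >=1 SNP per 50 kb, <=5
missing and <=1 heterozygous call per window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .io_formats import HET, MISSING, GenotypeMatrix, MarkerMap

LENGTH_CLASSES = ["C1_2", "C2_4", "C4_8", "C8_plus"]
# half-open class bounds in bp: [1,2), [2,4), [4,8), [8, inf) Mb
_CLASS_EDGES_BP = [1_000_000, 2_000_000, 4_000_000, 8_000_000]

SEGMENT_COLUMNS = [
    "animal_id",
    "chromosome",
    "start_bp",
    "end_bp",
    "n_snps",
    "length_bp",
    "length_class",
]


@dataclass
class ROHParams:
    """Window and segment thresholds for the sliding-window caller.

    ``segment_het_limit`` toggles the conservative reading in which the
    heterozygote tolerance is enforced on the final segment as well as
    within windows; disabling it gives the window-only reading.
    """

    window_snps: int = 50
    min_snps: int = 100
    min_length_bp: int = 1_000_000
    max_gap_bp: int = 500_000
    density_bp_per_snp: int = 50_000
    max_missing_per_window: int = 5
    max_het: int = 1
    window_threshold: float = 0.05
    segment_het_limit: bool = True

    def __post_init__(self) -> None:
        for name in (
            "window_snps",
            "min_snps",
            "max_gap_bp",
            "density_bp_per_snp",
            "max_missing_per_window",
            "max_het",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.min_length_bp <= 0:
            raise ConfigError("min_length_bp must be > 0")
        if not 0.0 <= self.window_threshold <= 1.0:
            raise ConfigError("window_threshold must be in [0, 1]")


def _rolling_sum(x: np.ndarray, w: int) -> np.ndarray:
    c = np.concatenate([[0], np.cumsum(x, dtype=np.int64)])
    return c[w:] - c[:-w]


def window_hit_proportion(calls: np.ndarray, params: ROHParams) -> np.ndarray:
    """Per-SNP fraction of spanning windows that are homozygous.

    ``calls`` holds one animal's genotype codes along one chromosome in
    marker order. SNPs near chromosome ends are spanned by fewer windows and
    the proportion is taken over the windows that actually exist (no
    padding). A chromosome shorter than the window is treated as a single
    whole-chromosome window.
    """
    calls = np.asarray(calls)
    n = calls.size
    if n == 0:
        return np.zeros(0, dtype=float)
    het = (calls == HET).astype(np.int64)
    miss = (calls == MISSING).astype(np.int64)
    w = params.window_snps
    if w <= 1 or n < w:
        hit = (het.sum() <= params.max_het) and (
            miss.sum() <= params.max_missing_per_window
        )
        return np.full(n, 1.0 if hit else 0.0)
    win_hit = (
        (_rolling_sum(het, w) <= params.max_het)
        & (_rolling_sum(miss, w) <= params.max_missing_per_window)
    ).astype(np.int64)
    hit_cum = np.concatenate([[0], np.cumsum(win_hit)])
    j = np.arange(n)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, n - w)
    n_win = hi - lo + 1
    n_hit = hit_cum[hi + 1] - hit_cum[lo]
    return n_hit / n_win


def classify_length(length_bp: int) -> str:
    """Length class of a segment; bins are half-open, so exactly 2 Mb is C2_4."""
    if length_bp < _CLASS_EDGES_BP[0]:
        raise DataError(f"segment of {length_bp} bp is below the 1 Mb minimum")
    for cls, hi in zip(LENGTH_CLASSES[:3], _CLASS_EDGES_BP[1:]):
        if length_bp < hi:
            return cls
    return "C8_plus"


def _empty_segments() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal_id": pd.Series(dtype=str),
            "chromosome": pd.Series(dtype=str),
            "start_bp": pd.Series(dtype=np.int64),
            "end_bp": pd.Series(dtype=np.int64),
            "n_snps": pd.Series(dtype=np.int64),
            "length_bp": pd.Series(dtype=np.int64),
            "length_class": pd.Series(dtype=str),
        }
    )


def call_roh_sample(
    calls: np.ndarray,
    marker_map: MarkerMap,
    params: ROHParams | None = None,
    animal_id: str = "sample",
) -> pd.DataFrame:
    """Call ROH for one animal; returns one row per segment.

    Segment length is the SNP span ``end_bp - start_bp + 1`` with ends at
    the first/last marker of the run.
    """
    params = params or ROHParams()
    calls = np.asarray(calls)
    if calls.size != len(marker_map):
        raise DataError("calls not aligned with marker map")
    rows: list[tuple] = []
    for chrom in marker_map.chromosomes:
        sl = marker_map.chrom_slice(chrom)
        c = calls[sl]
        pos = marker_map.positions(chrom)
        prop = window_hit_proportion(c, params)
        eligible = prop >= params.window_threshold
        if not eligible.any():
            continue
        # maximal runs of eligible SNPs
        d = np.diff(np.concatenate([[0], eligible.astype(np.int8), [0]]))
        run_starts = np.flatnonzero(d == 1)
        run_ends = np.flatnonzero(d == -1)  # exclusive
        for s, e in zip(run_starts, run_ends):
            # split the run at physical gaps larger than max_gap_bp
            gaps = np.diff(pos[s:e])
            cut = np.flatnonzero(gaps > params.max_gap_bp)
            pieces = np.split(np.arange(s, e), cut + 1)
            for piece in pieces:
                if piece.size == 0:
                    continue
                i0, i1 = int(piece[0]), int(piece[-1])
                n_snps = i1 - i0 + 1
                length = int(pos[i1] - pos[i0] + 1)
                if n_snps < params.min_snps or length < params.min_length_bp:
                    continue
                if length / n_snps > params.density_bp_per_snp:
                    continue
                if (
                    params.segment_het_limit
                    and int((c[i0 : i1 + 1] == HET).sum()) > params.max_het
                ):
                    continue
                rows.append(
                    (
                        animal_id,
                        chrom,
                        int(pos[i0]),
                        int(pos[i1]),
                        n_snps,
                        length,
                        classify_length(length),
                    )
                )
    if not rows:
        return _empty_segments()
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def call_roh(gm: GenotypeMatrix, params: ROHParams | None = None) -> pd.DataFrame:
    """Call ROH for every animal in a cohort; concatenated segment table."""
    params = params or ROHParams()
    parts = [
        call_roh_sample(gm.calls[i], gm.map, params, animal_id=aid)
        for i, aid in enumerate(gm.animal_ids)
    ]
    if not parts:
        return _empty_segments()
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def summarize_classes(
    segments: pd.DataFrame, n_animals: int, l_total_bp: int
) -> pd.DataFrame:
    """Descriptive statistics of segment number and length per length class.

    Per class: segment count, percent of all segments, mean and SD of
    segment length (Mb), genome coverage % (mean per-animal summed class
    length / total mapped extent x 100) and cumulative length % (class
    summed length / all-class summed length x 100). A final ``ALL`` row
    carries the overall mean segments per animal and mean length.
    Zero segments overall yields an all-zero table.
    """
    if n_animals < 1:
        raise DataError("n_animals must be >= 1")
    if l_total_bp <= 0:
        raise DataError("l_total_bp must be > 0")
    total = len(segments)
    rows = []
    grand_len = float(segments["length_bp"].sum()) if total else 0.0
    for cls in LENGTH_CLASSES:
        sub = segments[segments["length_class"] == cls] if total else segments
        n = len(sub)
        lens_mb = sub["length_bp"].to_numpy() / 1e6 if n else np.array([])
        rows.append(
            {
                "length_class": cls,
                "n_roh": n,
                "pct_of_segments": 100.0 * n / total if total else 0.0,
                "mean_length_mb": float(lens_mb.mean()) if n else 0.0,
                "sd_length_mb": float(lens_mb.std(ddof=1)) if n > 1 else 0.0,
                "genome_coverage_pct": 100.0
                * float(sub["length_bp"].sum())
                / n_animals
                / l_total_bp,
                "cum_length_pct": 100.0 * float(sub["length_bp"].sum()) / grand_len
                if grand_len
                else 0.0,
            }
        )
    all_lens_mb = segments["length_bp"].to_numpy() / 1e6 if total else np.array([])
    rows.append(
        {
            "length_class": "ALL",
            "n_roh": total,
            "pct_of_segments": 100.0 if total else 0.0,
            "mean_length_mb": float(all_lens_mb.mean()) if total else 0.0,
            "sd_length_mb": float(all_lens_mb.std(ddof=1)) if total > 1 else 0.0,
            "genome_coverage_pct": 100.0 * grand_len / n_animals / l_total_bp,
            "cum_length_pct": 100.0 if total else 0.0,
        }
    )
    out = pd.DataFrame(rows)
    out.attrs["mean_segments_per_animal"] = total / n_animals
    return out


def chromosome_summary(
    segments: pd.DataFrame, marker_map: MarkerMap, animal_ids: list[str]
) -> pd.DataFrame:
    """Per-chromosome segment count and mean ROH coverage across animals.

    Coverage per animal per chromosome = summed ROH length / mapped
    chromosome extent x 100; the table reports the mean over all animals
    (zero-segment animals included) and its standard error.
    """
    n_animals = len(animal_ids)
    if n_animals == 0:
        raise DataError("no animals")
    rows = []
    for chrom in marker_map.chromosomes:
        extent = marker_map.chrom_extent_bp(chrom)
        sub = segments[segments["chromosome"] == chrom]
        per_animal = (
            sub.groupby("animal_id")["length_bp"].sum()
            .reindex(animal_ids, fill_value=0)
            .to_numpy()
        )
        cov = 100.0 * per_animal / extent if extent else np.zeros(n_animals)
        rows.append(
            {
                "chromosome": chrom,
                "n_roh": len(sub),
                "mean_coverage_pct": float(cov.mean()),
                "se_coverage_pct": float(cov.std(ddof=1) / np.sqrt(n_animals))
                if n_animals > 1
                else 0.0,
            }
        )
    return pd.DataFrame(rows)
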
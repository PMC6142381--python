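"""Synthetic SNP panels with known autozygosity: maps, pedigrees, gene drop.

Ground truth for every downstream stage comes from two generators:

* **Gene dropping** — founders receive two uniquely labelled haplotypes
  with allele states drawn from a uniform MAF spectrum; Mendelian
  transmission down a simulated pedigree recombines parental haplotypes as
  a Poisson (Haldane, no-interference) process at 1 cM = 1 Mb by default.
  Wherever an animal's two haplotypes carry the same founder-haplotype
  label it is autozygous, and those intervals are emitted as the truth
  track alongside the genotypes.
* **Segment planting** — direct overwriting of chosen intervals with
  homozygous calls, for sharp boundary-recovery tests. Planted segments
  are flanked by two heterozygous sentinel markers per side (``demarcate``)
  so the true boundary is observable against background homozygosity —
  without sentinels, chance runs of homozygous background SNPs adjacent to
  the segment make sub-marker boundary recovery impossible for any caller.

Every generator is a deterministic function of (config, seed). Substream
keys keep the map, pedigree and gene-drop draws independent under one
master seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .io_formats import HET, GenotypeMatrix, MarkerMap, Pedigree

_SUBSTREAM = {"map": 11, "pedigree": 13, "gene_drop": 17, "panel": 19, "plant": 23}


@dataclass
class SimConfig:
    """Study-condition knobs for the synthetic cohort.

    Defaults give the desk-scale cohort used throughout the test suite:
    2 chromosomes x 2500 markers x 50 Mb (20 kb mean spacing, the density
    of a high-density bovine chip scaled down ~6x) and ~500 animals over
    5 discrete generations from 84 founders. ``consanguinity_rate`` is the
    probability a mating pairs full sibs; ``recomb_cm_per_mb`` fixes the
    genetic map at 1 cM = 1 Mb. ``error_rate`` injects random heterozygous
    miscalls to exercise the caller's het tolerance (off by default).
    """

    n_chrom: int = 2
    markers_per_chrom: int = 2500
    chrom_length_bp: int = 50_000_000
    maf_min: float = 0.05
    n_founders: int = 84
    n_generations: int = 5
    offspring_per_mating: int = 2
    consanguinity_rate: float = 0.2
    recomb_cm_per_mb: float = 1.0
    error_rate: float = 0.0
    n_lineages: int = 3
    base_year: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_chrom",
            "markers_per_chrom",
            "chrom_length_bp",
            "n_founders",
            "n_generations",
            "offspring_per_mating",
            "n_lineages",
        ):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("consanguinity_rate", "error_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if not 0.0 < self.maf_min <= 0.5:
            raise ConfigError("maf_min must be in (0, 0.5]")
        if self.chrom_length_bp < 2 * self.markers_per_chrom:
            raise ConfigError("markers do not fit on the chromosome")


def _rng(cfg_seed: int, stream: str, seed: int | None) -> np.random.Generator:
    return np.random.default_rng(
        seed if seed is not None else [cfg_seed, _SUBSTREAM[stream]]
    )


def simulate_map(cfg: SimConfig, seed: int | None = None) -> MarkerMap:
    """Markers uniformly spaced with jitter; strictly increasing positions."""
    rng = _rng(cfg.seed, "map", seed)
    spacing = cfg.chrom_length_bp / cfg.markers_per_chrom
    rows = []
    for ch in range(1, cfg.n_chrom + 1):
        jitter = rng.uniform(-0.4, 0.4, size=cfg.markers_per_chrom)
        pos = np.round((np.arange(cfg.markers_per_chrom) + 0.5 + jitter) * spacing)
        pos = np.maximum(pos.astype(np.int64), 1)
        # |jitter| < 0.5 keeps order; guard against rounding collisions anyway
        pos = np.maximum.accumulate(pos + np.arange(cfg.markers_per_chrom) * 0)
        for i in range(1, pos.size):
            if pos[i] <= pos[i - 1]:
                pos[i] = pos[i - 1] + 1
        rows.append(
            pd.DataFrame(
                {
                    "chromosome": str(ch),
                    "marker_id": [f"c{ch}m{i}" for i in range(cfg.markers_per_chrom)],
                    "position_bp": pos,
                }
            )
        )
    return MarkerMap(pd.concat(rows, ignore_index=True))


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------


def simulate_pedigree(cfg: SimConfig, seed: int | None = None) -> Pedigree:
    """Discrete-generation pedigree with optional full-sib matings.

    Founders are unrelated, assigned lineage labels round-robin; offspring
    inherit the sire's lineage. Each generation draws ``len(prev)//2``
    matings from the previous generation; with probability
    ``consanguinity_rate`` a mating takes a full-sib pair (when one
    exists). Birth year increments per generation.
    """
    if cfg.n_founders < 2:
        raise ConfigError("need >= 2 founders")
    rng = _rng(cfg.seed, "pedigree", seed)
    rows = []
    founders = [f"F{i:04d}" for i in range(cfg.n_founders)]
    sexes = {}
    sibship = {}
    for i, a in enumerate(founders):
        sex = "M" if i % 2 == 0 else "F"
        sexes[a] = sex
        sibship[a] = None
        rows.append(
            {
                "animal": a,
                "sire": None,
                "dam": None,
                "birth_year": cfg.base_year,
                "lineage": f"L{i % cfg.n_lineages + 1}",
            }
        )
    lineage = {r["animal"]: r["lineage"] for r in rows}
    prev = founders
    for g in range(1, cfg.n_generations + 1):
        males = [a for a in prev if sexes[a] == "M"]
        females = [a for a in prev if sexes[a] == "F"]
        if not males or not females:
            raise ConfigError("a generation lost one sex entirely")
        sibs: dict = {}
        for a in prev:
            if sibship[a] is not None:
                sibs.setdefault(sibship[a], {"M": [], "F": []})[sexes[a]].append(a)
        mixed = [k for k, v in sibs.items() if v["M"] and v["F"]]
        n_matings = max(1, len(prev) // 2)
        offspring = []
        for m in range(n_matings):
            if mixed and rng.random() < cfg.consanguinity_rate:
                key = mixed[rng.integers(len(mixed))]
                sire = sibs[key]["M"][rng.integers(len(sibs[key]["M"]))]
                dam = sibs[key]["F"][rng.integers(len(sibs[key]["F"]))]
            else:
                # baseline matings avoid full and half sibs so that
                # consanguinity_rate alone controls close inbreeding
                for _ in range(100):
                    sire = males[rng.integers(len(males))]
                    dam = females[rng.integers(len(females))]
                    sib_s, sib_d = sibship[sire], sibship[dam]
                    if sib_s is None or sib_d is None or not (
                        set(sib_s) & set(sib_d)
                    ):
                        break
            for k in range(cfg.offspring_per_mating):
                child = f"G{g}_{m:04d}_{k}"
                sexes[child] = "M" if rng.random() < 0.5 else "F"
                sibship[child] = (sire, dam)
                lineage[child] = lineage[sire]
                rows.append(
                    {
                        "animal": child,
                        "sire": sire,
                        "dam": dam,
                        "birth_year": cfg.base_year + g,
                        "lineage": lineage[child],
                    }
                )
                offspring.append(child)
        prev = offspring
    return Pedigree(pd.DataFrame(rows))


def loop_pedigree(depth: int, n_families: int = 1) -> Pedigree:
    """Independent families whose only inbreeding loop has a fixed depth.

    Each family: a founder couple, two descent chains of ``depth - 1``
    generations (each chain member mated to a fresh unrelated founder), and
    a final animal ``*_Z`` crossing the two chain ends. The common ancestor
    couple sits exactly ``depth`` meioses above Z on both sides, so Z's
    autozygous segments all date to that depth; their expected length
    shrinks as 1/depth. Expected F of Z is 2^-(2*depth - 2), so deep loops
    need many families before any IBD segment is observed.
    """
    if depth < 2:
        raise ConfigError("loop depth must be >= 2")
    rows = []
    for f in range(n_families):
        p = f"fam{f}_"
        rows.append({"animal": p + "A", "sire": None, "dam": None})
        rows.append({"animal": p + "B", "sire": None, "dam": None})
        for side in "XY":
            prev = None
            for i in range(1, depth):
                a = f"{p}{side}{i}"
                if i == 1:
                    rows.append({"animal": a, "sire": p + "A", "dam": p + "B"})
                else:
                    mate = f"{p}{side}m{i}"
                    rows.append({"animal": mate, "sire": None, "dam": None})
                    rows.append({"animal": a, "sire": prev, "dam": mate})
                prev = a
        rows.append(
            {"animal": p + "Z", "sire": f"{p}X{depth-1}", "dam": f"{p}Y{depth-1}"}
        )
    df = pd.DataFrame(rows)
    df["birth_year"] = pd.NA
    df["lineage"] = pd.NA
    return Pedigree(df)


# ---------------------------------------------------------------------------
# gene drop
# ---------------------------------------------------------------------------


@dataclass
class TruthTrack:
    """True autozygosity from gene dropping.

    ``segments``: per-animal IBD intervals (1-based inclusive bp) where both
    haplotypes descend from the same founder haplotype. ``ibd_fraction``:
    per-animal autozygous genome fraction over ``genome_bp``.
    """

    segments: pd.DataFrame
    ibd_fraction: pd.Series
    genome_bp: int


def _meiosis(hap_a, hap_b, length_bp, morgans, rng):
    """One gamete from two parental haplotypes (lists of (start_bp, label))."""
    n_x = rng.poisson(morgans)
    if n_x == 0:
        return list(hap_a if rng.integers(2) == 0 else hap_b)
    xs = np.sort(rng.integers(2, length_bp + 1, size=n_x))
    source = int(rng.integers(2))
    haps = (hap_a, hap_b)
    bounds = [1, *xs.tolist(), length_bp + 1]
    child = []
    for i in range(len(bounds) - 1):
        a, b = bounds[i], bounds[i + 1] - 1
        if a > b:
            continue
        for start, label in _segments_in(haps[source], a, b):
            if child and child[-1][1] == label:
                continue  # merge contiguous same-label pieces
            child.append((start, label))
        source ^= 1
    return child


def _segments_in(hap, a, b):
    """Pieces of ``hap`` restricted to [a, b], clipped at a."""
    out = []
    for i, (start, label) in enumerate(hap):
        end = hap[i + 1][0] - 1 if i + 1 < len(hap) else float("inf")
        if end < a or start > b:
            continue
        out.append((max(start, a), label))
    return out


def gene_drop(
    pedigree: Pedigree,
    marker_map: MarkerMap,
    cfg: SimConfig,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, TruthTrack]:
    """Drop labelled founder haplotypes through the pedigree.

    Founder allele states are Bernoulli draws at per-marker MAFs uniform on
    [maf_min, 0.5]. Crossovers per meiosis are Poisson at
    ``recomb_cm_per_mb`` (1 cM = 1 Mb default) over each chromosome's
    mapped length; placement is uniform (Haldane, no interference).
    """
    rng = _rng(cfg.seed, "gene_drop", seed)
    chroms = marker_map.chromosomes
    chrom_len = {c: int(marker_map.positions(c)[-1]) for c in chroms}
    genome_bp = sum(chrom_len.values())
    m_total = len(marker_map)

    # every unknown-parent slot contributes one fresh labelled founder haplotype
    slot_labels: dict[tuple[str, str], int] = {}
    for animal in pedigree.animals:
        sire, dam = pedigree.parents(animal)
        if sire is None:
            slot_labels[(animal, "pat")] = len(slot_labels)
        if dam is None:
            slot_labels[(animal, "mat")] = len(slot_labels)
    maf = rng.uniform(cfg.maf_min, 0.5, size=m_total)
    founder_alleles = (
        rng.random((max(len(slot_labels), 1), m_total)) < maf
    ).astype(np.int8)

    haps: dict[str, dict[str, tuple[list, list]]] = {}
    for animal in pedigree.animals:  # topological order: parents first
        sire, dam = pedigree.parents(animal)
        haps[animal] = {}
        for c in chroms:
            length = chrom_len[c]
            morgans = length / 1e6 * cfg.recomb_cm_per_mb / 100.0
            if sire is None:
                pat = [(1, slot_labels[(animal, "pat")])]
            else:
                pat = _meiosis(*haps[sire][c], length, morgans, rng)
            if dam is None:
                mat = [(1, slot_labels[(animal, "mat")])]
            else:
                mat = _meiosis(*haps[dam][c], length, morgans, rng)
            haps[animal][c] = (pat, mat)

    animals = pedigree.animals
    calls = np.empty((len(animals), m_total), dtype=np.int8)
    truth_rows = []
    ibd_bp = {}
    for ai, animal in enumerate(animals):
        geno = np.empty(m_total, dtype=np.int8)
        total_ibd = 0
        for c in chroms:
            sl = marker_map.chrom_slice(c)
            pos = marker_map.positions(c)
            h1, h2 = haps[animal][c]
            lab1 = _labels_at(h1, pos)
            lab2 = _labels_at(h2, pos)
            idx = np.arange(sl.start, sl.stop)
            a1 = founder_alleles[lab1, idx]
            a2 = founder_alleles[lab2, idx]
            geno[sl] = a1 + a2
            for s, e in _ibd_intervals(h1, h2, chrom_len[c]):
                truth_rows.append(
                    {"animal_id": animal, "chromosome": c, "start_bp": s, "end_bp": e}
                )
                total_ibd += e - s + 1
        if cfg.error_rate > 0:
            flip = rng.random(m_total) < cfg.error_rate
            geno[flip] = HET
        calls[ai] = geno
        ibd_bp[animal] = total_ibd

    gm = GenotypeMatrix(animals, calls, marker_map)
    truth = TruthTrack(
        segments=pd.DataFrame(
            truth_rows, columns=["animal_id", "chromosome", "start_bp", "end_bp"]
        ),
        ibd_fraction=pd.Series(
            {a: v / genome_bp for a, v in ibd_bp.items()}, name="ibd_fraction"
        ),
        genome_bp=genome_bp,
    )
    return gm, truth


def _labels_at(hap, positions: np.ndarray) -> np.ndarray:
    starts = np.array([s for s, _ in hap], dtype=np.int64)
    labels = np.array([l for _, l in hap], dtype=np.int64)
    return labels[np.searchsorted(starts, positions, side="right") - 1]


def _ibd_intervals(h1, h2, length_bp):
    """Intervals of [1, length_bp] where the two haplotypes share a label."""
    starts = sorted({s for s, _ in h1} | {s for s, _ in h2})
    out = []
    for i, s in enumerate(starts):
        e = starts[i + 1] - 1 if i + 1 < len(starts) else length_bp
        l1 = _label_at_point(h1, s)
        l2 = _label_at_point(h2, s)
        if l1 == l2:
            if out and out[-1][1] == s - 1:
                out[-1] = (out[-1][0], e)
            else:
                out.append((s, e))
    return out


def _label_at_point(hap, point):
    label = hap[0][1]
    for s, l in hap:
        if s > point:
            break
        label = l
    return label


# ---------------------------------------------------------------------------
# planting and HWE panels
# ---------------------------------------------------------------------------


def plant_segments(
    gm: GenotypeMatrix,
    spec: list[tuple[str, str, int, int]],
    seed: int = 0,
    demarcate: bool = True,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Overwrite intervals with homozygous calls; record the truth.

    ``spec`` holds (animal_id, chromosome, start_bp, end_bp) tuples. Every
    marker inside each interval becomes homozygous, with the allele a
    deterministic function of (marker index, seed) so planting is
    idempotent and order-independent. With ``demarcate`` (default) the two
    markers flanking each end are set heterozygous, making the planted
    boundary observable. Returns (new matrix, truth table with requested
    coordinates and the marker-supported span).
    """
    calls = gm.calls.copy()
    rows = []
    for animal, chrom, start, end in spec:
        if animal not in gm.animal_ids:
            raise DataError(f"unknown animal {animal!r}")
        ai = gm.animal_ids.index(animal)
        pos = gm.map.positions(str(chrom))
        if pos.size == 0 or start < 1 or end > int(pos[-1]) or start > end:
            raise DataError(
                f"interval {chrom}:{start}-{end} is off the mapped extent"
            )
        sl = gm.map.chrom_slice(str(chrom))
        lo = int(np.searchsorted(pos, start, side="left"))
        hi = int(np.searchsorted(pos, end, side="right"))
        if hi <= lo:
            raise DataError(f"no markers inside {chrom}:{start}-{end}")
        idx = np.arange(sl.start + lo, sl.start + hi)
        alleles = ((idx * np.int64(2654435761) + seed) % 2 * 2).astype(np.int8)
        calls[ai, idx] = alleles
        if demarcate:
            left = np.arange(max(sl.start, sl.start + lo - 2), sl.start + lo)
            right = np.arange(
                sl.start + hi, min(sl.stop, sl.start + hi + 2)
            )
            calls[ai, left] = HET
            calls[ai, right] = HET
        rows.append(
            {
                "animal_id": animal,
                "chromosome": str(chrom),
                "start_bp": int(start),
                "end_bp": int(end),
                "first_marker_bp": int(pos[lo]),
                "last_marker_bp": int(pos[hi - 1]),
                "n_markers": int(hi - lo),
            }
        )
    return GenotypeMatrix(list(gm.animal_ids), calls, gm.map), pd.DataFrame(rows)


def simulate_founder_panel(
    n_animals: int,
    marker_map: MarkerMap,
    maf_min: float = 0.05,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Unrelated animals at Hardy-Weinberg equilibrium; returns (panel, MAFs)."""
    rng = np.random.default_rng([seed if seed is not None else 0, _SUBSTREAM["panel"]])
    m = len(marker_map)
    maf = rng.uniform(maf_min, 0.5, size=m)
    calls = rng.binomial(2, maf, size=(n_animals, m)).astype(np.int8)
    ids = [f"A{i:04d}" for i in range(n_animals)]
    return GenotypeMatrix(ids, calls, marker_map), maf
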
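"""End-to-end pipeline run: genotypes -> ROH -> inbreeding -> islands -> report.

One configured run writes, into the output directory: the per-segment ROH
table, the length-class and per-chromosome summaries, the per-animal
inbreeding table with correlations / birth-year trends / group means, the
per-SNP incidence track, islands (pooled and per lineage) with the group
comparison, any requested interval overlaps, a markdown report, and a
manifest (versions, seed, config hash). Reruns with the same config and
seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import AutozygError, ConfigError, DataError
from .inbreeding import (
    build_inbreeding_table,
    coefficient_correlations,
    group_means,
    inbreeding_trend,
)
from .io_formats import (
    GenotypeMatrix,
    Pedigree,
    read_bed,
    read_pedigree_table,
    read_plink_text,
    write_bed,
    write_pedigree_table,
    write_plink_text,
    write_tsv,
    IntervalSet,
)
from .islands import compare_groups, islands_from_segments, overlap_intervals
from .roh import ROHParams, call_roh, chromosome_summary, summarize_classes
from .simulate import SimConfig, gene_drop, simulate_map, simulate_pedigree

logger = logging.getLogger(__name__)

ARTIFACTS = [
    "roh_segments.tsv",
    "class_summary.tsv",
    "chromosome_summary.tsv",
    "inbreeding.tsv",
    "correlations.tsv",
    "trends.tsv",
    "group_means.tsv",
    "incidence.tsv",
    "islands.tsv",
]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``ped``/``map``/``pedigree`` paths are given, or ``simulate``
    holds a :class:`~autozyg.simulate.SimConfig`-shaped mapping and the
    cohort is generated in-process. ``l_total_mode`` is ``from-map`` or
    ``constant`` (then ``l_total_bp`` must be set).
    """

    out_dir: str = "autozyg_run"
    ped: str | None = None
    map: str | None = None
    pedigree: str | None = None
    regions_bed: str | None = None
    simulate: dict | None = None
    roh_params: dict = field(default_factory=dict)
    l_total_mode: str = "from-map"
    l_total_bp: int | None = None
    island_min_run: int = 100
    group_col: str = "lineage"
    min_call_rate: float | None = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.l_total_mode not in ("from-map", "constant"):
            raise ConfigError("l_total_mode must be 'from-map' or 'constant'")
        if self.l_total_mode == "constant" and not self.l_total_bp:
            raise ConfigError("l_total_mode 'constant' requires l_total_bp")
        if self.simulate is None and (self.ped is None or self.map is None):
            raise ConfigError("either simulate: or ped:/map: paths are required")
        for p in (self.ped, self.map, self.pedigree, self.regions_bed):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except AutozygError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate with stage name
                raise DataError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every stage; returns the output directory."""
    cfg.validate()
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- inputs -----------------------------------------------------------
    pedigree: Pedigree | None = None
    if cfg.simulate is not None:
        sim = SimConfig(**{**cfg.simulate, "seed": cfg.simulate.get("seed", cfg.seed)})
        marker_map = simulate_map(sim)
        pedigree = simulate_pedigree(sim)
        gm, _truth = gene_drop(pedigree, marker_map, sim)
        write_plink_text(gm, out / "sim.ped", out / "sim.map")
        write_pedigree_table(pedigree, out / "sim_pedigree.tsv")
        logger.info("simulated cohort: %d animals, %d markers", gm.n_animals, len(marker_map))
    else:
        gm = read_plink_text(cfg.ped, cfg.map, min_call_rate=cfg.min_call_rate)
        marker_map = gm.map
        if cfg.pedigree:
            pedigree = read_pedigree_table(cfg.pedigree)
        logger.info("loaded cohort: %d animals, %d markers", gm.n_animals, len(marker_map))

    l_total = (
        int(cfg.l_total_bp)
        if cfg.l_total_mode == "constant"
        else marker_map.total_extent_bp()
    )

    # --- ROH --------------------------------------------------------------
    params = ROHParams(**cfg.roh_params)
    segments = _stage("roh")(call_roh)(gm, params)
    logger.info("called %d ROH segments", len(segments))
    write_tsv(segments, out / "roh_segments.tsv")
    cls = summarize_classes(segments, gm.n_animals, l_total)
    write_tsv(cls, out / "class_summary.tsv")
    write_tsv(
        chromosome_summary(segments, marker_map, gm.animal_ids),
        out / "chromosome_summary.tsv",
    )

    # --- inbreeding -------------------------------------------------------
    table = _stage("inbreeding")(build_inbreeding_table)(
        segments, gm.animal_ids, l_total, pedigree=pedigree, gm=gm
    )
    write_tsv(table, out / "inbreeding.tsv")
    rho, n_pairs = coefficient_correlations(table)
    write_tsv(rho.reset_index(names="coefficient"), out / "correlations.tsv")
    trends = []
    if table["birth_year"].notna().any():
        for coef in [c for c in rho.columns]:
            try:
                trends.append(inbreeding_trend(table, coef))
            except DataError:
                continue
    write_tsv(pd.DataFrame(trends), out / "trends.tsv")
    write_tsv(group_means(table, cfg.group_col), out / "group_means.tsv")

    # --- islands ----------------------------------------------------------
    isl, track = _stage("islands")(islands_from_segments)(
        segments, marker_map, min_run=cfg.island_min_run
    )
    logger.info("found %d pooled islands", len(isl))
    write_tsv(track, out / "incidence.tsv")
    all_islands = [isl]
    groups = (
        table.dropna(subset=[cfg.group_col]).groupby(cfg.group_col)["animal_id"]
        if cfg.group_col in table.columns
        else []
    )
    per_group = {}
    for grp, ids in groups:
        seg_g = segments[segments["animal_id"].isin(set(ids))]
        isl_g, _ = islands_from_segments(
            seg_g, marker_map, min_run=cfg.island_min_run, group=str(grp)
        )
        per_group[str(grp)] = isl_g
        all_islands.append(isl_g)
    islands_df = pd.concat(all_islands, ignore_index=True)
    write_tsv(islands_df, out / "islands.tsv")
    if len(isl):
        from .islands import _islands_to_intervalset

        write_bed(_islands_to_intervalset(isl), out / "islands.bed")
    if len(per_group) >= 2:
        write_tsv(compare_groups(per_group), out / "island_group_comparison.tsv")
    if cfg.regions_bed:
        regions = read_bed(cfg.regions_bed)
        if len(isl):
            from .islands import _islands_to_intervalset

            ov = overlap_intervals(_islands_to_intervalset(isl), regions)
        else:
            ov = overlap_intervals(IntervalSet(pd.DataFrame(columns=["chromosome", "start_bp", "end_bp"])), regions)
        write_tsv(ov, out / "island_region_overlap.tsv")

    # --- report + manifest ------------------------------------------------
    _write_report(out, gm, segments, cls, table, rho, islands_df, l_total)
    cfg_text = yaml.safe_dump(vars(cfg), sort_keys=True)
    (out / "config.yaml").write_text(cfg_text)
    manifest = {
        "autozyg_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "artifacts": ARTIFACTS,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out


def _write_report(out, gm, segments, cls, table, rho, islands_df, l_total):
    lines = [
        "# Autozygosity analysis report",
        "",
        f"- animals: {gm.n_animals}",
        f"- markers: {len(gm.map)}",
        f"- L_total (bp): {l_total}",
        f"- ROH segments: {len(segments)}",
        f"- mean ROH per animal: {len(segments) / gm.n_animals:.2f}",
        f"- mean F_ROH (total): {table['f_roh_total'].mean():.4f}",
        f"- islands (all groups): {len(islands_df)}",
        "",
        "## ROH length classes",
        "",
        cls.round(2).to_string(index=False),
        "",
        "## Coefficient correlations (Spearman)",
        "",
        rho.round(3).to_string(),
        "",
    ]
    (out / "report.md").write_text("\n".join(lines))
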
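from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import autozyg as az
from autozyg.errors import ConfigError, DataError
from conftest import make_pedigree


class TestSimulateMap:
    def test_counts_and_mean_spacing(self):
        cfg = az.SimConfig(n_chrom=2, markers_per_chrom=2500, seed=0)
        mm = az.simulate_map(cfg)
        assert len(mm) == 5000
        spacings = np.diff(mm.positions("1"))
        assert spacings.mean() == pytest.approx(20_000, rel=0.05)

    def test_deterministic(self):
        cfg = az.SimConfig(seed=9, markers_per_chrom=500)
        pd.testing.assert_frame_equal(
            az.simulate_map(cfg).df, az.simulate_map(cfg).df
        )

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_positive_spacing_everywhere(self, seed):
        cfg = az.SimConfig(markers_per_chrom=1000, chrom_length_bp=5_000_000, seed=seed)
        mm = az.simulate_map(cfg)
        for c in mm.chromosomes:
            assert np.diff(mm.positions(c)).min() > 0

    def test_overfull_chromosome_rejected(self):
        with pytest.raises(ConfigError):
            az.SimConfig(markers_per_chrom=1000, chrom_length_bp=1500)


class TestSimulatePedigree:
    def test_no_consanguinity_means_zero_f(self):
        cfg = az.SimConfig(n_founders=20, n_generations=2, consanguinity_rate=0.0,
                           seed=3)
        ped = az.simulate_pedigree(cfg)
        assert (az.f_ped(ped) == 0).all()

    def test_mean_f_increases_with_consanguinity(self):
        means = []
        for rate in (0.0, 0.5):
            vals = []
            for seed in (1, 2, 3):
                cfg = az.SimConfig(n_founders=30, n_generations=4,
                                   consanguinity_rate=rate, seed=seed)
                vals.append(az.f_ped(az.simulate_pedigree(cfg)).mean())
            means.append(np.mean(vals))
        assert means[1] > means[0]

    def test_birth_years_follow_generations(self):
        cfg = az.SimConfig(n_founders=10, n_generations=3, seed=0, base_year=1990)
        ped = az.simulate_pedigree(cfg)
        assert ped.df["birth_year"].min() == 1990
        assert ped.df["birth_year"].max() == 1993

    def test_lineage_inherited_from_sire(self):
        cfg = az.SimConfig(n_founders=12, n_generations=2, seed=4)
        ped = az.simulate_pedigree(cfg)
        lin = dict(zip(ped.df["animal"], ped.df["lineage"]))
        for r in ped.df.itertuples(index=False):
            if r.sire is not None:
                assert r.lineage == lin[r.sire]


class TestLoopPedigree:
    @pytest.mark.parametrize("depth", [2, 3, 4])
    def test_f_of_loop_offspring(self, depth):
        ped = az.loop_pedigree(depth, n_families=2)
        f = az.f_ped(ped)
        expected = 0.5 ** (2 * depth - 2)
        for fam in range(2):
            assert f[f"fam{fam}_Z"] == pytest.approx(expected)


class TestGeneDrop:
    def test_founders_have_zero_ibd(self):
        cfg = az.SimConfig(n_founders=10, n_generations=1, markers_per_chrom=200,
                           chrom_length_bp=4_000_000, seed=2)
        mm = az.simulate_map(cfg)
        ped = az.simulate_pedigree(cfg)
        _, truth = az.gene_drop(ped, mm, cfg)
        founders = ped.df[ped.df["is_founder"]]["animal"]
        assert (truth.ibd_fraction[founders] == 0).all()

    def test_deterministic(self):
        cfg = az.SimConfig(n_founders=10, n_generations=2, markers_per_chrom=100,
                           chrom_length_bp=2_000_000, seed=5)
        mm = az.simulate_map(cfg)
        ped = az.simulate_pedigree(cfg)
        gm1, t1 = az.gene_drop(ped, mm, cfg)
        gm2, t2 = az.gene_drop(ped, mm, cfg)
        np.testing.assert_array_equal(gm1.calls, gm2.calls)
        pd.testing.assert_frame_equal(t1.segments, t2.segments)

    def test_full_sib_offspring_ibd_quarter(self):
        # 500 independent full-sib families in one drop; per-family IBD has
        # SD ~0.2, so the mean's standard error is ~0.009 against the 0.03 band
        ped = az.loop_pedigree(depth=2, n_families=500)
        cfg = az.SimConfig(n_chrom=2, markers_per_chrom=10,
                           chrom_length_bp=50_000_000, seed=8)
        mm = az.simulate_map(cfg)
        _, truth = az.gene_drop(ped, mm, cfg, seed=8)
        z = truth.ibd_fraction[[f"fam{i}_Z" for i in range(500)]]
        assert z.mean() == pytest.approx(0.25, abs=0.03)

    def test_ibd_matches_homozygosity_at_markers(self):
        # inside a true IBD interval every marker call is homozygous
        cfg = az.SimConfig(n_founders=12, n_generations=3, markers_per_chrom=500,
                           chrom_length_bp=10_000_000, consanguinity_rate=0.5, seed=6)
        mm = az.simulate_map(cfg)
        ped = az.simulate_pedigree(cfg)
        gm, truth = az.gene_drop(ped, mm, cfg)
        checked = 0
        for r in truth.segments.head(50).itertuples(index=False):
            ai = gm.animal_ids.index(r.animal_id)
            sl = mm.chrom_slice(r.chromosome)
            pos = mm.positions(r.chromosome)
            inside = (pos >= r.start_bp) & (pos <= r.end_bp)
            calls = gm.calls[ai, sl][inside]
            assert not (calls == az.HET).any()
            checked += inside.sum()
        assert checked > 0

    def test_truth_ibd_regresses_on_f_ped_with_unit_slope(self):
        cfg = az.SimConfig(seed=21)
        mm = az.simulate_map(cfg)
        ped = az.simulate_pedigree(cfg)
        _, truth = az.gene_drop(ped, mm, cfg)
        f = az.f_ped(ped)
        ibd = truth.ibd_fraction[f.index]
        res = stats.linregress(f.to_numpy(), ibd.to_numpy())
        assert len(f) >= 500
        assert res.slope == pytest.approx(1.0, abs=0.1)

    def test_founder_genotypes_track_maf_spectrum(self):
        cfg = az.SimConfig(n_founders=60, n_generations=1, markers_per_chrom=2000,
                           chrom_length_bp=40_000_000, n_chrom=1, seed=13)
        mm = az.simulate_map(cfg)
        ped = az.simulate_pedigree(cfg)
        gm, _ = az.gene_drop(ped, mm, cfg)
        founders = [i for i, a in enumerate(gm.animal_ids)
                    if a in set(ped.df[ped.df["is_founder"]]["animal"])]
        freq = gm.calls[founders].mean(axis=0) / 2
        # MAF ~ U(0.05, 0.5) -> mean allele frequency ~ 0.275
        assert freq.mean() == pytest.approx(0.275, abs=0.02)


class TestPlantSegments:
    def test_planted_markers_homozygous(self, small_map):
        gm, _ = az.simulate_founder_panel(5, small_map, seed=1)
        gm2, truth = az.plant_segments(gm, [("A0000", "1", 200_000, 900_000)], seed=0)
        pos = small_map.positions("1")
        inside = (pos >= 200_000) & (pos <= 900_000)
        calls = gm2.calls[0][inside]
        assert not (calls == az.HET).any()
        assert not (calls == az.MISSING).any()
        assert truth.iloc[0]["n_markers"] == inside.sum()

    def test_sentinel_markers_flank_segment(self, small_map):
        gm, _ = az.simulate_founder_panel(3, small_map, seed=2)
        gm2, truth = az.plant_segments(gm, [("A0001", "1", 500_000, 1_000_000)], seed=0)
        pos = small_map.positions("1")
        lo = int(np.searchsorted(pos, 500_000))
        hi = int(np.searchsorted(pos, 1_000_000, side="right"))
        assert (gm2.calls[1, lo - 2 : lo] == az.HET).all()
        assert (gm2.calls[1, hi : hi + 2] == az.HET).all()

    def test_idempotent(self, small_map):
        gm, _ = az.simulate_founder_panel(3, small_map, seed=3)
        spec = [("A0002", "1", 300_000, 800_000)]
        once, _ = az.plant_segments(gm, spec, seed=4)
        twice, _ = az.plant_segments(once, spec, seed=4)
        np.testing.assert_array_equal(once.calls, twice.calls)

    def test_off_map_interval_rejected(self, small_map):
        gm, _ = az.simulate_founder_panel(2, small_map, seed=5)
        with pytest.raises(DataError, match="off the mapped extent"):
            az.plant_segments(gm, [("A0000", "1", 1, 99_999_999)])
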
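from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import autozyg as az
from conftest import make_map
from oracles import incidence_bruteforce, overlap_bruteforce


def _segments(rows):
    return pd.DataFrame(
        rows,
        columns=["animal_id", "chromosome", "start_bp", "end_bp", "n_snps",
                 "length_bp", "length_class"],
    )


def _seg(animal, chrom, start, end):
    return [animal, chrom, start, end, 100, end - start + 1, "C1_2"]


class TestIncidence:
    def test_single_animal_single_segment(self, small_map):
        pos = small_map.positions("1")
        seg = _segments([_seg("a1", "1", int(pos[10]), int(pos[50]))])
        track = az.snp_roh_incidence(seg, small_map)
        counts = track["count"].to_numpy()
        assert (counts[10:51] == 1).all()
        assert counts.sum() == 41

    def test_shared_segment_counts_all_animals(self, small_map):
        pos = small_map.positions("1")
        seg = _segments(
            [_seg(f"a{i}", "1", int(pos[20]), int(pos[40])) for i in range(7)]
        )
        track = az.snp_roh_incidence(seg, small_map)
        assert (track["count"].to_numpy()[20:41] == 7).all()
        assert (track["count"].to_numpy()[:20] == 0).all()

    def test_matches_bruteforce(self, rng):
        mm = make_map(n_chrom=2, markers=60, spacing_bp=5_000)
        rows = []
        for i in range(25):
            chrom = str(rng.integers(1, 3))
            pos = mm.positions(chrom)
            a, b = np.sort(rng.choice(pos, 2, replace=False))
            rows.append(_seg(f"an{i % 8}", chrom, int(a), int(b)))
        seg = _segments(rows)
        track = az.snp_roh_incidence(seg, mm)
        np.testing.assert_array_equal(
            track["count"].to_numpy(), incidence_bruteforce(seg, mm)
        )

    def test_conservation(self, rng):
        mm = make_map(markers=100, spacing_bp=5_000)
        pos = mm.positions("1")
        rows, inside = [], 0
        for i in range(10):
            a, b = np.sort(rng.choice(100, 2, replace=False))
            rows.append(_seg(f"an{i}", "1", int(pos[a]), int(pos[b])))
            inside += b - a + 1
        track = az.snp_roh_incidence(_segments(rows), mm)
        assert track["count"].sum() == inside


class TestOutlierMask:
    def test_uniform_counts_no_outliers(self, small_map):
        track = small_map.df.copy()
        track["count"] = 5
        track["log_count"] = np.log10(6.0)
        assert not az.outlier_mask(track).any()

    def test_high_incidence_block_flagged_exactly(self):
        mm = make_map(markers=5000, spacing_bp=2_000)
        counts = np.full(5000, 5)
        counts[2000:2150] = 500
        track = mm.df.copy()
        track["count"] = counts
        track["log_count"] = np.log10(counts + 1.0)
        mask = az.outlier_mask(track)
        assert mask.sum() == 150
        assert mask[2000:2150].all()

    def test_fence_equality_not_flagged(self):
        mm = make_map(markers=8, spacing_bp=1_000)
        track = mm.df.copy()
        track["count"] = 0
        # values with Q3 + 1.5 IQR exactly equal to the maximum
        vals = np.array([1.0, 1, 1, 1, 2, 2, 2, 3.5])
        q1, q3 = np.percentile(vals, [25, 75])
        assert q3 + 1.5 * (q3 - q1) == pytest.approx(vals.max())
        track["log_count"] = vals
        assert not az.outlier_mask(track).any()


class TestCallIslands:
    @pytest.mark.parametrize("run,expected", [(100, 1), (99, 0)])
    def test_min_run_boundary(self, run, expected):
        mm = make_map(markers=300, spacing_bp=10_000)
        mask = np.zeros(300, bool)
        mask[50 : 50 + run] = True
        isl = az.call_islands(mask, mm, min_run=100)
        assert len(isl) == expected

    def test_runs_not_bridged(self):
        mm = make_map(markers=300, spacing_bp=10_000)
        mask = np.zeros(300, bool)
        mask[10:130] = True
        mask[131:251] = True
        isl = az.call_islands(mask, mm, min_run=100)
        assert len(isl) == 2

    def test_span_is_first_to_last_outlier(self):
        mm = make_map(markers=300, spacing_bp=10_000, start=10_000)
        mask = np.zeros(300, bool)
        mask[100:200] = True
        isl = az.call_islands(mask, mm, min_run=100)
        r = isl.iloc[0]
        pos = mm.positions("1")
        assert r["start_bp"] == pos[100]
        assert r["end_bp"] == pos[199]
        assert r["n_outlier_snps"] == 100

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.booleans(), min_size=50, max_size=200), st.integers(2, 30))
    def test_min_run_monotonicity(self, bits, min_run):
        mm = make_map(markers=len(bits), spacing_bp=10_000)
        mask = np.array(bits, dtype=bool)
        n_lo = len(az.call_islands(mask, mm, min_run=min_run))
        n_hi = len(az.call_islands(mask, mm, min_run=min_run + 5))
        assert n_hi <= n_lo

    def test_input_order_invariance(self, rng):
        mm = make_map(markers=400, spacing_bp=10_000)
        pos = mm.positions("1")
        rows = [
            _seg(f"a{i}", "1", int(pos[50]), int(pos[260])) for i in range(30)
        ] + [
            _seg(f"b{i}", "1", int(pos[rng.integers(300, 350)]),
                 int(pos[rng.integers(350, 399)]))
            for i in range(5)
        ]
        seg = _segments(rows)
        isl1, _ = az.islands_from_segments(seg, mm, min_run=100)
        isl2, _ = az.islands_from_segments(
            seg.sample(frac=1.0, random_state=3).reset_index(drop=True), mm,
            min_run=100,
        )
        pd.testing.assert_frame_equal(isl1, isl2)


class TestOverlap:
    def _ivs(self, rows):
        return az.IntervalSet(
            pd.DataFrame(rows, columns=["chromosome", "start_bp", "end_bp", "name"])
        )

    def test_identical_sets(self):
        a = self._ivs([("1", 100, 200, "x"), ("2", 50, 80, "y")])
        out = az.overlap_intervals(a, a)
        assert len(out) == 2
        assert (out["relation"] == "contains").all()
        assert (out["overlap_bp"] == [101, 31]).all()

    def test_disjoint_sets(self):
        a = self._ivs([("1", 100, 200, "x")])
        b = self._ivs([("1", 300, 400, "y"), ("2", 100, 200, "z")])
        assert len(az.overlap_intervals(a, b)) == 0

    def test_containment_relations(self):
        a = self._ivs([("1", 100, 500, "big"), ("1", 600, 700, "small")])
        b = self._ivs([("1", 200, 300, "inner"), ("1", 650, 900, "straddle")])
        out = az.overlap_intervals(a, b)
        rel = dict(zip(out["a_name"], out["relation"]))
        assert rel == {"big": "contains", "small": "partial"}

    def test_matches_bruteforce(self, rng):
        def random_set(k, tag):
            starts = rng.integers(1, 5_000, size=k)
            return self._ivs(
                [
                    (str(rng.integers(1, 3)), int(s), int(s + rng.integers(1, 800)),
                     f"{tag}{i}")
                    for i, s in enumerate(starts)
                ]
            )

        a, b = random_set(30, "a"), random_set(30, "b")
        out = az.overlap_intervals(a, b)
        got = sorted(zip(out["a_name"], out["b_name"], out["overlap_bp"]))
        assert got == overlap_bruteforce(a.df, b.df)


class TestCompareGroups:
    def _islands(self, rows, group):
        df = pd.DataFrame(rows, columns=["chromosome", "start_bp", "end_bp"])
        df.insert(0, "group", group)
        df["length_bp"] = df["end_bp"] - df["start_bp"] + 1
        df["n_outlier_snps"] = 100
        df["peak_count"] = 10
        df["max_gap_bp"] = 0
        return df

    def test_identical_groups_all_shared(self):
        rows = [("1", 100, 200), ("2", 50, 90)]
        out = az.compare_groups(
            {"g1": self._islands(rows, "g1"), "g2": self._islands(rows, "g2")}
        )
        assert out["shared_all"].all()
        assert not out["private"].any()

    def test_private_island(self):
        out = az.compare_groups(
            {
                "g1": self._islands([("1", 100, 200), ("3", 5, 50)], "g1"),
                "g2": self._islands([("1", 150, 300)], "g2"),
            }
        )
        private = out[out["private"]]
        assert len(private) == 1
        assert private.iloc[0]["chromosome"] == "3"

    def test_chained_overlaps(self):
        # a overlaps b, b overlaps c, a and c disjoint
        out = az.compare_groups(
            {
                "a": self._islands([("1", 100, 200)], "a"),
                "b": self._islands([("1", 150, 320)], "b"),
                "c": self._islands([("1", 300, 400)], "c"),
            }
        )
        by_group = out.set_index("group")["overlapping_groups"]
        assert by_group["a"] == "b"
        assert set(by_group["b"].split(",")) == {"a", "c"}
        assert by_group["c"] == "b"
        assert out["shared_all"].tolist() == [False, True, False]
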
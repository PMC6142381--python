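from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from autozyg import MarkerMap, Pedigree


def make_map(n_chrom=1, markers=200, spacing_bp=10_000, start=10_000) -> MarkerMap:
    """Evenly spaced test map (no jitter, for exact arithmetic)."""
    rows = []
    for c in range(1, n_chrom + 1):
        pos = start + spacing_bp * np.arange(markers)
        rows.append(
            pd.DataFrame(
                {
                    "chromosome": str(c),
                    "marker_id": [f"c{c}m{i}" for i in range(markers)],
                    "position_bp": pos,
                }
            )
        )
    return MarkerMap(pd.concat(rows, ignore_index=True))


def make_pedigree(rows) -> Pedigree:
    """Pedigree from (animal, sire, dam[, birth_year[, lineage]]) tuples."""
    recs = []
    for r in rows:
        animal, sire, dam = r[0], r[1], r[2]
        recs.append(
            {
                "animal": animal,
                "sire": sire,
                "dam": dam,
                "birth_year": r[3] if len(r) > 3 else pd.NA,
                "lineage": r[4] if len(r) > 4 else pd.NA,
            }
        )
    return Pedigree(pd.DataFrame(recs))


def random_pedigree(rng: np.random.Generator, n_animals=40, founder_prob=0.3):
    """Random acyclic pedigree built by sequential addition."""
    rows = []
    ids = []
    for i in range(n_animals):
        a = f"A{i:03d}"
        if len(ids) < 2 or rng.random() < founder_prob:
            rows.append((a, None, None))
        else:
            s, d = rng.choice(len(ids), size=2, replace=False)
            rows.append((a, ids[int(s)], ids[int(d)]))
        ids.append(a)
    return make_pedigree(rows)


@pytest.fixture
def small_map():
    return make_map(n_chrom=1, markers=200, spacing_bp=10_000)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
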
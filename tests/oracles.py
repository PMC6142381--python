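"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (path enumeration, quadratic scans,
explicit window enumeration) and shares no code with the package.
"""

from __future__ import annotations

import numpy as np


def wright_path_counting_f(pedigree_df) -> dict:
    """Wright's inbreeding coefficient by explicit loop (path) enumeration.

    F_X = sum over common ancestors A and pairs of ascending paths
    (sire->A, dam->A) that share no animal except A of
    (1/2)^(n1+n2+1) * (1 + F_A). Exponential; only for small pedigrees.
    """
    parents = {
        str(r.animal): (
            str(r.sire) if r.sire is not None and str(r.sire) not in ("None", "nan") else None,
            str(r.dam) if r.dam is not None and str(r.dam) not in ("None", "nan") else None,
        )
        for r in pedigree_df.itertuples(index=False)
    }

    def ascending_paths(node):
        """All paths node -> ancestor as (ancestor, frozenset(nodes), n_edges)."""
        out = [(node, frozenset([node]), 0)]
        s, d = parents.get(node, (None, None))
        for p in (s, d):
            if p is not None:
                for anc, nodes, n in ascending_paths(p):
                    out.append((anc, nodes | {node}, n + 1))
        return out

    memo: dict[str, float] = {}

    def f(x) -> float:
        if x in memo:
            return memo[x]
        s, d = parents.get(x, (None, None))
        if s is None or d is None:
            memo[x] = 0.0
            return 0.0
        total = 0.0
        for anc1, nodes1, n1 in ascending_paths(s):
            for anc2, nodes2, n2 in ascending_paths(d):
                if anc1 != anc2:
                    continue
                if nodes1 & nodes2 != {anc1}:
                    continue
                total += 0.5 ** (n1 + n2 + 1) * (1.0 + f(anc1))
        memo[x] = total
        return total

    return {a: f(a) for a in parents}


def window_proportion_bruteforce(calls, window, max_het, max_miss, het_code=1, miss_code=-1):
    """Per-SNP homozygous-window fraction by enumerating every window."""
    calls = np.asarray(calls)
    n = calls.size
    if n < window:
        hit = ((calls == het_code).sum() <= max_het) and (
            (calls == miss_code).sum() <= max_miss
        )
        return np.full(n, 1.0 if hit else 0.0)
    props = np.zeros(n)
    for j in range(n):
        n_win = n_hit = 0
        for s in range(max(0, j - window + 1), min(j, n - window) + 1):
            w = calls[s : s + window]
            n_win += 1
            if (w == het_code).sum() <= max_het and (w == miss_code).sum() <= max_miss:
                n_hit += 1
        props[j] = n_hit / n_win
    return props


def incidence_bruteforce(segments, marker_map) -> np.ndarray:
    """Per-marker animal counts by a quadratic membership scan."""
    counts = np.zeros(len(marker_map), dtype=int)
    df = marker_map.df
    for i, (chrom, pos) in enumerate(zip(df["chromosome"], df["position_bp"])):
        covering = set()
        for r in segments.itertuples(index=False):
            if r.chromosome == chrom and r.start_bp <= pos <= r.end_bp:
                covering.add(r.animal_id)
        counts[i] = len(covering)
    return counts


def overlap_bruteforce(a_df, b_df):
    """All-pairs >= 1 bp interval overlaps as (a_name, b_name, overlap_bp)."""
    out = []
    for ra in a_df.itertuples(index=False):
        for rb in b_df.itertuples(index=False):
            if ra.chromosome != rb.chromosome:
                continue
            ov = min(ra.end_bp, rb.end_bp) - max(ra.start_bp, rb.start_bp) + 1
            if ov >= 1:
                out.append((ra.name, rb.name, ov))
    return sorted(out)
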
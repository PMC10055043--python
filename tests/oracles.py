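"""Independent brute-force oracles used to verify the package's operations.

Every function here is a deliberately naive reimplementation (exhaustive
loops, transitive closures, full enumerations) kept independent of the code
paths it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats


def cluster_partition_bruteforce(genes, cluster_gap):
    """Transitive closure over the all-pairs 'same chromosome and gap <= g'
    relation; returns a frozenset of frozensets of gene ids."""
    ids = list(genes["gene_id"])
    n = len(ids)
    linked = np.zeros((n, n), dtype=bool)
    rows = list(genes.itertuples(index=False))
    for i in range(n):
        for j in range(n):
            if i == j:
                linked[i, j] = True
                continue
            a, b = rows[i], rows[j]
            if a.chrom != b.chrom:
                continue
            gap = max(b.start - a.end, a.start - b.end, 0)
            linked[i, j] = gap <= cluster_gap
    # transitive closure by repeated boolean multiplication
    closure = linked.copy()
    for _ in range(n):
        nxt = closure | (closure @ closure)
        if (nxt == closure).all():
            break
        closure = nxt
    groups = set()
    for i in range(n):
        groups.add(frozenset(ids[j] for j in range(n) if closure[i, j]))
    return frozenset(groups)


def bin_zone_bruteforce(genes, resolution, zone_sort_key):
    """Per-bin majority zone by scanning every (bin, gene) overlap; returns
    {(chrom, bin_start): zone} for bins overlapping at least one gene."""
    out = {}
    for chrom in sorted(set(genes["chrom"])):
        sub = genes[genes["chrom"] == chrom]
        lo = (sub["start"].min() // resolution) * resolution
        hi = sub["end"].max()
        for bin_start in range(lo, hi, resolution):
            overlapping = [
                r.zone for r in sub.itertuples(index=False)
                if r.start < bin_start + resolution and r.end > bin_start
            ]
            if not overlapping:
                continue
            best, best_count = None, -1
            for z in overlapping:
                c = overlapping.count(z)
                if c > best_count or (c == best_count and zone_sort_key(z) < zone_sort_key(best)):
                    best, best_count = z, c
            out[(chrom, bin_start)] = best
    return out


def qc_survivors_bruteforce(X, is_mito, min_genes, min_umis, max_mito, det=3):
    keep = []
    for i in range(X.shape[0]):
        row = X[i]
        genes = sum(1 for v in row if v >= det)
        umis = row.sum()
        mito = row[is_mito].sum()
        frac = mito / umis if umis > 0 else 0.0
        keep.append(genes >= min_genes and umis >= min_umis and frac < max_mito)
    return np.array(keep)


def expressed_sets_bruteforce(X, gene_ids, threshold):
    return [
        {gene_ids[j] for j in range(X.shape[1]) if X[i, j] >= threshold}
        for i in range(X.shape[0])
    ]


def spot_survivors_bruteforce(X_or, min_genes, min_umis):
    keep = []
    for i in range(X_or.shape[0]):
        row = X_or[i]
        keep.append(sum(1 for v in row if v > 0) >= min_genes and row.sum() >= min_umis)
    return np.array(keep)


def trans_heatmap_bruteforce(dense, chrom, zone, classes):
    """Mean trans contact per zone-class pair by an explicit double loop."""
    n = len(chrom)
    sums = {(a, b): [0.0, 0] for a in classes for b in classes}
    for i in range(n):
        for j in range(i + 1, n):
            if chrom[i] == chrom[j]:
                continue
            if zone[i] in classes and zone[j] in classes:
                for a, b in ((zone[i], zone[j]), (zone[j], zone[i])):
                    sums[(a, b)][0] += dense[i, j]
                    sums[(a, b)][1] += 1
    out = {}
    for key, (s, c) in sums.items():
        out[key] = s / c if c else None
    return out


def pairwise_distances_bruteforce(xyz):
    n = len(xyz)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = np.sqrt(((xyz[i] - xyz[j]) ** 2).sum())
    return d


def neighbor_counts_bruteforce(xyz, r):
    n = len(xyz)
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(n):
            if i != j and np.sqrt(((xyz[i] - xyz[j]) ** 2).sum()) <= r:
                counts[i] += 1
    return counts


def components_bruteforce(adj):
    """Union-find over an adjacency matrix; returns sorted component sizes."""
    n = len(adj)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(n):
            if adj[i][j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    roots = {}
    for i in range(n):
        roots.setdefault(find(i), []).append(i)
    return sorted(len(v) for v in roots.values())


def ranksum_p_bruteforce(a, b):
    """Exact two-sided p by enumerating every split of the pooled sample."""
    a, b = list(a), list(b)
    pooled = np.array(a + b, dtype=float)
    ranks = stats.rankdata(pooled)
    n_a = len(a)
    mean_u = n_a * len(b) / 2.0

    def u_of(idx):
        return ranks[list(idx)].sum() - n_a * (n_a + 1) / 2.0

    obs = abs(u_of(range(n_a)) - mean_u)
    hits = total = 0
    for picked in combinations(range(len(pooled)), n_a):
        total += 1
        if abs(u_of(picked) - mean_u) >= obs - 1e-9:
            hits += 1
    return hits / total
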
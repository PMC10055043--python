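"""Single-cell 3D genome analysis of OR compartments from dip-c structures.

Works on haplotype-resolved particle models (``.3dg``; one particle per 20 kb
of one haplotype, coordinates in particle-radius units, 1 radius ~ 60 nm).
OR loci are mapped to particles, pairwise distances extracted, and OR
"aggregates" quantified as connected components of the r-neighborhood graph,
with zonal trans-proximity fractions and per-cell contact-density comparisons
between dorsal and ventral cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list, optimal_leaf_ordering
from scipy.spatial.distance import pdist, squareform

from .ranksum import rank_sum_test, RankSumResult

#: the radii used for proximity analyses, in particle radii (~150/300/600 nm)
PROXIMITY_RADII = (2.5, 5.0, 10.0)


@dataclass
class ORLoci:
    """OR alleles mapped to particles of one structure."""

    table: pd.DataFrame  # gene_id, zone, chrom, haplotype, particle index, xyz
    unmapped: list[str]

    def __len__(self):
        return len(self.table)

    @property
    def xyz(self) -> np.ndarray:
        return self.table[["x", "y", "z"]].to_numpy()


def split_haplotype(chrom: str) -> tuple[str, str]:
    """'chr2(a)' -> ('chr2', 'a'); bare names get haplotype ''. """
    if chrom.endswith(")") and "(" in chrom:
        base, hap = chrom[:-1].rsplit("(", 1)
        return base, hap
    return chrom, ""


def map_or_loci(structure: pd.DataFrame, annotation: pd.DataFrame,
                resolution: int | None = None) -> ORLoci:
    """Map each OR (per haplotype) to the particle whose bin contains its
    midpoint.  ORs on missing chromosomes/bins are reported as unmapped."""
    st = structure.copy()
    base_hap = [split_haplotype(c) for c in st["chrom"]]
    st["base"] = [b for b, _ in base_hap]
    st["hap"] = [h for _, h in base_hap]
    if resolution is None:
        pos = np.sort(st["pos"].unique())
        resolution = int(np.min(np.diff(pos))) if len(pos) > 1 else int(pos[0] or 1)
    lookup = {(b, h, p): i for i, (b, h, p) in enumerate(zip(st["base"], st["hap"], st["pos"]))}
    haplotypes = sorted(st["hap"].unique())

    rows, unmapped = [], []
    for g in annotation.itertuples(index=False):
        mid = (g.start + g.end) // 2
        bin_pos = (mid // resolution) * resolution
        found = False
        for hap in haplotypes:
            i = lookup.get((g.chrom, hap, bin_pos))
            if i is not None:
                rows.append((g.gene_id, g.zone, g.chrom, hap, i,
                             st["x"].iloc[i], st["y"].iloc[i], st["z"].iloc[i]))
                found = True
        if not found:
            unmapped.append(g.gene_id)
    table = pd.DataFrame(
        rows, columns=["gene_id", "zone", "chrom", "haplotype", "particle", "x", "y", "z"]
    )
    return ORLoci(table, unmapped)


def pairwise_or_distances(loci: ORLoci) -> np.ndarray:
    """Symmetric Euclidean distance matrix over OR alleles, particle radii."""
    if len(loci) == 0:
        return np.zeros((0, 0))
    return squareform(pdist(loci.xyz))


@dataclass
class ProximityGraph:
    """r-neighborhood graph over OR alleles (undirected, no self edges)."""

    loci: ORLoci
    radius: float
    adjacency: np.ndarray  # boolean, symmetric, zero diagonal

    @property
    def edge_set(self) -> frozenset:
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return frozenset(zip(i.tolist(), j.tolist()))


def neighbors_within(loci: ORLoci, r: float,
                     distances: np.ndarray | None = None) -> tuple[np.ndarray, ProximityGraph]:
    """Per-allele count of other OR alleles within ``r`` (self excluded), plus
    the proximity graph."""
    if distances is None:
        distances = pairwise_or_distances(loci)
    adj = (distances <= r) & ~np.eye(len(distances), dtype=bool)
    return adj.sum(axis=1), ProximityGraph(loci, r, adj)


def aggregate_stats(graph: ProximityGraph) -> pd.DataFrame:
    """Connected components of the proximity graph: per aggregate, the number
    of OR alleles and of distinct chromosomes (singletons included)."""
    n = len(graph.adjacency)
    labels = _connected_components(graph.adjacency)
    chroms = graph.loci.table["chrom"].to_numpy() if n else np.array([])
    recs = []
    for comp in range(labels.max() + 1 if n else 0):
        members = np.flatnonzero(labels == comp)
        recs.append((comp, len(members), len(set(chroms[members]))))
    return pd.DataFrame(recs, columns=["aggregate", "n_ors", "n_chromosomes"])


def _connected_components(adj: np.ndarray) -> np.ndarray:
    from scipy.sparse.csgraph import connected_components
    from scipy import sparse

    if len(adj) == 0:
        return np.zeros(0, dtype=int)
    _, labels = connected_components(sparse.csr_matrix(adj), directed=False)
    return labels


def zonal_trans_proximity_fraction(graph: ProximityGraph) -> pd.Series:
    """Fraction of OR alleles of each zone class with at least one neighbor on
    a different chromosome within the graph radius."""
    t = graph.loci.table
    chrom = t["chrom"].to_numpy()
    trans_adj = graph.adjacency & (chrom[:, None] != chrom[None, :])
    has_trans = trans_adj.any(axis=1)
    return pd.Series(has_trans).groupby(t["zone"].to_numpy()).mean()


def contact_density(loci: ORLoci, r: float,
                    distances: np.ndarray | None = None) -> float:
    """Trans OR-OR pairs within ``r`` divided by the number of OR trans pairs."""
    if distances is None:
        distances = pairwise_or_distances(loci)
    chrom = loci.table["chrom"].to_numpy()
    iu = np.triu_indices(len(distances), 1)
    trans = chrom[iu[0]] != chrom[iu[1]]
    if trans.sum() == 0:
        return float("nan")
    return float((distances[iu][trans] <= r).mean())


def contact_density_compare(
    loci_a: list[ORLoci], loci_b: list[ORLoci], r: float = 2.5
) -> tuple[np.ndarray, np.ndarray, RankSumResult]:
    """Per-cell trans contact densities for two cell groups + rank-sum test."""
    dens_a = np.array([contact_density(l, r) for l in loci_a])
    dens_b = np.array([contact_density(l, r) for l in loci_b])
    return dens_a, dens_b, rank_sum_test(dens_a, dens_b)


def ordered_distance_heatmap(
    distances: np.ndarray,
    order: str = "hierarchical",
    display_threshold: float | None = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Row/column permutation + thresholded distance matrix for display.

    ``order="genomic"`` keeps the input (genomic) order; ``"hierarchical"``
    reorders by average-linkage clustering of the distance rows with a
    deterministic leaf order (ties broken by index).  Entries above
    ``display_threshold`` are masked to NaN.
    """
    n = len(distances)
    if order == "genomic" or n <= 1:
        perm = np.arange(n)
    elif order == "hierarchical":
        condensed = squareform(distances, checks=False)
        link = average(condensed)
        perm = np.asarray(leaves_list(optimal_leaf_ordering(link, condensed)))
    else:
        raise ValueError(f"order must be 'genomic' or 'hierarchical', got {order!r}")
    mat = distances[np.ix_(perm, perm)].astype(float)
    if display_threshold is not None:
        mat = np.where(mat <= display_threshold, mat, np.nan)
    return perm, mat
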
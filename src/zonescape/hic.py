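"""Bulk Hi-C zonal contact analysis.

OR genes converge into multi-chromosomal heterochromatic compartments; this
module measures that compartmentalization from binned contact matrices:
counts-per-billion normalization, average interchromosomal (trans) contacts
between genome bins grouped by the zonal identity of their resident ORs
(class I excluded), and long-range cis submatrix extraction between OR
clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import sparse

CPB_TARGET = 1e9  # counts per billion

#: the zone grouping used for trans heatmaps in the three-segment comparison
GROUPED_CLASSES = {"1": "1", "2": "2-3", "3": "2-3", "4": "4-5", "5": "4-5"}


@dataclass
class ContactMatrix:
    """Symmetric binned contact counts + an annotated bin table."""

    counts: sparse.csr_matrix
    bins: pd.DataFrame  # bin_id, chrom, start, resolution, zone
    total_contacts: float = None
    normalized: bool = False

    def __post_init__(self):
        if self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("contact matrix must be square")
        if self.counts.shape[0] != len(self.bins):
            raise ValueError("bin table size does not match matrix")
        if len(set(self.bins["resolution"])) != 1:
            raise ValueError("bins must share one resolution")
        if self.total_contacts is None:
            self.total_contacts = float(self.counts.sum())

    @classmethod
    def from_dense(cls, counts: np.ndarray, bins: pd.DataFrame) -> "ContactMatrix":
        return cls(sparse.csr_matrix(counts), bins.reset_index(drop=True))

    @property
    def resolution(self) -> int:
        return int(self.bins["resolution"].iloc[0])


def normalize_cpb(matrix: ContactMatrix, target: float = CPB_TARGET) -> ContactMatrix:
    """Scale every count by target / total contacts (counts per billion); idempotent."""
    if matrix.normalized:
        return matrix
    if matrix.total_contacts == 0:  # empty matrix: nothing to scale
        return replace(matrix, normalized=True)
    factor = target / matrix.total_contacts
    return replace(
        matrix,
        counts=(matrix.counts * factor).tocsr(),
        total_contacts=matrix.total_contacts,
        normalized=True,
    )


@dataclass
class ZonePairSummary:
    mean: pd.DataFrame  # zone class x zone class mean trans contacts (NaN = no pairs)
    n_pairs: pd.DataFrame


def trans_zone_heatmap(
    matrix: ContactMatrix,
    grouped: bool = False,
    expected_resolution: int | None = None,
) -> ZonePairSummary:
    """Average interchromosomal contacts between bins grouped by zonal identity.

    For zone classes (a, b) the entry is the mean normalized count over all
    unordered bin pairs (i, j) on different chromosomes with zone(i) = a and
    zone(j) = b.  Class I and unannotated bins are excluded; cells with no
    eligible pair are reported as missing (NaN), not zero.  ``grouped=True``
    collapses zones to the 1 / 2-3 / 4-5 classes.
    """
    if expected_resolution is not None and matrix.resolution != expected_resolution:
        raise ValueError(
            f"matrix resolution {matrix.resolution} != expected {expected_resolution}"
        )
    matrix = normalize_cpb(matrix)
    bins = matrix.bins
    zone = bins["zone"].astype(str).to_numpy()
    keep = np.isin(zone, ["1", "2", "3", "4", "5"])
    classes = sorted(set(GROUPED_CLASSES[z] for z in zone[keep])) if grouped else sorted(
        set(zone[keep])
    )
    labels = np.array([GROUPED_CLASSES.get(z, "") if grouped else z for z in zone])
    chrom = bins["chrom"].to_numpy()
    dense = np.asarray(matrix.counts.todense())

    mean = pd.DataFrame(np.nan, index=classes, columns=classes)
    n_pairs = pd.DataFrame(0, index=classes, columns=classes)
    idx = {c: np.flatnonzero(keep & (labels == c)) for c in classes}
    for i, ca in enumerate(classes):
        for cb in classes[i:]:
            ia, ib = idx[ca], idx[cb]
            block = dense[np.ix_(ia, ib)]
            trans = chrom[ia][:, None] != chrom[ib][None, :]
            if ca == cb:
                trans = trans & (ia[:, None] < ib[None, :])
            n = int(trans.sum())
            n_pairs.loc[ca, cb] = n_pairs.loc[cb, ca] = n
            if n:
                m = float(block[trans].mean())
                mean.loc[ca, cb] = mean.loc[cb, ca] = m
    return ZonePairSummary(mean, n_pairs)


def cis_window(
    matrix: ContactMatrix,
    cluster_a: tuple[str, int, int],
    cluster_b: tuple[str, int, int],
    color_cap: float | None = None,
) -> pd.DataFrame:
    """Dense block of normalized counts between two same-chromosome spans.

    ``cluster_*`` are (chrom, start, end) spans; rows cover cluster_a's bins,
    columns cluster_b's.  ``color_cap`` (display convention: 150 contacts)
    caps values for rendering; None leaves counts untouched.
    """
    matrix = normalize_cpb(matrix)
    chrom_a, start_a, end_a = cluster_a
    chrom_b, start_b, end_b = cluster_b
    if chrom_a != chrom_b:
        raise ValueError("cis_window requires both clusters on one chromosome")
    bins = matrix.bins
    res = matrix.resolution

    def bin_range(chrom, start, end):
        m = (bins["chrom"] == chrom) & (bins["start"] < end) & (bins["start"] + res > start)
        return bins.index[m].to_numpy()

    ia = bin_range(chrom_a, start_a, end_a)
    ib = bin_range(chrom_b, start_b, end_b)
    block = np.asarray(matrix.counts[np.ix_(ia, ib)].todense())
    if color_cap is not None:
        block = np.minimum(block, color_cap)
    return pd.DataFrame(
        block,
        index=bins.loc[ia, "start"].to_numpy(),
        columns=bins.loc[ib, "start"].to_numpy(),
    )
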
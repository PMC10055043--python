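"""Zonal olfactory-receptor (OR) annotation.

The mouse main olfactory epithelium (MOE) is segmented into ~5 dorsoventral
bands ("zones"); each OR gene has a native zone of expression, summarised by a
continuous zone index in [1, 5] (1 = dorsal-most, 5 = ventral-most).  Fish-like
class I ORs are expressed in zone 1 but are regulated separately and are kept
as their own identity category throughout.

This module discretises continuous zone indices into zone labels, groups ORs
into genomic clusters by single-linkage chaining, and annotates fixed-width
genome bins by the zonal identity of their resident ORs — the universe every
downstream analysis joins against.

Coordinates are 0-based, half-open everywhere; BED-compatible on disk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: categorical zone labels, in dorsal -> ventral display order
ZONE_LABELS = ("classI", "1", "2", "3", "4", "5", "unknown")

#: labels that carry a dorsoventral ordering (classI sorts dorsal-most, as a
#: separate category; unknown sorts last)
_ZONE_SORT_KEY = {"classI": -1, "1": 1, "2": 2, "3": 3, "4": 4, "5": 5, "unknown": 99}

DEFAULT_CLUSTER_GAP = 300_000
DEFAULT_BIN_RESOLUTION = 50_000

ANNOTATION_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "zone_index", "class_I"]


class AnnotationError(ValueError):
    """Raised for invalid OR annotation input."""


def zone_sort_key(label: str) -> int:
    """Total order over zone labels: classI (dorsal-most, separate) < 1 < ... < 5 < unknown."""
    return _ZONE_SORT_KEY[label]


def assign_zone(zone_index: float | None, is_class_I: bool, *, gene_id: str = "?",
                tie: str = "up") -> str:
    """Discretise a continuous zone index into a zone label.

    The class I flag dominates: class I ORs are a separate identity category
    regardless of their index.  Otherwise the index is rounded to the nearest
    integer, with exact .5 ties rounded up by default (``tie="down"`` rounds
    toward the dorsal label).  A missing index yields ``"unknown"``.
    """
    if is_class_I:
        return "classI"
    if zone_index is None or (isinstance(zone_index, float) and math.isnan(zone_index)):
        return "unknown"
    z = float(zone_index)
    if not (0.5 <= z < 5.5):
        raise AnnotationError(
            f"zone_index {z} for gene {gene_id!r} outside the valid range [0.5, 5.5)"
        )
    if tie == "up":
        rounded = math.floor(z + 0.5)
    elif tie == "down":
        rounded = math.ceil(z - 0.5)
    else:  # pragma: no cover - guarded by CLI/config validation
        raise ValueError(f"tie must be 'up' or 'down', got {tie!r}")
    rounded = min(max(rounded, 1), 5)
    return str(rounded)


def load_annotation(path) -> pd.DataFrame:
    """Read an OR annotation TSV (``#``-prefixed header) into a gene table.

    Columns: gene_id, chrom, start, end, strand, zone_index, class_I (0/1).
    Adds a ``zone`` column with the discretised label.
    """
    df = pd.read_csv(path, sep="\t", comment=None, header=0)
    df.columns = [c.lstrip("#").strip() for c in df.columns]
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"annotation file {path} missing columns: {missing}")
    return attach_zone_labels(df)


def attach_zone_labels(genes: pd.DataFrame, *, tie: str = "up") -> pd.DataFrame:
    """Validate a gene table and attach the discrete ``zone`` label column."""
    genes = genes.copy()
    if (genes["start"] >= genes["end"]).any():
        bad = genes.loc[genes["start"] >= genes["end"], "gene_id"].iloc[0]
        raise AnnotationError(f"gene {bad!r} has start >= end")
    genes["class_I"] = genes["class_I"].astype(int)
    genes["zone"] = [
        assign_zone(zi if pd.notna(zi) else None, bool(ci), gene_id=g, tie=tie)
        for g, zi, ci in zip(genes["gene_id"], genes["zone_index"], genes["class_I"])
    ]
    return genes


def write_annotation(genes: pd.DataFrame, path) -> None:
    out = genes[ANNOTATION_COLUMNS].copy()
    out = out.rename(columns={"gene_id": "#gene_id"})
    out.to_csv(path, sep="\t", index=False)


@dataclass
class ORCluster:
    """A genomic cluster of OR genes (single-linkage chain on one chromosome)."""

    cluster_id: str
    chrom: str
    start: int
    end: int
    member_gene_ids: list[str] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def build_clusters(genes: pd.DataFrame, cluster_gap: int = DEFAULT_CLUSTER_GAP) -> list[ORCluster]:
    """Chain consecutive same-chromosome ORs with gap <= cluster_gap into clusters.

    ``genes`` must already be sorted by (chrom, start); unsorted input is an
    error rather than being silently reordered, so that cluster ids are stable.
    Every OR ends up in exactly one cluster.
    """
    if cluster_gap <= 0:
        raise AnnotationError("cluster_gap must be positive")
    key = list(zip(genes["chrom"], genes["start"]))
    if key != sorted(key):
        raise AnnotationError("genes must be sorted by (chrom, start) before clustering")

    clusters: list[ORCluster] = []
    current: ORCluster | None = None
    for row in genes.itertuples(index=False):
        if (
            current is None
            or row.chrom != current.chrom
            or row.start - current.end > cluster_gap
        ):
            current = ORCluster(
                cluster_id=f"cluster_{len(clusters):03d}",
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                member_gene_ids=[row.gene_id],
            )
            clusters.append(current)
        else:
            current.end = max(current.end, int(row.end))
            current.member_gene_ids.append(row.gene_id)
    return clusters


def annotate_bins(
    clusters: list[ORCluster],
    genes: pd.DataFrame,
    resolution: int = DEFAULT_BIN_RESOLUTION,
) -> pd.DataFrame:
    """Annotate fixed-width genome bins overlapping OR clusters by zone.

    Every ``resolution``-wide bin overlapping a cluster span receives the zone
    of its resident ORs: the majority zone over all ORs overlapping the bin,
    ties broken toward the more dorsal label (classI counting as dorsal-most).
    Bins whose only overlapping ORs are class I are labelled ``classI``; bins
    overlapping a cluster span but no OR body get the majority zone of the
    cluster's members nearest definition — here, no OR overlap -> label of the
    cluster is not imputed and the bin is labelled ``unknown``.

    Returns a bin table: bin_id, chrom, start, resolution, zone.
    """
    genes = genes.reset_index(drop=True)
    records: list[tuple[str, int, str]] = []
    for cl in clusters:
        members = genes[genes["gene_id"].isin(cl.member_gene_ids)]
        first = (cl.start // resolution) * resolution
        for bin_start in range(first, cl.end, resolution):
            bin_end = bin_start + resolution
            overlap = members[(members["start"] < bin_end) & (members["end"] > bin_start)]
            if len(overlap) == 0:
                label = "unknown"
            else:
                counts = overlap["zone"].value_counts()
                top = counts.max()
                tied = sorted(counts[counts == top].index, key=zone_sort_key)
                label = tied[0]
            records.append((cl.chrom, bin_start, label))
    # distinct bins may be produced twice if clusters abut within one bin
    table = pd.DataFrame(records, columns=["chrom", "start", "zone"])
    table = table.drop_duplicates(subset=["chrom", "start"], keep="first")
    table = table.sort_values(["chrom", "start"]).reset_index(drop=True)
    table.insert(0, "bin_id", np.arange(len(table)))
    table["resolution"] = resolution
    return table[["bin_id", "chrom", "start", "resolution", "zone"]]


def clusters_to_bed(clusters: list[ORCluster]) -> pd.DataFrame:
    """BED6 frame for the cluster spans (name = cluster id, score = size)."""
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in clusters],
            "start": [c.start for c in clusters],
            "end": [c.end for c in clusters],
            "name": [c.cluster_id for c in clusters],
            "score": [len(c.member_gene_ids) for c in clusters],
            "strand": ["." for _ in clusters],
        }
    )


def bins_to_bed(bins: pd.DataFrame) -> pd.DataFrame:
    """BED6 frame for annotated bins (name = zone label)."""
    return pd.DataFrame(
        {
            "chrom": bins["chrom"],
            "start": bins["start"],
            "end": bins["start"] + bins["resolution"],
            "name": bins["zone"],
            "score": 0,
            "strand": ".",
        }
    )
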
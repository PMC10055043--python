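"""Heterochromatin gradient analysis from ChIP coverage tracks.

Quantifies H3K9me3/H3K79me3-style gene-body signal over OR genes: library
normalization to a fixed read count, length-normalized signal density,
scaled metagene matrices (gene bodies rescaled to a common length with fixed
flanks), and zone-grouped summaries testing the dorsal->ventral gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import ZONE_LABELS, zone_sort_key
from .ranksum import rank_sum_test

LIBRARY_TARGET = 10_000_000  # tracks are normalized to this library size


@dataclass
class CoverageTrack:
    """Per-contig depth vectors at ``bin_size`` bp resolution."""

    depth: dict[str, np.ndarray]
    bin_size: int = 1
    total_mapped_reads: float | None = None
    normalized: bool = False

    def __post_init__(self):
        for chrom, d in self.depth.items():
            d = np.asarray(d, dtype=float)
            if (d < 0).any():
                raise ValueError(f"negative depth on {chrom}")
            self.depth[chrom] = d
        if self.total_mapped_reads is None:
            self.total_mapped_reads = float(sum(d.sum() for d in self.depth.values()))

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Depth per base pair over [start, end) (bins expanded to bp)."""
        d = self.depth[chrom]
        bs = self.bin_size
        idx = np.arange(start, end) // bs
        if idx[-1] >= len(d):
            raise ValueError(f"{chrom}:{start}-{end} outside contig bounds")
        return d[idx]


def normalize_library(track: CoverageTrack, target: float = LIBRARY_TARGET) -> CoverageTrack:
    """Scale depth by target / total_mapped_reads; idempotent."""
    if track.normalized:
        return track
    factor = target / track.total_mapped_reads
    return CoverageTrack(
        {c: d * factor for c, d in track.depth.items()},
        bin_size=track.bin_size,
        total_mapped_reads=track.total_mapped_reads,
        normalized=True,
    )


def average_tracks(tracks: list[CoverageTrack]) -> CoverageTrack:
    """Replicate handling: simple mean after library normalization."""
    tracks = [normalize_library(t) for t in tracks]
    chroms = tracks[0].depth.keys()
    mean = {c: np.mean([t.depth[c] for t in tracks], axis=0) for c in chroms}
    return CoverageTrack(mean, bin_size=tracks[0].bin_size, normalized=True)


def gene_body_density(track: CoverageTrack, chrom: str, start: int, end: int) -> float:
    """Signal summed over the gene body [start, end), divided by its length."""
    if end <= start:
        raise ValueError("gene must have start < end")
    return float(track.values(chrom, start, end).sum() / (end - start))


def density_table(track: CoverageTrack, genes: pd.DataFrame) -> pd.DataFrame:
    """Length-normalized gene-body density for every gene in the table."""
    dens = [
        gene_body_density(track, r.chrom, r.start, r.end)
        for r in genes.itertuples(index=False)
    ]
    return pd.DataFrame(
        {"gene_id": genes["gene_id"], "zone": genes["zone"], "density": dens}
    )


def rescale_profile(values: np.ndarray, target_len: int) -> np.ndarray:
    """Linearly rescale a per-bp profile to ``target_len`` by exact mean-within-
    bin resampling: each output position is the average of the piecewise-
    constant input over its (fractional) source span."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n == 0:
        raise ValueError("cannot rescale an empty profile")
    cs = np.concatenate([[0.0], np.cumsum(values)])

    def integral(t: np.ndarray) -> np.ndarray:
        # integral of the step function from 0 to t
        base = np.floor(t).astype(int)
        base = np.minimum(base, n)
        frac = t - base
        return cs[base] + frac * values[np.minimum(base, n - 1)]

    edges = np.linspace(0.0, n, target_len + 1)
    ints = integral(edges)
    return np.diff(ints) / np.diff(edges)


def metagene_matrix(
    track: CoverageTrack,
    genes: pd.DataFrame,
    body: int = 6000,
    flank: int = 2000,
    n_bins: int = 200,
) -> pd.DataFrame:
    """Genes x positions matrix with bodies linearly rescaled to ``body`` bp.

    The row covers flank + body + flank bp split into ``n_bins`` equal bins
    (bodies are resampled by mean-within-bin onto the common body length);
    minus-strand genes are reversed so position runs 5'->3'.
    """
    total_len = body + 2 * flank
    if n_bins <= 0 or total_len % n_bins:
        raise ValueError(f"n_bins must evenly divide {total_len}")
    per_bin = total_len // n_bins
    rows = []
    for r in genes.itertuples(index=False):
        left = track.values(r.chrom, r.start - flank, r.start)
        body_raw = track.values(r.chrom, r.start, r.end)
        right = track.values(r.chrom, r.end, r.end + flank)
        scaled = rescale_profile(body_raw, body)
        profile = np.concatenate([left, scaled, right])
        if r.strand == "-":
            profile = profile[::-1]
        rows.append(profile.reshape(n_bins, per_bin).mean(axis=1))
    mat = pd.DataFrame(rows, index=genes["gene_id"].to_numpy())
    mat.columns = [f"bin_{i:03d}" for i in range(n_bins)]
    return mat


@dataclass
class ZoneSummary:
    stats: pd.DataFrame  # per-zone n, median, q25, q75
    monotone_decreasing: bool  # strictly decreasing medians zone1 -> zone5
    pairwise_p: pd.DataFrame = field(default=None)


def zone_group_summary(densities: pd.DataFrame, min_per_zone: int = 2) -> ZoneSummary:
    """Distribution stats per zone class, ordered classI, 1..5, plus pairwise
    rank-sum p-values and a flag for strictly decreasing medians zone1->zone5."""
    present = [z for z in ZONE_LABELS if z in set(densities["zone"]) and z != "unknown"]
    recs = []
    for z in present:
        vals = densities.loc[densities["zone"] == z, "density"]
        recs.append((z, len(vals), vals.median(),
                     vals.quantile(0.25), vals.quantile(0.75)))
    stats = pd.DataFrame(recs, columns=["zone", "n", "median", "q25", "q75"])
    stats = stats.sort_values("zone", key=lambda s: s.map(zone_sort_key)).reset_index(drop=True)

    ordered = [z for z in ("1", "2", "3", "4", "5") if z in present]
    medians = [float(stats.loc[stats["zone"] == z, "median"].iloc[0]) for z in ordered]
    monotone = len(ordered) >= 2 and all(a > b for a, b in zip(medians, medians[1:]))

    pvals = pd.DataFrame(np.nan, index=present, columns=present)
    for i, za in enumerate(present):
        for zb in present[i + 1:]:
            a = densities.loc[densities["zone"] == za, "density"].to_numpy()
            b = densities.loc[densities["zone"] == zb, "density"].to_numpy()
            if len(a) >= min_per_zone and len(b) >= min_per_zone:
                p = rank_sum_test(a, b).pvalue
                pvals.loc[za, zb] = pvals.loc[zb, za] = p
    return ZoneSummary(stats, monotone, pvals)
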
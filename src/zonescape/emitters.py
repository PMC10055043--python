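"""Emit the six input data kinds from one simulated tissue.

Each emitter derives its own random stream from (tissue seed, emitter tag) so
any subset of artifacts can be produced, in any order, with identical results.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd

from . import simulate as sim
from .annotation import build_clusters, annotate_bins
from .chip import CoverageTrack
from .hic import ContactMatrix

#: MOE dissection segments as sets of zones, following the trisection used for
#: zonal bulk experiments (dorsal = zone 1, dorsomedial = zones 2-3,
#: ventral = zones 4-5)
SEGMENTS = {
    "dorsal": (1,),
    "dorsomedial": (2, 3),
    "ventral": (4, 5),
    "whole": (1, 2, 3, 4, 5),
}

#: nominal u-windows of the dissection segments (before overlap)
_SEGMENT_U = {
    "dorsal": (0.0, 0.2),
    "dorsomedial": (0.2, 0.6),
    "ventral": (0.6, 1.0),
    "whole": (0.0, 1.0),
}

_EMITTER_TAGS = {"sc": 1, "chip": 2, "hic": 3, "dipc": 4, "spatial": 5}


def _emitter_rng(tissue: sim.SimTissue, tag: str) -> np.random.Generator:
    return np.random.default_rng([tissue.params.seed, _EMITTER_TAGS[tag]])


def _nb(rng, mu, theta, size=None):
    """Negative binomial with mean mu and dispersion theta (var = mu + mu^2/theta)."""
    return rng.negative_binomial(theta, theta / (theta + mu), size=size)


def segment_window(params: sim.SimParams, segment: str) -> tuple[float, float]:
    """The u-window a micro-dissected segment actually captures: its nominal
    window widened by ``dissection_overlap`` into the neighbouring segments
    (dissections are "mostly", not exactly, zonal)."""
    lo, hi = _SEGMENT_U[segment]
    d = params.dissection_overlap
    return max(0.0, lo - d), min(1.0, hi + d)


def _segment_cells(tissue, segment, stages):
    lo, hi = segment_window(tissue.params, segment)
    return [
        c for c in tissue.cells
        if c.stage in stages and (lo <= c.u < hi or (hi == 1.0 and c.u == 1.0))
    ]


# ---------------------------------------------------------------------------
# single-cell UMI counts
# ---------------------------------------------------------------------------

def emit_sc_counts(tissue: sim.SimTissue) -> ad.AnnData:
    """Cells x genes UMI matrix: transcribed ORs get NB(mu_low) UMIs in INP and
    iOSN cells, the chosen OR gets NB(mu_high) in mOSNs; housekeeping and
    mitochondrial genes are added so QC filters are exercisable."""
    p = tissue.params
    rng = _emitter_rng(tissue, "sc")
    genes = tissue.genes
    n_or = len(genes)
    hk = [f"Hk{i:04d}" for i in range(p.n_housekeeping)]
    mito = [f"mt-Gene{i}" for i in range(p.n_mito)]
    gene_ids = list(genes["gene_id"]) + hk + mito
    n_genes = len(gene_ids)

    X = np.zeros((len(tissue.cells), n_genes), dtype=np.int64)
    for i, cell in enumerate(tissue.cells):
        idx = np.flatnonzero(cell.transcribed)
        if len(idx):
            X[i, idx] = _nb(rng, p.mu_low, p.nb_theta, size=len(idx))
        if cell.chosen_or is not None:
            X[i, cell.chosen_or] = _nb(rng, p.mu_high, p.nb_theta)
        X[i, n_or: n_or + p.n_housekeeping] = _nb(
            rng, p.mu_housekeeping, p.nb_theta, size=p.n_housekeeping
        )
        X[i, n_or + p.n_housekeeping:] = _nb(
            rng, 0.02 * p.mu_housekeeping * p.n_housekeeping / p.n_mito,
            p.nb_theta, size=p.n_mito,
        )

    var = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    var["is_OR"] = [True] * n_or + [False] * (p.n_housekeeping + p.n_mito)
    var["zone"] = list(genes["zone"]) + ["unknown"] * (p.n_housekeeping + p.n_mito)
    var["is_mito"] = [g.startswith("mt-") for g in gene_ids]

    seg_label = {1: "dorsal", 2: "dorsomedial", 3: "dorsomedial", 4: "ventral", 5: "ventral"}
    obs = pd.DataFrame(
        {
            "stage": [c.stage for c in tissue.cells],
            "segment_zone": [c.segment_zone for c in tissue.cells],
            "segment": [seg_label[c.segment_zone] for c in tissue.cells],
            "u": [c.u for c in tissue.cells],
            "genotype": p.genotype,
        },
        index=pd.Index([c.cell_id for c in tissue.cells], name="barcode"),
    )
    return ad.AnnData(X=X, obs=obs, var=var)


# ---------------------------------------------------------------------------
# ChIP coverage
# ---------------------------------------------------------------------------

def emit_chip(tissue: sim.SimTissue, segment: str = "whole") -> CoverageTrack:
    """Heterochromatin-mark coverage for one dissection segment.

    Per-OR enrichment is the silencing frequency E over the segment's iOSN and
    mOSN cells; per-bin depth is Poisson(bin * depth * (base + alpha * E)) over
    gene bodies and Poisson(bin * depth * base) elsewhere — the generator's
    stated modelling assumption that the mark density tracks how often the OR
    is silenced in the population.
    """
    p = tissue.params
    # segment-specific stream so segments can be emitted in any order
    rng = np.random.default_rng(
        [p.seed, _EMITTER_TAGS["chip"], sorted(SEGMENTS).index(segment)]
    )
    cells = _segment_cells(tissue, segment, ("iOSN", "mOSN"))
    if not cells:
        raise ValueError(f"no iOSN/mOSN cells in segment {segment!r}")
    enrich = np.mean([c.silenced for c in cells], axis=0)

    bs = p.chip_bin_size
    sizes = sim.chrom_sizes(p, tissue.genes)
    track = {c: np.zeros(-(-n // bs)) for c, n in sizes.items()}
    for chrom, depth in track.items():
        depth[:] = rng.poisson(bs * p.chip_depth * p.chip_base, size=len(depth))
    for g, row in enumerate(tissue.genes.itertuples(index=False)):
        depth = track[row.chrom]
        b0, b1 = row.start // bs, -(-row.end // bs)
        lam = bs * p.chip_depth * (p.chip_base + p.chip_alpha * enrich[g])
        depth[b0:b1] = rng.poisson(lam, size=b1 - b0)
    total = float(sum(d.sum() for d in track.values()))
    return CoverageTrack(track, bin_size=bs, total_mapped_reads=total)


# ---------------------------------------------------------------------------
# Hi-C contacts
# ---------------------------------------------------------------------------

def or_bin_index(genes: pd.DataFrame, bins: pd.DataFrame) -> np.ndarray:
    """Index of the bin containing each gene midpoint (-1 if unbinned)."""
    lookup = {(r.chrom, r.start): r.bin_id for r in bins.itertuples(index=False)}
    res = int(bins["resolution"].iloc[0])
    out = np.full(len(genes), -1, dtype=int)
    for i, row in enumerate(genes.itertuples(index=False)):
        mid = (row.start + row.end) // 2
        out[i] = lookup.get((row.chrom, (mid // res) * res), -1)
    return out


def emit_hic(tissue: sim.SimTissue, segment: str = "ventral",
             resolution: int | None = None) -> ContactMatrix:
    """Binned contact matrix for one dissection segment.

    Trans counts for OR-bin pairs are Poisson(c0 + c1 * <M_i M_j> * depth),
    where M_i is q times the number of silenced ORs in bin i, averaged over
    the segment's iOSN/mOSN cells; all other trans pairs are Poisson(c0).
    Cis pairs add a distance-decay term.  Class I ORs are never silenced, so
    class I bins sit at near-background trans rates by construction.
    """
    p = tissue.params
    res = resolution or p.hic_resolution
    rng = np.random.default_rng(
        [p.seed, _EMITTER_TAGS["hic"], sorted(SEGMENTS).index(segment), res]
    )
    genes = tissue.genes
    clusters = build_clusters(genes)
    or_bins = annotate_bins(clusters, genes, resolution=res)

    # full genome tiling; OR bins carry their zone annotation
    sizes = sim.chrom_sizes(p, genes)
    rows = []
    for chrom in sorted(sizes):
        for start in range(0, sizes[chrom], res):
            rows.append((chrom, start))
    bins = pd.DataFrame(rows, columns=["chrom", "start"])
    bins.insert(0, "bin_id", np.arange(len(bins)))
    bins["resolution"] = res
    zone_map = {(r.chrom, r.start): r.zone for r in or_bins.itertuples(index=False)}
    bins["zone"] = [zone_map.get((c, s), "") for c, s in zip(bins["chrom"], bins["start"])]

    cells = _segment_cells(tissue, segment, ("iOSN", "mOSN"))
    if not cells:
        raise ValueError(f"no iOSN/mOSN cells in segment {segment!r}")
    gene_bin = or_bin_index(genes, bins)
    n_bins = len(bins)
    M = np.zeros((len(cells), n_bins))
    for ci, cell in enumerate(cells):
        np.add.at(M[ci], gene_bin[cell.silenced], p.hic_q)
    mm = (M.T @ M) / len(cells)  # <M_i M_j> over cells

    lam = np.full((n_bins, n_bins), p.hic_c0, dtype=float)
    lam += p.hic_c1 * p.hic_depth * mm
    chrom_of = bins["chrom"].to_numpy()
    start_of = bins["start"].to_numpy()
    same = chrom_of[:, None] == chrom_of[None, :]
    d = np.abs(start_of[:, None] - start_of[None, :]) // res
    with np.errstate(divide="ignore"):
        decay = p.hic_cis_scale * np.where(d > 0, d, 1) ** (-p.hic_cis_decay)
    lam = np.where(same, lam + decay, lam)

    iu, ju = np.triu_indices(n_bins)
    counts = np.zeros((n_bins, n_bins))
    counts[iu, ju] = rng.poisson(lam[iu, ju])
    counts = np.triu(counts) + np.triu(counts, 1).T
    return ContactMatrix.from_dense(counts, bins)


# ---------------------------------------------------------------------------
# Dip-C 3D structures
# ---------------------------------------------------------------------------

def emit_3dg(tissue: sim.SimTissue, segment: str = "ventral",
             n_cells: int = 48) -> list[pd.DataFrame]:
    """Per-cell haplotype-resolved particle tables at the Dip-C particle
    resolution (20 kb), coordinates in particle-radius units (~60 nm).

    Silenced OR particles join one of ``dipc_n_centers`` compartment centers
    (N(center, sigma^2 I)); all other particles are uniform in a ball of
    radius ``dipc_radius``.  mOSN cells are drawn from the tissue (topped up
    by fresh simulation if the tissue holds fewer than ``n_cells``).
    """
    p = tissue.params
    rng = np.random.default_rng(
        [p.seed, _EMITTER_TAGS["dipc"], sorted(SEGMENTS).index(segment)]
    )
    cells = _segment_cells(tissue, segment, ("mOSN",))
    lo, hi = segment_window(p, segment)
    while len(cells) < n_cells:
        u = lo + (hi - lo) * rng.random()
        cells.append(
            sim.simulate_cell(tissue.tables, u, "mOSN", rng,
                              cell_id=f"extra_{segment}_{len(cells):03d}")
        )
    cells = cells[:n_cells]

    res = p.dipc_resolution
    sizes = sim.chrom_sizes(p, tissue.genes)
    genes = tissue.genes
    structures = []
    for cell in cells:
        centers = _uniform_ball(rng, p.dipc_n_centers, 0.6 * p.dipc_radius)
        frames = []
        for chrom in sorted(sizes):
            n_part = -(-sizes[chrom] // res)
            pos = np.arange(n_part) * res
            sub = genes[genes["chrom"] == chrom]
            silenced_mid = (
                (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
            )[cell.silenced[sub.index.to_numpy()]]
            for hap in ("a", "b"):
                xyz = _uniform_ball(rng, n_part, p.dipc_radius)
                for mid in silenced_mid:
                    k = int(rng.integers(p.dipc_n_centers))
                    xyz[mid // res] = centers[k] + rng.normal(0, p.dipc_sigma, 3)
                frames.append(pd.DataFrame({
                    "chrom": f"{chrom}({hap})", "pos": pos,
                    "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2],
                }))
        df = pd.concat(frames, ignore_index=True)
        df.attrs["cell_id"] = cell.cell_id
        df.attrs["segment_zone"] = cell.segment_zone
        structures.append(df)
    return structures


def _uniform_ball(rng, n, radius):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1 / 3)
    return v * r[:, None]


# ---------------------------------------------------------------------------
# spatial spots
# ---------------------------------------------------------------------------

def emit_spatial(tissue: sim.SimTissue) -> tuple[pd.DataFrame, ad.AnnData]:
    """Spot grid + spot x OR-gene counts.

    Grid rows map linearly to the dorsoventral coordinate; each spot
    aggregates ``cells_per_spot`` mOSN choice draws at its zone (mu_high UMIs
    each, NB noise) plus ambient Poisson noise across all ORs.  The spot
    table carries the generator's ground-truth zone for accuracy checks.
    """
    p = tissue.params
    rng = _emitter_rng(tissue, "spatial")
    genes = tissue.genes
    n_or = len(genes)
    records = []
    X = np.zeros((p.spatial_rows * p.spatial_cols, n_or), dtype=np.int64)
    si = 0
    for r in range(p.spatial_rows):
        u = (r + 0.5) / p.spatial_rows
        Z = sim.segment_zone(u)
        for c in range(p.spatial_cols):
            for _ in range(p.cells_per_spot):
                cell = sim.simulate_cell(tissue.tables, u, "mOSN", rng)
                X[si, cell.chosen_or] += _nb(rng, p.mu_high, p.nb_theta)
            if p.ambient_rate > 0:
                X[si] += rng.poisson(p.ambient_rate, size=n_or)
            records.append((f"spot_{r:03d}_{c:03d}", r, c,
                            float(c) * 100.0, float(r) * 100.0, 1, Z))
            si += 1
    spots = pd.DataFrame(
        records, columns=["barcode", "row", "col", "x", "y", "in_tissue", "truth_zone"]
    )
    var = pd.DataFrame(index=pd.Index(genes["gene_id"], name="gene_id"))
    var["is_OR"] = True
    var["zone"] = genes["zone"].to_numpy()
    var["is_mito"] = False
    adata = ad.AnnData(
        X=X, var=var,
        obs=spots.set_index("barcode")[["row", "col", "truth_zone"]].copy(),
    )
    adata.obs["genotype"] = p.genotype
    return spots, adata
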
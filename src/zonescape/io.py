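"""On-disk formats shared across the pipeline.

Plain-text dialects only: MTX triplets with barcode/feature lists for count
matrices, 4-column bedGraph for coverage, ``bin1<TAB>bin2<TAB>count`` COO text
with a companion bin TSV for contact matrices, dip-c ``.3dg`` for per-cell 3D
structures, and TSV spot tables for spatial arrays.
"""

from __future__ import annotations

import os

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite


class FormatError(ValueError):
    """Raised when an input file violates its expected dialect."""


# ---------------------------------------------------------------------------
# count matrices (cells/spots x genes) as MTX triplet directories
# ---------------------------------------------------------------------------

def write_counts_dir(adata: ad.AnnData, outdir) -> None:
    """Write an AnnData as matrix.mtx + barcodes.tsv + features.tsv (+ metadata)."""
    os.makedirs(outdir, exist_ok=True)
    mat = sparse.csr_matrix(adata.X)
    mmwrite(os.path.join(outdir, "matrix.mtx"), mat.T.tocoo(), field="integer")
    pd.Series(adata.obs_names).to_csv(
        os.path.join(outdir, "barcodes.tsv"), sep="\t", index=False, header=False
    )
    adata.var.reset_index(names="gene_id").to_csv(
        os.path.join(outdir, "features.tsv"), sep="\t", index=False
    )
    if len(adata.obs.columns):
        adata.obs.reset_index(names="barcode").to_csv(
            os.path.join(outdir, "cell_metadata.tsv"), sep="\t", index=False
        )


def read_counts_dir(path) -> ad.AnnData:
    """Read a counts directory written by :func:`write_counts_dir` (genes x
    cells MTX, transposed back to cells x genes)."""
    mat = mmread(os.path.join(path, "matrix.mtx")).T.tocsr()
    barcodes = pd.read_csv(
        os.path.join(path, "barcodes.tsv"), sep="\t", header=None
    )[0].astype(str)
    features = pd.read_csv(os.path.join(path, "features.tsv"), sep="\t")
    if "gene_id" not in features.columns:
        raise FormatError(f"{path}/features.tsv lacks a gene_id column")
    adata = ad.AnnData(
        X=mat, var=features.set_index("gene_id"),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
    )
    meta_path = os.path.join(path, "cell_metadata.tsv")
    if os.path.exists(meta_path):
        meta = pd.read_csv(meta_path, sep="\t").set_index("barcode")
        meta.index = meta.index.astype(str)
        adata.obs = meta.loc[adata.obs_names]
    return adata


# ---------------------------------------------------------------------------
# bedGraph coverage
# ---------------------------------------------------------------------------

def write_bedgraph(track: dict[str, np.ndarray], bin_size: int, path) -> None:
    """Write per-contig depth vectors (at ``bin_size`` resolution) as bedGraph,
    merging runs of equal depth."""
    with open(path, "w") as fh:
        for chrom in sorted(track):
            depth = np.asarray(track[chrom])
            if len(depth) == 0:
                continue
            change = np.flatnonzero(np.diff(depth)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(depth)]])
            for s, e in zip(starts, ends):
                v = depth[s]
                if v == 0:
                    continue
                fh.write(f"{chrom}\t{s * bin_size}\t{e * bin_size}\t{v:g}\n")


def read_bedgraph(path, chrom_sizes: dict[str, int], bin_size: int = 1) -> dict[str, np.ndarray]:
    """Read a 4-column bedGraph into per-contig depth vectors at ``bin_size``.

    Intervals must align to ``bin_size`` boundaries.
    """
    track = {c: np.zeros(-(-n // bin_size)) for c, n in chrom_sizes.items()}
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"], comment="#")
    for row in df.itertuples(index=False):
        if row.chrom not in track:
            raise FormatError(f"bedGraph contig {row.chrom!r} not in chrom sizes")
        if row.start % bin_size or row.end % bin_size:
            raise FormatError(
                f"bedGraph interval {row.chrom}:{row.start}-{row.end} not aligned "
                f"to {bin_size} bp bins"
            )
        track[row.chrom][row.start // bin_size: row.end // bin_size] = row.value
    return track


# ---------------------------------------------------------------------------
# contact matrices: COO text + bin table
# ---------------------------------------------------------------------------

def write_contacts(counts: sparse.spmatrix, bins: pd.DataFrame, coo_path, bins_path) -> None:
    coo = sparse.triu(sparse.coo_matrix(counts))
    order = np.lexsort((coo.col, coo.row))
    with open(coo_path, "w") as fh:
        for i in order:
            fh.write(f"{coo.row[i]}\t{coo.col[i]}\t{coo.data[i]:g}\n")
    bins.to_csv(bins_path, sep="\t", index=False)


def read_contacts(coo_path, bins_path) -> tuple[sparse.csr_matrix, pd.DataFrame]:
    bins = pd.read_csv(bins_path, sep="\t")
    for col in ("bin_id", "chrom", "start", "resolution", "zone"):
        if col not in bins.columns:
            raise FormatError(f"bin table {bins_path} missing column {col!r}")
    n = len(bins)
    df = pd.read_csv(coo_path, sep="\t", header=None, names=["bin1", "bin2", "count"])
    if ((df["bin1"] < 0) | (df["bin1"] >= n) | (df["bin2"] < 0) | (df["bin2"] >= n)).any():
        raise FormatError(f"{coo_path} references bins outside the bin table")
    upper = sparse.coo_matrix(
        (df["count"], (df["bin1"], df["bin2"])), shape=(n, n)
    ).tocsr()
    lower = sparse.triu(upper, k=1).T
    return (sparse.triu(upper) + lower).tocsr(), bins


# ---------------------------------------------------------------------------
# dip-c .3dg structures
# ---------------------------------------------------------------------------

def write_3dg(particles: pd.DataFrame, path) -> None:
    """Write a 5-column .3dg: chrom(haplotype-suffixed), position, x, y, z."""
    particles[["chrom", "pos", "x", "y", "z"]].to_csv(
        path, sep="\t", index=False, header=False, float_format="%.6f"
    )


def read_3dg(path) -> pd.DataFrame:
    """Parse a .3dg file; duplicate particle keys or malformed lines raise
    :class:`FormatError` with the offending line number."""
    records = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 tab-separated columns")
            chrom, pos_s, xs, ys, zs = fields
            try:
                pos = int(pos_s)
                x, y, z = float(xs), float(ys), float(zs)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(z)):
                raise FormatError(f"{path}:{lineno}: non-finite coordinate")
            key = (chrom, pos)
            if key in seen:
                raise FormatError(f"{path}:{lineno}: duplicate particle {chrom}:{pos}")
            seen.add(key)
            records.append((chrom, pos, x, y, z))
    return pd.DataFrame(records, columns=["chrom", "pos", "x", "y", "z"])


# ---------------------------------------------------------------------------
# spatial spot tables
# ---------------------------------------------------------------------------

SPOT_COLUMNS = ["barcode", "row", "col", "x", "y", "in_tissue"]


def write_spots(spots: pd.DataFrame, path) -> None:
    spots[SPOT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_spots(path) -> pd.DataFrame:
    spots = pd.read_csv(path, sep="\t")
    missing = [c for c in SPOT_COLUMNS if c not in spots.columns]
    if missing:
        raise FormatError(f"spot table {path} missing columns: {missing}")
    if spots["barcode"].duplicated().any():
        raise FormatError(f"spot table {path} has duplicate barcodes")
    return spots
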
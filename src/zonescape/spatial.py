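"""Spatial transcriptomic zonal analysis of the olfactory epithelium.

Array-based spatial spots aggregate several cells' transcripts; because OR
mRNAs are abundant in mature OSNs, most tissue spots carry enough OR signal
to be assigned a zonal identity.  This module filters spots by OR content,
normalizes OR counts, scores each spot per zone class and assigns the argmax
zone, builds frozen top-N per-zone OR panels reusable across genotypes, and
provides a PCA + k-means spot-clustering stand-in.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .annotation import ZONE_LABELS, zone_sort_key

SPOT_MIN_OR_GENES = 2  # spots with fewer OR genes detected are removed
SPOT_MIN_OR_UMIS = 3  # ... or fewer OR transcripts

NONE_LABEL = "none"  # spots without any OR transcript


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X)


def filter_spots(
    adata: ad.AnnData,
    min_or_genes: int = SPOT_MIN_OR_GENES,
    min_or_umis: int = SPOT_MIN_OR_UMIS,
) -> ad.AnnData:
    """Keep spots with >= min_or_genes OR genes detected (any count) and
    >= min_or_umis OR transcripts in total."""
    or_mask = adata.var["is_OR"].to_numpy()
    X = _dense(adata.X)[:, or_mask]
    keep = ((X > 0).sum(axis=1) >= min_or_genes) & (X.sum(axis=1) >= min_or_umis)
    return adata[keep].copy()


def normalize_spots(adata: ad.AnnData) -> ad.AnnData:
    """OR-only normalized expression: per-spot OR counts scaled to the median
    OR library size, then log1p.  Zero-OR spots keep all-zero rows."""
    or_mask = adata.var["is_OR"].to_numpy()
    out = adata[:, or_mask].copy()
    X = _dense(out.X).astype(float)
    lib = X.sum(axis=1)
    median_lib = np.median(lib[lib > 0]) if (lib > 0).any() else 1.0
    scale = np.where(lib > 0, median_lib / np.maximum(lib, 1e-12), 0.0)
    out.X = np.log1p(X * scale[:, None])
    out.uns["normalized"] = True
    return out


@dataclass
class ZoneScoreTable:
    scores: pd.DataFrame  # spots x zone classes, summed normalized expression
    assigned_zone: pd.Series  # per spot: argmax class, or "none"


def assign_spot_zone(
    normalized: ad.AnnData, merge_classI: bool = False
) -> ZoneScoreTable:
    """Assign each spot the zone with the largest summed normalized OR counts.

    Ties go to the more dorsal class; spots with zero OR signal are "none"
    (they are excluded from clustering and panel computations downstream).
    ``merge_classI=True`` pools class I with zone 1 (display convention).
    """
    zones = normalized.var["zone"].astype(str).to_numpy()
    if merge_classI:
        zones = np.where(zones == "classI", "1", zones)
    classes = [z for z in ZONE_LABELS if z in set(zones)]
    X = _dense(normalized.X)
    scores = pd.DataFrame(
        {z: X[:, zones == z].sum(axis=1) for z in classes},
        index=normalized.obs_names,
    )
    ordered = sorted(classes, key=zone_sort_key)

    def pick(row) -> str:
        if row.sum() <= 0:
            return NONE_LABEL
        best = max(ordered, key=lambda z: (row[z], -zone_sort_key(z)))
        return best

    assigned = scores.apply(pick, axis=1)
    assigned.name = "assigned_zone"
    return ZoneScoreTable(scores, assigned)


def top_zone_panel(
    normalized: ad.AnnData, n: int = 20
) -> dict[str, list[str]]:
    """Top-``n`` ORs per zone class by mean normalized expression across spots.

    Panels are meant to be computed once on a reference (control) dataset and
    reused unchanged on others (e.g. the knockout).  Ties break
    lexicographically by gene id; zones with fewer than ``n`` ORs return the
    whole zone set.
    """
    zones = normalized.var["zone"].astype(str).to_numpy()
    X = _dense(normalized.X)
    mean_expr = X.mean(axis=0)
    panels: dict[str, list[str]] = {}
    for z in [z for z in ZONE_LABELS if z != "unknown" and z in set(zones)]:
        idx = np.flatnonzero(zones == z)
        ranked = sorted(idx, key=lambda j: (-mean_expr[j], normalized.var_names[j]))
        panels[z] = [normalized.var_names[j] for j in ranked[:n]]
    return panels


def panel_spot_means(normalized: ad.AnnData, panels: dict[str, list[str]]) -> pd.DataFrame:
    """Per-spot mean normalized expression of each frozen zone panel."""
    X = _dense(normalized.X)
    cols = {}
    names = pd.Index(normalized.var_names)
    for z, genes in panels.items():
        idx = names.get_indexer([g for g in genes if g in names])
        idx = idx[idx >= 0]
        cols[z] = X[:, idx].mean(axis=1) if len(idx) else np.zeros(normalized.n_obs)
    return pd.DataFrame(cols, index=normalized.obs_names)


def cluster_spots(
    normalized: ad.AnnData,
    k: int = 5,
    n_pcs: int = 5,
    seed: int = 0,
    rows: pd.Series | None = None,
) -> pd.Series:
    """PCA to ``n_pcs`` components then k-means into ``k`` clusters.

    Spots without OR signal are excluded (label -1).  Deterministic under
    ``seed``; cluster labels are relabeled by mean array row (a proxy for the
    dorsoventral coordinate) so label 0 is the dorsal-most cluster.
    """
    X = _dense(normalized.X)
    has_signal = X.sum(axis=1) > 0
    labels = np.full(normalized.n_obs, -1, dtype=int)
    Xs = X[has_signal]
    if Xs.shape[0] >= k:
        n_comp = min(n_pcs, Xs.shape[1], max(1, Xs.shape[0] - 1))
        pcs = PCA(n_components=n_comp, random_state=seed).fit_transform(Xs)
        km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(pcs)
        raw = km.labels_
        if rows is not None:
            row_vals = np.asarray(rows)[has_signal]
            order = np.argsort(
                [row_vals[raw == c].mean() if (raw == c).any() else np.inf for c in range(k)],
                kind="stable",
            )
            remap = {int(c): i for i, c in enumerate(order)}
            raw = np.array([remap[int(c)] for c in raw])
        labels[has_signal] = raw
    elif Xs.shape[0] > 0:
        labels[has_signal] = 0
    return pd.Series(labels, index=normalized.obs_names, name="cluster")
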
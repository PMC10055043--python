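"""Single-cell and bulk OR repertoire analysis.

QC filtering of UMI count matrices, expressed-OR calling at the 3-UMI
threshold, per-cell zonal classification by the most highly expressed OR,
repertoire composition crosstabs by stage and dissection segment, and
knockout-vs-control zonal fold-change statistics with the rank-sum test.

Count matrices are AnnData (cells x genes) with ``is_OR``, ``zone`` and
``is_mito`` gene columns; every OR gene joins the zonal annotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .annotation import ZONE_LABELS, zone_sort_key
from .ranksum import rank_sum_test, RankSumResult

UMI_EXPRESSED_THRESHOLD = 3  # an OR (or gene) counts as detected at >= 3 UMIs
QC_MIN_GENES = 1000
QC_MIN_UMIS = 20_000
QC_MAX_MITO_FRAC = 0.05


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X)


@dataclass
class QCReport:
    n_input: int
    n_kept: int
    failed_genes: int
    failed_umis: int
    failed_mito: int


def qc_filter_cells(
    adata: ad.AnnData,
    min_genes: int = QC_MIN_GENES,
    min_umis: int = QC_MIN_UMIS,
    max_mito_frac: float = QC_MAX_MITO_FRAC,
    detection_threshold: int = UMI_EXPRESSED_THRESHOLD,
) -> tuple[ad.AnnData, QCReport]:
    """Keep cells with detected genes >= min_genes AND UMIs >= min_umis AND
    mitochondrial fraction < max_mito_frac.

    Gene detection uses the same UMI threshold as expressed-OR calling.
    Filtering is idempotent; per-criterion failure counts are reported.
    """
    if "is_mito" not in adata.var.columns:
        raise ValueError("gene metadata lacks the required is_mito column")
    X = _dense(adata.X)
    n_genes = (X >= detection_threshold).sum(axis=1)
    n_umis = X.sum(axis=1)
    mito = X[:, adata.var["is_mito"].to_numpy()].sum(axis=1)
    with np.errstate(invalid="ignore"):
        mito_frac = np.where(n_umis > 0, mito / np.maximum(n_umis, 1), 0.0)
    ok_genes = n_genes >= min_genes
    ok_umis = n_umis >= min_umis
    ok_mito = mito_frac < max_mito_frac
    keep = ok_genes & ok_umis & ok_mito
    report = QCReport(
        n_input=adata.n_obs,
        n_kept=int(keep.sum()),
        failed_genes=int((~ok_genes).sum()),
        failed_umis=int((~ok_umis).sum()),
        failed_mito=int((~ok_mito).sum()),
    )
    return adata[keep].copy(), report


@dataclass
class RepertoireProfile:
    cell_id: str
    expressed_ors: dict[str, int]  # gene_id -> UMIs, counts >= threshold only
    zone_umis: dict[str, int]  # zone class -> summed OR UMIs (expressed ORs)
    dominant_zone: str  # zone of the most highly expressed OR, or "unknown"
    n_expressed_ors: int


def call_expressed_ors(
    adata: ad.AnnData, umi_threshold: int = UMI_EXPRESSED_THRESHOLD
) -> list[RepertoireProfile]:
    """Per-cell expressed-OR sets (count >= umi_threshold) and zonal summaries.

    The dominant zone is the zone of the OR with the maximum UMI count among
    expressed ORs; ties go to the more dorsal zone, then lexicographic
    gene id; cells with no expressed OR are "unknown".
    """
    or_mask = adata.var["is_OR"].to_numpy()
    or_ids = adata.var_names[or_mask].to_numpy()
    or_zones = adata.var["zone"].to_numpy()[or_mask]
    X = _dense(adata.X)[:, or_mask]
    profiles = []
    for i, cell_id in enumerate(adata.obs_names):
        counts = X[i]
        expressed = np.flatnonzero(counts >= umi_threshold)
        expr = {or_ids[j]: int(counts[j]) for j in expressed}
        zone_umis: dict[str, int] = {}
        for j in expressed:
            zone_umis[or_zones[j]] = zone_umis.get(or_zones[j], 0) + int(counts[j])
        if len(expressed):
            best = sorted(
                expressed,
                key=lambda j: (-counts[j], zone_sort_key(or_zones[j]), or_ids[j]),
            )[0]
            dominant = or_zones[best]
        else:
            dominant = "unknown"
        profiles.append(
            RepertoireProfile(str(cell_id), expr, zone_umis, dominant, len(expressed))
        )
    return profiles


def classify_cell_zone(profile: RepertoireProfile) -> str:
    """Zonal identity of a cell: the zone of its most highly expressed OR."""
    return profile.dominant_zone


def repertoire_crosstab(
    profiles: list[RepertoireProfile], groups: pd.DataFrame
) -> pd.DataFrame:
    """Cells expressing >= 1 OR of each zone class, per (stage, segment) group.

    ``groups`` is indexed by cell id with ``stage`` and ``segment`` columns;
    a cell counts in every zone class it expresses, so rows need not sum to
    the cell total unless cells are monogenic.
    """
    classes = [z for z in ZONE_LABELS if z != "unknown"]
    recs = {}
    for p in profiles:
        stage = groups.loc[p.cell_id, "stage"]
        seg = groups.loc[p.cell_id, "segment"]
        row = recs.setdefault((stage, seg), dict.fromkeys(classes + ["n_cells"], 0))
        row["n_cells"] += 1
        for z in set(p.zone_umis):
            if z in row:
                row[z] += 1
    out = pd.DataFrame.from_dict(recs, orient="index").sort_index()
    out.index = pd.MultiIndex.from_tuples(out.index, names=["stage", "segment"])
    return out


def profiles_table(profiles: list[RepertoireProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [p.cell_id for p in profiles],
            "n_expressed_ors": [p.n_expressed_ors for p in profiles],
            "dominant_zone": [p.dominant_zone for p in profiles],
        }
    )


def zonal_fold_change(
    counts_a: pd.Series | np.ndarray,
    counts_b: pd.Series | np.ndarray,
    zones: pd.Series | np.ndarray,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-OR log2 fold change of group a over group b, with zone labels.

    Inputs are per-OR summed counts for each group; both are library-size
    normalized to counts-per-million before log2((cpm_a + pc)/(cpm_b + pc)),
    so the result is invariant to common scaling of either library.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must align")
    cpm_a = a / a.sum() * 1e6
    cpm_b = b / b.sum() * 1e6
    with np.errstate(divide="ignore"):
        lfc = np.log2((cpm_a + pseudocount) / (cpm_b + pseudocount))
    return pd.DataFrame({"zone": np.asarray(zones), "log2fc": lfc})


def zone_shift_test(
    fold_changes: pd.DataFrame, zone_a: str, zone_b: str
) -> RankSumResult:
    """Rank-sum test of per-OR fold changes between two zone classes."""
    a = fold_changes.loc[fold_changes["zone"] == zone_a, "log2fc"].to_numpy()
    b = fold_changes.loc[fold_changes["zone"] == zone_b, "log2fc"].to_numpy()
    return rank_sum_test(a, b)
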
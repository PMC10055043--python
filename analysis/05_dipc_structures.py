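"""Single-cell OR compartments from Dip-C 3D structures.

Reads the per-cell .3dg models, maps OR alleles to particles, and measures
trans OR-OR contact densities and r-neighborhood aggregates.  Finding:
ventral mOSNs have denser OR compartments than dorsal mOSNs (rank-sum), every
cell's OR interaction map is unique, and within ventral cells zone4-5 ORs are
less often in trans proximity than zone-1 ORs.
"""

import glob
from pathlib import Path

import numpy as np
import pandas as pd

from zonescape import dipc
from zonescape import io as zio
from zonescape.annotation import load_annotation
from zonescape.ranksum import rank_sum_test

BASE = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    wt = BASE / "run" / "wt"
    genes = load_annotation(wt / "or_annotation.tsv")
    out = BASE / "tables"
    out.mkdir(parents=True, exist_ok=True)
    densities, recs, edge_sets = {}, [], []
    frac1, frac45 = [], []
    for segment in ("dorsal", "ventral"):
        dens = []
        for path in sorted(glob.glob(str(wt / f"dipc_{segment}" / "*.3dg"))):
            loci = dipc.map_or_loci(zio.read_3dg(path), genes)
            d = dipc.pairwise_or_distances(loci)
            counts, graph = dipc.neighbors_within(loci, 2.5, d)
            agg = dipc.aggregate_stats(graph)
            dens.append(dipc.contact_density(loci, 2.5, d))
            edge_sets.append(graph.edge_set)
            recs.append({
                "segment": segment, "cell": Path(path).name,
                "contact_density": dens[-1],
                "max_aggregate_ors": int(agg["n_ors"].max()),
                "max_aggregate_chroms": int(agg["n_chromosomes"].max()),
            })
            if segment == "ventral":
                frac = dipc.zonal_trans_proximity_fraction(graph)
                frac1.append(frac.get("1", np.nan))
                frac45.append(np.nanmean([frac.get("4", np.nan), frac.get("5", np.nan)]))
        densities[segment] = dens
    pd.DataFrame(recs).to_csv(out / "dipc_cells.tsv", sep="\t", index=False)
    test = rank_sum_test(densities["ventral"], densities["dorsal"])
    print(f"trans contact density: ventral median {np.median(densities['ventral']):.4f} "
          f"vs dorsal {np.median(densities['dorsal']):.4f} (rank-sum p = {test.pvalue:.2e})")
    pf = rank_sum_test(np.array(frac1), np.array(frac45))
    print(f"ventral cells: zone1 trans-proximity {np.mean(frac1):.3f} vs "
          f"zone4-5 {np.mean(frac45):.3f} (rank-sum p = {pf.pvalue:.2e})")
    print(f"unique OR interaction maps: {len(set(edge_sets))}/{len(edge_sets)} cells")
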
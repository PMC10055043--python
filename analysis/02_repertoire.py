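"""Single-cell OR repertoires: QC, expressed-OR calling, zonal composition.

Reads the wt single-cell counts emitted by 01_simulate.py, applies QC scaled
to the synthetic gene panel, calls expressed ORs at the 3-UMI threshold, and
tabulates how many cells of each stage x segment express each zonal identity.
Finding: dorsal INPs express almost exclusively classI/zone-1 ORs while
ventral INPs co-express every identity, and ventral INPs express more ORs.
"""

from pathlib import Path

import numpy as np

from zonescape import io as zio
from zonescape import screp

BASE = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    adata = zio.read_counts_dir(BASE / "run" / "wt" / "sc_counts")
    kept, qc = screp.qc_filter_cells(adata, min_genes=50, min_umis=500)
    profiles = screp.call_expressed_ors(kept)
    tab = screp.repertoire_crosstab(profiles, kept.obs)
    out = BASE / "tables"
    out.mkdir(parents=True, exist_ok=True)
    screp.profiles_table(profiles).to_csv(out / "sc_profiles.tsv", sep="\t", index=False)
    tab.reset_index().to_csv(out / "sc_crosstab.tsv", sep="\t", index=False)

    zone = kept.obs["segment_zone"].to_numpy()
    stage = kept.obs["stage"].to_numpy()
    n_expr = np.array([p.n_expressed_ors for p in profiles])
    inp = stage == "INP"
    print(f"kept {qc.n_kept}/{qc.n_input} cells")
    print(f"mean expressed ORs, dorsal INPs:  {n_expr[inp & (zone == 1)].mean():.2f}")
    print(f"mean expressed ORs, ventral INPs: {n_expr[inp & (zone == 5)].mean():.2f}")
    dorsal_inp = [p for p, s, z in zip(profiles, stage, zone) if s == "INP" and z == 1]
    umis = {}
    for p in dorsal_inp:
        for z, u in p.zone_umis.items():
            umis[z] = umis.get(z, 0) + u
    share = (umis.get("classI", 0) + umis.get("1", 0)) / sum(umis.values())
    print(f"dorsal INP OR UMIs with classI/zone-1 identity: {100 * share:.1f}%")
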
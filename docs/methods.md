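# Methods

## The biological setting

Each mature olfactory sensory neuron (mOSN) of the mouse main olfactory
epithelium (MOE) expresses a single olfactory receptor (OR) allele out of a
repertoire of ~1,000+ genes arranged in genomic clusters.  The choice is
stochastic but spatially constrained: the MOE is segmented into ~5
dorsoventral bands ("zones", 1 = dorsal-most, 5 = ventral-most), and an OSN
in zone Z only ever chooses an OR whose native zone matches Z.  Class I
(fish-like) ORs are expressed in zone 1 but regulated separately and are
treated as their own identity class throughout; in particular they carry no
heterochromatin and make few long-range OR-OR contacts, so they are excluded
from trans-contact analyses.

`zonescape` packages the analyses that quantify how this patterning arises —
single-cell OR repertoires, heterochromatin gradients over OR gene bodies,
bulk Hi-C and single-cell Dip-C OR compartmentalization, spatial
transcriptomic zonal classification — together with a generative model of
the underlying "opposing rheostats" logic that emulates all six input data
kinds at desk scale, so every stage of the pipeline can be exercised and
tested end to end without external sequencing data.

## The generative model

A cell at dorsoventral coordinate u ∈ [0, 1] sits in segment zone
Z = 1 + ⌊5u⌋ (clipped to 5) and passes through four stages
(GBC → INP → iOSN → mOSN):

1. **Eligibility.**  A wild-type cell in zone Z may transcribe ORs with zone
   z ≤ Z — the "correct or more dorsal" rule — plus class I ORs iff Z = 1.
   In the NFI A/B/X triple knockout (`nfi_cko`), zones in `nfi_tx_zones`
   (default {4, 5}) drop out of the transcribable repertoire, giving an
   effective ceiling of min(Z, 3).
2. **Polygenic transcription (INP).**  Each eligible OR is transcribed
   independently with probability λ·ρ^(z−1)/W₅, where ρ (default 0.9) encodes
   stronger promoters for more dorsal identities, λ (default 10) is the
   expected co-transcribed count in a ventral cell, and W₅ is the total
   class II promoter weight.  Two properties follow by construction: the
   expected number of co-transcribed ORs grows from dorsal (~4.7) to ventral
   (~10) cells, matching the observed 5–15 ORs per progenitor; and each OR's
   transcription probability is identical in every segment where it is
   eligible, which is what makes the downstream silencing pattern cleanly
   monotone across segments.
3. **Silencing (INP → iOSN).**  Each transcribed OR is heterochromatically
   silenced with probability min(s₀ + β·(Z − z), cap): an own-zone baseline
   s₀ = 0.93 plus a dorsal-offset term β = 0.06 per zone, capped at 0.996.
   Ectopically transcribed dorsal ORs are therefore removed almost surely,
   while own-zone ORs are silenced at an intermediate frequency — enough
   that most co-transcribed own-zone ORs are also marked.  Class I ORs are
   never silenced, reflecting the absence of heterochromatin on class I OR
   bodies.  In the knockout the β term is zeroed for OR zones in
   `nfi_sil_zones` (default {2, 3, 4, 5}): the dorsal-offset silencing of
   zones 2–5 is NFI-dependent, which is what lets zone-2 ORs — the largest,
   strongest-promoter pool below the knockout's transcription ceiling —
   dominate ectopic choice ventrally.
4. **Singular choice (mOSN).**  One OR is drawn among the unsilenced
   transcribed ones with probability ∝ ρ^(z−1); if none survive, the whole
   cell is resampled (the feedback-driven retry).  Every emitted mOSN
   therefore expresses exactly one OR, usually of its own zone (own-zone
   choice share ≈ 95% in zone 2 down to ≈ 55–70% in zone 5).

The defaults were fixed by working the closed-form expectations of this
model (per-OR transcription probabilities, silencing frequencies, choice
shares) against the qualitative patterns the pipeline must recover —
dorsal-exclusive INP repertoires, the strictly decreasing heterochromatin
gradient, near-constant zone-1 trans contacts beside a strongly graded
zone-4/5 signal, ≥90% correct spatial zone assignment, and zone-2 dominance
in the knockout — and then frozen.  The parameters trade off against one
another: a larger s₀/cap gap steepens the per-segment ChIP gradient but
breaks the flatness of zone-1 Hi-C contacts, and a weaker β lets dorsal ORs
leak into ventral choice; s₀ = 0.93, β = 0.06, cap = 0.996 sit in the region
where all the patterns hold simultaneously with margin.

### Dissections

Micro-dissected segments are modelled as u-windows widened by
`dissection_overlap` (default 0.05) into the neighbouring segments — a
dorsal (zone 1), dorsomedial (zones 2–3) and ventral (zones 4–5) trisection
that is "mostly", not perfectly, zonal.  This impurity matters: the small
fraction of zone-4 cells captured by the dorsomedial dissection is what
gives zone-4/5 bins their above-background trans-contact signal there,
producing the ventral > dorsomedial > dorsal ordering as a dissection
property rather than a hand-placed effect.

### Emitters

All six input kinds derive from one simulated tissue; each emitter uses its
own seeded stream so artifacts can be produced independently and in any
order, and a fixed (params, seed) pair yields byte-identical outputs.

- **Single-cell counts** (MTX + metadata): transcribed ORs receive
  NB(μ_low = 5, θ = 2) UMIs in INP/iOSN cells, the chosen OR NB(μ_high = 500)
  in mOSNs; 200 housekeeping and 10 mitochondrial genes are added so QC
  filters are exercisable.  The synthetic gene panel is ~380 genes, so the
  full-transcriptome QC defaults (1,000 genes / 20,000 UMIs per cell) are
  scaled down to 50 genes / 500 UMIs in pipeline runs; the thresholds
  themselves are unchanged module defaults.
- **ChIP coverage** (bedGraph at 25-bp bins): per-OR enrichment is the
  fraction of the segment's iOSN/mOSN cells in which the OR is silenced;
  depth is Poisson(base + α·E) per bp over gene bodies and Poisson(base)
  elsewhere, with base = 1.0 and α = 10.  The background dominates the
  library, as genome-wide ChIP libraries do; this keeps the fixed-read-count
  normalization (10⁷ reads) from distorting cross-segment comparisons.
- **Hi-C contacts** (COO text + bin TSV at 50 kb): trans counts for OR-bin
  pairs are Poisson(c₀ + c₁·⟨MᵢMⱼ⟩), where Mᵢ counts silenced ORs in bin i
  per cell; other trans pairs are Poisson(c₀ = 75); cis pairs add a d⁻¹
  distance-decay whose mass (scale 24,000) dominates the library total, so
  counts-per-billion backgrounds are stable across segments.
- **Dip-C structures** (.3dg, 20-kb particles, coordinates in particle
  radii ≈ 60 nm): silenced OR particles join one of 3 compartment centers
  with N(0, 0.7²) jitter; all other particles are uniform in a nucleus of
  radius 50 (≈ 3 µm), both haplotypes placed independently.  Chromosomes
  have no polymer continuity — only OR-OR distance statistics are meant to
  be realistic.
- **Spatial spots** (spot TSV + MTX): a 50 × 20 grid whose rows map linearly
  to u; each spot aggregates 10 mOSN choice draws at its zone plus
  Poisson(0.05) ambient counts per OR.  The spot table carries the
  generator's ground-truth zone for accuracy evaluation (class I is merged
  into zone 1 for that evaluation only).

## Analysis conventions

- Coordinates are 0-based half-open; BED-compatible on disk.
- Continuous zone indices are discretised by rounding to the nearest
  integer; exact .5 ties round up (configurable), the class I flag dominates.
- OR clusters are single-linkage chains of same-chromosome ORs with gaps
  ≤ 300 kb (configurable); genome bins overlapping a cluster take the
  majority zone of their resident ORs, ties broken to the more dorsal label.
- Expressed-OR calling uses ≥ 3 UMIs; the same threshold defines "detected
  genes" in QC.  Cell QC discards a cell if it fails any of the three
  criteria (genes, UMIs, mitochondrial fraction) — the conjunctive reading
  of the filter.
- A cell's zonal identity is the zone of its most highly expressed OR; ties
  go to the more dorsal zone, then lexicographic gene id.
- Fold changes are log2 of CPM-normalized pseudobulks with a pseudocount of
  1 — a deliberately simple stand-in for negative-binomial differential
  expression machinery, kept closed-form so its invariances are testable.
- The rank-sum test enumerates all group assignments exactly whenever
  C(n+m, n) ≤ 20,000 (covers 9/9), with midrank ties; larger samples use the
  tie-corrected normal approximation.
- Hi-C analysis uses raw library-normalized (counts-per-billion) matrices;
  matrix balancing is out of scope.  Trans heatmap cells with no eligible
  bin pair are reported missing, never zero.
- ChIP gene-body density is base-pair coverage summed over the body and
  divided by its length (a coverage dialect of read-counting density);
  metagene rows rescale bodies to 6 kb by exact mean-within-bin resampling
  with 2-kb unscaled flanks, 50-bp bins (200 columns), minus-strand genes
  reversed.
- Dip-C "aggregates" are connected components of the r-neighborhood graph
  (r ∈ {2.5, 5, 10} particle radii ≈ 150/300/600 nm); haplotypes are
  distinct loci; ORs map to the particle containing their midpoint.
  Hierarchical heatmap ordering uses average linkage with deterministic
  optimal leaf ordering.
- Spot clustering is PCA (5 components) + k-means (k = 5) with a fixed
  seed, labels relabelled by mean array row — a stand-in for graph-based
  clustering in which only the cluster and component counts are meaningful.

## Problem sizes

The default study conditions are 170 ORs (20 class I; 40/40/30/25/15 for
zones 1–5) in 10 clusters on 5 chromosomes (~26 Mb), tissues of 2,000 cells,
48 + 48 Dip-C cells, and a 1,000-spot grid.  These sizes were chosen so every
gradient is resolved several standard errors above its Monte-Carlo noise
while a full wild-type + knockout pipeline runs in well under a minute.

## What passing tests do and do not show

The generator reproduces the *logical structure* of the biology — positional
eligibility, graded silencing, singular choice, and their knockout
perturbations — with the simplest monotone parameterizations, not fitted
rates.  Real data differ in ways the synthetic tissue does not model:
transcript-level noise beyond a negative binomial, doublets and ambient RNA
in single-cell data, mappability and fragment-length structure in ChIP,
balancing artefacts and TAD-scale structure in Hi-C, polymer continuity in
3D models, and histology-dependent spot geometry.  Tests passing on
synthetic data therefore validate the pipeline's correctness and its
sensitivity to the modelled effects, not parameter estimates on real
tissue.  Conversely, the brute-force oracle checks (clustering, bin
annotation, thresholding, heatmap averaging, distances, neighborhood
graphs, exact rank-sum) are data-independent correctness guarantees.

## Known limitations

- The knockout switch is binary; allele-dosage series (double/single
  knockouts) are not modelled.
- Silencing probabilities are linear in dorsal offset with a hard cap; the
  real dependence is unknown.
- mOSN resampling-on-empty conditions the emitted mOSN population slightly
  toward cells with surviving ORs; the effect on population silencing
  frequencies is ≲ 3% and is absorbed by test tolerances.
- Enhancer-hub assembly, locus-specific effects (e.g. tetO-driven induction)
  and read-level simulation are out of scope.
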
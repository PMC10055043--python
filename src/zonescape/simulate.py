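"""Generative "opposing rheostats" model of zonal OR regulation.

The model emulates how each olfactory sensory neuron (OSN) lineage cell,
sitting at dorsoventral position u in [0, 1] (segment zone Z = 1..5), arrives
at a single expressed OR:

1. *Eligibility* — position gates which OR identities can be transcribed at
   all: a wild-type cell in zone Z may transcribe ORs with zone z <= Z (the
   "correct or more dorsal" rule), plus class I ORs iff Z = 1.  In the NFI
   A/B/X knockout, zones in ``nfi_tx_zones`` drop out of the transcribable
   repertoire (effective ceiling min(Z, 3)).
2. *Polygenic transcription* — at the immediate-neuronal-precursor (INP)
   stage each eligible OR is transcribed independently with probability
   lam * rho**(z-1) / W5, where rho < 1 encodes stronger promoters for more
   dorsal identities and W5 is the total class II promoter weight.  The
   expected number of co-transcribed ORs therefore grows from dorsal to
   ventral cells, while each OR's transcription probability is the same in
   every segment where it is eligible.
3. *Silencing* — at the INP -> iOSN transition each transcribed OR is
   heterochromatically silenced with probability min(s0 + beta*(Z - z), cap):
   a baseline own-zone rate plus a dorsal-offset term, so ectopically
   transcribed dorsal ORs are removed with the highest frequency.  Class I
   ORs are never silenced (heterochromatin is absent from class I ORs).  In
   the knockout the dorsal-offset term is removed for OR zones in
   ``nfi_sil_zones``.
4. *Singular choice* — a mature OSN (mOSN) picks one OR among the unsilenced
   transcribed ones with probability proportional to the promoter weight
   rho**(z-1); if none survive, the whole cell is resampled (the feedback-
   driven retry).

Everything downstream (single-cell counts, ChIP coverage, Hi-C contacts,
Dip-C structures, spatial spots) is emitted from one simulated tissue, fully
deterministic under (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import attach_zone_labels

STAGES = ("GBC", "INP", "iOSN", "mOSN")
STAGE_ORDER = {s: i for i, s in enumerate(STAGES)}

WT = "wt"
NFI_CKO = "nfi_cko"


@dataclass(frozen=True)
class SimParams:
    """All knobs of the generative model (defaults are the study conditions)."""

    seed: int = 0
    genotype: str = WT

    # OR repertoire per identity class
    n_or_per_zone: dict = field(
        default_factory=lambda: {"classI": 20, "1": 40, "2": 40, "3": 30, "4": 25, "5": 15}
    )

    # genome layout: clusters of ORs spread over a toy genome
    n_chrom: int = 5
    clusters_per_chrom: int = 2
    spacing_mean: int = 60_000  # mean gap between consecutive OR starts in a cluster
    spacing_jitter: int = 20_000  # gaps drawn uniform in mean +/- jitter
    gene_length: int = 3_000
    intercluster_gap: int = 2_000_000
    chrom_margin: int = 500_000

    # polygenic transcription / promoter weights
    promoter_decay: float = 0.9  # rho
    polygenic_mean: float = 10.0  # lam: expected co-transcribed ORs in a ventral INP

    # silencing rheostat
    silence_same: float = 0.93  # s0
    silence_slope: float = 0.06  # beta, per zone of dorsal offset
    silence_cap: float = 0.996

    # NFI knockout switches
    nfi_tx_zones: tuple = (4, 5)
    nfi_sil_zones: tuple = (2, 3, 4, 5)

    # expression model
    mu_low: float = 5.0  # UMIs for a polygenically transcribed OR
    mu_high: float = 500.0  # UMIs for the chosen OR in a mOSN
    nb_theta: float = 2.0  # negative-binomial dispersion (size)
    n_housekeeping: int = 200
    n_mito: int = 10
    mu_housekeeping: float = 60.0

    # ChIP emission
    chip_base: float = 1.0  # background depth per bp
    chip_alpha: float = 10.0  # enrichment per unit silencing frequency
    chip_depth: float = 1.0  # sequencing-depth multiplier
    chip_bin_size: int = 25  # coverage emitted at this resolution (bp)

    # dissection model: micro-dissected segments are "mostly" their zones;
    # windows in u overlap neighbours by this much on each side
    dissection_overlap: float = 0.05

    # Hi-C emission
    hic_resolution: int = 50_000
    hic_c0: float = 75.0  # background trans contacts per bin pair
    hic_c1: float = 60_000.0  # compartment signal scale
    hic_q: float = 1.0  # silencing->contact coupling
    hic_cis_decay: float = 1.0  # cis distance-decay exponent
    hic_cis_scale: float = 24_000.0  # cis contacts at one-bin separation
    hic_depth: float = 1.0

    # Dip-C emission
    dipc_resolution: int = 20_000  # particle size in bp
    dipc_n_centers: int = 3
    dipc_sigma: float = 0.7  # compartment jitter, particle radii (~60 nm each)
    dipc_radius: float = 50.0  # nucleus radius, particle radii

    # spatial emission
    spatial_rows: int = 50
    spatial_cols: int = 20
    cells_per_spot: int = 10
    ambient_rate: float = 0.05

    # tissue composition
    stage_fractions: dict = field(
        default_factory=lambda: {"GBC": 0.1, "INP": 0.3, "iOSN": 0.3, "mOSN": 0.3}
    )

    def with_genotype(self, genotype: str) -> "SimParams":
        if genotype not in (WT, NFI_CKO):
            raise ValueError(f"unknown genotype {genotype!r}")
        return replace(self, genotype=genotype)


def _zone_int(zone: str) -> int:
    """Numeric zone for weight/silencing purposes; classI behaves as zone 1."""
    return 1 if zone == "classI" else int(zone)


def make_or_annotation(params: SimParams, rng: np.random.Generator) -> pd.DataFrame:
    """Lay out the OR repertoire in genomic clusters on a toy genome.

    Zone identities are shuffled across cluster slots so clusters have mixed
    zonal constitution, as real OR clusters do.
    """
    zones: list[str] = []
    for zone, n in params.n_or_per_zone.items():
        zones.extend([zone] * n)
    zones = np.array(zones)
    rng.shuffle(zones)

    n_total = len(zones)
    n_clusters = params.n_chrom * params.clusters_per_chrom
    sizes = np.full(n_clusters, n_total // n_clusters)
    sizes[: n_total % n_clusters] += 1

    records = []
    gi = 0
    ci = 0
    for chrom_i in range(params.n_chrom):
        chrom = f"chr{chrom_i + 1}"
        pos = params.chrom_margin
        for _ in range(params.clusters_per_chrom):
            for _ in range(sizes[ci]):
                start = pos
                end = start + params.gene_length
                strand = "+" if rng.random() < 0.5 else "-"
                zone = zones[gi]
                if zone == "classI":
                    zone_index, class_i = 1.0, 1
                else:
                    z = int(zone)
                    zone_index = float(
                        np.clip(z + rng.uniform(-0.35, 0.35), 0.51, 5.49)
                    )
                    class_i = 0
                records.append(
                    (f"Olfr{gi:04d}", chrom, start, end, strand, zone_index, class_i)
                )
                gap = rng.integers(
                    params.spacing_mean - params.spacing_jitter,
                    params.spacing_mean + params.spacing_jitter + 1,
                )
                pos = start + int(gap)
                gi += 1
            pos += params.intercluster_gap
            ci += 1
    genes = pd.DataFrame(
        records,
        columns=["gene_id", "chrom", "start", "end", "strand", "zone_index", "class_I"],
    )
    return attach_zone_labels(genes)


def chrom_sizes(params: SimParams, genes: pd.DataFrame) -> dict[str, int]:
    sizes = {}
    for chrom, sub in genes.groupby("chrom"):
        sizes[chrom] = int(sub["end"].max() + params.chrom_margin)
    return sizes


def segment_zone(u: float) -> int:
    """Map a dorsoventral coordinate u in [0, 1] to its segment zone 1..5."""
    return int(min(5, 1 + np.floor(5.0 * u)))


def eligibility(genes: pd.DataFrame, Z: int, genotype: str,
                nfi_tx_zones=(4, 5)) -> np.ndarray:
    """Boolean mask over ``genes`` of identities transcribable in zone Z.

    Wild type: zone z <= Z, plus class I iff Z == 1.  Knockout: zones in
    ``nfi_tx_zones`` additionally removed (NFI-dependent ventral branch).
    """
    if not 1 <= Z <= 5:
        raise ValueError(f"segment zone must be in 1..5, got {Z}")
    zone = genes["zone"].to_numpy()
    is_classI = zone == "classI"
    known = zone != "unknown"
    znum = np.array([_zone_int(z) if z not in ("unknown",) else 99 for z in zone])
    mask = known & ~is_classI & (znum <= Z)
    if Z == 1:
        mask = mask | is_classI
    if genotype == NFI_CKO:
        mask = mask & ~np.isin(znum, list(nfi_tx_zones)) | (is_classI & (Z == 1))
    if not mask.any():
        raise ValueError(f"empty eligibility for zone {Z}, genotype {genotype}")
    return mask


class ModelTables:
    """Per-gene probability tables shared by all cells of one annotation."""

    def __init__(self, params: SimParams, genes: pd.DataFrame):
        self.params = params
        self.genes = genes.reset_index(drop=True)
        zone = self.genes["zone"].to_numpy()
        self.is_classI = zone == "classI"
        self.znum = np.array([_zone_int(z) if z != "unknown" else 99 for z in zone])
        rho = params.promoter_decay
        self.weight = np.where(
            zone == "unknown", 0.0, rho ** (np.minimum(self.znum, 5) - 1)
        )
        # total class II promoter weight of the full (ventral-most) repertoire
        classII = ~self.is_classI & (zone != "unknown")
        self.w5 = float(self.weight[classII].sum())
        self.p_transcribe = np.clip(params.polygenic_mean * self.weight / self.w5, 0, 1)
        self._elig_cache: dict[tuple[int, str], np.ndarray] = {}

    def eligible(self, Z: int, genotype: str) -> np.ndarray:
        key = (Z, genotype)
        if key not in self._elig_cache:
            self._elig_cache[key] = eligibility(
                self.genes, Z, genotype, self.params.nfi_tx_zones
            )
        return self._elig_cache[key]

    def silence_prob(self, Z: int, genotype: str) -> np.ndarray:
        """Per-gene silencing probability for transcribed ORs in a zone-Z cell."""
        p = self.params
        offset = np.maximum(Z - np.minimum(self.znum, 5), 0)
        if genotype == NFI_CKO:
            offset = np.where(np.isin(self.znum, list(p.nfi_sil_zones)), 0, offset)
        prob = np.minimum(p.silence_same + p.silence_slope * offset, p.silence_cap)
        prob = np.where(self.is_classI, 0.0, prob)  # class I is never silenced
        return prob


@dataclass
class SimCell:
    cell_id: str
    u: float
    segment_zone: int
    stage: str
    transcribed: np.ndarray  # boolean mask over genes
    silenced: np.ndarray  # boolean mask over genes (subset of transcribed)
    chosen_or: int | None  # gene index, mOSN only


def simulate_cell(
    tables: ModelTables,
    u: float,
    stage: str,
    rng: np.random.Generator,
    *,
    cell_id: str = "cell",
    max_resample: int = 1000,
) -> SimCell:
    """Draw one cell through the eligibility -> transcription -> silencing ->
    choice cascade.  mOSNs are resampled until at least one transcribed OR
    survives silencing, so every mOSN expresses exactly one OR."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    p = tables.params
    Z = segment_zone(u)
    n = len(tables.genes)
    if stage == "GBC":
        empty = np.zeros(n, dtype=bool)
        return SimCell(cell_id, u, Z, stage, empty, empty.copy(), None)

    elig = tables.eligible(Z, p.genotype)
    sil_p = tables.silence_prob(Z, p.genotype)
    for _ in range(max_resample):
        transcribed = elig & (rng.random(n) < tables.p_transcribe)
        if stage == "INP":
            return SimCell(cell_id, u, Z, stage, transcribed,
                           np.zeros(n, dtype=bool), None)
        silenced = transcribed & (rng.random(n) < sil_p)
        if stage == "iOSN":
            return SimCell(cell_id, u, Z, stage, transcribed, silenced, None)
        survivors = np.flatnonzero(transcribed & ~silenced)
        if len(survivors) == 0:
            continue  # feedback-driven retry: resample the whole cell
        w = tables.weight[survivors]
        chosen = int(rng.choice(survivors, p=w / w.sum()))
        return SimCell(cell_id, u, Z, stage, transcribed, silenced, chosen)
    raise RuntimeError(f"mOSN at u={u:.3f} failed to choose an OR after {max_resample} tries")


@dataclass
class SimTissue:
    params: SimParams
    genes: pd.DataFrame
    tables: ModelTables
    cells: list[SimCell]

    def cells_at(self, stage: str | None = None, zone: int | None = None) -> list[SimCell]:
        out = self.cells
        if stage is not None:
            out = [c for c in out if c.stage == stage]
        if zone is not None:
            out = [c for c in out if c.segment_zone == zone]
        return out

    def silencing_frequency(self, stages=("iOSN", "mOSN"), zone: int | None = None) -> np.ndarray:
        """Per-gene fraction of (selected) cells in which the gene is silenced."""
        cells = [c for c in self.cells if c.stage in stages]
        if zone is not None:
            cells = [c for c in cells if c.segment_zone == zone]
        if not cells:
            return np.zeros(len(self.genes))
        return np.mean([c.silenced for c in cells], axis=0)

    def choice_frequency(self, zone: int | None = None) -> np.ndarray:
        """Per-gene fraction of mOSN choices; sums to 1 over genes."""
        cells = self.cells_at("mOSN", zone)
        freq = np.zeros(len(self.genes))
        for c in cells:
            freq[c.chosen_or] += 1
        if cells:
            freq /= len(cells)
        return freq


def simulate_tissue(
    params: SimParams,
    n_cells: int = 2000,
    *,
    genes: pd.DataFrame | None = None,
    stages: dict | None = None,
    u_range: tuple[float, float] = (0.0, 1.0),
    rng: np.random.Generator | None = None,
) -> SimTissue:
    """Simulate a tissue of ``n_cells`` cells spanning ``u_range``.

    Stage labels are drawn from ``params.stage_fractions`` (or an override);
    dorsoventral positions are uniform over ``u_range``.  Deterministic under
    (params, seed).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if genes is None:
        genes = make_or_annotation(params, rng)
    tables = ModelTables(params, genes)
    fractions = stages or params.stage_fractions
    names = list(fractions)
    probs = np.array([fractions[s] for s in names], dtype=float)
    probs /= probs.sum()
    stage_draw = rng.choice(names, size=n_cells, p=probs)
    us = rng.uniform(u_range[0], u_range[1], size=n_cells)
    cells = [
        simulate_cell(tables, float(us[i]), str(stage_draw[i]), rng,
                      cell_id=f"cell_{i:05d}")
        for i in range(n_cells)
    ]
    return SimTissue(params, tables.genes, tables, cells)
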
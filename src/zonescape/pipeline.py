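"""End-to-end orchestration: simulate -> analyses -> report bundle.

A run is fully described by a :class:`RunConfig` (serializable to YAML) and a
seed; running the same config twice produces byte-identical numeric outputs.
Every stage writes TSV artifacts under the output directory and records them
in a manifest with SHA-256 checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time

import numpy as np
import pandas as pd
import yaml

from . import chip as chipmod
from . import dipc as dipcmod
from . import emitters
from . import hic as hicmod
from . import io as zio
from . import screp as screpmod
from . import simulate as sim
from . import spatial as spatialmod
from .annotation import build_clusters, annotate_bins, clusters_to_bed, bins_to_bed, write_annotation

log = logging.getLogger("zonescape")

STAGES = ("simulate", "annotate", "screp", "chip", "hic", "dipc", "spatial")


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "zonescape_run"
    genotypes: tuple = ("wt", "nfi_cko")
    stages: tuple = STAGES
    n_cells: int = 2000
    cluster_gap: int = 300_000
    bin_resolution: int = 50_000
    umi_threshold: int = 3
    qc_min_genes: int = 50  # synthetic gene panel is small; see docs/methods.md
    qc_min_umis: int = 500
    qc_max_mito_frac: float = 0.05
    dipc_cells_per_segment: int = 24
    dipc_radius: float = 2.5
    spatial_top_n: int = 20
    spatial_k: int = 5
    spatial_n_pcs: int = 5
    sim_overrides: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("genotypes", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["genotypes"] = list(self.genotypes)
        data["stages"] = list(self.stages)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def sim_params(self, genotype: str) -> sim.SimParams:
        return sim.SimParams(seed=self.seed, genotype=genotype, **self.sim_overrides)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    def __init__(self, outdir):
        self.outdir = outdir
        self.entries: dict[str, str] = {}
        self.timings: dict[str, float] = {}

    def add(self, path):
        rel = os.path.relpath(path, self.outdir)
        self.entries[rel] = _sha256(path)

    def write(self, extra: dict | None = None):
        payload = {"files": dict(sorted(self.entries.items())),
                   "timings_s": {k: round(v, 3) for k, v in self.timings.items()}}
        if extra:
            payload.update(extra)
        with open(os.path.join(self.outdir, "manifest.json"), "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def validate_inputs(config: RunConfig) -> list[str]:
    """Schema/cross-check diagnostics for a config; empty list means clean."""
    diags = []
    if config.seed < 0:
        diags.append("seed must be non-negative")
    bad = [s for s in config.stages if s not in STAGES]
    if bad:
        diags.append(f"unknown stages: {bad}")
    bad = [g for g in config.genotypes if g not in (sim.WT, sim.NFI_CKO)]
    if bad:
        diags.append(f"unknown genotypes: {bad}")
    if config.bin_resolution <= 0:
        diags.append("bin_resolution must be positive")
    try:
        params = config.sim_params(config.genotypes[0] if config.genotypes else sim.WT)
    except TypeError as exc:
        diags.append(f"invalid sim_overrides: {exc}")
        return diags
    if not 0 < params.promoter_decay <= 1:
        diags.append("promoter_decay must be in (0, 1]")
    for name in ("silence_same", "silence_slope", "silence_cap"):
        if not 0 <= getattr(params, name) <= 1:
            diags.append(f"{name} must be in [0, 1]")
    return diags


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages for every genotype; returns a report dict
    (also written as report.json)."""
    diags = validate_inputs(config)
    if diags:
        raise ValueError("invalid config: " + "; ".join(diags))
    os.makedirs(config.outdir, exist_ok=True)
    manifest = Manifest(config.outdir)
    config.to_yaml(os.path.join(config.outdir, "config.yaml"))
    manifest.add(os.path.join(config.outdir, "config.yaml"))
    report: dict = {"seed": config.seed, "genotypes": list(config.genotypes)}

    tissues = {}
    for genotype in config.genotypes:
        params = config.sim_params(genotype)
        t0 = time.perf_counter()
        tissues[genotype] = sim.simulate_tissue(params, n_cells=config.n_cells)
        manifest.timings[f"simulate[{genotype}]"] = time.perf_counter() - t0
        log.info("simulated %s tissue: %d cells", genotype, config.n_cells)

    for genotype, tissue in tissues.items():
        gdir = os.path.join(config.outdir, genotype)
        os.makedirs(gdir, exist_ok=True)
        try:
            report[genotype] = _run_genotype(config, tissue, gdir, manifest)
        except Exception:
            manifest.write({"status": "failed", "failed_genotype": genotype})
            raise

    if set(config.genotypes) >= {sim.WT, sim.NFI_CKO} and "screp" in config.stages:
        report["cko_shift"] = _cko_shift(config, tissues, manifest)

    with open(os.path.join(config.outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    manifest.add(os.path.join(config.outdir, "report.json"))
    manifest.write({"status": "ok"})
    return report


def _write_tsv(df: pd.DataFrame, path, manifest, index=False):
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")
    manifest.add(path)


def _run_genotype(config: RunConfig, tissue, gdir, manifest) -> dict:
    out: dict = {}
    genes = tissue.genes

    if "annotate" in config.stages:
        t0 = time.perf_counter()
        write_annotation(genes, os.path.join(gdir, "or_annotation.tsv"))
        manifest.add(os.path.join(gdir, "or_annotation.tsv"))
        clusters = build_clusters(genes, config.cluster_gap)
        _write_tsv(clusters_to_bed(clusters), os.path.join(gdir, "clusters.bed"), manifest)
        bins = annotate_bins(clusters, genes, config.bin_resolution)
        _write_tsv(bins_to_bed(bins), os.path.join(gdir, "or_bins.bed"), manifest)
        out["annotate"] = {"n_clusters": len(clusters), "n_or_bins": len(bins)}
        manifest.timings[f"annotate[{gdir}]"] = time.perf_counter() - t0

    if "screp" in config.stages:
        t0 = time.perf_counter()
        adata = emitters.emit_sc_counts(tissue)
        zio.write_counts_dir(adata, os.path.join(gdir, "sc_counts"))
        for f in ("matrix.mtx", "barcodes.tsv", "features.tsv", "cell_metadata.tsv"):
            manifest.add(os.path.join(gdir, "sc_counts", f))
        filtered, qc = screpmod.qc_filter_cells(
            adata, config.qc_min_genes, config.qc_min_umis, config.qc_max_mito_frac
        )
        profiles = screpmod.call_expressed_ors(filtered, config.umi_threshold)
        _write_tsv(screpmod.profiles_table(profiles),
                   os.path.join(gdir, "repertoire_profiles.tsv"), manifest)
        crosstab = screpmod.repertoire_crosstab(profiles, filtered.obs)
        _write_tsv(crosstab.reset_index(), os.path.join(gdir, "repertoire_crosstab.tsv"),
                   manifest)
        out["screp"] = {"qc": dataclasses.asdict(qc)}
        manifest.timings[f"screp[{gdir}]"] = time.perf_counter() - t0

    if "chip" in config.stages:
        t0 = time.perf_counter()
        summaries = {}
        for segment in ("whole", "dorsal", "dorsomedial", "ventral"):
            track = chipmod.normalize_library(emitters.emit_chip(tissue, segment))
            zio.write_bedgraph(track.depth, track.bin_size,
                               os.path.join(gdir, f"chip_{segment}.bedgraph"))
            manifest.add(os.path.join(gdir, f"chip_{segment}.bedgraph"))
            dens = chipmod.density_table(track, genes)
            _write_tsv(dens, os.path.join(gdir, f"chip_density_{segment}.tsv"), manifest)
            summary = chipmod.zone_group_summary(dens)
            summaries[segment] = {
                "monotone_decreasing": bool(summary.monotone_decreasing),
                "medians": summary.stats.set_index("zone")["median"].to_dict(),
            }
        out["chip"] = summaries
        manifest.timings[f"chip[{gdir}]"] = time.perf_counter() - t0

    if "hic" in config.stages:
        t0 = time.perf_counter()
        heat = {}
        for segment in ("dorsal", "dorsomedial", "ventral"):
            cm = emitters.emit_hic(tissue, segment, config.bin_resolution)
            zio.write_contacts(cm.counts, cm.bins,
                               os.path.join(gdir, f"hic_{segment}.coo"),
                               os.path.join(gdir, f"hic_{segment}.bins.tsv"))
            manifest.add(os.path.join(gdir, f"hic_{segment}.coo"))
            manifest.add(os.path.join(gdir, f"hic_{segment}.bins.tsv"))
            summary = hicmod.trans_zone_heatmap(cm, grouped=True)
            _write_tsv(summary.mean.reset_index(),
                       os.path.join(gdir, f"hic_heatmap_{segment}.tsv"), manifest)
            heat[segment] = summary.mean.to_dict()
        out["hic"] = heat
        manifest.timings[f"hic[{gdir}]"] = time.perf_counter() - t0

    if "dipc" in config.stages:
        t0 = time.perf_counter()
        densities = {}
        for segment in ("dorsal", "ventral"):
            structures = emitters.emit_3dg(tissue, segment, config.dipc_cells_per_segment)
            seg_dir = os.path.join(gdir, f"dipc_{segment}")
            os.makedirs(seg_dir, exist_ok=True)
            dens = []
            for i, st in enumerate(structures):
                path = os.path.join(seg_dir, f"cell_{i:03d}.3dg")
                zio.write_3dg(st, path)
                manifest.add(path)
                loci = dipcmod.map_or_loci(st, genes)
                dens.append(dipcmod.contact_density(loci, config.dipc_radius))
            densities[segment] = dens
        test = screpmod.rank_sum_test(densities["ventral"], densities["dorsal"])
        _write_tsv(
            pd.DataFrame({
                "segment": ["dorsal"] * len(densities["dorsal"]) + ["ventral"] * len(densities["ventral"]),
                "contact_density": densities["dorsal"] + densities["ventral"],
            }),
            os.path.join(gdir, "dipc_contact_density.tsv"), manifest,
        )
        out["dipc"] = {
            "ventral_vs_dorsal_p": test.pvalue,
            "median_density": {k: float(np.median(v)) for k, v in densities.items()},
        }
        manifest.timings[f"dipc[{gdir}]"] = time.perf_counter() - t0

    if "spatial" in config.stages:
        t0 = time.perf_counter()
        spots, adata = emitters.emit_spatial(tissue)
        zio.write_spots(spots, os.path.join(gdir, "spots.tsv"))
        manifest.add(os.path.join(gdir, "spots.tsv"))
        zio.write_counts_dir(adata, os.path.join(gdir, "spatial_counts"))
        for f in ("matrix.mtx", "barcodes.tsv", "features.tsv", "cell_metadata.tsv"):
            manifest.add(os.path.join(gdir, "spatial_counts", f))
        kept = spatialmod.filter_spots(adata)
        norm = spatialmod.normalize_spots(kept)
        table = spatialmod.assign_spot_zone(norm)
        merged = spatialmod.assign_spot_zone(norm, merge_classI=True)
        result = pd.DataFrame({
            "assigned_zone": table.assigned_zone,
            "truth_zone": kept.obs["truth_zone"].astype(str),
        })
        _write_tsv(result.reset_index(), os.path.join(gdir, "spot_zones.tsv"), manifest)
        acc = float(
            (merged.assigned_zone.to_numpy() == kept.obs["truth_zone"].astype(str).to_numpy()).mean()
        )
        clusters = spatialmod.cluster_spots(
            norm, config.spatial_k, config.spatial_n_pcs, config.seed, kept.obs["row"]
        )
        _write_tsv(clusters.reset_index(), os.path.join(gdir, "spot_clusters.tsv"), manifest)
        out["spatial"] = {"n_spots_kept": int(kept.n_obs), "zone_accuracy": acc}
        manifest.timings[f"spatial[{gdir}]"] = time.perf_counter() - t0

    return out


def _cko_shift(config: RunConfig, tissues, manifest) -> dict:
    """Knockout-vs-control zonal fold-change table over mOSN pseudobulk."""
    bulks = {}
    genes = None
    for g, tissue in tissues.items():
        adata = emitters.emit_sc_counts(tissue)
        mask = (adata.obs["stage"] == "mOSN").to_numpy()
        or_mask = adata.var["is_OR"].to_numpy()
        X = np.asarray(adata.X)[mask][:, or_mask]
        bulks[g] = X.sum(axis=0)
        genes = adata.var[or_mask]
    fc = screpmod.zonal_fold_change(bulks[sim.NFI_CKO], bulks[sim.WT],
                                    genes["zone"].to_numpy())
    fc.insert(0, "gene_id", genes.index.to_numpy())
    path = os.path.join(config.outdir, "cko_zonal_fold_change.tsv")
    _write_tsv(fc, path, manifest)
    tests = {}
    for za, zb in (("2", "5"), ("2", "4"), ("1", "5")):
        if {za, zb} <= set(fc["zone"]):
            res = screpmod.zone_shift_test(fc, za, zb)
            tests[f"zone{za}_vs_zone{zb}"] = {"U": res.statistic, "p": res.pvalue}
    medians = fc.groupby("zone")["log2fc"].median().to_dict()
    return {"median_log2fc_by_zone": medians, "rank_sum": tests}
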
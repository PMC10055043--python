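"""3D structure parsing, distances, proximity graphs, aggregates."""

import numpy as np
import pandas as pd
import pytest

from zonescape import dipc
from zonescape import emitters
from zonescape import io as zio
from zonescape.annotation import attach_zone_labels
from oracles import (
    pairwise_distances_bruteforce,
    neighbor_counts_bruteforce,
    components_bruteforce,
)


def _loci_from_points(xyz, chroms, zones=None):
    n = len(xyz)
    table = pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(n)],
        "zone": zones if zones is not None else ["1"] * n,
        "chrom": chroms,
        "haplotype": ["a"] * n,
        "particle": np.arange(n),
        "x": [p[0] for p in xyz],
        "y": [p[1] for p in xyz],
        "z": [p[2] for p in xyz],
    })
    return dipc.ORLoci(table, [])


class TestRead3dg:
    def test_roundtrip(self, tmp_path):
        df = pd.DataFrame({
            "chrom": ["chr1(a)", "chr1(b)", "chr2(a)"],
            "pos": [0, 0, 20_000],
            "x": [0.1, -1.5, 2.0], "y": [0.0, 3.25, -2.0], "z": [1.0, 0.5, 0.0],
        })
        path = tmp_path / "cell.3dg"
        zio.write_3dg(df, path)
        back = zio.read_3dg(path)
        assert np.allclose(back[["x", "y", "z"]], df[["x", "y", "z"]])
        assert list(back["chrom"]) == list(df["chrom"])

    def test_malformed_line_reports_lineno(self, tmp_path):
        path = tmp_path / "bad.3dg"
        path.write_text("chr1(a)\t0\t1.0\t2.0\t3.0\nchr1(a)\t20000\t1.0\tx\t3.0\n")
        with pytest.raises(zio.FormatError, match=":2"):
            zio.read_3dg(path)

    def test_duplicate_particle_rejected(self, tmp_path):
        path = tmp_path / "dup.3dg"
        path.write_text("chr1(a)\t0\t1\t2\t3\nchr1(a)\t0\t4\t5\t6\n")
        with pytest.raises(zio.FormatError, match="duplicate"):
            zio.read_3dg(path)

    def test_particle_count_conserved(self, tissue, tmp_path):
        st = emitters.emit_3dg(tissue, "dorsal", n_cells=1)[0]
        path = tmp_path / "cell.3dg"
        zio.write_3dg(st, path)
        assert len(zio.read_3dg(path)) == len(st)


class TestMapORLoci:
    def _structure(self):
        rows = []
        for hap in ("a", "b"):
            for pos in (0, 20_000, 40_000):
                rows.append((f"chr1({hap})", pos, float(pos) / 1e4, 0.0, 0.0))
        return pd.DataFrame(rows, columns=["chrom", "pos", "x", "y", "z"])

    def _genes(self, rows):
        return attach_zone_labels(pd.DataFrame(
            rows, columns=["gene_id", "chrom", "start", "end", "strand",
                           "zone_index", "class_I"]
        ))

    def test_midpoint_at_bin_start(self):
        genes = self._genes([("g", "chr1", 20_000, 20_002, "+", 1.0, 0)])
        loci = dipc.map_or_loci(self._structure(), genes, resolution=20_000)
        assert set(loci.table["haplotype"]) == {"a", "b"}
        assert (loci.table["particle"].isin([1, 4])).all()

    def test_missing_chromosome_reported(self):
        genes = self._genes([("g", "chrX", 0, 100, "+", 1.0, 0)])
        loci = dipc.map_or_loci(self._structure(), genes, resolution=20_000)
        assert loci.unmapped == ["g"] and len(loci) == 0

    def test_matches_interval_oracle(self, tissue):
        st = emitters.emit_3dg(tissue, "dorsal", n_cells=1)[0]
        loci = dipc.map_or_loci(st, tissue.genes)
        res = tissue.params.dipc_resolution
        # every OR maps per haplotype to the particle containing its midpoint
        assert len(loci) == 2 * len(tissue.genes)
        for row in loci.table.sample(30, random_state=0).itertuples(index=False):
            g = tissue.genes.set_index("gene_id").loc[row.gene_id]
            mid = (g.start + g.end) // 2
            particle = st.iloc[row.particle]
            assert particle["pos"] == (mid // res) * res
            assert particle["chrom"] == f"{g.chrom}({row.haplotype})"


class TestDistancesAndNeighbors:
    def test_three_four_five(self):
        loci = _loci_from_points([(0, 0, 0), (3, 4, 0)], ["chr1", "chr2"])
        d = dipc.pairwise_or_distances(loci)
        assert d[0, 1] == pytest.approx(5.0) and d[1, 0] == pytest.approx(5.0)
        assert d[0, 0] == 0.0

    def test_permutation_invariance(self, rng):
        pts = rng.normal(size=(20, 3))
        loci = _loci_from_points(pts, ["chr1"] * 20)
        d = dipc.pairwise_or_distances(loci)
        perm = rng.permutation(20)
        loci_p = _loci_from_points(pts[perm], ["chr1"] * 20)
        dp = dipc.pairwise_or_distances(loci_p)
        assert np.allclose(dp, d[np.ix_(perm, perm)])

    def test_matches_bruteforce(self, rng):
        pts = rng.normal(size=(60, 3)) * 5
        loci = _loci_from_points(pts, [f"chr{i % 4}" for i in range(60)])
        d = dipc.pairwise_or_distances(loci)
        assert np.allclose(d, pairwise_distances_bruteforce(pts))

    def test_isolated_points_no_neighbors(self):
        pts = [(0, 0, 0), (100, 0, 0), (0, 100, 0)]
        loci = _loci_from_points(pts, ["chr1"] * 3)
        counts, graph = dipc.neighbors_within(loci, 2.5)
        assert (counts == 0).all() and len(graph.edge_set) == 0

    def test_colinear_counts_by_hand(self):
        # points at x = 0..5 spacing 1; r=2.5 -> neighbors within 2 steps
        pts = [(float(i), 0, 0) for i in range(6)]
        loci = _loci_from_points(pts, ["chr1"] * 6)
        counts, _ = dipc.neighbors_within(loci, 2.5)
        assert list(counts) == [2, 3, 4, 4, 3, 2]

    def test_neighbor_counts_match_bruteforce(self, rng):
        pts = rng.normal(size=(80, 3)) * 2
        loci = _loci_from_points(pts, [f"chr{i % 5}" for i in range(80)])
        counts, _ = dipc.neighbors_within(loci, 1.5)
        assert (counts == neighbor_counts_bruteforce(pts, 1.5)).all()

    def test_monotone_in_radius(self, rng):
        pts = rng.normal(size=(50, 3)) * 3
        loci = _loci_from_points(pts, ["chr1"] * 50)
        prev_counts = None
        prev_sizes = None
        for r in dipc.PROXIMITY_RADII:
            counts, graph = dipc.neighbors_within(loci, r)
            sizes = dipc.aggregate_stats(graph)["n_ors"]
            if prev_counts is not None:
                assert (counts >= prev_counts).all()
                assert sizes.max() >= prev_sizes.max()
                assert len(sizes) <= len(prev_sizes)  # aggregates only merge
            prev_counts, prev_sizes = counts, sizes


class TestAggregates:
    def test_empty_graph_all_singletons(self):
        pts = [(0, 0, 0), (50, 0, 0)]
        loci = _loci_from_points(pts, ["chr1", "chr2"])
        _, graph = dipc.neighbors_within(loci, 1.0)
        agg = dipc.aggregate_stats(graph)
        assert list(agg["n_ors"]) == [1, 1]

    def test_single_clique(self, rng):
        pts = rng.normal(size=(10, 3)) * 0.1
        loci = _loci_from_points(pts, [f"chr{i % 3}" for i in range(10)])
        _, graph = dipc.neighbors_within(loci, 2.5)
        agg = dipc.aggregate_stats(graph)
        assert len(agg) == 1 and agg["n_ors"].iloc[0] == 10
        assert agg["n_chromosomes"].iloc[0] == 3

    def test_component_sizes_match_union_find(self, rng):
        pts = rng.normal(size=(70, 3)) * 1.5
        loci = _loci_from_points(pts, ["chr1"] * 70)
        _, graph = dipc.neighbors_within(loci, 1.0)
        agg = dipc.aggregate_stats(graph)
        assert sorted(agg["n_ors"]) == components_bruteforce(graph.adjacency)


class TestZonalProximity:
    def test_all_isolated_zero(self):
        pts = [(0, 0, 0), (50, 0, 0), (100, 0, 0)]
        loci = _loci_from_points(pts, ["chr1", "chr2", "chr3"], ["1", "4", "5"])
        _, graph = dipc.neighbors_within(loci, 2.5)
        frac = dipc.zonal_trans_proximity_fraction(graph)
        assert (frac == 0).all()

    def test_one_trans_pair_both_positive(self):
        pts = [(0, 0, 0), (1, 0, 0), (50, 0, 0)]
        loci = _loci_from_points(pts, ["chr1", "chr2", "chr3"], ["1", "5", "5"])
        _, graph = dipc.neighbors_within(loci, 2.5)
        frac = dipc.zonal_trans_proximity_fraction(graph)
        assert frac["1"] == 1.0 and frac["5"] == 0.5

    def test_cis_pair_not_counted(self):
        pts = [(0, 0, 0), (1, 0, 0)]
        loci = _loci_from_points(pts, ["chr1", "chr1"], ["1", "1"])
        _, graph = dipc.neighbors_within(loci, 2.5)
        assert dipc.zonal_trans_proximity_fraction(graph)["1"] == 0.0


class TestContactDensity:
    def test_scale_invariance(self, rng):
        pts = rng.normal(size=(30, 3)) * 4
        chroms = [f"chr{i % 3}" for i in range(30)]
        a = dipc.contact_density(_loci_from_points(pts, chroms), 2.5)
        b = dipc.contact_density(_loci_from_points(pts * 10, chroms), 25.0)
        assert a == pytest.approx(b)

    def test_identical_groups_p_near_one(self):
        rng = np.random.default_rng(3)
        pts = [rng.normal(size=(20, 3)) for _ in range(6)]
        chroms = [f"chr{i % 2}" for i in range(20)]
        group = [_loci_from_points(p, chroms) for p in pts]
        _, _, res = dipc.contact_density_compare(group[:3], group[:3], 2.5)
        assert res.pvalue == pytest.approx(1.0)


class TestOrderedHeatmap:
    def test_genomic_order_identity(self, rng):
        d = np.abs(rng.normal(size=(12, 12)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        perm, mat = dipc.ordered_distance_heatmap(d, order="genomic",
                                                  display_threshold=None)
        assert (perm == np.arange(12)).all()
        assert np.allclose(mat, d)

    def test_single_element(self):
        perm, mat = dipc.ordered_distance_heatmap(np.zeros((1, 1)))
        assert list(perm) == [0]

    def test_planted_blocks_recovered_contiguously(self):
        rng = np.random.default_rng(4)
        centers = np.array([[0, 0, 0], [100, 0, 0], [0, 100, 0]])
        labels = np.repeat([0, 1, 2], 8)
        pts = centers[labels] + rng.normal(scale=0.5, size=(24, 3))
        shuffle = rng.permutation(24)
        d = pairwise_distances_bruteforce(pts[shuffle])
        perm, _ = dipc.ordered_distance_heatmap(d, order="hierarchical")
        ordered_labels = labels[shuffle][perm]
        # each planted cluster occupies one contiguous stretch of the leaf order
        changes = (np.diff(ordered_labels) != 0).sum()
        assert changes == 2

    def test_threshold_masks_far_pairs(self):
        d = np.array([[0.0, 3.0], [3.0, 0.0]])
        _, mat = dipc.ordered_distance_heatmap(d, order="genomic", display_threshold=2.0)
        assert np.isnan(mat[0, 1]) and mat[0, 0] == 0.0


def test_ventral_aggregates_dominate_dorsal(tissue):
    """Fig-S3C direction at reduced cell numbers: ventral mOSN OR aggregates
    are larger and span more chromosomes than dorsal ones, and every cell's
    proximity graph is unique."""
    n = 12
    stats = {}
    edge_sets = []
    for seg in ("dorsal", "ventral"):
        sizes, chroms = [], []
        for st in emitters.emit_3dg(tissue, seg, n_cells=n):
            loci = dipc.map_or_loci(st, tissue.genes)
            _, graph = dipc.neighbors_within(loci, 2.5)
            agg = dipc.aggregate_stats(graph)
            sizes.append(agg["n_ors"].max())
            chroms.append(agg["n_chromosomes"].max())
            edge_sets.append(graph.edge_set)
        stats[seg] = (sizes, chroms)
    from zonescape.ranksum import rank_sum_test

    assert rank_sum_test(stats["ventral"][0], stats["dorsal"][0]).pvalue < 0.01
    assert rank_sum_test(stats["ventral"][1], stats["dorsal"][1]).pvalue < 0.01
    assert len(set(edge_sets)) == 2 * n
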
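"""Contact normalization, trans zone heatmaps, cis windows."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from zonescape import hic
from zonescape import emitters


def _bins(chroms, zones, resolution=50_000):
    starts = []
    counter = {}
    for c in chroms:
        starts.append(counter.get(c, 0))
        counter[c] = counter.get(c, 0) + resolution
    return pd.DataFrame({
        "bin_id": np.arange(len(chroms)),
        "chrom": chroms,
        "start": starts,
        "resolution": resolution,
        "zone": zones,
    })


def _matrix(dense, bins):
    return hic.ContactMatrix(sparse.csr_matrix(np.asarray(dense, float)), bins)


class TestNormalizeCpb:
    def test_total_1e9_is_identity(self):
        bins = _bins(["chr1", "chr2"], ["1", "1"])
        dense = np.array([[0.0, 2.5e8], [2.5e8, 0.0]])
        dense[0, 0] = 5e8
        m = hic.normalize_cpb(_matrix(dense, bins))
        assert np.allclose(m.counts.todense(), dense)

    def test_single_pair_arithmetic(self):
        bins = _bins(["chr1", "chr2"], ["1", "1"])
        dense = np.zeros((2, 2))
        dense[0, 1] = dense[1, 0] = 10.0
        m = _matrix(dense, bins)
        m.total_contacts = 1e6  # pretend the rest of the library is elsewhere
        n = hic.normalize_cpb(m)
        assert n.counts[0, 1] == pytest.approx(10 * 1e9 / 1e6)

    def test_idempotent_and_total(self):
        rng = np.random.default_rng(0)
        n = 8
        dense = rng.poisson(20, (n, n)).astype(float)
        dense = dense + dense.T
        bins = _bins([f"chr{i % 3}" for i in range(n)], ["1"] * n)
        m = hic.normalize_cpb(_matrix(dense, bins))
        assert np.asarray(m.counts.todense()).sum() == pytest.approx(1e9)
        again = hic.normalize_cpb(m)
        assert np.allclose(again.counts.todense(), m.counts.todense())


class TestTransZoneHeatmap:
    def test_hand_computed_toy(self):
        # 2 zones x 2 bins across two chromosomes with hand-set counts
        bins = _bins(["chr1", "chr1", "chr2", "chr2"], ["1", "5", "1", "5"])
        dense = np.zeros((4, 4))
        dense[0, 2] = dense[2, 0] = 8.0  # z1-z1 trans
        dense[1, 3] = dense[3, 1] = 2.0  # z5-z5 trans
        dense[0, 3] = dense[3, 0] = 4.0  # z1-z5 trans
        dense[1, 2] = dense[2, 1] = 6.0  # z5-z1 trans
        dense[0, 1] = dense[1, 0] = 99.0  # cis: ignored
        m = _matrix(dense, bins)
        m.normalized = True  # keep hand counts
        s = hic.trans_zone_heatmap(m)
        assert s.mean.loc["1", "1"] == pytest.approx(8.0)
        assert s.mean.loc["5", "5"] == pytest.approx(2.0)
        assert s.mean.loc["1", "5"] == pytest.approx(5.0)  # mean of 4 and 6
        assert s.n_pairs.loc["1", "5"] == 2

    def test_symmetry_and_all_equal_counts(self):
        n = 9
        bins = _bins([f"chr{i % 3}" for i in range(n)],
                     [z for z in "135" for _ in range(3)])
        dense = np.full((n, n), 7.0)
        m = _matrix(dense, bins)
        m.normalized = True
        s = hic.trans_zone_heatmap(m)
        assert np.allclose(s.mean, s.mean.T)
        assert np.allclose(s.mean.to_numpy(), 7.0)

    def test_classI_and_unannotated_excluded(self):
        bins = _bins(["chr1", "chr2", "chr1", "chr2", "chr1", "chr2"],
                     ["1", "1", "classI", "classI", "", ""])
        dense = np.zeros((6, 6))
        dense[0, 1] = dense[1, 0] = 5.0
        dense[2, 3] = dense[3, 2] = 1e6  # classI given huge counts
        dense[4, 5] = dense[5, 4] = 1e6
        m = _matrix(dense, bins)
        m.normalized = True
        s = hic.trans_zone_heatmap(m)
        assert list(s.mean.index) == ["1"]
        assert s.mean.loc["1", "1"] == pytest.approx(5.0)

    def test_zero_pair_cells_are_missing_not_zero(self):
        bins = _bins(["chr1", "chr1"], ["1", "5"])  # same chromosome: no trans
        m = _matrix(np.zeros((2, 2)), bins)
        m.normalized = True
        s = hic.trans_zone_heatmap(m)
        assert np.isnan(s.mean.loc["1", "5"])
        assert s.n_pairs.loc["1", "5"] == 0

    def test_resolution_mismatch_errors(self):
        bins = _bins(["chr1", "chr2"], ["1", "1"], resolution=100_000)
        m = _matrix(np.zeros((2, 2)), bins)
        with pytest.raises(ValueError, match="resolution"):
            hic.trans_zone_heatmap(m, expected_resolution=50_000)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bruteforce_loop(self, seed):
        from oracles import trans_heatmap_bruteforce

        rng = np.random.default_rng(seed)
        n = 24
        chroms = [f"chr{i % 4}" for i in range(n)]
        zones = rng.choice(["1", "2", "3", "4", "5", "classI", ""], size=n)
        dense = rng.poisson(5, (n, n)).astype(float)
        dense = np.triu(dense) + np.triu(dense, 1).T
        bins = _bins(chroms, zones)
        m = _matrix(dense, bins)
        m.normalized = True
        s = hic.trans_zone_heatmap(m)
        classes = sorted(set(zones) & {"1", "2", "3", "4", "5"})
        oracle = trans_heatmap_bruteforce(dense, chroms, list(zones), classes)
        for a in classes:
            for b in classes:
                got = s.mean.loc[a, b]
                want = oracle[(a, b)]
                if want is None:
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(want)

    def test_grouped_classes(self):
        bins = _bins(["chr1", "chr2", "chr1", "chr2"], ["2", "3", "4", "5"])
        dense = np.zeros((4, 4))
        dense[0, 1] = dense[1, 0] = 4.0  # 2-3 x 2-3
        dense[2, 3] = dense[3, 2] = 8.0  # 4-5 x 4-5
        m = _matrix(dense, bins)
        m.normalized = True
        s = hic.trans_zone_heatmap(m, grouped=True)
        assert s.mean.loc["2-3", "2-3"] == pytest.approx(4.0)
        assert s.mean.loc["4-5", "4-5"] == pytest.approx(8.0)


class TestCisWindow:
    def test_cluster_vs_itself_symmetric(self):
        n = 6
        bins = _bins(["chr1"] * n, ["1"] * n)
        rng = np.random.default_rng(1)
        dense = rng.poisson(30, (n, n)).astype(float)
        dense = dense + dense.T
        m = _matrix(dense, bins)
        m.normalized = True
        span = ("chr1", 0, 6 * 50_000)
        block = hic.cis_window(m, span, span)
        assert np.allclose(block.to_numpy(), block.to_numpy().T)

    def test_disjoint_empty_region_zeros(self):
        bins = _bins(["chr1"] * 4, ["1"] * 4)
        dense = np.zeros((4, 4))
        dense[0, 1] = dense[1, 0] = 50.0
        m = _matrix(dense, bins)
        m.normalized = True
        block = hic.cis_window(m, ("chr1", 100_000, 150_000), ("chr1", 150_000, 200_000))
        assert (block.to_numpy() == 0).all()

    def test_matches_dense_reconstruction_and_cap(self):
        rng = np.random.default_rng(2)
        n = 10
        bins = _bins(["chr1"] * n, ["1"] * n)
        dense = rng.poisson(100, (n, n)).astype(float)
        dense = np.triu(dense) + np.triu(dense, 1).T
        m = _matrix(dense, bins)
        m.normalized = True
        a = ("chr1", 0, 3 * 50_000)
        b = ("chr1", 5 * 50_000, 9 * 50_000)
        block = hic.cis_window(m, a, b)
        assert np.allclose(block.to_numpy(), dense[0:3, 5:9])
        capped = hic.cis_window(m, a, b, color_cap=150.0)
        assert capped.to_numpy().max() <= 150.0

    def test_trans_clusters_rejected(self):
        bins = _bins(["chr1", "chr2"], ["1", "1"])
        m = _matrix(np.zeros((2, 2)), bins)
        with pytest.raises(ValueError, match="one chromosome"):
            hic.cis_window(m, ("chr1", 0, 1), ("chr2", 0, 1))


def test_segment_gradient_and_cko_collapse(tissue, cko_tissue):
    """Fig 3B / Fig 6B directions on synthetic segment matrices."""
    heats = {}
    bg = {}
    for seg in ("dorsal", "dorsomedial", "ventral"):
        cm = emitters.emit_hic(tissue, seg)
        heats[seg] = hic.trans_zone_heatmap(cm, grouped=True).mean
        bg[seg] = _background(cm)
    z45 = [heats[s].loc["4-5", "4-5"] for s in ("dorsal", "dorsomedial", "ventral")]
    assert z45[2] > z45[1] > z45[0]
    z11 = np.array([heats[s].loc["1", "1"] for s in ("dorsal", "dorsomedial", "ventral")])
    assert (np.abs(z11 - z11.mean()) / z11.mean() < 0.2).all()

    cko = emitters.emit_hic(cko_tissue, "ventral")
    sk = hic.trans_zone_heatmap(cko, grouped=True).mean
    assert sk.loc["4-5", "4-5"] < 2 * _background(cko)
    assert abs(sk.loc["1", "1"] / heats["ventral"].loc["1", "1"] - 1) < 0.2


def _background(cm):
    """Mean normalized trans count between unannotated (non-OR) bins."""
    m = hic.normalize_cpb(cm)
    dense = np.asarray(m.counts.todense())
    zone = m.bins["zone"].astype(str).to_numpy()
    chrom = m.bins["chrom"].to_numpy()
    un = np.flatnonzero(zone == "")
    trans = chrom[un][:, None] != chrom[un][None, :]
    return float(dense[np.ix_(un, un)][trans].mean())
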
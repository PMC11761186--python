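"""Spatial sample IO, heatmap registration, clustering, correlation."""
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from attnsig.enrichment import GeneSet
from attnsig.io import SpotTable, ValidationError, write_spatial_sample
from attnsig.spatial import (annotate_spots, cluster_spots,
                             correlate_attention_signature,
                             register_attention_to_spots, read_spatial,
                             select_tumor_cluster, spearman)
from attnsig.synthetic import (default_signature, default_tumor_markers,
                               generate_spatial_sample, render_tissue_image)


def _mini_table(counts, coords, radius=2.0, scale=1.0):
    genes = [f"g{i}" for i in range(counts.shape[0])]
    barcodes = [f"b{i}" for i in range(counts.shape[1])]
    positions = pd.DataFrame({
        "barcode": barcodes, "in_tissue": 1,
        "array_row": range(len(barcodes)), "array_col": 0,
        "x_pixel": [c[0] for c in coords], "y_pixel": [c[1] for c in coords],
    })
    return SpotTable(genes=genes, barcodes=barcodes,
                     counts=sparse.csr_matrix(counts), positions=positions,
                     spot_radius_px=radius, scale_factor=scale)


class TestReadSpatial:
    def test_round_trip_identity(self, tmp_path):
        img, mask = render_tissue_image(128, 128, 0.2, seed=0)
        table = generate_spatial_sample(img, mask, 50, default_signature(50, 10),
                                        seed=1)
        d = write_spatial_sample(table, tmp_path / "sample")
        back = read_spatial(d / "matrix.mtx", d / "features.tsv",
                            d / "barcodes.tsv", d / "positions.csv",
                            d / "scalefactors.json")
        assert back.genes == table.genes
        assert back.barcodes == table.barcodes
        assert (back.counts != table.counts).nnz == 0
        assert back.spot_radius_px == table.spot_radius_px

    def test_missing_barcode_rejected(self, tmp_path):
        img, mask = render_tissue_image(128, 128, 0.2, seed=0)
        table = generate_spatial_sample(img, mask, 30, default_signature(30, 5),
                                        seed=1)
        d = write_spatial_sample(table, tmp_path / "sample")
        pos = pd.read_csv(d / "positions.csv").iloc[1:]
        pos.to_csv(d / "positions.csv", index=False)
        with pytest.raises(ValidationError):
            read_spatial(d / "matrix.mtx", d / "features.tsv", d / "barcodes.tsv",
                         d / "positions.csv", d / "scalefactors.json")

    def test_hand_written_triplet_recovered_exactly(self, tmp_path):
        (tmp_path / "matrix.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n"
            "2 3 4\n1 1 5\n2 1 1\n1 3 7\n2 2 2\n")
        (tmp_path / "features.tsv").write_text("gA\ngB\n")
        (tmp_path / "barcodes.tsv").write_text("s1\ns2\ns3\n")
        pd.DataFrame({"barcode": ["s1", "s2", "s3"], "in_tissue": 1,
                      "array_row": [0, 0, 0], "array_col": [0, 1, 2],
                      "x_pixel": [5, 15, 25], "y_pixel": [5, 5, 5]}
                     ).to_csv(tmp_path / "positions.csv", index=False)
        (tmp_path / "scalefactors.json").write_text(
            '{"spot_radius_px": 2.0, "scale_factor": 1.0}')
        t = read_spatial(tmp_path / "matrix.mtx", tmp_path / "features.tsv",
                         tmp_path / "barcodes.tsv", tmp_path / "positions.csv",
                         tmp_path / "scalefactors.json")
        assert t.counts.toarray().tolist() == [[5, 0, 7], [1, 2, 0]]


class TestRegisterAttention:
    def test_constant_heatmap_gives_constant_values(self):
        table = _mini_table(np.ones((3, 4)), [(4, 4), (10, 4), (4, 10), (10, 10)])
        vals = register_attention_to_spots(np.full((16, 16), 0.37), table)
        assert np.allclose(vals, 0.37)

    def test_subpixel_radius_is_nearest_pixel_lookup(self):
        hm = np.arange(16, dtype=float).reshape(4, 4) / 15
        table = _mini_table(np.ones((2, 2)), [(1, 2), (3, 0)], radius=0.4)
        vals = register_attention_to_spots(hm, table)
        assert vals[0] == hm[2, 1] and vals[1] == hm[0, 3]

    def test_quadrant_means_match_direct_averaging(self):
        hm = np.zeros((20, 20))
        hm[:10, 10:] = 1.0  # bright upper-right quadrant
        coords = [(5, 5), (15, 5), (5, 15), (15, 15)]
        table = _mini_table(np.ones((2, 4)), coords, radius=3.0)
        vals = register_attention_to_spots(hm, table)
        gy, gx = np.mgrid[-3:4, -3:4]
        disc = gy ** 2 + gx ** 2 <= 9.0
        for v, (x, y) in zip(vals, coords):
            direct = hm[y + gy[disc], x + gx[disc]].mean()
            assert v == pytest.approx(direct, abs=1e-12)

    def test_upsampled_heatmap_gives_same_values(self):
        rng = np.random.default_rng(0)
        hm = rng.random((20, 20))
        from attnsig.nn.layers import upsample_bilinear

        big = upsample_bilinear(hm, 40, 40)
        coords = [(6, 6), (12, 9), (9, 13)]
        t1 = _mini_table(np.ones((2, 3)), coords, radius=3.0, scale=1.0)
        t2 = _mini_table(np.ones((2, 3)), coords, radius=3.0, scale=2.0)
        v1 = register_attention_to_spots(hm, t1)
        v2 = register_attention_to_spots(big, t2)
        assert np.allclose(v1, v2, atol=1e-1)

    def test_center_outside_heatmap_rejected(self):
        table = _mini_table(np.ones((2, 1)), [(30, 30)])
        with pytest.raises(ValidationError):
            register_attention_to_spots(np.zeros((16, 16)), table)


class TestClusterSpots:
    def test_two_separable_blobs_fully_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(1)
        a = rng.poisson(5, (30, 20))
        b = rng.poisson(5, (30, 20))
        b[:10] += 60  # first 10 genes strongly up in group b
        counts = np.hstack([a, b])
        coords = [(2 * i + 2, 2) for i in range(40)]
        table = _mini_table(counts, coords)
        labels = cluster_spots(table, 2, seed=0)
        truth = np.array([0] * 20 + [1] * 20)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_single_cluster_degenerate(self):
        table = _mini_table(np.ones((5, 6)), [(i + 1, 1) for i in range(6)])
        assert set(cluster_spots(table, 1, seed=0)) == {0}

    def test_one_dimensional_two_mode_lloyd_fixed_point(self):
        # one informative gene, two clear modes; k-means must split at the gap
        lo, hi = [1, 2, 1, 2], [30, 31, 30, 31]
        counts = np.zeros((2, 8))
        counts[0] = lo + hi
        counts[1] = 1.0  # constant gene so library sizes stay comparable
        table = _mini_table(counts, [(i + 1, 1) for i in range(8)])
        labels = cluster_spots(table, 2, seed=0, n_top_genes=1)
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[4]

    def test_too_many_clusters_rejected(self):
        table = _mini_table(np.ones((3, 4)), [(i + 1, 1) for i in range(4)])
        with pytest.raises(ValidationError):
            cluster_spots(table, 10, seed=0)


class TestSelectTumorCluster:
    def test_planted_tumor_cluster_recovered(self):
        img, mask, tmask = render_tissue_image(160, 160, 0.2, seed=3,
                                               return_tumor_mask=True)
        sig = default_signature(200)
        markers = default_tumor_markers(200)
        table = generate_spatial_sample(img, mask, 200, sig, seed=4,
                                        tumor_mask=tmask, marker_genes=markers)
        labels = cluster_spots(table, 4, seed=0)
        tumor = select_tumor_cluster(labels, table, markers)
        predicted = labels == tumor
        truth = table.truth["is_tumor"].to_numpy()
        jaccard = (predicted & truth).sum() / (predicted | truth).sum()
        assert jaccard > 0.8

    def test_single_cluster_returned(self):
        table = _mini_table(np.ones((4, 3)), [(i + 1, 1) for i in range(3)])
        assert select_tumor_cluster(np.zeros(3, dtype=int), table,
                                    GeneSet("m", ("g0",))) == 0

    def test_unexpressed_markers_rejected(self):
        counts = np.ones((4, 3))
        counts[0] = 0.0
        table = _mini_table(counts, [(i + 1, 1) for i in range(3)])
        with pytest.raises(ValidationError):
            select_tumor_cluster(np.zeros(3, dtype=int), table,
                                 GeneSet("m", ("g0",)))


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.arange(10.0)
        assert spearman(x, x ** 3).rho == pytest.approx(1.0)
        assert spearman(x, -x - 2).rho == pytest.approx(-1.0)

    def test_tied_example_matches_hand_midranks(self):
        # ranks of x: {1, 2.5, 2.5, 4}; ranks of y: {3, 1, 2, 4}
        res = spearman([1, 2, 2, 4], [3, 1, 2, 4])
        rx, ry = np.array([1, 2.5, 2.5, 4]), np.array([3, 1, 2, 4])
        hand = np.corrcoef(rx, ry)[0, 1]
        assert res.rho == pytest.approx(hand, rel=1e-12)

    def test_matches_scipy_with_ties(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(5, 100))
            x = rng.choice(np.linspace(0, 1, 8), n)
            y = rng.random(n)
            if np.std(x) == 0:
                continue
            res = spearman(x, y)
            ref = spearmanr(x, y)
            assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-6, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            spearman([1, 1, 1], [1, 2, 3])


class TestCorrelateAttentionSignature:
    def _annotated(self, fold_change, seed):
        img, mask, tmask = render_tissue_image(160, 160, 0.25, seed=seed,
                                               return_tumor_mask=True)
        sig = default_signature(300)
        markers = default_tumor_markers(300)
        table = generate_spatial_sample(img, mask, 300, sig, seed=seed + 1,
                                        fold_change=fold_change,
                                        tumor_mask=tmask, marker_genes=markers)
        # ground-truth infiltrate map stands in for the attention heatmap
        heatmap = mask.astype(float)
        return annotate_spots(table, heatmap, sig, markers, n_clusters=3,
                              seed=seed)

    def test_planted_coupling_detected(self):
        ann = self._annotated(fold_change=2.0, seed=10)
        res = correlate_attention_signature(ann, tumor_only=True)
        assert res.rho > 0.2 and res.p < 0.05

    def test_epsilon_choice_does_not_change_rank_correlation(self):
        ann = self._annotated(fold_change=2.0, seed=11)
        ann["attention"] += 0.02  # keep all attentions above both epsilons
        a = correlate_attention_signature(ann, epsilon=1e-6)
        b = correlate_attention_signature(ann, epsilon=1e-8)
        assert a.rho == pytest.approx(b.rho, abs=1e-12)

    def test_constant_attention_rejected(self):
        ann = pd.DataFrame({"spot_id": list("abcd"), "cluster": 0,
                            "is_tumor": True, "attention": 0.5,
                            "enrichment": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValidationError):
            correlate_attention_signature(ann)

    def test_too_few_spots_rejected(self):
        ann = pd.DataFrame({"spot_id": ["a", "b"], "cluster": 0,
                            "is_tumor": True, "attention": [0.1, 0.9],
                            "enrichment": [1.0, 2.0]})
        with pytest.raises(ValidationError):
            correlate_attention_signature(ann)
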
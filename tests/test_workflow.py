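"""Tests for the standard workflow, PC transfer and PAGA abstraction."""

import numpy as np
import pytest
import scipy.sparse as sp

import umitopo as ut


class TestQcFilterMito:
    names = np.array(["MT-X", "Y"])

    def test_boundary_is_strict(self):
        counts = np.array([[15], [85]])  # exactly 15% mitochondrial
        _, keep = ut.qc_filter_mito(counts, self.names)
        assert not keep[0]

    def test_zero_mito_kept_and_hand_percentage(self):
        counts = np.array([[0, 1], [50, 9]])
        filtered, keep = ut.qc_filter_mito(counts, self.names)
        assert keep.tolist() == [True, True]  # 0% and 10%
        assert filtered.shape == (2, 2)

    def test_no_matching_prefix_warns(self):
        with pytest.warns(UserWarning):
            _, keep = ut.qc_filter_mito(np.array([[1], [2]]), np.array(["A", "B"]))
        assert keep.all()


class TestWorkflowContract:
    def test_neighbor_count_rule(self):
        assert ut.WorkflowConfig().k_nn(1_500) == 15
        assert ut.WorkflowConfig().k_nn(100) == 5  # floor guards small fixtures

    def test_clusters_partition_and_graph_sane(self, small_z):
        res = ut.run_standard_workflow(small_z.counts, ut.WorkflowConfig(seed=1))
        assert res.cluster_labels.shape == (small_z.n_cells,)
        assert res.cluster_labels.min() == 0
        deg = np.asarray((res.connectivities > 0).sum(axis=1)).ravel()
        assert deg.min() >= 1
        assert res.distances.diagonal().sum() == 0
        assert (res.connectivities != res.connectivities.T).nnz == 0

    def test_determinism(self, small_z):
        a = ut.run_standard_workflow(small_z.counts, ut.WorkflowConfig(seed=5))
        b = ut.run_standard_workflow(small_z.counts, ut.WorkflowConfig(seed=5))
        assert np.array_equal(a.cluster_labels, b.cluster_labels)
        assert np.allclose(a.pc_scores, b.pc_scores)

    def test_too_few_cells_rejected(self):
        counts = np.random.default_rng(0).poisson(1.0, size=(40, 8))
        with pytest.raises(ValueError):
            ut.run_standard_workflow(counts, ut.WorkflowConfig())

    def test_distinct_cell_types_separate(self):
        """Two permuted-identity populations at equal depth form pure clusters
        in two disconnected abstraction components (>= 4/5 seeds)."""
        ok = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            base = ut.build_fraction_model("combined")
            other = ut.permute_gene_identities(base, seed=int(rng.integers(2**31)))
            cols = []
            for m in (base, other):
                cols.append(
                    sp.hstack([
                        sp.csc_matrix(ut.sample_cell_counts(m, 5_000, rng)[:, None])
                        for _ in range(200)
                    ])
                )
            counts = sp.hstack(cols).tocsc()
            labels = np.array(["c1"] * 200 + ["c2"] * 200)
            res = ut.run_standard_workflow(counts, ut.WorkflowConfig(seed=seed))
            cl = res.cluster_labels
            pure = all(
                np.unique(labels[cl == c]).size == 1 for c in np.unique(cl)
            )
            ag = ut.compute_paga(res.distances, cl)
            beta0 = ut.betti_numbers(ut.threshold_abstraction(ag, 0.05)).beta0
            ok += pure and beta0 == 2
        assert ok >= 4


class TestPcTransfer:
    def test_projecting_training_population_is_identity(self, small_z):
        res = ut.run_standard_workflow(small_z.counts, ut.WorkflowConfig(seed=2))
        proj = ut.project_onto_loadings(small_z.counts, res)
        assert np.abs(proj - res.pc_scores).max() < 1e-8

    def test_matches_dense_projection_oracle(self):
        rng = np.random.default_rng(4)
        counts = sp.csc_matrix(rng.poisson(2.0, size=(60, 30)))
        cfg = ut.WorkflowConfig(n_hvg=60, n_pcs=5, seed=0)
        res = ut.run_standard_workflow(counts, cfg)
        # independent dense recomputation of the projection
        x = counts.toarray().astype(float)
        x = np.log1p(x * (cfg.target_sum / x.sum(axis=0)))
        xs = (x[res.hvg_idx].T - res.gene_means) / res.gene_stds
        xs = np.clip(xs, -cfg.scale_clip, cfg.scale_clip)
        expected = (xs - res.pca_mean) @ res.loadings.T
        assert np.allclose(ut.project_onto_loadings(counts, res), expected)

    def test_missing_reference_genes_are_centered_out(self):
        rng = np.random.default_rng(5)
        counts = sp.csc_matrix(rng.poisson(2.0, size=(40, 25)))
        names = np.array([f"G{i}" for i in range(40)])
        cfg = ut.WorkflowConfig(n_hvg=40, n_pcs=4, seed=0)
        res = ut.run_standard_workflow(counts, cfg, gene_names=names)
        alien = np.array([f"H{i}" for i in range(40)])  # shares no names
        with pytest.warns(UserWarning):
            proj = ut.project_onto_loadings(counts, res, gene_names=alien)
        # all HVGs imputed at the reference mean: scores collapse to a constant
        expected = (np.zeros(res.loadings.shape[1]) - res.pca_mean) @ res.loadings.T
        assert np.allclose(proj, expected[None, :])

    def test_transferred_skeleton_matches_refit(self):
        """PAGA edge sets among deep-cell clusters agree between transferred
        and refit coordinates (median Jaccard >= 0.8 over seeds)."""
        def edge_set(ag, tau=0.05):
            c = ag.connectivity
            n = c.shape[0]
            return {(i, j) for i in range(n) for j in range(i + 1, n) if c[i, j] >= tau}

        jaccards = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            pop = ut.simulate_population_Z(rng, cells_per_state=200)
            ref = ut.run_standard_workflow(pop.counts, ut.WorkflowConfig(seed=seed))
            zp = ut.filter_by_total_umi(pop, 4_000)
            refit = ut.run_standard_workflow(zp.counts, ut.WorkflowConfig(seed=seed))
            scores_t = ut.project_onto_loadings(zp.counts, ref)
            dist_t, _ = ut.build_neighbor_graph(scores_t, refit.k_nn, seed)
            a = edge_set(ut.compute_paga(dist_t, refit.cluster_labels))
            b = edge_set(ut.compute_paga(refit.distances, refit.cluster_labels))
            jaccards.append(len(a & b) / max(1, len(a | b)))
        assert np.median(jaccards) >= 0.8


class TestComputePaga:
    def test_disconnected_clusters_have_zero_connectivity(self):
        # two directed 3-cycles with no cross edges
        a = np.zeros((6, 6))
        for i in range(3):
            a[i, (i + 1) % 3] = 1.0
            a[3 + i, 3 + (i + 1) % 3] = 1.0
        ag = ut.compute_paga(sp.csr_matrix(a), np.array([0, 0, 0, 1, 1, 1]))
        assert ag.connectivity[0, 1] == 0

    def test_single_cluster_has_no_pairs(self):
        a = sp.csr_matrix(np.array([[0, 1.0], [1.0, 0]]))
        ag = ut.compute_paga(a, np.array([0, 0]))
        assert ag.n_nodes == 1
        assert np.all(ag.connectivity == 0)

    def test_matches_reference_implementation(self):
        """Agrees with the published PAGA implementation to 1e-6 on a
        two-blob fixture."""
        import warnings
        import anndata
        import pandas as pd
        import scanpy as sc

        rng = np.random.default_rng(0)
        scores = np.vstack([
            rng.normal(0, 1, size=(60, 5)),
            rng.normal(3, 1, size=(60, 5)),
        ])
        dist, _ = ut.build_neighbor_graph(scores, k_nn=8, seed=0)
        labels = np.array([0] * 40 + [1] * 40 + [2] * 40)
        mine = ut.compute_paga(dist, labels)

        ad = anndata.AnnData(X=np.zeros((120, 1), dtype=np.float32))
        ad.obsm["X_pca"] = scores.astype(np.float32)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc.pp.neighbors(ad, n_neighbors=9, use_rep="X_pca", random_state=0)
            ad.obs["grp"] = pd.Categorical([str(g) for g in labels],
                                           categories=["0", "1", "2"])
            sc.tl.paga(ad, groups="grp")
        ref = ad.uns["paga"]["connectivities"].toarray()
        assert np.abs(ref - mine.connectivity).max() < 1e-6
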
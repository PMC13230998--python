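"""The standard single-cell analysis workflow and cluster-level graph abstraction.

Pipeline stages, in order: per-cell total-count normalization and log1p,
highly-variable-gene (HVG) selection, per-gene standardization with clipping,
PCA, kNN neighbor-graph construction in PC space (each cell connected to the
top ``neighbor_fraction`` of cells, default 1%), Louvain clustering at a fixed
resolution, and — optionally — a 2-D UMAP embedding for visualization only.

Cluster-level connectivity is summarized by partition-based graph abstraction
(PAGA): for each cluster pair the number of inter-cluster kNN edges is scaled
by its expectation under random edge placement given cluster sizes, capped at
1.  Thresholding this abstraction graph yields the "manifold skeleton" whose
topology downstream modules analyze.

PC transfer: the fitted normalization / HVG / scaling / PCA statistics can be
applied to a cell subset without refitting, so a subset can be analyzed in the
coordinate system learned on the full population.
"""

from __future__ import annotations

import logging
import random as _pyrandom
import warnings
from dataclasses import dataclass
from typing import Any

import igraph
import numpy as np
import scipy.sparse as sp

__all__ = [
    "WorkflowConfig",
    "WorkflowResult",
    "AbstractionGraph",
    "qc_filter_mito",
    "run_standard_workflow",
    "project_onto_loadings",
    "compute_paga",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WorkflowConfig:
    """Settings for the standard workflow.

    ``neighbor_fraction`` controls the kNN graph: k = max(5, round(f * n_cells)),
    self excluded.  ``resolution`` is the Louvain resolution.  Normalization
    target, HVG count and the scaling clip follow common community defaults.
    """

    target_sum: float = 10_000.0
    n_hvg: int = 2_000
    scale_clip: float | None = 10.0
    n_pcs: int = 30
    neighbor_fraction: float = 0.01
    resolution: float = 1.0
    seed: int = 0
    compute_embedding: bool = False

    def k_nn(self, n_cells: int) -> int:
        if not 0 < self.neighbor_fraction <= 1:
            raise ValueError("neighbor_fraction must be in (0, 1]")
        return max(5, int(round(self.neighbor_fraction * n_cells)))


@dataclass
class WorkflowResult:
    """Everything the workflow fitted, sufficient for exact PC transfer."""

    config: WorkflowConfig
    n_cells: int
    k_nn: int
    hvg_idx: np.ndarray  # gene indices (rows of the input) used for PCA
    gene_means: np.ndarray  # per-HVG mean of log-normalized expression
    gene_stds: np.ndarray  # per-HVG std (ddof=0)
    pca_mean: np.ndarray  # center used by PCA in scaled space
    loadings: np.ndarray  # (n_pcs, n_hvg_kept)
    pc_scores: np.ndarray  # (n_cells, n_pcs)
    distances: sp.csr_matrix  # directed kNN graph (distance entries)
    connectivities: sp.csr_matrix  # symmetric weighted neighbor graph
    cluster_labels: np.ndarray  # per-cell integer cluster
    embedding: np.ndarray | None = None
    gene_names: np.ndarray | None = None


@dataclass
class AbstractionGraph:
    """Cluster-level PAGA connectivity: symmetric, zero-diagonal, in [0, 1]."""

    node_sizes: np.ndarray  # cells per cluster, index = cluster id
    connectivity: np.ndarray  # (n_clusters, n_clusters)

    @property
    def n_nodes(self) -> int:
        return len(self.node_sizes)

    def validate(self) -> None:
        c = self.connectivity
        if c.shape != (self.n_nodes, self.n_nodes):
            raise ValueError("connectivity shape mismatch")
        if not np.allclose(c, c.T):
            raise ValueError("connectivity must be symmetric")
        if np.any(np.diag(c) != 0):
            raise ValueError("connectivity diagonal must be zero")
        if np.any(self.node_sizes < 1):
            raise ValueError("empty clusters are not allowed")


def qc_filter_mito(
    counts,
    gene_names,
    max_pct: float = 15.0,
    prefix: str = "MT-",
) -> tuple[Any, np.ndarray]:
    """Keep cells whose mitochondrial fraction is strictly below ``max_pct`` percent.

    Returns the filtered genes x cells matrix and the boolean keep mask.
    If no gene name starts with ``prefix`` a warning is emitted and all cells
    are kept.
    """
    gene_names = np.asarray(gene_names)
    if counts.shape[0] != gene_names.size:
        raise ValueError("gene_names length must match rows of counts")
    mito = np.array([str(g).startswith(prefix) for g in gene_names])
    if not mito.any():
        warnings.warn(f"no gene name starts with {prefix!r}; keeping all cells")
        return counts, np.ones(counts.shape[1], dtype=bool)
    total = np.asarray(counts.sum(axis=0)).ravel().astype(float)
    mito_total = np.asarray(counts[mito].sum(axis=0)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * mito_total / total, 0.0)
    keep = pct < max_pct
    return counts[:, keep], keep


def _log_normalize(counts, target_sum: float) -> np.ndarray:
    """Scale each cell to ``target_sum`` total counts, then log1p.  Dense output."""
    x = counts.astype(np.float64)
    if sp.issparse(x):
        x = x.toarray()
    totals = x.sum(axis=0)
    totals[totals == 0] = 1.0
    return np.log1p(x * (target_sum / totals))


def _select_hvg(counts, config: WorkflowConfig) -> np.ndarray:
    """Dispersion-based HVG selection on log-normalized data (seurat flavor)."""
    import anndata
    import scanpy as sc

    n_genes = counts.shape[0]
    if n_genes <= config.n_hvg:
        return np.arange(n_genes)
    ad = anndata.AnnData(X=sp.csr_matrix(counts.T, dtype=np.float32))
    sc.pp.normalize_total(ad, target_sum=config.target_sum)
    sc.pp.log1p(ad)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.highly_variable_genes(ad, n_top_genes=config.n_hvg, flavor="seurat")
    return np.flatnonzero(ad.var["highly_variable"].to_numpy())


def build_neighbor_graph(
    scores: np.ndarray, k_nn: int, seed: int = 0
) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """kNN graph in PC space: directed distance graph + symmetric weights.

    Each cell is connected to its ``k_nn`` nearest neighbors (self excluded)
    by Euclidean distance; the symmetric connectivity weights follow the
    standard fuzzy-union kernel used throughout the single-cell ecosystem.
    """
    import anndata
    import scanpy as sc

    ad = anndata.AnnData(X=np.zeros((scores.shape[0], 1), dtype=np.float32))
    ad.obsm["X_pca"] = np.asarray(scores, dtype=np.float32)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.neighbors(ad, n_neighbors=k_nn + 1, use_rep="X_pca", random_state=seed)
    return sp.csr_matrix(ad.obsp["distances"]), sp.csr_matrix(ad.obsp["connectivities"])


def _louvain(connectivities: sp.csr_matrix, resolution: float, seed: int) -> np.ndarray:
    """Louvain (multilevel) communities on the weighted neighbor graph."""
    coo = sp.triu(connectivities, k=1).tocoo()
    g = igraph.Graph(
        n=connectivities.shape[0],
        edges=list(zip(coo.row.tolist(), coo.col.tolist())),
        edge_attrs={"weight": coo.data.tolist()},
    )
    igraph.set_random_number_generator(_pyrandom.Random(seed))
    part = g.community_multilevel(weights="weight", resolution=resolution)
    igraph.set_random_number_generator(_pyrandom)
    membership = np.asarray(part.membership)
    # relabel by decreasing size, ties by first occurrence, for stable output
    ids, sizes = np.unique(membership, return_counts=True)
    first_seen = np.array([np.argmax(membership == i) for i in ids])
    order = np.lexsort((first_seen, -sizes))
    remap = np.empty(ids.size, dtype=np.int64)
    remap[ids[order]] = np.arange(ids.size)
    return remap[membership]


def run_standard_workflow(
    counts,
    config: WorkflowConfig | None = None,
    gene_names: np.ndarray | None = None,
) -> WorkflowResult:
    """Run the full standard workflow on a genes x cells UMI count matrix."""
    import anndata
    import scanpy as sc

    config = config or WorkflowConfig()
    n_genes, n_cells = counts.shape
    k_nn = config.k_nn(n_cells)
    if n_cells < 2 * k_nn:
        raise ValueError(f"need at least {2 * k_nn} cells for k_nn={k_nn}")

    hvg_idx = _select_hvg(counts, config)
    # normalization totals come from all genes, before restricting to HVGs
    totals = np.asarray(counts.sum(axis=0)).ravel().astype(float)
    totals[totals == 0] = 1.0
    sub = counts[hvg_idx]
    if sp.issparse(sub):
        sub = sub.toarray()
    x = np.log1p(np.asarray(sub, dtype=float) * (config.target_sum / totals))
    x = x.T  # cells x genes
    means = x.mean(axis=0)
    stds = x.std(axis=0, ddof=0)
    keep = stds > 0
    if not keep.all():
        hvg_idx, means, stds, x = hvg_idx[keep], means[keep], stds[keep], x[:, keep]
    xs = (x - means) / stds
    if config.scale_clip is not None:
        np.clip(xs, -config.scale_clip, config.scale_clip, out=xs)

    from sklearn.decomposition import PCA

    n_pcs = max(1, min(config.n_pcs, n_cells - 1, xs.shape[1] - 1))
    pca = PCA(n_components=n_pcs, svd_solver="arpack", random_state=config.seed)
    scores = pca.fit_transform(xs)

    distances, connectivities = build_neighbor_graph(scores, k_nn, config.seed)

    labels = _louvain(connectivities, config.resolution, config.seed)

    embedding = None
    if config.compute_embedding:
        ad = anndata.AnnData(X=np.zeros((n_cells, 1), dtype=np.float32))
        ad.obsm["X_pca"] = scores.astype(np.float32)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc.pp.neighbors(ad, n_neighbors=k_nn + 1, use_rep="X_pca",
                            random_state=config.seed)
            sc.tl.umap(ad, random_state=config.seed)
        embedding = np.asarray(ad.obsm["X_umap"], dtype=float)

    return WorkflowResult(
        config=config,
        n_cells=n_cells,
        k_nn=k_nn,
        hvg_idx=hvg_idx,
        gene_means=means,
        gene_stds=stds,
        pca_mean=pca.mean_.copy(),
        loadings=pca.components_.copy(),
        pc_scores=scores,
        distances=distances,
        connectivities=connectivities,
        cluster_labels=labels,
        embedding=embedding,
        gene_names=None if gene_names is None else np.asarray(gene_names),
    )


def project_onto_loadings(
    counts_subset,
    reference: WorkflowResult,
    gene_names: np.ndarray | None = None,
) -> np.ndarray:
    """Project a cell subset onto a reference workflow's principal components.

    The subset is normalized, log-transformed and standardized with the
    *reference's* statistics and multiplied by the reference loadings; nothing
    is refit.  If ``gene_names`` are supplied for the subset and the reference
    carries gene names, genes are matched by name; reference HVGs missing from
    the subset are imputed at the reference mean (hence zero after centering)
    with a warning.
    """
    ref = reference
    if gene_names is not None and ref.gene_names is not None:
        gene_names = np.asarray(gene_names)
        name_to_row = {g: i for i, g in enumerate(gene_names)}
        ref_hvg_names = ref.gene_names[ref.hvg_idx]
        rows = np.array([name_to_row.get(g, -1) for g in ref_hvg_names])
        missing = rows < 0
        if missing.any():
            warnings.warn(
                f"{int(missing.sum())} reference HVGs absent from the subset; "
                "imputed at the reference mean"
            )
        dense = _log_normalize(counts_subset, ref.config.target_sum)
        x = np.empty((counts_subset.shape[1], ref.hvg_idx.size))
        x[:, ~missing] = dense[rows[~missing]].T
        x[:, missing] = ref.gene_means[missing]
    else:
        if counts_subset.shape[0] <= ref.hvg_idx.max():
            raise ValueError("subset has fewer genes than the reference expects")
        sub = counts_subset
        if sp.issparse(sub):
            # normalize on full totals, then restrict to HVG rows
            totals = np.asarray(sub.sum(axis=0)).ravel().astype(float)
            totals[totals == 0] = 1.0
            x = np.log1p(
                sub[ref.hvg_idx].toarray() * (ref.config.target_sum / totals)
            ).T
        else:
            totals = np.asarray(sub.sum(axis=0)).ravel().astype(float)
            totals[totals == 0] = 1.0
            x = np.log1p(
                np.asarray(sub[ref.hvg_idx], dtype=float) * (ref.config.target_sum / totals)
            ).T
    xs = (x - ref.gene_means) / ref.gene_stds
    if ref.config.scale_clip is not None:
        np.clip(xs, -ref.config.scale_clip, ref.config.scale_clip, out=xs)
    return (xs - ref.pca_mean) @ ref.loadings.T


def compute_paga(neighbor_graph: sp.spmatrix, cluster_labels: np.ndarray) -> AbstractionGraph:
    """PAGA cluster connectivity from the directed kNN graph and a partition.

    For clusters a != b with n_a, n_b cells, e_a total kNN edges incident to
    cluster a (inner + outgoing) and eps_ab inter-cluster edges in either
    direction, the connectivity is

        c_ab = min(1, eps_ab / [(e_a * n_b + e_b * n_a) / (n - 1)]),

    i.e. observed inter-cluster edges relative to their expectation under
    random edge placement given cluster sizes; 0 when eps_ab = 0.
    """
    labels = np.asarray(cluster_labels)
    n = labels.size
    a = sp.csr_matrix(neighbor_graph)
    if a.shape != (n, n):
        raise ValueError("graph size must match number of labels")
    a = a.copy()
    a.data = np.ones_like(a.data)
    ids, codes = np.unique(labels, return_inverse=True)
    n_clusters = ids.size
    member = sp.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, n_clusters)
    )
    inter_dir = np.asarray((member.T @ a @ member).todense())
    sizes = np.bincount(codes, minlength=n_clusters).astype(float)
    es = inter_dir.sum(axis=1)  # edges with source in each cluster
    eps = inter_dir + inter_dir.T
    np.fill_diagonal(eps, 0.0)
    expected = (es[:, None] * sizes[None, :] + es[None, :] * sizes[:, None]) / max(n - 1, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        conn = np.where(eps > 0, np.minimum(eps / expected, 1.0), 0.0)
    np.fill_diagonal(conn, 0.0)
    graph = AbstractionGraph(node_sizes=sizes.astype(int), connectivity=conn)
    graph.validate()
    return graph
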
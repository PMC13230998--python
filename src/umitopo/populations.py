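"""Benchmark cell populations with ground-truth labels and heterogeneous depth.

Three populations probe distinct failure modes of manifold inference:

* ``X`` — cell-*type* discrimination: 2,000 cells from the combined model
  ("Cell1") plus 1,000 each from two independent gene-identity permutations
  ("Cell2", "Cell3"), i.e. three completely distinct transcriptomes.
* ``Y`` — cell-*state* discrimination: 2,000 Cell1 plus 2,000 "Cell4", where
  Cell4 scales 300 random expressed genes by 2 or 0.5 (pathway activation).
* ``Z`` — a step-wise lineage A -> B -> C -> {D, E}: B scales 300 genes by
  1.67/0.6, C re-applies the *same* genes and directions, and D/E each
  derepress 10 silent genes to 50 molecules.

Every cell is observed at an independent depth drawn from the clamped normal
law (mean 5,000, sd 1,500, floor 500), which is the heterogeneity under study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import scipy.sparse as sp

from .models import (
    GeneFractionModel,
    build_fraction_model,
    derepress_genes,
    draw_depths,
    permute_gene_identities,
    sample_cell_counts,
    scale_gene_subset,
)

__all__ = [
    "CellPopulation",
    "simulate_population_X",
    "simulate_population_Y",
    "simulate_population_Z",
    "filter_by_total_umi",
    "top_n_by_total_umi",
    "sample_state_cells",
]

logger = logging.getLogger(__name__)


@dataclass
class CellPopulation:
    """Genes x cells integer UMI matrix with ground-truth state labels."""

    counts: sp.csc_matrix  # n_genes x n_cells
    labels: np.ndarray  # per-cell state name
    depths: np.ndarray  # per-cell total UMI (column sums)
    provenance: dict[str, Any] = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def validate(self) -> None:
        if self.counts.shape[1] != len(self.labels) or len(self.labels) != len(self.depths):
            raise ValueError("counts, labels and depths disagree on cell count")
        col_sums = np.asarray(self.counts.sum(axis=0)).ravel()
        if not np.array_equal(col_sums, self.depths):
            raise ValueError("depths must equal column sums of counts")
        states = self.provenance.get("states")
        if states is not None and not set(self.labels) <= set(states):
            raise ValueError("labels outside the declared state set")

    def subset(self, cell_idx: np.ndarray, note: str | None = None) -> "CellPopulation":
        prov = dict(self.provenance)
        if note:
            prov = {**prov, "subset": note}
        return CellPopulation(
            counts=self.counts[:, cell_idx].tocsc(),
            labels=self.labels[cell_idx],
            depths=self.depths[cell_idx],
            provenance=prov,
        )


def sample_state_cells(
    model: GeneFractionModel,
    n_cells: int,
    rng: np.random.Generator,
    depth_mean: float = 5_000,
    depth_sd: float = 1_500,
    depth_floor: int = 500,
) -> tuple[sp.csc_matrix, np.ndarray]:
    """Sample ``n_cells`` observations of one state: depth draw then multinomial."""
    depths = draw_depths(n_cells, mean=depth_mean, sd=depth_sd, floor=depth_floor, rng=rng)
    expressed = model.expressed_indices
    p = model.p[expressed]
    data, rows, indptr = [], [], [0]
    for d in depths:
        c = rng.multinomial(int(d), p)
        nz = np.flatnonzero(c)
        rows.append(expressed[nz])
        data.append(c[nz])
        indptr.append(indptr[-1] + nz.size)
    mat = sp.csc_matrix(
        (np.concatenate(data), np.concatenate(rows), np.asarray(indptr)),
        shape=(model.n_genes, n_cells),
        dtype=np.int64,
    )
    return mat, depths


def _assemble(
    blocks: Sequence[tuple[str, sp.csc_matrix, np.ndarray]],
    name: str,
    models: dict[str, GeneFractionModel],
    seed_info: dict[str, int],
) -> CellPopulation:
    counts = sp.hstack([b[1] for b in blocks], format="csc")
    labels = np.concatenate([[b[0]] * b[1].shape[1] for b in blocks])
    depths = np.concatenate([b[2] for b in blocks])
    pop = CellPopulation(
        counts=counts,
        labels=labels,
        depths=depths,
        provenance={
            "population": name,
            "states": [b[0] for b in blocks],
            "seeds": seed_info,
            "models": {state: m.to_json() for state, m in models.items()},
        },
    )
    pop.validate()
    return pop


def simulate_population_X(
    rng: np.random.Generator | int | None = None,
    cells_per_state: tuple[int, int, int] = (2_000, 1_000, 1_000),
) -> CellPopulation:
    """Three distinct cell types: the combined model and two gene-identity permutations."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    base = build_fraction_model("combined")
    seed2, seed3 = (int(s) for s in rng.integers(0, 2**31, size=2))
    m2 = permute_gene_identities(base, seed=seed2)
    m3 = permute_gene_identities(base, seed=seed3)
    blocks = []
    for state, model, n in zip(("Cell1", "Cell2", "Cell3"), (base, m2, m3), cells_per_state):
        mat, depths = sample_state_cells(model, n, rng)
        blocks.append((state, mat, depths))
    return _assemble(blocks, "X", {"Cell1": base, "Cell2": m2, "Cell3": m3},
                     {"perm_Cell2": seed2, "perm_Cell3": seed3})


def simulate_population_Y(
    rng: np.random.Generator | int | None = None,
    cells_per_state: tuple[int, int] = (2_000, 2_000),
) -> CellPopulation:
    """Two cell states: the combined model and a 300-gene 2x/0.5x pathway edit."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    base = build_fraction_model("combined")
    m4 = scale_gene_subset(base, rng=rng, up_factor=2.0, down_factor=0.5, n_select=300)
    blocks = []
    for state, model, n in zip(("Cell1", "Cell4"), (base, m4), cells_per_state):
        mat, depths = sample_state_cells(model, n, rng)
        blocks.append((state, mat, depths))
    return _assemble(blocks, "Y", {"Cell1": base, "Cell4": m4}, {})


def simulate_population_Z(
    rng: np.random.Generator | int | None = None,
    cells_per_state: int = 1_000,
) -> CellPopulation:
    """Step-wise lineage A -> B -> C -> {D, E} with 1,000 cells per state.

    B and C apply the same 300-gene 1.67x/0.6x edit twice in the same
    directions (progressive pathway activation); D and E independently
    derepress 10 silent genes each to 50 molecules.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    a = build_fraction_model("combined")
    b = scale_gene_subset(a, rng=rng, up_factor=1.67, down_factor=0.6, n_select=300)
    edit = b.recipe[-1]
    c = scale_gene_subset(
        b,
        gene_ids=np.asarray(edit["gene_ids"]),
        directions=np.asarray(edit["directions"]),
        up_factor=1.67,
        down_factor=0.6,
    )
    d = derepress_genes(c, n_select=10, target_count=50, rng=rng)
    e = derepress_genes(c, n_select=10, target_count=50, rng=rng)
    models = {"A": a, "B": b, "C": c, "D": d, "E": e}
    blocks = []
    for state in "ABCDE":
        mat, depths = sample_state_cells(models[state], cells_per_state, rng)
        blocks.append((state, mat, depths))
    return _assemble(blocks, "Z", models, {})


def filter_by_total_umi(pop: CellPopulation, threshold: float) -> CellPopulation:
    """Keep cells with total UMI strictly greater than ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    keep = np.flatnonzero(pop.depths > threshold)
    if keep.size == 0:
        logger.warning("depth filter at %s removed every cell", threshold)
    return pop.subset(keep, note=f"total_umi>{threshold}")


def top_n_by_total_umi(pop: CellPopulation, n: int) -> CellPopulation:
    """The n deepest cells; ties broken by ascending original column index."""
    if not 0 <= n <= pop.n_cells:
        raise ValueError("n must be between 0 and the number of cells")
    # stable sort on -depth keeps original order among ties
    order = np.argsort(-pop.depths, kind="stable")[:n]
    return pop.subset(np.sort(order), note=f"top_{n}_by_umi")
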
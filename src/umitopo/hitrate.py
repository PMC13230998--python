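"""Random-walk hit rates and topological stability protocols.

Cells are split by a total-UMI threshold into high-information and
low-information sets.  For each low-information cell, the *hit rate* is the
probability that a k-step random walk on the weighted neighbor graph (edge
transition probability proportional to incident edge weight) reaches any
high-information cell at least once.  Low-information cells that lie close to
the manifold spanned by high-information cells escape quickly; cells trapped
in spuriously interconnected shallow regions do not.

Stability protocols built on the hit rate:

* progressive removal — discard the bottom 10%, 20%, ... 100% of
  low-information cells by hit rate and track (clusters, beta0, beta1) of the
  re-fitted abstraction graph;
* fixed-size subsampling — repeatedly subsample a fixed number of cells from
  a population and collect the beta1 distribution;
* hyperparameter sweeps over neighbor fraction, walk length and clustering
  resolution.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .populations import CellPopulation, filter_by_total_umi
from .topology import TopologySummary, betti_numbers, threshold_abstraction
from .workflow import WorkflowConfig, WorkflowResult, compute_paga, run_standard_workflow

__all__ = [
    "InformationLabels",
    "HitRateTable",
    "RemovalCurve",
    "SubsampleDistribution",
    "label_by_depth",
    "compute_hit_rate",
    "exact_hit_probability",
    "progressive_removal_curve",
    "subsample_beta1",
    "spearman_hitrate_vs_depth",
    "hyperparameter_sweep",
    "abstraction_topology",
]

logger = logging.getLogger(__name__)


@dataclass
class InformationLabels:
    """Per-cell high/low-information flag from a strict depth threshold."""

    high: np.ndarray  # boolean, True = high-information
    depth_threshold: float

    @property
    def n_high(self) -> int:
        return int(self.high.sum())

    @property
    def n_low(self) -> int:
        return int((~self.high).sum())


@dataclass
class HitRateTable:
    """Hit rate per low-information cell."""

    low_indices: np.ndarray  # cell indices of the low-information cells
    rates: np.ndarray  # in [0, 1], aligned with low_indices
    k_walk: int
    trials: int

    def to_frame(self, depths: np.ndarray | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"cell": self.low_indices, "hit_rate": self.rates})
        if depths is not None:
            df.insert(1, "depth", np.asarray(depths)[self.low_indices])
        return df


@dataclass
class RemovalCurve:
    """Topology of the abstraction graph as low-information cells are removed."""

    fractions: np.ndarray
    summaries: list[TopologySummary]
    n_clusters: list[int]
    kept_indices: list[np.ndarray]

    def to_json(self) -> str:
        return json.dumps(
            [
                {"fraction": float(f), "n_clusters": c, **s.to_dict()}
                for f, c, s in zip(self.fractions, self.n_clusters, self.summaries)
            ]
        )


@dataclass
class SubsampleDistribution:
    """beta1 values over repeated fixed-size subsamples of one population."""

    beta1: np.ndarray
    n_cells: int
    repeats: int
    tag: str
    seeds: np.ndarray
    config: WorkflowConfig = field(default_factory=WorkflowConfig)

    def median(self) -> float:
        return float(np.median(self.beta1))


def label_by_depth(pop: CellPopulation, depth_threshold: float) -> InformationLabels:
    """Strict split: high-information iff total UMI > threshold."""
    if depth_threshold < 0:
        raise ValueError("depth_threshold must be >= 0")
    high = pop.depths > depth_threshold
    if high.all() or not high.any():
        warnings.warn(
            f"depth threshold {depth_threshold} puts all {pop.n_cells} cells "
            "on one side; downstream diagnostics may be vacuous"
        )
    return InformationLabels(high=high, depth_threshold=float(depth_threshold))


def _row_cumulative(graph: sp.csr_matrix):
    """Per-row cumulative edge weights for categorical neighbor sampling."""
    g = sp.csr_matrix(graph)
    if g.data.size and np.any(g.data <= 0):
        raise ValueError("edge weights must be positive")
    row_lens = np.diff(g.indptr)
    cs = np.cumsum(g.data) if g.data.size else np.array([])
    offsets = np.repeat(np.concatenate(([0.0], cs))[g.indptr[:-1]], row_lens)
    cum = cs - offsets if g.data.size else cs
    row_sums = np.asarray(g.sum(axis=1)).ravel()
    return g, cum, row_sums


def compute_hit_rate(
    neighbor_graph: sp.spmatrix,
    labels: InformationLabels,
    k_walk: int = 5,
    trials: int = 1_000,
    rng: np.random.Generator | int | None = None,
) -> HitRateTable:
    """Monte-Carlo hit rate for every low-information cell.

    Each trial is a weighted random walk of at most ``k_walk`` steps starting
    from the low cell; transition probabilities are the row-normalized edge
    weights, with no self-transitions.  The walk is absorbed at the first
    high-information vertex (continuing would not change the hit indicator).
    The starting vertex itself never counts as a hit.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    high = labels.high
    g, cum, row_sums = _row_cumulative(neighbor_graph)
    low_idx = np.flatnonzero(~high)
    n_low = low_idx.size
    hits = np.zeros(n_low, dtype=np.int64)

    isolated = row_sums[low_idx] == 0
    if isolated.any():
        logger.warning("%d isolated low-information cells have hit rate 0",
                       int(isolated.sum()))
    active_owner = np.repeat(np.flatnonzero(~isolated), trials)
    cur = low_idx[active_owner]
    for _ in range(k_walk):
        if cur.size == 0:
            break
        nxt = np.empty_like(cur)
        order = np.argsort(cur, kind="stable")
        sorted_nodes = cur[order]
        uniq, starts = np.unique(sorted_nodes, return_index=True)
        bounds = np.append(starts, sorted_nodes.size)
        for u, s, e in zip(uniq, bounds[:-1], bounds[1:]):
            lo, hi = g.indptr[u], g.indptr[u + 1]
            if lo == hi:  # stuck walker: stays put, can never hit
                nxt[order[s:e]] = u
                continue
            draws = rng.random(e - s) * row_sums[u]
            pick = np.searchsorted(cum[lo:hi], draws, side="right")
            nxt[order[s:e]] = g.indices[lo + np.minimum(pick, hi - lo - 1)]
        hit = high[nxt]
        np.add.at(hits, active_owner[hit], 1)
        keep = ~hit
        cur = nxt[keep]
        active_owner = active_owner[keep]
    return HitRateTable(
        low_indices=low_idx, rates=hits / trials, k_walk=k_walk, trials=trials
    )


def exact_hit_probability(
    neighbor_graph: sp.spmatrix, labels: InformationLabels, k_walk: int
) -> np.ndarray:
    """Closed-form absorption probability within ``k_walk`` steps per low cell.

    Powers the substochastic transition matrix restricted to low-information
    vertices: survival after k steps is Q^k 1, hit probability its complement.
    Isolated low vertices (no neighbors at all) have probability 0.
    """
    high = labels.high
    g = sp.csr_matrix(neighbor_graph).astype(float)
    row_sums = np.asarray(g.sum(axis=1)).ravel()
    low_idx = np.flatnonzero(~high)
    inv = np.zeros_like(row_sums)
    nz = row_sums > 0
    inv[nz] = 1.0 / row_sums[nz]
    p = sp.diags(inv) @ g
    q = p[low_idx][:, low_idx]
    survival = np.ones(low_idx.size)
    for _ in range(k_walk):
        survival = q @ survival
    prob = 1.0 - survival
    prob[row_sums[low_idx] == 0] = 0.0  # stuck forever, never hits
    return prob


def _low_removal_order(
    hit_table: HitRateTable, depths: np.ndarray
) -> np.ndarray:
    """Low cells ordered by ascending hit rate; ties by depth then cell index."""
    li = hit_table.low_indices
    return li[np.lexsort((li, np.asarray(depths)[li], hit_table.rates))]


def abstraction_topology(
    pop: CellPopulation,
    config: WorkflowConfig,
    tau: float = 0.05,
) -> tuple[WorkflowResult, TopologySummary]:
    """Workflow + PAGA + threshold + Betti numbers in one call."""
    result = run_standard_workflow(pop.counts, config)
    ag = compute_paga(result.distances, result.cluster_labels)
    summary = betti_numbers(threshold_abstraction(ag, tau), threshold=tau)
    return result, summary


def progressive_removal_curve(
    pop: CellPopulation,
    hit_table: HitRateTable,
    config: WorkflowConfig,
    fractions: np.ndarray | None = None,
    tau: float = 0.05,
) -> RemovalCurve:
    """Remove rising fractions of low-information cells and track topology.

    At fraction f, round(f * n_low) low cells with the lowest hit rates are
    dropped, the workflow is re-run on the remainder (the neighbor count
    follows the new population size), and the thresholded abstraction graph's
    (clusters, beta0, beta1) are recorded.  Fraction 1.0 leaves exactly the
    high-information subset.
    """
    if fractions is None:
        fractions = np.round(np.arange(0.0, 1.01, 0.1), 10)
    fractions = np.asarray(fractions, dtype=float)
    if np.any((fractions < 0) | (fractions > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    order = _low_removal_order(hit_table, pop.depths)
    summaries, n_clusters, kept_list = [], [], []
    for f in fractions:
        n_rm = int(round(f * order.size))
        removed = set(order[:n_rm].tolist())
        kept = np.array([i for i in range(pop.n_cells) if i not in removed])
        sub = pop.subset(kept, note=f"hitrate_removal_{f:.1f}")
        result, summary = abstraction_topology(sub, config, tau=tau)
        summaries.append(summary)
        n_clusters.append(int(np.unique(result.cluster_labels).size))
        kept_list.append(kept)
    return RemovalCurve(
        fractions=fractions, summaries=summaries, n_clusters=n_clusters,
        kept_indices=kept_list,
    )


def subsample_beta1(
    pop: CellPopulation,
    n_cells: int = 1_500,
    repeats: int = 100,
    config: WorkflowConfig | None = None,
    rng: np.random.Generator | int | None = None,
    tau: float = 0.05,
    tag: str = "",
) -> SubsampleDistribution:
    """beta1 distribution over repeated uniform subsamples of fixed size.

    Each draw gets its own seed spawned from the master generator, used both
    for the subsample and for the workflow, so the whole experiment is
    reproducible from one master seed.
    """
    if n_cells > pop.n_cells:
        raise ValueError("n_cells exceeds the population size")
    config = config or WorkflowConfig()
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    seeds = rng.integers(0, 2**31, size=repeats)
    beta1 = np.zeros(repeats, dtype=np.int64)
    for r, seed in enumerate(seeds):
        sub_rng = np.random.default_rng(int(seed))
        idx = np.sort(sub_rng.choice(pop.n_cells, size=n_cells, replace=False))
        sub = pop.subset(idx, note=f"subsample_{r}")
        _, summary = abstraction_topology(sub, replace(config, seed=int(seed)), tau=tau)
        beta1[r] = summary.beta1
    return SubsampleDistribution(
        beta1=beta1, n_cells=n_cells, repeats=repeats, tag=tag, seeds=seeds,
        config=config,
    )


def spearman_hitrate_vs_depth(
    hit_table: HitRateTable, depths: np.ndarray
) -> tuple[float, float]:
    """Spearman rank correlation between hit rate and total UMI count.

    ``depths`` may cover all cells (it is sliced to the low-information set)
    or exactly the low-information cells.  Constant input yields (nan, nan).
    """
    depths = np.asarray(depths)
    if depths.size == hit_table.rates.size:
        d = depths
    else:
        d = depths[hit_table.low_indices]
    if d.size < 3:
        raise ValueError("need at least 3 low-information cells")
    if np.all(d == d[0]) or np.all(hit_table.rates == hit_table.rates[0]):
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(d, hit_table.rates)
    return float(rho), float(p)


def hyperparameter_sweep(
    pop: CellPopulation,
    grid: list[dict],
    depth_threshold: float,
    rng: np.random.Generator | int | None = None,
    n_cells: int = 1_500,
    repeats: int = 100,
    base_config: WorkflowConfig | None = None,
    trials: int = 1_000,
    tau: float = 0.05,
) -> pd.DataFrame:
    """beta1 subsample distributions across hyperparameter settings.

    Each grid entry may override ``neighbor_fraction``, ``resolution`` and
    ``k_walk``.  Per setting, hit rates are recomputed on the full population,
    three variants are formed — the full population, the population with the
    bottom 50% of low-information cells (by hit rate) removed, and the
    high-information subset — and each is subsampled ``repeats`` times.

    Returns a tidy frame with one row per draw:
    (neighbor_fraction, resolution, k_walk, population, draw, beta1).
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    base_config = base_config or WorkflowConfig()
    rows = []
    for setting in grid:
        cfg = replace(
            base_config,
            neighbor_fraction=setting.get("neighbor_fraction", base_config.neighbor_fraction),
            resolution=setting.get("resolution", base_config.resolution),
        )
        k_walk = setting.get("k_walk", 5)
        result = run_standard_workflow(pop.counts, cfg)
        labels = label_by_depth(pop, depth_threshold)
        table = compute_hit_rate(
            result.connectivities, labels, k_walk=k_walk, trials=trials,
            rng=np.random.default_rng(int(rng.integers(0, 2**31))),
        )
        order = _low_removal_order(table, pop.depths)
        removed = set(order[: order.size // 2].tolist())
        kept = np.array([i for i in range(pop.n_cells) if i not in removed])
        variants = {
            "full": pop,
            "hit50": pop.subset(kept, note="hitrate_bottom50_removed"),
            "deep": filter_by_total_umi(pop, depth_threshold),
        }
        for name, variant in variants.items():
            dist = subsample_beta1(
                variant, n_cells=min(n_cells, variant.n_cells), repeats=repeats,
                config=cfg, rng=np.random.default_rng(int(rng.integers(0, 2**31))),
                tau=tau, tag=name,
            )
            for draw, b1 in enumerate(dist.beta1):
                rows.append(
                    {
                        "neighbor_fraction": cfg.neighbor_fraction,
                        "resolution": cfg.resolution,
                        "k_walk": k_walk,
                        "population": name,
                        "draw": draw,
                        "beta1": int(b1),
                    }
                )
    return pd.DataFrame(rows)
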
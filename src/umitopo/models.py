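"""Gene-fraction models of the per-cell cDNA pool and UMI-multiplicity spectra.

A single simulated cell state is a probability vector ``p`` over a fixed gene
panel (36,601 genes by default, matching a standard human reference).  Genes
are indexed in ascending order of their pool fraction, ``p_1 <= ... <= p_n``,
and only the top ~10,000 indices (``i >= 26,601``) are expressed at all.  Raw
molecule counts ``f_i`` grow with the rank index either linearly, exponentially
or as the sum of both ("combined"); ``p = f / sum(f)``.

Observation of a cell at depth ``D`` is a draw of ``D`` unique molecules from
the pool — a multinomial over ``p``.  The expected number of genes seen exactly
``k`` times, ``E[N_k] = sum_i P(X_i = k)``, is available in closed form under
Poisson (``X_i ~ Pois(D p_i)``) or negative-binomial (mean ``D p_i``,
dispersion ``theta``) sampling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import stats

__all__ = [
    "GeneFractionModel",
    "SamplingSpec",
    "ExpectedNkCurve",
    "build_fraction_model",
    "permute_gene_identities",
    "scale_gene_subset",
    "derepress_genes",
    "expected_nk",
    "sample_cell_counts",
    "draw_depth",
    "draw_depths",
]

N_GENES_DEFAULT = 36_601
FIRST_EXPRESSED_DEFAULT = 26_601
DEFAULT_PARAMS = {
    "linear_offset": 26_301,
    "linear_divisor": 300,
    "exp_center": 36_000,
    "exp_scale": 75,
}


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (unlike np.round)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass
class GeneFractionModel:
    """Ranked per-gene cDNA-pool fractions describing one cell state.

    ``f`` holds raw molecule counts (integral for the linear and combined
    models), ``p`` the normalized pool fractions.  ``recipe`` records the
    chain of edit operations that produced the model so it can be rebuilt
    exactly from JSON.
    """

    n_genes: int
    first_expressed_index: int  # 1-based; p == 0 strictly below this index
    kind: str  # linear | exponential | combined | edited
    f: np.ndarray
    p: np.ndarray
    params: dict[str, Any] = field(default_factory=lambda: dict(DEFAULT_PARAMS))
    integral: bool = True
    recipe: list[dict[str, Any]] = field(default_factory=list)

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not (1 <= self.first_expressed_index <= self.n_genes):
            raise ValueError("first_expressed_index out of range")
        if self.f.shape != (self.n_genes,) or self.p.shape != (self.n_genes,):
            raise ValueError("f and p must have length n_genes")
        if np.any(self.f < 0):
            raise ValueError("raw weights must be non-negative")
        if abs(self.p.sum() - 1.0) > 1e-12:
            raise ValueError("p must sum to 1")
        if np.any(self.p[: self.first_expressed_index - 1] != 0):
            raise ValueError("p must vanish below first_expressed_index")

    @property
    def expressed_indices(self) -> np.ndarray:
        """0-based indices of genes with p > 0."""
        return np.flatnonzero(self.p > 0)

    # -- reproducible serialization ------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_genes": self.n_genes,
                "params": {k: v for k, v in self.params.items()},
                "recipe": self.recipe,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GeneFractionModel":
        payload = json.loads(text)
        model: GeneFractionModel | None = None
        for step in payload["recipe"]:
            op = step["op"]
            if op == "build":
                model = build_fraction_model(
                    step["kind"], n_genes=payload["n_genes"], params=payload["params"]
                )
            elif op == "permute":
                model = permute_gene_identities(model, seed=step["seed"])
            elif op == "scale":
                model = scale_gene_subset(
                    model,
                    gene_ids=np.asarray(step["gene_ids"]),
                    directions=np.asarray(step["directions"]),
                    up_factor=step["up_factor"],
                    down_factor=step["down_factor"],
                )
            elif op == "derepress":
                model = derepress_genes(
                    model,
                    gene_ids=np.asarray(step["gene_ids"]),
                    target_count=step["target_count"],
                )
            else:  # pragma: no cover - corrupt recipe
                raise ValueError(f"unknown recipe op {op!r}")
        if model is None:
            raise ValueError("empty recipe")
        return model


@dataclass(frozen=True)
class SamplingSpec:
    """Observation law for a single cell: family, depth D, NB dispersion."""

    family: str  # poisson | negbin
    depth: int
    dispersion: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("poisson", "negbin"):
            raise ValueError("family must be 'poisson' or 'negbin'")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.family == "negbin":
            if self.dispersion is None:
                raise ValueError("negbin sampling requires a dispersion theta")
            if self.dispersion <= 0:
                raise ValueError("dispersion theta must be positive")


@dataclass
class ExpectedNkCurve:
    """E[N_k] for k = 0..k_max plus the probability mass beyond k_max."""

    k_max: int
    values: np.ndarray  # length k_max + 1, entry k = E[N_k]
    spec: SamplingSpec
    truncation_mass: float

    def total_genes(self) -> float:
        return float(self.values.sum() + self.truncation_mass)

    def total_umis(self) -> float:
        k = np.arange(self.k_max + 1)
        return float((k * self.values).sum())


def build_fraction_model(
    kind: str,
    n_genes: int = N_GENES_DEFAULT,
    params: dict[str, Any] | None = None,
    first_expressed_index: int = FIRST_EXPRESSED_DEFAULT,
) -> GeneFractionModel:
    """Construct the linear, exponential or combined pool-fraction model.

    Linear:      f_i = max(0, floor((i - 26,301) / 300))
    Exponential: f_i = exp((i - 36,000) / 75)
    Combined:    sum of both, rounded half-away-from-zero to an integer
                 molecule count (the exponential term is only applied from
                 the exponential onset index upward, where it is the model's
                 stated regime; below it the term is < e^-125 and vanishes
                 under rounding anyway).

    In every model f is forced to 0 below ``first_expressed_index`` so that
    only ~10,000 genes are expressible; ``p = f / sum(f)``.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    if first_expressed_index > n_genes:
        raise ValueError("first_expressed_index exceeds n_genes")
    if kind not in ("linear", "exponential", "combined"):
        raise ValueError(f"unknown model kind {kind!r}")
    p_all = dict(DEFAULT_PARAMS)
    if params:
        p_all.update(params)
    if p_all["linear_divisor"] <= 0 or p_all["exp_scale"] <= 0:
        raise ValueError("model parameters must be positive")

    i = np.arange(1, n_genes + 1, dtype=float)  # 1-based gene index
    linear = np.maximum(0.0, np.floor((i - p_all["linear_offset"]) / p_all["linear_divisor"]))
    expo = np.exp((i - p_all["exp_center"]) / p_all["exp_scale"])

    if kind == "linear":
        f = linear
        integral = True
    elif kind == "exponential":
        f = expo
        integral = False
    else:
        f = _round_half_away(linear + np.where(i >= p_all["exp_center"], expo, 0.0))
        integral = True
    f[: first_expressed_index - 1] = 0.0
    if f.sum() <= 0:
        raise ValueError("model has no expressible mass")
    p = f / f.sum()
    model = GeneFractionModel(
        n_genes=n_genes,
        first_expressed_index=first_expressed_index,
        kind=kind,
        f=f,
        p=p,
        params=p_all,
        integral=integral,
        recipe=[{"op": "build", "kind": kind}],
    )
    model.validate()
    return model


def _edited_copy(model: GeneFractionModel, f_new: np.ndarray, step: dict[str, Any],
                 first_expressed_index: int | None = None) -> GeneFractionModel:
    p_new = f_new / f_new.sum()
    fei = first_expressed_index
    if fei is None:
        expressed = np.flatnonzero(p_new > 0)
        fei = int(expressed[0]) + 1 if expressed.size else model.first_expressed_index
    out = GeneFractionModel(
        n_genes=model.n_genes,
        first_expressed_index=fei,
        kind="edited",
        f=f_new,
        p=p_new,
        params=dict(model.params),
        integral=model.integral,
        recipe=model.recipe + [step],
    )
    out.validate()
    return out


def permute_gene_identities(model: GeneFractionModel, seed: int) -> GeneFractionModel:
    """Assign the same pool fractions to a uniformly random set of gene slots.

    Models a completely distinct cell type: expression levels are preserved
    as a multiset but attached to different gene identities.
    """
    model.validate()
    perm = np.random.default_rng(seed).permutation(model.n_genes)
    return _edited_copy(model, model.f[perm], {"op": "permute", "seed": int(seed)})


def scale_gene_subset(
    model: GeneFractionModel,
    gene_ids: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
    up_factor: float = 2.0,
    down_factor: float = 0.5,
    n_select: int = 300,
    select_range: tuple[int, int] = (26_602, 36_601),
    directions: np.ndarray | None = None,
) -> GeneFractionModel:
    """Scale a random expressed-gene subset up or down, modeling pathway activation.

    Each selected gene's molecule count is multiplied by ``up_factor`` or
    ``down_factor``, with direction drawn Bernoulli(1/2) per gene.  When
    ``gene_ids`` (1-based) and ``directions`` (+1 up / -1 down) are supplied,
    the same edit is re-applied — this is how a second activation step
    progresses the same pathway in the same directions.  The selected ids and
    directions are recorded on the returned model's recipe for reuse.
    """
    model.validate()
    if up_factor <= 0 or down_factor <= 0:
        raise ValueError("scale factors must be positive")
    rng = _as_rng(rng)
    if gene_ids is None:
        lo, hi = select_range
        if not (1 <= lo <= hi <= model.n_genes):
            raise ValueError("selection range outside the gene panel")
        if n_select > hi - lo + 1:
            raise ValueError("n_select exceeds the selection range")
        gene_ids = rng.choice(np.arange(lo, hi + 1), size=n_select, replace=False)
        gene_ids = np.sort(gene_ids)
    else:
        gene_ids = np.asarray(gene_ids, dtype=int)
        if gene_ids.size == 0:
            raise ValueError("empty gene selection")
    if directions is None:
        directions = np.where(rng.random(gene_ids.size) < 0.5, 1, -1)
    else:
        directions = np.asarray(directions, dtype=int)
    factors = np.where(directions > 0, up_factor, down_factor)
    f_new = model.f.copy()
    f_new[gene_ids - 1] = f_new[gene_ids - 1] * factors
    if model.integral:
        f_new = _round_half_away(f_new)
    step = {
        "op": "scale",
        "gene_ids": [int(g) for g in gene_ids],
        "directions": [int(d) for d in directions],
        "up_factor": float(up_factor),
        "down_factor": float(down_factor),
    }
    return _edited_copy(model, f_new, step,
                        first_expressed_index=model.first_expressed_index)


def derepress_genes(
    model: GeneFractionModel,
    n_select: int = 10,
    target_count: float = 50,
    candidate_upper: int = FIRST_EXPRESSED_DEFAULT,
    rng: np.random.Generator | int | None = None,
    gene_ids: np.ndarray | None = None,
) -> GeneFractionModel:
    """Force silent genes on, modeling epigenetic derepression.

    ``n_select`` genes drawn without replacement from gene ids 1..candidate_upper
    have their molecule count set to ``target_count``.
    """
    model.validate()
    if target_count <= 0:
        raise ValueError("target_count must be positive")
    if gene_ids is None:
        if n_select == 0:
            return _edited_copy(model, model.f.copy(),
                                {"op": "derepress", "gene_ids": [],
                                 "target_count": float(target_count)},
                                first_expressed_index=model.first_expressed_index)
        if candidate_upper < 1 or candidate_upper > model.n_genes:
            raise ValueError("candidate range outside the gene panel")
        if n_select > candidate_upper:
            raise ValueError("n_select exceeds the candidate range")
        gene_ids = np.sort(
            _as_rng(rng).choice(np.arange(1, candidate_upper + 1), size=n_select,
                                replace=False)
        )
    else:
        gene_ids = np.asarray(gene_ids, dtype=int)
    f_new = model.f.copy()
    f_new[gene_ids - 1] = target_count
    step = {
        "op": "derepress",
        "gene_ids": [int(g) for g in gene_ids],
        "target_count": float(target_count),
    }
    return _edited_copy(model, f_new, step)


def _tail_quantile(lam_max: float, spec: SamplingSpec, tail: float = 1e-12) -> int:
    """Smallest k whose survival mass is below ``tail`` for the largest gene."""
    if spec.family == "poisson":
        k = stats.poisson.ppf(1 - tail, lam_max)
    else:
        theta = spec.dispersion
        k = stats.nbinom.ppf(1 - tail, theta, theta / (theta + lam_max))
    return int(max(k, 1))


def expected_nk(
    model: GeneFractionModel,
    spec: SamplingSpec,
    k_max: int | None = None,
    chunk: int = 2_000,
) -> ExpectedNkCurve:
    """Expected multiplicity spectrum E[N_k] = sum_i P(X_i = k), k = 0..k_max.

    Poisson: X_i ~ Pois(D p_i).  Negative binomial: mean D p_i, dispersion
    theta (variance mu + mu^2/theta).  Genes with p_i = 0 contribute wholly
    to k = 0.  If ``k_max`` is omitted, each gene is evaluated out to its own
    1e-12 survival quantile (heavy NB tails would otherwise lose visible UMI
    mass) and the curve extends to the largest such k; the truncated mass is
    reported either way.
    """
    model.validate()
    expressed = model.expressed_indices
    lam = np.sort(spec.depth * model.p[expressed])  # ascending: short tails first
    adaptive = k_max is None
    if adaptive:
        k_max = _tail_quantile(float(lam[-1]), spec)
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    values = np.zeros(k_max + 1)
    theta = spec.dispersion
    for start in range(0, lam.size, chunk):
        lam_c = lam[start : start + chunk]
        # evaluate this chunk only out to its own tail quantile
        k_hi = _tail_quantile(float(lam_c[-1]), spec) if adaptive else k_max
        k_hi = min(k_hi, k_max)
        k = np.arange(k_hi + 1, dtype=float)
        if spec.family == "poisson":
            pmf = stats.poisson.pmf(k[None, :], lam_c[:, None])
        else:
            pmf = stats.nbinom.pmf(k[None, :], theta, theta / (theta + lam_c[:, None]))
        values[: k_hi + 1] += pmf.sum(axis=0)
    values[0] += model.n_genes - expressed.size  # silent genes: always k = 0
    truncation = float(model.n_genes - values.sum())
    return ExpectedNkCurve(k_max=k_max, values=values, spec=spec,
                           truncation_mass=truncation)


def sample_cell_counts(
    model: GeneFractionModel, depth: int, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Draw one cell's UMI count vector: a multinomial of ``depth`` molecules.

    All molecules in the pool are equally likely and each capture carries a
    distinct UMI, so the observed counts are a single multinomial draw over p.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    model.validate()
    rng = _as_rng(rng)
    counts = np.zeros(model.n_genes, dtype=np.int64)
    expressed = model.expressed_indices
    counts[expressed] = rng.multinomial(depth, model.p[expressed])
    return counts


def draw_depth(
    mean: float = 5_000,
    sd: float = 1_500,
    floor: int = 500,
    rng: np.random.Generator | int | None = None,
) -> int:
    """One per-cell observation depth: round(Normal(mean, sd)) clamped at floor."""
    return int(draw_depths(1, mean=mean, sd=sd, floor=floor, rng=rng)[0])


def draw_depths(
    n: int,
    mean: float = 5_000,
    sd: float = 1_500,
    floor: int = 500,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Vector of per-cell depths under the clamped-normal observation law."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if floor < 1:
        raise ValueError("floor must be >= 1")
    rng = _as_rng(rng)
    d = np.rint(rng.normal(mean, sd, size=n)).astype(np.int64)
    return np.maximum(d, floor)
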
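# umitopo

Simulation of heterogeneous single-cell UMI observations and topology-guided
diagnostics for manifold inference.

## The problem

Droplet-based scRNA-seq observes each cell at a different depth: per-cell
total UMI counts commonly range from a few hundred to tens of thousands
within one library. Manifold-based analysis — PCA, kNN neighbor graphs,
Louvain clustering, PAGA graph abstraction — implicitly assumes uniformly
informative observations. When shallowly and deeply observed cells are mixed,
shallow cells drift toward one another in expression space, form spurious
subclusters and hub-like bridges, and inflate the number of independent loops
in the cluster-level abstraction graph. `umitopo` provides:

* a **generative simulator** of single cells with realistic gene-expression
  rank structure and heterogeneous observation depth, with ground-truth cell
  states and edit operations (identity permutation, pathway scaling,
  derepression) that build benchmark populations for cell-type, cell-state
  and lineage inference;
* **expected UMI-multiplicity spectra** `E[N_k]` under Poisson and
  negative-binomial sampling, and empirical depth-binned `N̄_k` profiles for
  any 10x-format count matrix;
* **topological descriptors** of the thresholded PAGA abstraction graph
  (β₀ = connected components, β₁ = E − V + β₀ = independent loops);
* **random-walk hit rates** that score each shallowly observed cell by how
  quickly a weighted k-step walk on the neighbor graph reaches the
  deeply observed subset, plus the stability protocols built on them
  (progressive removal curves, fixed-size subsample β₁ distributions,
  hyperparameter sweeps).

## The model

A cell state is a probability vector over a 36,601-gene panel. Genes are
ranked by pool fraction, `p_1 ≤ … ≤ p_36601`, and only the top ~10,000 ranks
(`i ≥ 26,601`) are expressible. Raw molecule counts follow

```
linear:       f_i = max(0, ⌊(i − 26301)/300⌋)
exponential:  f_i = exp((i − 36000)/75)
combined:     f_i = round(linear + exponential)      p_i = f_i / Σ_j f_j
```

Observing a cell at depth `D` is a multinomial draw of `D` molecules from
`p`; depths are drawn per cell from round(Normal(5000, 1500)) clamped at 500.
The expected number of genes seen exactly `k` times is
`E[N_k] = Σ_i P(X_i = k)` with `X_i ~ Pois(D·p_i)` or `X_i ~ NB(mean D·p_i,
dispersion θ)`.

Benchmark populations: **X** (2,000 base-model cells + 1,000 each from two
gene-identity permutations — three distinct cell types), **Y** (2,000 base +
2,000 with 300 random expressed genes scaled ×2/×0.5 — a cell-state shift),
and **Z** (a step-wise lineage A→B→C→{D,E}: two successive ×1.67/×0.6 edits
of the same 300 genes, then two independent derepressions of 10 silent genes
to 50 molecules; 1,000 cells per state).

## Worked example

```python
import numpy as np
import umitopo as ut

model = ut.build_fraction_model("combined")
curve = ut.expected_nk(model, ut.SamplingSpec("poisson", 5_000))
print(round(curve.values[1], 1), round(curve.values[1] / curve.values[10], 1))
# 1590.6 202.5

pop = ut.simulate_population_Z(np.random.default_rng(0), cells_per_state=1_000)
zp = ut.filter_by_total_umi(pop, 4_000)          # deep-cell subset Z'
res, topo = ut.abstraction_topology(zp, ut.WorkflowConfig(seed=0))
print(topo)
# TopologySummary(n_nodes=5, n_edges=6, beta0=1, beta1=2, threshold=0.05)
```

At depth 5,000 the combined model expects ~1,591 genes observed exactly once
and a ~200-fold drop from `E[N_1]` to `E[N_10]` — the sharp-then-gradual
multiplicity decay seen in real 10x data. On the deep-cell lineage subset the
thresholded abstraction graph is a single component whose strong edges trace
A–B–C with D and E attached at C; the full heterogeneous population yields a
loop-richer graph (higher β₁) because shallow cells from different states
intermix.

The same analyses run from the shell on simulated or real 10x matrices:

```sh
umitopo simulate Z --seed 1 --out sim_z
umitopo nk --input sim_z --out nk_out
umitopo run --input sim_z --seed 0 --out run_out
umitopo hitrate --input sim_z --threshold 4000 --removal-curve --out hr_out
```

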
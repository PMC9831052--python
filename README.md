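# netshy

Topology-aware summarization of biological network modules, with a
simulation benchmark for comparing module summaries.

## The problem

Biological networks — co-expression, protein–protein, multi-omics
similarity networks — are modular: tight subnetworks of `p` features act
as functional units. To relate a module to a phenotype (disease status,
lung function, survival) you first need a *subject-level summary*: one
score per subject that stands in for the whole module. The standard
summary is the module "eigengene", the first principal component of the
`n × p` profile matrix `X`, which ignores the module's wiring entirely;
the other classical baseline is the profile of the hub node (the most
highly connected feature), which ignores everything *but* the wiring.

`netshy` implements a hybrid: score each subject by the first principal
component of the Laplacian-weighted profile matrix

```
X* = X L,     L = D − A,     D_kk = Σ_l a_kl,
```

where `A` is the module's symmetric non-negative adjacency matrix and
`D` its diagonal weighted-degree matrix. Right-multiplying by the graph
Laplacian re-expresses every feature as a degree-weighted contrast
against its neighbours, so the leading direction of `X*` reflects both
the measurements and the topology. The package provides:

- `summarize_netshy`, `summarize_nonet` (eigengene), `summarize_hub` —
  scores `Z` (length `n`) and unit loadings `φ` (length `p`), plus a
  rank-based inverse-normal transform for downstream regression;
- a Gaussian-graphical-model simulator in which the adjacency seeds the
  precision matrix, the phenotype loads on node degrees
  (`Y0 = β0 + X0 β + ε`, `β` = weighted degrees), and observed profiles
  are noise-perturbed truth (`X = X0 + E`);
- evaluation criteria — `|corr(Z, Y0)|` and the proportion of *true*
  variance explained, `‖X0 φ‖² / ‖X0‖²` — ratioed against the optimal
  baseline computed from the noise-free `X0`;
- a subsampling robustness protocol (1000 → 500/300/200/100/50
  subjects), a truth-free real-data variant, and a paired bootstrap for
  comparing two methods' phenotype correlations;
- a `netshy` CLI (`summarize`, `simulate`, `benchmark`, `evaluate`).

## Worked example

Simulate one benchmark dataset (30 nodes, edge probability 0.3, 1000
subjects) and compare the summaries:

```python
import netshy as ns

cfg = ns.SimulationConfig(p=30, alpha0=0.3, seed=11)
ds = ns.run_scenario1(cfg)
for r in ns.evaluate_methods(ds, include_hub=True):
    print(f"{r.method:>7s}: rho={r.rho:.3f} pve={r.pve:.3f} "
          f"rho_ratio={r.rho_ratio:.3f} pve_ratio={r.pve_ratio:.3f}")
```

```
  nonet: rho=0.381 pve=0.462 rho_ratio=0.839 pve_ratio=0.977
 netshy: rho=0.344 pve=0.397 rho_ratio=0.757 pve_ratio=0.841
    hub: rho=0.086 pve=0.032 rho_ratio=0.190 pve_ratio=0.068
```

`rho` is each score's absolute correlation with the true phenotype and
`pve` the fraction of noise-free profile variance its loading captures;
the `_ratio` columns divide by the optimal values attainable from the
noise-free data (closer to 1 is better). At the full n = 1000 the plain
eigengene is hard to beat. The picture reverses as samples shrink:

```python
st = ns.subsampling_study(ds, sizes=(500, 300, 200, 100, 50),
                          iterations=200, seed=0)
print(st.table[st.table["metric"] == "pve_ratio"].to_string(index=False))
```

```
 size method    metric     mean       sd  iterations
 1000 netshy pve_ratio 0.840904 0.000000           1
 1000  nonet pve_ratio 0.977000 0.000000           1
  500 netshy pve_ratio 0.835664 0.027254         200
  500  nonet pve_ratio 0.951443 0.030046         200
  300 netshy pve_ratio 0.828524 0.040177         200
  300  nonet pve_ratio 0.922047 0.047660         200
  200 netshy pve_ratio 0.821659 0.054955         200
  200  nonet pve_ratio 0.880757 0.068381         200
  100 netshy pve_ratio 0.800430 0.081801         200
  100  nonet pve_ratio 0.772865 0.114954         200
   50 netshy pve_ratio 0.743000 0.117312         200
   50  nonet pve_ratio 0.563390 0.203252         200
```

The eigengene's explained-variance ratio collapses from 0.95 to 0.56 as
the subsample shrinks from 500 to 50 subjects, while the
Laplacian-weighted summary degrades gently (0.84 → 0.74) — the topology
acts as a prior that stabilizes the loading when data are scarce. The
same trend holds for the phenotype correlation, and the per-iteration
spread (`sd`) grows monotonically as samples shrink.

The CLI equivalent for data on disk:

```
netshy summarize --profiles X.csv --network net.csv --method netshy \
    --out scores.tsv --loadings-out loadings.tsv
netshy benchmark --grid grid.yaml --out results/
```

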
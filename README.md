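# sdcorr — spatial density correlation of target-labeled neuron clouds

`sdcorr` asks whether neurons that sit near each other project to related
targets. Its motivating system is the basal forebrain (BF) cholinergic
projection system of the rat: thousands of cholinergic neurons, each labeled
by a retrograde tracer deposited in one of 30 ontologically defined cortical
areas and registered into a common reference space. If the projection system
were diffuse, the cortical-target composition of any local cell ensemble
would look random; if it is organized, nearby cells should share target
combinations, and correlating local target densities should expose the
underlying network structure.

The package is for anatomists and systems neuroscientists with point-cloud
tracing data (cell positions + injection labels + injection volume masks),
and it ships a synthetic generator with planted three-network structure so
the entire pipeline is testable without any dataset.

## Method

For every labeled neuron **p** (a *sampling point*), count the neighbors
within a 300 μm sphere that project to each injection site *j*: the counts
N<sub>p,j</sub>. Overlapping injections multiply label the same cortical
territory, so each injection gets a normalization constant

&nbsp;&nbsp;&nbsp;&nbsp;C<sub>j</sub> = V(I<sub>j</sub>) / Σ<sub>I<sub>k</sub>∈I<sub>R</sub></sub> V(I<sub>j</sub> ∩ I<sub>k</sub>),

where I<sub>R</sub> is the set of injections covering the same cortical
category R (the self term keeps the denominator positive). Normalized counts
Ñ<sub>p,j</sub> = C<sub>j</sub>·N<sub>p,j</sub> are summed within category,
giving the n<sub>cells</sub> × 30 **target-projection-vector (TPV) matrix**.
Pearson correlation between every pair of TPV columns yields a 30 × 30
cortical-area correlation matrix: red blocks are areas innervated by the
same local cholinergic ensembles.

Structure in that matrix is then extracted and validated:

* **Hierarchical clustering** — Euclidean distances between correlation-matrix
  rows, complete (MAX) linkage, deterministic lowest-index tie-breaking;
  rows/columns reordered to dendrogram leaf order.
* **Cophenetic correlation** r<sub>c</sub> — dendrogram faithfulness to the
  row distances.
* **Silhouette cut** — mean silhouette score of every cut k = 2…29 selects
  the optimal number of clusters.
* **AU p-values** — multiscale bootstrap over TPV rows (resample sizes
  τ·n, τ = 0.5…1.4, B per scale), per-branch probit-curve fit
  z(τ) = v·√τ + c/√τ, approximately-unbiased support AU = Φ(c − v).
* **PCA** of the correlation matrix — a clustering-free check of the same
  block structure.
* **Distance analyses** — cortical injection-centroid distances and BF
  cell-population distances (mean/median over all cross pairs) correlated
  with projection-pattern similarity over all C(30,2) = 435 area pairs.

Supporting geometry: Dice coefficient 2·V(X∩Y)/(V(X)+V(Y)) for registration
validation, participation V(I∩R)/V(I), and pairwise overlap V(A∩B)/V(A),
all computed by voxel counting on a shared 50 μm grid.

## Worked example

Simulate a small planted-structure dataset (600 cells, 30 areas in three
networks) and run the full analysis:

```sh
sdc simulate --small --seed 1 --out demo
# wrote 600 cells, 60 injections to demo
sdc run --cells demo/cells.csv --injections demo/injections.csv \
    --ontology demo/ontology.csv --masks-dir demo/masks --out out
# cophenetic r_c = 0.962; best silhouette cut k = 3 (s = 0.578); row-distance vs cell-distance r = 0.728
```

Reading the output: the dendrogram summarizes the row distances faithfully
(r<sub>c</sub> = 0.962); the silhouette-optimal cut recovers exactly the
three planted networks (k = 3, mean silhouette 0.578); and area pairs whose
BF cell populations are physically close also have similar projection
patterns (r = 0.728 over the 435 pairs). `out/` contains the TPV matrices,
raw and reordered correlation matrices, merge list, Newick dendrogram,
silhouette and PCA tables, distance scatter table, a heatmap PNG and a JSON
run manifest. Add `--bootstrap` to also write per-branch AU p-values, and
`sdc validate` to check a dataset's referential integrity.

The same steps are available as a library:

```python
import sdcorr as s

cells, injections, ontology, truth = s.generate_dataset(s.SyntheticConfig(rng_seed=1))
result = s.run_pipeline(cells, injections, ontology, s.AnalysisConfig(rng_seed=1))
au = s.au_pvalues(result.tpv, s.AnalysisConfig(rng_seed=1))
print(s.planted_recovery_report(truth, ontology, result.silhouette, au).to_dict())
# {'best_k': 3, 'ari': 1.0, 'network_au': {'Auditory': 1.0, 'SSM': 1.0, 'Visual': 1.0},
#  'min_network_au': 1.0}
```

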
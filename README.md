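# metagrn

Gene regulatory network (GRN) inference from single-cell RNA-seq UMI
counts via homogeneous, **disjoint metacells**, with lineage-specific
networks derived from cell-fate probabilities.

Single-cell counts are too noisy for reliable GRN inference, and the
usual remedy — imputation by neighborhood smoothing — induces spurious
gene–gene correlations because neighboring cells share information.
`metagrn` instead aggregates raw counts over *disjoint* groups of
homogeneous cells and infers the network from those metacell profiles.
For differentiation systems with multiple terminal states it further
resolves the global network into lineage-specific networks using
cell-fate probabilities as a pseudo-temporal axis for Granger-style
lagged regression.

## Method

1. **Pruned KNN graph.** Cells are embedded by PCA on log-normalized
   counts and an exact K-nearest-neighbor graph is built (Euclidean, PC
   space). For each cell a local negative-binomial background
   NB(μ<sub>i</sub>, r<sub>i</sub>) is fitted per gene on its
   neighborhood (means after depth rescaling; dispersion from a
   quadratic fit of log variance on log mean). A link's probability
   P<sub>jl</sub> is the geometric mean of the three smallest per-gene
   two-sided NB tail probabilities of neighbor *l*'s counts under seed
   *j*'s background; links with P<sub>jl</sub> < p<sup>tr</sup> (default
   0.01) are pruned.
2. **Seed cells and metacells.** A subset of *S* seed cells is sampled —
   geometric (covering-box) sketching in PC space, or uniformly.
   Surviving neighbors ("partner cells") shared by several seeds are
   assigned to the seed with the largest link probability (ties: fewest
   partners, then lowest index), so **no cell enters two metacells**.
   Metacell profiles are the summed raw counts of seed + partners; seeds
   with fewer than `min_partners` (default 5) partners are dropped. The
   optimal *S* maximizes score(S) = S\* · n_s\*, where S\* is min–max
   normalized S and n_s\* is min–max normalized √(n_s − 1) for the mean
   effective metacell size n_s.
3. **Global GRN.** A GENIE3-style random-forest regression per target
   gene on all other candidate regulators' metacell profiles yields an
   importance matrix **W**; binarizing (weight ≥ 0.001, top 50 targets
   per TF) gives the skeleton network, optionally intersected with a
   user-supplied prior (e.g. ATAC-derived) edge list.
4. **Lineage GRNs.** Cell-fate probability rows (from any fate
   predictor, or the built-in absorbing-Markov-chain fallback) are
   averaged per metacell, clustered with a Gaussian mixture (components
   by BIC), and clusters are assigned to every lineage toward which they
   are ≥ k-fold biased (k = 2). Each lineage's metacells, ordered by
   increasing fate probability, form a time series x(t); for each target
   *i* a lagged ridge regression

   min Σ<sub>t</sub> ( x<sub>i</sub>(t) − Σ<sub>j</sub>Σ<sub>l=1..L</sub>
   a<sub>ij</sub>(l) x<sub>j</sub>(t−l) )² + λ‖a‖²

   over its skeleton parents (L = 30, λ = 150 by default; an unsquared
   group-L2 penalty mode is also available) gives edge weights
   G<sub>ji</sub> = |Σ<sub>l</sub> a<sub>ij</sub>(l)|, rank-transformed
   per regulator to 1/rank².
5. **Evaluation and modules.** Early precision rate (EPR = precision of
   the top-k predicted edges / truth density; random = 1), AUROC/AUPRC,
   a differential-expression lineage baseline, regulator connectivity
   ranking, spin-glass module extraction, and a gene-label permutation
   test for module significance.

A bundled simulator generates benchmark datasets with known global and
lineage-specific ground-truth networks (NB noise, dropout, bifurcating
or cyclic trajectories, per-cell fate probabilities), so the whole
pipeline is testable end to end without external data.

## Worked example

```python
from metagrn import data_io, evaluation, grn_core, knn_prune, metacell, sketch
from metagrn.evaluation import RankedPrediction, early_precision_rate
from metagrn.synthetic import simulate_dataset, small_benchmark_config

ds = simulate_dataset(small_benchmark_config(rng_seed=0, n_cells=1000))
norm = data_io.normalize_counts(ds.counts)
emb = data_io.compute_pca(norm, n_pcs=10)
graph = knn_prune.build_knn(emb, K=15)
seeds = sketch.geometric_sketch(emb, S=120, rng_seed=0)
probs = knn_prune.link_probabilities(ds.counts, graph, cells=seeds.seed_indices)
pruned = knn_prune.prune_graph(probs, graph, p_tr=0.01)
assignment = metacell.assign_partners(pruned, seeds)
mcs = metacell.aggregate_metacells(ds.counts, assignment, min_partners=3)
print(f"{mcs.n_metacells} metacells, mean size {mcs.sizes().mean():.1f}")

grn = grn_core.infer_global_grn(mcs, ds.truth.tf_ids, n_trees=100, rng_seed=0)
pred = RankedPrediction.from_weighted(grn)
epr = early_precision_rate(pred, ds.truth.global_truth)
auroc, auprc = evaluation.auroc_auprc(pred, ds.truth.global_truth)
print(f"EPR = {epr:.2f}  AUROC = {auroc:.2f}  AUPRC = {auprc:.2f}")
```

prints

```
103 metacells, mean size 7.0
EPR = 1.54  AUROC = 0.56  AUPRC = 0.19
```

The 1000 simulated cells collapse into 103 disjoint metacells of ~7
cells each. An EPR of 1.54 means the top-ranked predicted edges contain
1.54× more true regulator→target interactions than random guessing
(EPR = 1); the same inference on raw single-cell counts of this dataset
scores ≈ 1.0, i.e. no better than random.

The same pipeline is available from the shell:

```sh
metagrn simulate --n-cells 1000 demo_data
metagrn run demo_data/counts.mtx --fates demo_data/fates.csv --out demo_out \
    --n-seeds 120 --k 15 --min-partners 3
metagrn evaluate demo_out/grn_global.tsv demo_data/truth_global.tsv
```

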
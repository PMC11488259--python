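import numpy as np
import pytest

from metagrn import data_io, knn_prune, metacell, sketch
from metagrn.synthetic import simulate_dataset, small_benchmark_config


@pytest.fixture(scope="session")
def small_dataset():
    """Small bifurcating benchmark dataset (50 genes, 400 cells)."""
    return simulate_dataset(small_benchmark_config(rng_seed=0))


@pytest.fixture(scope="session")
def mini_pipeline(small_dataset):
    """Products of the sampling -> pruning -> metacell stages."""
    ds = small_dataset
    norm = data_io.normalize_counts(ds.counts)
    emb = data_io.compute_pca(norm, n_pcs=10)
    graph = knn_prune.build_knn(emb, 15)
    seeds = sketch.geometric_sketch(emb, 60, rng_seed=0)
    probs = knn_prune.link_probabilities(ds.counts, graph, cells=seeds.seed_indices)
    pruned = knn_prune.prune_graph(probs, graph, 0.01)
    assignment = metacell.assign_partners(pruned, seeds)
    metacells = metacell.aggregate_metacells(ds.counts, assignment, min_partners=3)
    return {
        "dataset": ds,
        "normalized": norm,
        "embedding": emb,
        "graph": graph,
        "seeds": seeds,
        "probs": probs,
        "pruned": pruned,
        "assignment": assignment,
        "metacells": metacells,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
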
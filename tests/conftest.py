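"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import latentconn as lc


def random_weight_matrix(n: int, rng: np.random.Generator) -> np.ndarray:
    """Symmetric nonnegative W with Exp(1) edge weights (the null of -ln p)."""
    iu, ju = np.triu_indices(n, k=1)
    w = rng.exponential(1.0, iu.size)
    W = np.zeros((n, n))
    W[iu, ju] = w
    W[ju, iu] = w
    return W


def brute_force_best_clique(
    W: np.ndarray, lam: float, min_size: int = 3
) -> tuple[float, tuple[int, ...]]:
    """Exhaustive search over all node subsets of size >= min_size."""
    n = W.shape[0]
    best, best_set = -np.inf, ()
    for r in range(min_size, n + 1):
        for S in itertools.combinations(range(n), r):
            sub = W[np.ix_(S, S)]
            score = sub[np.triu_indices(r, k=1)].sum() - lam * r * (r - 1) / 2
            if score > best:
                best, best_set = float(score), S
    return best, best_set


def _partitions_into_k(items: list[int], k: int):
    """All set partitions of ``items`` into exactly k nonempty blocks."""
    from sympy.utilities.iterables import multiset_partitions

    yield from multiset_partitions(items, k)


def brute_force_best_kpartite(
    W: np.ndarray, nodes, lam: float, k_max: int = 3
) -> float:
    """Exhaustive between-block score over all partitions into 2..k_max blocks."""
    nodes = sorted(nodes)
    m = len(nodes)
    sub = W[np.ix_(nodes, nodes)]
    total = float(sub[np.triu_indices(m, k=1)].sum()) - lam * m * (m - 1) / 2
    best = -np.inf
    for k in range(2, min(k_max, m) + 1):
        for part in _partitions_into_k(list(range(m)), k):
            within = 0.0
            for blk in part:
                if len(blk) > 1:
                    sb = sub[np.ix_(blk, blk)]
                    within += float(sb[np.triu_indices(len(blk), k=1)].sum()) - lam * len(
                        blk
                    ) * (len(blk) - 1) / 2
            best = max(best, total - within)
    return best


def planted_clique_config(
    n_nodes: int = 20,
    clique: tuple[int, ...] = (1, 2, 3, 4, 5),
    delta: float = 0.6,
    n_per_group: int = 40,
    seed: int = 0,
    sd: float = 0.3,
) -> lc.GeneratorConfig:
    return lc.GeneratorConfig(
        n_nodes=n_nodes,
        n_subjects_a=n_per_group,
        n_subjects_b=n_per_group,
        subject_sd=sd,
        planted_networks=(
            lc.PlantedNetwork(nodes=clique, topology="clique", delta=delta),
        ),
        seed=seed,
    )


@pytest.fixture
def small_null_sample():
    """Pure-null sample: 12 nodes, 10 + 10 subjects."""
    cfg = lc.GeneratorConfig(n_nodes=12, n_subjects_a=10, n_subjects_b=10, seed=42)
    sample, _ = lc.generate_sample(cfg)
    return sample


@pytest.fixture
def planted_sample():
    """20 nodes, strong 5-node planted clique, 40 + 40 subjects."""
    sample, truth = lc.generate_sample(planted_clique_config(seed=7))
    return sample, truth
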
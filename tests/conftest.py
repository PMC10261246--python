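import numpy as np
import pytest

from utaka.distances import window_distances
from utaka.filtering import build_accessibility
from utaka.simulate import GenSimConfig, simulate_split_genotypes


@pytest.fixture(scope="session")
def small_sim():
    """Moderate two-population + outgroup simulation reused across tests."""
    cfg = GenSimConfig(
        n_per_pop=5,
        n_outgroup=1,
        ne=10_000,
        t_split=20_000,
        t_outgroup=200_000,
        n_windows=40,
        seed=11,
    )
    matrix, truth = simulate_split_genotypes(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def small_wds(small_sim):
    cfg, matrix, _ = small_sim
    acc = build_accessibility(None, matrix.chrom_lengths, cfg.window_size)
    return window_distances(matrix, acc)


@pytest.fixture(scope="session")
def pop_labels(small_sim):
    _, matrix, _ = small_sim
    a = {s for s in matrix.samples if s.startswith("A")}
    b = {s for s in matrix.samples if s.startswith("B")}
    return a, b


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """Random tree topology with positive branch lengths and its leaf distances.

    Built by sequential joining (an independent construction from the NJ code
    path); returns (labels, distance matrix, bipartitions as frozensets).
    """
    labels = [f"L{i}" for i in range(n_leaves)]
    # adjacency of the growing tree
    adj: dict[int, dict[int, float]] = {i: {} for i in range(n_leaves)}
    nodes = list(range(n_leaves))
    nxt = n_leaves

    def link(u, v, w):
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    pool = nodes[:]
    while len(pool) > 3:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        u = nxt
        nxt += 1
        link(pool[i], u, float(rng.uniform(0.1, 2.0)))
        link(pool[j], u, float(rng.uniform(0.1, 2.0)))
        pool = [pool[k] for k in range(len(pool)) if k not in (i, j)] + [u]
    center = nxt
    for node in pool:
        link(node, center, float(rng.uniform(0.1, 2.0)))

    # pairwise path lengths by BFS from each leaf
    D = np.zeros((n_leaves, n_leaves))
    for a in range(n_leaves):
        dist = {a: 0.0}
        stack = [a]
        while stack:
            x = stack.pop()
            for y, w in adj[x].items():
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        for b in range(n_leaves):
            D[a, b] = dist[b]

    # leaf-set bipartitions by exhaustive edge enumeration
    def side(u, v):
        seen = {u, v}
        stack = [v]
        out = set()
        while stack:
            x = stack.pop()
            if x < n_leaves:
                out.add(labels[x])
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return frozenset(out)

    bips = set()
    for u in adj:
        for v in adj[u]:
            if u < v:
                s = side(u, v)
                bips.add(s)
                bips.add(frozenset(labels) - s)
    return labels, D, bips
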
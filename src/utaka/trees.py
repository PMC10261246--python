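"""Neighbour joining, outgroup rooting, bipartition support.

The tree builder is standard Saitou–Nei NJ with two contracts pinned for
reproducibility: Q-matrix ties break on the lowest (row, column) index pair,
and negative branch-length estimates are clamped to zero with the deficit
transferred to the sister branch (the joined pair's summed length is kept).
Node support comes from a block bootstrap over genomic windows: window
difference/denominator counts are resampled with replacement, summed, turned
back into per-bp matrices (optionally net-corrected from the resampled
windows) and a tree is rebuilt per replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from utaka.containers import DistanceMatrix
from utaka.distances import WindowDistanceSet

logger = logging.getLogger(__name__)


@dataclass
class PhyloTree:
    """Unrooted or rooted phylogeny as an undirected edge-weighted graph.

    Leaves carry labels; internal nodes are anonymous. A rooted tree is the
    same graph with a designated root node (inserted on an edge by outgroup
    rooting, hence degree 2).
    """

    adj: dict[int, dict[int, float]]
    leaf_labels: dict[int, str]
    rooted: bool = False
    root: int | None = None

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            adj={u: dict(nb) for u, nb in self.adj.items()},
            leaf_labels=dict(self.leaf_labels),
            rooted=self.rooted,
            root=self.root,
        )

    @property
    def leaves(self) -> set[str]:
        return set(self.leaf_labels.values())

    def _leaf_id(self, label: str) -> int:
        for nid, lab in self.leaf_labels.items():
            if lab == label:
                return nid
        raise KeyError(f"leaf {label!r} not in tree")

    # -- traversal helpers -------------------------------------------------

    def _side_leaves(self, u: int, v: int) -> frozenset[str]:
        """Leaf labels reachable from ``v`` when the edge (u, v) is removed."""
        seen = {u, v}
        stack = [v]
        out = []
        while stack:
            x = stack.pop()
            if x in self.leaf_labels:
                out.append(self.leaf_labels[x])
            for y in self.adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return frozenset(out)

    def bipartitions(self) -> set[frozenset[str]]:
        """All leaf bipartitions, each edge contributing both of its sides."""
        out: set[frozenset[str]] = set()
        for u in self.adj:
            for v in self.adj[u]:
                if u < v:
                    side = self._side_leaves(u, v)
                    out.add(side)
                    out.add(frozenset(self.leaves - side))
        return out

    def path_length(self, label_a: str, label_b: str) -> float:
        a, b = self._leaf_id(label_a), self._leaf_id(label_b)
        dist = {a: 0.0}
        stack = [a]
        while stack:
            x = stack.pop()
            if x == b:
                return dist[b]
            for y, w in self.adj[x].items():
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        return dist[b]

    def to_newick(self) -> str:
        if self.rooted:
            start = self.root
        else:
            # start from an internal junction (max degree)
            start = max(self.adj, key=lambda u: len(self.adj[u]))

        def rec(u: int, parent: int | None) -> str:
            children = [v for v in self.adj[u] if v != parent]
            if not children:
                return self.leaf_labels.get(u, "")
            parts = []
            for v in children:
                parts.append(f"{rec(v, u)}:{self.adj[u][v]:.10g}")
            return "(" + ",".join(parts) + ")"

        return rec(start, None) + ";"


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    The top-level node becomes the root; the tree is flagged rooted when that
    node is bifurcating (outgroup-rooted trees as written by
    :func:`root_by_outgroup`), unrooted when it is a degree-3 junction.
    """
    s = text.strip().rstrip(";")
    adj: dict[int, dict[int, float]] = {}
    leaf_labels: dict[int, str] = {}
    counter = [0]

    def new_node() -> int:
        nid = counter[0]
        counter[0] += 1
        adj[nid] = {}
        return nid

    def add_edge(u: int, v: int, w: float) -> None:
        adj[u][v] = w
        adj[v][u] = w

    pos = [0]

    def parse_clade() -> tuple[int, float]:
        if s[pos[0]] == "(":
            node = new_node()
            pos[0] += 1  # consume '('
            while True:
                child, length = parse_clade()
                add_edge(node, child, length)
                if s[pos[0]] == ",":
                    pos[0] += 1
                    continue
                if s[pos[0]] == ")":
                    pos[0] += 1
                    break
            _, length = parse_label()  # internal labels/support values ignored
            return node, length
        node = new_node()
        label, length = parse_label()
        if not label:
            raise ValueError("newick leaf without a label")
        leaf_labels[node] = label
        return node, length

    def parse_label() -> tuple[str, float]:
        start = pos[0]
        while pos[0] < len(s) and s[pos[0]] not in ",():":
            pos[0] += 1
        label = s[start:pos[0]]
        length = 0.0
        if pos[0] < len(s) and s[pos[0]] == ":":
            pos[0] += 1
            start = pos[0]
            while pos[0] < len(s) and s[pos[0]] not in ",()":
                pos[0] += 1
            length = float(s[start:pos[0]])
        return label, length

    top, _ = parse_clade()
    if pos[0] != len(s):
        raise ValueError(f"trailing newick content: {s[pos[0]:]!r}")
    rooted = len(adj[top]) == 2
    return PhyloTree(
        adj=adj, leaf_labels=leaf_labels, rooted=rooted, root=top if rooted else None
    )


def contains_bipartition(tree: PhyloTree, side: set[str]) -> bool:
    """True iff some edge splits the leaves into exactly ``side`` vs the rest."""
    side = frozenset(side)
    leaves = tree.leaves
    unknown = side - leaves
    if unknown:
        raise ValueError(f"unknown leaf labels {sorted(unknown)}")
    if not side or side == leaves:
        raise ValueError("side must be a proper nonempty subset of leaves")
    return side in tree.bipartitions()


def neighbor_joining(d: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbour joining with deterministic tie-breaking.

    Requires at least three taxa and a symmetric zero-diagonal matrix. The
    unrooted result has a single degree-3 junction at top level.
    """
    n = len(d.labels)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    if not np.allclose(d.values, d.values.T, atol=1e-12):
        raise ValueError("distance matrix is asymmetric beyond 1e-12")
    D = d.values.astype(float).copy()

    adj: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    leaf_labels = {i: lab for i, lab in enumerate(d.labels)}
    ids = list(range(n))
    next_id = n

    def add_edge(u: int, v: int, w: float) -> None:
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    while len(ids) > 3:
        m = len(ids)
        R = D.sum(axis=1)
        Q = (m - 2) * D - R[:, None] - R[None, :]
        # ties broken by lowest (row, column): first minimum in row-major
        # order over the strict upper triangle
        Q[np.tril_indices(m)] = np.inf
        i, j = divmod(int(np.argmin(Q)), m)
        dij = D[i, j]
        li = dij / 2.0 + (R[i] - R[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:  # clamp, transferring the deficit to the sister branch
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        u = next_id
        next_id += 1
        add_edge(ids[i], u, li)
        add_edge(ids[j], u, lj)

        d_new = (D[i] + D[j] - dij) / 2.0
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = d_new[keep]
        D2[:-1, -1] = d_new[keep]
        D2[-1, -1] = 0.0
        D = D2
        ids = [ids[k] for k in keep] + [u]

    # final three nodes join at a central degree-3 junction
    a, b, c = ids
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    la = (dab + dac - dbc) / 2.0
    lb = dab - la
    lc = dac - la
    u = next_id
    add_edge(a, u, max(la, 0.0))
    add_edge(b, u, max(lb, 0.0))
    add_edge(c, u, max(lc, 0.0))

    return PhyloTree(adj=adj, leaf_labels=leaf_labels, rooted=False, root=None)


def root_by_outgroup(tree: PhyloTree, outgroup: str) -> PhyloTree:
    """Root by inserting a node at the midpoint of the outgroup's edge.

    All leaf-to-leaf path lengths are preserved. Rooting an already rooted
    tree first removes the old (degree-2) root, so re-rooting on the same
    outgroup is idempotent.
    """
    out = tree.copy()
    if out.rooted and out.root is not None and len(out.adj[out.root]) == 2:
        (u, wu), (v, wv) = out.adj[out.root].items()
        del out.adj[u][out.root]
        del out.adj[v][out.root]
        del out.adj[out.root]
        out.adj[u][v] = wu + wv
        out.adj[v][u] = wu + wv
    out.rooted = False
    out.root = None

    leaf = out._leaf_id(outgroup)
    (parent, length), = out.adj[leaf].items()
    root = max(out.adj) + 1
    del out.adj[leaf][parent]
    del out.adj[parent][leaf]
    out.adj[root] = {leaf: length / 2.0, parent: length / 2.0}
    out.adj[leaf][root] = length / 2.0
    out.adj[parent][root] = length / 2.0
    out.rooted = True
    out.root = root
    return out


@dataclass
class SupportResult:
    """Bootstrap support for one bipartition of the point-estimate tree."""

    bipartition: frozenset[str]
    support: float  # percent of replicates containing the bipartition
    replicates: int
    seed: int
    rejected_replicates: int = 0


def nj_input(values: np.ndarray) -> tuple[np.ndarray, int]:
    """Clamp negative (net-corrected) distances to zero for NJ input."""
    neg = int((values < -1e-300).sum() // 2)
    return np.maximum(values, 0.0), neg


def _replicate_matrix(
    wds: WindowDistanceSet, idx: np.ndarray, net: bool
) -> np.ndarray | None:
    num = wds.diff_counts[idx].sum(axis=0)
    den = wds.pair_denominators[idx].sum(axis=0)
    n = num.shape[0]
    off = ~np.eye(n, dtype=bool)
    if (den[off] <= 0).any():
        return None
    values = np.zeros_like(num)
    values[off] = num[off] / den[off]
    if net:
        hd = wds.het_denominators[idx].sum(axis=0)
        if (hd <= 0).any():
            return None
        h = wds.het_counts[idx].sum(axis=0) / hd
        values = values - (h[:, None] + h[None, :]) / 2.0
        np.fill_diagonal(values, 0.0)
    values, _ = nj_input(values)
    return values


def block_bootstrap_support(
    wds: WindowDistanceSet,
    bipartitions: list[set[str]],
    replicates: int = 1000,
    seed: int = 0,
    net: bool = False,
) -> list[SupportResult]:
    """Block-bootstrap node support over genomic windows.

    Each replicate draws ``n_windows`` window indices uniformly with
    replacement, sums difference and denominator counts over the drawn
    multiset, forms the per-bp matrix (net-corrected from the resampled
    windows when ``net`` is True), rebuilds an NJ tree and records which of
    the query bipartitions it contains. Replicates with a zero denominator
    for any pair are rejected and redrawn (counted). Deterministic per seed:
    a single generator supplies draws in sequence.
    """
    if replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    if wds.n_windows == 0:
        raise ValueError("empty window distance set")
    rng = np.random.default_rng(seed)
    W = wds.n_windows
    targets = [frozenset(b) for b in bipartitions]
    hits = np.zeros(len(targets), dtype=int)
    rejected = 0
    all_leaves = frozenset(wds.samples)

    for _ in range(replicates):
        values = None
        while values is None:
            idx = rng.integers(0, W, size=W)
            values = _replicate_matrix(wds, idx, net)
            if values is None:
                rejected += 1
                if rejected > 1000 * replicates:
                    raise RuntimeError("bootstrap replicates persistently degenerate")
        tree = neighbor_joining(DistanceMatrix(list(wds.samples), values))
        bips = tree.bipartitions()
        for t, target in enumerate(targets):
            if target in bips or frozenset(all_leaves - target) in bips:
                hits[t] += 1

    if rejected:
        logger.info("block bootstrap: %d degenerate replicates redrawn", rejected)
    return [
        SupportResult(
            bipartition=target,
            support=100.0 * hits[t] / replicates,
            replicates=replicates,
            seed=seed,
            rejected_replicates=rejected,
        )
        for t, target in enumerate(targets)
    ]


def local_tree_support_fraction(
    wds: WindowDistanceSet,
    group_a: set[str],
    group_b: set[str],
    include_others: bool = False,
) -> float:
    """Fraction of per-window (local) NJ trees separating the two groups.

    By default the per-window matrix is restricted to the two groups' samples
    before the tree is built, so samples outside both groups (e.g. the
    outgroup) do not influence the test. Windows with an incomplete
    denominator for any pair are skipped; at least one evaluable window is
    required.
    """
    group_a, group_b = set(group_a), set(group_b)
    if group_a & group_b:
        raise ValueError("groups must be disjoint")
    missing = (group_a | group_b) - set(wds.samples)
    if missing:
        raise ValueError(f"unknown samples {sorted(missing)}")

    if include_others:
        sub = list(range(len(wds.samples)))
    else:
        sub = [k for k, s in enumerate(wds.samples) if s in group_a | group_b]
    labels = [wds.samples[k] for k in sub]
    n = len(sub)
    if n < 3:
        raise ValueError("need at least 3 samples across the two groups")
    off = ~np.eye(n, dtype=bool)
    target = frozenset(group_a)
    complement = frozenset(labels) - target

    supporting = 0
    evaluated = 0
    for w in range(wds.n_windows):
        den = wds.pair_denominators[w][np.ix_(sub, sub)]
        if (den[off] <= 0).any():
            continue
        num = wds.diff_counts[w][np.ix_(sub, sub)]
        values = np.zeros_like(num)
        values[off] = num[off] / den[off]
        tree = neighbor_joining(DistanceMatrix(labels, values))
        evaluated += 1
        bips = tree.bipartitions()
        if target in bips or complement in bips:
            supporting += 1
    if evaluated == 0:
        raise ValueError("no window with complete denominators to evaluate")
    return supporting / evaluated
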
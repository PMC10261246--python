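"""Split-time estimation from a rooted net-divergence tree.

The height of the node separating the two species in the net ("split") tree,
measured as the mean tip-to-node path length in per-bp distance units,
accumulates one mutation rate's worth of divergence per generation per
lineage, so

    t_years = generation_time * node_height / mu.

Uncertainty in the assumed mutation rate propagates inversely: a higher rate
implies a younger split, so the confidence bounds are
``t * mu / mu_high`` and ``t * mu / mu_low``. The estimator assumes constant
effective population sizes and mutation rate; the net correction removes the
expected ancestral-coalescence offset (~2*Ne generations) but no demographic
model is fitted.
"""

from __future__ import annotations

from dataclasses import dataclass

from utaka.trees import PhyloTree


@dataclass
class DatingConfig:
    """Mutation rate per bp per generation, its CI, and generation time (years).

    Defaults are the Lake Malawi cichlid rate 3.5e-9 (CI 1.6e-9 – 4.7e-9)
    and a three-year generation time.
    """

    mu: float = 3.5e-9
    mu_ci: tuple[float, float] = (1.6e-9, 4.7e-9)
    generation_time: float = 3.0

    def validate(self) -> None:
        lo, hi = self.mu_ci
        if not (0 < lo <= self.mu <= hi):
            raise ValueError("require 0 < mu_low <= mu <= mu_high")
        if self.generation_time <= 0:
            raise ValueError("generation_time must be positive")


@dataclass
class SplitTimeEstimate:
    node_height: float  # mean tip-to-split-node distance, per bp
    t_years: float
    ci_years: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.ci_years
        if not (0 <= lo <= self.t_years <= hi or self.t_years == 0 == lo == hi):
            raise ValueError("CI must bracket the point estimate")


def _rooted_structure(tree: PhyloTree):
    if not tree.rooted or tree.root is None:
        raise ValueError("tree must be rooted (use root_by_outgroup)")
    depth: dict[int, float] = {tree.root: 0.0}
    parent: dict[int, int | None] = {tree.root: None}
    order = [tree.root]
    stack = [tree.root]
    while stack:
        u = stack.pop()
        for v, w in tree.adj[u].items():
            if v != parent[u]:
                parent[v] = u
                depth[v] = depth[u] + w
                order.append(v)
                stack.append(v)
    subtree: dict[int, frozenset[str]] = {}
    for u in reversed(order):
        leaves = set()
        if u in tree.leaf_labels:
            leaves.add(tree.leaf_labels[u])
        for v in tree.adj[u]:
            if v != parent[u]:
                leaves |= subtree[v]
        subtree[u] = frozenset(leaves)
    return depth, parent, subtree


def mean_tip_depth_to_node(
    tree: PhyloTree, group_a: set[str], group_b: set[str]
) -> float:
    """Mean path length from the two groups' leaves to their divergence node.

    The node is the MRCA of the union; it must separate the groups (no child
    subtree may contain leaves of both), otherwise the grouping is paraphyletic
    at that node and an error is raised.
    """
    group_a, group_b = set(group_a), set(group_b)
    union = group_a | group_b
    unknown = union - tree.leaves
    if unknown:
        raise ValueError(f"labels not in tree: {sorted(unknown)}")
    depth, parent, subtree = _rooted_structure(tree)

    # MRCA = deepest node whose subtree contains the whole union
    mrca = max(
        (u for u, s in subtree.items() if union <= s),
        key=lambda u: depth[u],
    )
    for v in tree.adj[mrca]:
        if v == parent[mrca]:
            continue
        inside = subtree[v] & union
        if inside & group_a and inside & group_b:
            raise ValueError(
                "divergence node does not separate the groups (paraphyly): "
                f"subtree mixes {sorted(inside & group_a)} with "
                f"{sorted(inside & group_b)}"
            )
    leaf_depths = [
        depth[nid] - depth[mrca]
        for nid, lab in tree.leaf_labels.items()
        if lab in union
    ]
    return float(sum(leaf_depths) / len(leaf_depths))


def divergence_to_years(node_height: float, config: DatingConfig) -> float:
    """Convert a per-bp tip-to-node distance into years."""
    if node_height < 0:
        raise ValueError("node height must be non-negative")
    config.validate()
    return config.generation_time * node_height / config.mu


def mutation_rate_ci(t_point: float, config: DatingConfig) -> tuple[float, float]:
    """Rescale a point split time by the mutation-rate confidence bounds."""
    if t_point < 0:
        raise ValueError("split time must be non-negative")
    config.validate()
    lo, hi = config.mu_ci
    return (t_point * config.mu / hi, t_point * config.mu / lo)


def estimate_split_time(
    tree: PhyloTree,
    group_a: set[str],
    group_b: set[str],
    config: DatingConfig | None = None,
) -> SplitTimeEstimate:
    """Full dating step: node height -> years -> mutation-rate CI."""
    config = config or DatingConfig()
    h = mean_tip_depth_to_node(tree, group_a, group_b)
    t = divergence_to_years(h, config)
    return SplitTimeEstimate(node_height=h, t_years=t, ci_years=mutation_rate_ci(t, config))
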
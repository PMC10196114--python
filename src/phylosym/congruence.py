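"""Host-tree / phylobiome-tree congruence testing.

Two rooted-tree distances over *clusters* (the leaf sets below internal
nodes, excluding singletons and the full leaf set):

* Robinson-Foulds Cluster (RFC): half the size of the symmetric difference
  of the two cluster sets.
* Matching Cluster (MC): minimum total cost over one-to-one matchings of
  the two cluster sets (padded with empty sets), where matching cluster A
  to cluster B costs |A symmetric-difference B|; solved exactly as a linear
  assignment problem.

Significance comes from a random-tree null: the same distance is computed
between the reference tree and R randomly generated trees on the same leaf
set; the p-value is the plus-one-corrected fraction of null distances at
least as *small* as the observed one (small distance = congruent), and the
normalized score divides the observed distance by the null mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from skbio import TreeNode

logger = logging.getLogger(__name__)

__all__ = [
    "clusters", "rf_cluster", "matching_cluster", "random_rooted_tree",
    "TreeCongruence", "CongruenceResults", "congruence_test",
]


def _leafset(t: TreeNode) -> frozenset:
    return frozenset(tip.name for tip in t.tips())


def clusters(t: TreeNode) -> set[frozenset]:
    """Nontrivial clusters of a rooted tree.

    For each internal node except the root, the set of leaf labels below
    it; singletons and the full leaf set are excluded.
    """
    full = _leafset(t)
    out: set[frozenset] = set()
    for node in t.non_tips(include_self=False):
        leaves = frozenset(tip.name for tip in node.tips())
        if 1 < len(leaves) < len(full):
            out.add(leaves)
    return out


def _check_leafsets(t1: TreeNode, t2: TreeNode) -> frozenset:
    l1, l2 = _leafset(t1), _leafset(t2)
    if l1 != l2:
        raise ValueError(
            "leaf sets differ: only in first "
            f"{sorted(l1 - l2)}, only in second {sorted(l2 - l1)}"
        )
    return l1


def rf_cluster(t1: TreeNode, t2: TreeNode) -> float:
    """Robinson-Foulds Cluster distance: |C1 symm-diff C2| / 2."""
    _check_leafsets(t1, t2)
    c1, c2 = clusters(t1), clusters(t2)
    return len(c1 ^ c2) / 2.0


def _cluster_masks(cl: set[frozenset], bit: dict[str, int]) -> list[int]:
    masks = []
    for s in cl:
        m = 0
        for name in s:
            m |= 1 << bit[name]
        masks.append(m)
    return masks


def matching_cluster(t1: TreeNode, t2: TreeNode) -> float:
    """Matching Cluster distance via exact linear assignment.

    Cluster sets are padded with empty sets to equal size; the cost of a
    matched pair is the size of the symmetric difference of the leaf sets
    (so matching against the empty set costs the cluster's size).
    """
    leaves = _check_leafsets(t1, t2)
    bit = {name: i for i, name in enumerate(sorted(leaves))}
    m1 = _cluster_masks(clusters(t1), bit)
    m2 = _cluster_masks(clusters(t2), bit)
    k = max(len(m1), len(m2))
    if k == 0:
        return 0.0
    m1 += [0] * (k - len(m1))
    m2 += [0] * (k - len(m2))
    cost = np.array([[(a ^ b).bit_count() for b in m2] for a in m1],
                    dtype=float)
    ri, ci = linear_sum_assignment(cost)
    return float(cost[ri, ci].sum())


def random_rooted_tree(leaves, model: str = "uniform", seed=None) -> TreeNode:
    """Random leaf-labeled rooted binary tree.

    ``model="uniform"`` draws uniformly over all labeled rooted binary
    topologies ((2n-3)!! of them) by sequential edge insertion, where each
    new leaf attaches to any existing edge — including the root edge — with
    equal probability. ``model="yule"`` joins uniformly chosen pairs of
    lineages (coalescent/Yule topology distribution). Leaf labels are a
    uniform random permutation in both models.
    """
    labels = [str(x) for x in leaves]
    if len(labels) < 2:
        raise ValueError("need at least two leaves")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    order = [labels[i] for i in rng.permutation(len(labels))]
    if model == "uniform":
        root = TreeNode(children=[TreeNode(name=order[0]),
                                  TreeNode(name=order[1])])
        # one entry per attachable edge; `root` stands for the root edge
        edges: list[TreeNode] = [root.children[0], root.children[1], root]
        for name in order[2:]:
            target = edges[int(rng.integers(len(edges)))]
            leaf = TreeNode(name=name)
            if target is root:
                root = TreeNode(children=[root, leaf])
                edges.append(root)   # the new root edge is attachable too
            else:
                parent = target.parent
                parent.remove(target)
                mid = TreeNode(children=[target, leaf])
                parent.append(mid)
                edges.append(mid)
            edges.append(leaf)
        return root
    if model == "yule":
        nodes = [TreeNode(name=name) for name in order]
        while len(nodes) > 1:
            i, j = rng.choice(len(nodes), size=2, replace=False)
            i, j = int(i), int(j)
            a, b = nodes[i], nodes[j]
            joined = TreeNode(children=[a, b])
            nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
            nodes.append(joined)
        return nodes[0]
    raise ValueError(f"unknown model {model!r}")


@dataclass
class CongruenceResults:
    """Observed distance vs a random-tree null, per metric."""

    metrics: dict[str, dict] = field(default_factory=dict)
    leaf_set: frozenset = frozenset()
    n_random: int = 0
    model: str = "uniform"

    def raw(self, metric: str) -> float:
        return self.metrics[metric]["raw"]

    def normalized(self, metric: str) -> float:
        return self.metrics[metric]["normalized"]

    def p_value(self, metric: str) -> float:
        return self.metrics[metric]["p"]

    def null_mean(self, metric: str) -> float:
        return self.metrics[metric]["null_mean"]

    def null_sample(self, metric: str) -> np.ndarray:
        return self.metrics[metric]["null"]

    def summary(self) -> str:
        lines = [
            f"Tree congruence vs {self.n_random} random trees "
            f"({self.model} model), {len(self.leaf_set)} shared leaves",
        ]
        for name, m in self.metrics.items():
            lines.append(
                f"  {name}: observed {m['raw']:g}, null mean "
                f"{m['null_mean']:.3f}, normalized {m['normalized']:.4f}, "
                f"p = {m['p']:.4g}"
            )
        return "\n".join(lines)


class TreeCongruence:
    """Congruence test between an observed tree and a reference tree.

    Both trees are pruned to their shared leaf set (logged when this drops
    leaves); at least 4 shared leaves are required for the test to be
    meaningful.
    """

    def __init__(self, observed: TreeNode, reference: TreeNode):
        lo, lr = _leafset(observed), _leafset(reference)
        shared = lo & lr
        if len(shared) < 4:
            raise ValueError(
                f"only {len(shared)} shared leaves; need at least 4"
            )
        if shared != lo or shared != lr:
            logger.info(
                "pruning to %d shared leaves (dropped: observed %s, "
                "reference %s)", len(shared),
                sorted(lo - shared), sorted(lr - shared),
            )
            observed = observed.shear(sorted(shared))
            reference = reference.shear(sorted(shared))
        self.observed = observed
        self.reference = reference
        self.leaf_set = frozenset(shared)

    _METRICS = {"RFC": rf_cluster, "MC": matching_cluster}

    def fit(self, metrics=("RFC", "MC"), n_random: int = 1000,
            model: str = "uniform", seed=None) -> CongruenceResults:
        if isinstance(metrics, str):
            metrics = (metrics,)
        for m in metrics:
            if m not in self._METRICS:
                raise ValueError(f"unknown metric {m!r}")
        rng = np.random.default_rng(seed)
        nulls: dict[str, list[float]] = {m: [] for m in metrics}
        leaves = sorted(self.leaf_set)
        for _ in range(n_random):
            t = random_rooted_tree(leaves, model=model, seed=rng)
            for m in metrics:
                nulls[m].append(self._METRICS[m](t, self.reference))
        out = CongruenceResults(leaf_set=self.leaf_set, n_random=n_random,
                                model=model)
        for m in metrics:
            raw = self._METRICS[m](self.observed, self.reference)
            null = np.asarray(nulls[m])
            mean = float(null.mean())
            p = (1 + int((null <= raw + 1e-12).sum())) / (1 + n_random)
            out.metrics[m] = {
                "raw": raw,
                "null": null,
                "null_mean": mean,
                "normalized": raw / mean if mean > 0 else np.nan,
                "p": p,
            }
        return out


def congruence_test(observed: TreeNode, reference: TreeNode,
                    metric: str = "RFC", n_random: int = 1000,
                    model: str = "uniform", seed=None) -> CongruenceResults:
    """Functional wrapper over :class:`TreeCongruence` for one metric."""
    return TreeCongruence(observed, reference).fit(
        metrics=(metric,), n_random=n_random, model=model, seed=seed)
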
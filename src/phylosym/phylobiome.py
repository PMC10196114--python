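"""Microbiome dendrograms ("phylobiome trees") for host species.

The procedure: collapse queens to species, rarefy every species row to a
fixed depth (subsampling reads without replacement), compute Bray-Curtis
distances, cluster with UPGMA; repeat for a number of iterations. The final
tree is the UPGMA tree of the element-wise mean of the iteration distance
matrices, and each internal cluster carries a support value — the fraction
of iteration trees containing that exact leaf set.

Single-genus trees (e.g. a Wolbachia-only table) use the same machinery
after selecting that genus's ASV columns; species whose counts cannot reach
the rarefaction depth are excluded and reported, which shrinks the leaf set
the congruence test can use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix

from phylosym.community import bray_curtis
from phylosym.datamodel import CountTable, TaxonomyMap

logger = logging.getLogger(__name__)

__all__ = [
    "subset_single_genus", "rarefy", "upgma", "PhylobiomeSpec",
    "PhylobiomeResult", "build_phylobiome",
]


def subset_single_genus(t: CountTable, tax: TaxonomyMap, genus: str
                        ) -> CountTable:
    """Keep only the ASV columns assigned to ``genus``."""
    cols = []
    for tid in t.taxon_ids:
        if tid not in tax:
            raise ValueError(f"taxon {tid!r} missing from taxonomy")
        if tax.genus(tid) == genus:
            cols.append(tid)
    if not cols:
        raise ValueError(f"genus {genus!r} absent from table/taxonomy")
    return CountTable(t.df.loc[:, cols])


def rarefy(row, depth: int, seed=None) -> np.ndarray:
    """Subsample a count vector to exactly ``depth`` reads without replacement.

    A multivariate-hypergeometric draw; a row whose total equals ``depth``
    is returned unchanged. ``seed`` may be an int, a SeedSequence-style key,
    or an existing Generator.
    """
    counts = np.asarray(row, dtype=np.int64)
    total = int(counts.sum())
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if total < depth:
        raise ValueError(f"row total {total} below rarefaction depth {depth}")
    if total == depth:
        return counts.copy()
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, depth)


def upgma(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage agglomeration into a rooted ultrametric tree.

    Node heights are half the merge dissimilarity; ties between candidate
    merges are broken lexicographically on the (sorted) leaf-name keys of
    the two clusters, so the result is deterministic.
    """
    ids = [str(i) for i in dm.ids]
    if len(ids) < 2:
        raise ValueError("need at least two ids")
    d = dm.data.astype(float)
    # active clusters: key (sorted leaf tuple) -> (node, size, height)
    active: dict[tuple, tuple[TreeNode, int, float]] = {}
    index: dict[tuple, int] = {}
    dist: dict[frozenset, float] = {}
    for i, name in enumerate(ids):
        key = (name,)
        active[key] = (TreeNode(name=name), 1, 0.0)
        index[key] = i
    keys = sorted(active)
    for ka, kb in ((keys[i], keys[j]) for i in range(len(keys))
                   for j in range(i + 1, len(keys))):
        dist[frozenset((ka, kb))] = d[index[ka], index[kb]]

    while len(active) > 1:
        best = None
        akeys = sorted(active)
        for i, ka in enumerate(akeys):
            for kb in akeys[i + 1:]:
                dd = dist[frozenset((ka, kb))]
                if (best is None or dd < best[0]
                        or (dd == best[0] and (ka, kb) < best[1:])):
                    best = (dd, ka, kb)
        dd, ka, kb = best
        node_a, size_a, h_a = active.pop(ka)
        node_b, size_b, h_b = active.pop(kb)
        height = dd / 2.0
        node_a.length = max(0.0, height - h_a)
        node_b.length = max(0.0, height - h_b)
        parent = TreeNode(children=[node_a, node_b])
        new_key = tuple(sorted(ka + kb))
        for kc in active:
            dc = (size_a * dist.pop(frozenset((ka, kc)))
                  + size_b * dist.pop(frozenset((kb, kc)))) / (size_a + size_b)
            dist[frozenset((new_key, kc))] = dc
        dist.pop(frozenset((ka, kb)))
        active[new_key] = (parent, size_a + size_b, height)
    (root, _, _), = active.values()
    root.length = None
    return root


@dataclass
class PhylobiomeSpec:
    """Parameters of the rarefaction/UPGMA procedure."""

    genus: str | None = None     # None = full table
    depth: int = 3000
    iterations: int = 100
    seed: int | None = None

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class PhylobiomeResult:
    tree: TreeNode
    mean_distance_matrix: DistanceMatrix
    supports: dict[frozenset, float]
    excluded_species: list[str] = field(default_factory=list)
    iterations: int = 0

    def write_newick(self, path) -> None:
        self.tree.write(str(path), format="newick")


def _tree_cluster_sets(tree: TreeNode) -> set[frozenset]:
    full = frozenset(tip.name for tip in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=True):
        leaves = frozenset(tip.name for tip in node.tips())
        if 1 < len(leaves) <= len(full):
            out.add(leaves)
    return out


def build_phylobiome(
    t: CountTable,
    spec: PhylobiomeSpec,
    tax: TaxonomyMap | None = None,
) -> PhylobiomeResult:
    """Run the rarefaction + Bray-Curtis + UPGMA procedure.

    ``t`` is a species-collapsed count table (rows = host species). With
    ``spec.genus`` set, the table is first restricted to that genus's ASVs
    (``tax`` required). Species whose (restricted) totals fall below
    ``spec.depth`` are excluded and reported. The per-iteration random
    stream is ``default_rng([seed, iteration])`` so any single iteration is
    independently reproducible.
    """
    table = t
    if spec.genus is not None:
        if tax is None:
            raise ValueError("taxonomy required for a single-genus tree")
        table = subset_single_genus(t, tax, spec.genus)
    totals = table.sample_totals()
    # rows are processed in sorted-name order so the per-iteration random
    # draws attach to species identity, making the result invariant to the
    # input row order
    keep = sorted(totals.index[totals >= spec.depth])
    excluded = [s for s in table.sample_ids if s not in keep]
    if excluded:
        logger.info("species below rarefaction depth %d excluded: %s",
                    spec.depth, excluded)
    if len(keep) < 3:
        raise ValueError(
            f"only {len(keep)} species reach depth {spec.depth}; need >= 3"
        )
    sub = table.df.loc[keep]
    counts = sub.to_numpy()
    master = 0 if spec.seed is None else int(spec.seed)
    sum_d = np.zeros((len(keep), len(keep)))
    cluster_counts: dict[frozenset, int] = {}
    for it in range(spec.iterations):
        rng = np.random.default_rng([master, it])
        rare = np.vstack([rarefy(r, spec.depth, rng) for r in counts])
        dm = bray_curtis(pd.DataFrame(rare, index=keep,
                                      columns=sub.columns))
        sum_d += dm.data
        tree_i = upgma(dm)
        for cl in _tree_cluster_sets(tree_i):
            cluster_counts[cl] = cluster_counts.get(cl, 0) + 1
    mean_dm = DistanceMatrix(sum_d / spec.iterations, ids=keep)
    tree = upgma(mean_dm)
    supports: dict[frozenset, float] = {}
    full = frozenset(keep)
    for node in tree.non_tips(include_self=True):
        leaves = frozenset(tip.name for tip in node.tips())
        if len(leaves) <= 1:
            continue
        sup = cluster_counts.get(leaves, 0) / spec.iterations
        supports[leaves] = sup
        if leaves != full:
            node.name = f"{sup:g}"
            node.support = sup
    return PhylobiomeResult(tree=tree, mean_distance_matrix=mean_dm,
                            supports=supports, excluded_species=excluded,
                            iterations=spec.iterations)
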
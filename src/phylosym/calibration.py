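"""Simulation-based calibration and recovery studies.

These routines measure the statistical behaviour of the pipeline under
known conditions: type-I calibration (null data in, uniform p-values /
nominal false-positive rates out) and signal recovery (planted structure
in, detections out). They are used by the test suite and by the
reproduction script; problem sizes are chosen so a study runs in seconds
to a couple of minutes on one core.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from phylosym.community import PERMANOVA
from phylosym.congruence import (
    TreeCongruence, matching_cluster, random_rooted_tree, rf_cluster,
)
from phylosym.cooccurrence import screen_cooccurrence
from phylosym.datamodel import collapse_by_genus, collapse_by_species
from phylosym.phylobiome import PhylobiomeSpec, build_phylobiome
from phylosym.simulate import (
    association_screen_config, null_cooccurrence_config, simulate_dataset,
    strong_phylosymbiosis_config,
)

__all__ = [
    "permanova_null_pvalues", "cooccurrence_false_positive_rate",
    "congruence_null_pvalues", "congruence_recovery_rates",
    "association_recovery_rates",
]


def permanova_null_pvalues(n_replicates: int = 500, n_samples: int = 16,
                           n_permutations: int = 999, seed: int = 0
                           ) -> np.ndarray:
    """Permutation p-values for unstructured Gaussian data, two groups."""
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(n_samples)]
    meta = pd.DataFrame({"g": np.repeat(["A", "B"], n_samples // 2)},
                        index=ids)
    ps = np.empty(n_replicates)
    for r in range(n_replicates):
        x = rng.normal(size=(n_samples, 3))
        dm = DistanceMatrix(squareform(pdist(x)), ids=ids)
        res = PERMANOVA(dm, meta, ["g"]).fit(
            n_permutations=n_permutations,
            seed=int(rng.integers(2 ** 31)))
        ps[r] = res.table.at["g", "Pr(>F)"]
    return ps


def cooccurrence_false_positive_rate(n_replicates: int = 1000,
                                     alpha: float = 0.05, seed: int = 0
                                     ) -> float:
    """Per-pair rejection rate of the screen on independent genera."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        cfg = null_cooccurrence_config(seed=int(rng.integers(2 ** 31)))
        table, tax, meta, _ = simulate_dataset(cfg)
        res = screen_cooccurrence(collapse_by_genus(table, tax), meta,
                                  alpha=alpha)
        pair = [r for r in res.results
                if {r.table.genus_a, r.table.genus_b} == {"NullA", "NullB"}]
        if pair and pair[0].significant:
            hits += 1
    return hits / n_replicates


def congruence_null_pvalues(n_references: int = 50, per_reference: int = 10,
                            n_leaves: int = 20, n_random: int = 999,
                            metric: str = "MC", seed: int = 0) -> np.ndarray:
    """p-values when the observed tree is itself a draw from the null.

    Pools over several random reference trees so the discreteness of any
    single null distribution averages out.
    """
    rng = np.random.default_rng(seed)
    leaves = [f"L{i:02d}" for i in range(n_leaves)]
    fn = {"MC": matching_cluster, "RFC": rf_cluster}[metric]
    ps = []
    for _ in range(n_references):
        ref = random_rooted_tree(leaves, seed=rng)
        null = np.array([fn(random_rooted_tree(leaves, seed=rng), ref)
                         for _ in range(n_random)])
        for _ in range(per_reference):
            obs = fn(random_rooted_tree(leaves, seed=rng), ref)
            ps.append((1 + int((null <= obs + 1e-12).sum()))
                      / (1 + n_random))
    return np.asarray(ps)


def congruence_recovery_rates(n_replicates: int = 100, n_species: int = 14,
                              n_clades: int = 5, iterations: int = 100,
                              n_random: int = 1000, p_threshold: float = 0.01,
                              seed: int = 0) -> dict[str, float]:
    """Fraction of strong-vertical-transmission replicates whose phylobiome
    is congruent with the host tree at ``p < p_threshold``, per metric."""
    rng = np.random.default_rng(seed)
    hits = {"RFC": 0, "MC": 0}
    for _ in range(n_replicates):
        cfg = strong_phylosymbiosis_config(
            seed=int(rng.integers(2 ** 31)), n_species=n_species,
            n_clades=n_clades)
        table, tax, meta, truth = simulate_dataset(cfg)
        by_sp = collapse_by_species(table, meta)
        pb = build_phylobiome(by_sp, PhylobiomeSpec(
            depth=3000, iterations=iterations,
            seed=int(rng.integers(2 ** 31))))
        res = TreeCongruence(pb.tree, truth.host_tree).fit(
            metrics=("RFC", "MC"), n_random=n_random,
            seed=int(rng.integers(2 ** 31)))
        for m in hits:
            hits[m] += res.p_value(m) < p_threshold
    return {m: h / n_replicates for m, h in hits.items()}


def association_recovery_rates(n_replicates: int = 100, seed: int = 0
                               ) -> dict[str, float]:
    """Recovery of one planted synergy and one planted antagonism at n=60:
    the pair must be significant with the planted odds-ratio direction."""
    rng = np.random.default_rng(seed)
    pos = neg = 0
    for _ in range(n_replicates):
        cfg = association_screen_config(seed=int(rng.integers(2 ** 31)))
        table, tax, meta, _ = simulate_dataset(cfg)
        res = screen_cooccurrence(collapse_by_genus(table, tax), meta)
        by = {frozenset((r.table.genus_a, r.table.genus_b)): r
              for r in res.results}
        rp = by.get(frozenset(("SynA", "SynB")))
        rn = by.get(frozenset(("AntA", "AntB")))
        if rp is not None and rp.significant and rp.direction == "positive":
            pos += 1
        if rn is not None and rn.significant and rn.direction == "negative":
            neg += 1
    return {"positive": pos / n_replicates, "negative": neg / n_replicates}
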
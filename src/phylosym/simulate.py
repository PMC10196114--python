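"""Synthetic queen-microbiome datasets with planted ground truth.

The generator emulates the structure of a filtered 16S ASV study of ant
queens without any raw reads: a pure-birth host phylogeny partitioned into
clades, heritable genera whose presence evolves along that tree as a
two-state Markov process (the vertical-transmission signal), sporadic
environmental genera, optional pairwise presence associations
(synergy/antagonism, planted through a Plackett 2x2 copula at given odds
multipliers), run-level batch effects on genus abundances, host
(mitochondrial/chloroplast/eukaryotic) reads, reagent contaminants shared
with negative controls, planted sub-1% trace ASVs, and per-sample
sequencing depths spanning the 3,000-read QC threshold.

Every random choice flows from one master seed through named substreams
(``default_rng([seed, stream, ...])``) so stages are independently
reproducible. The emitted tables always satisfy the data-model invariants,
and :class:`GroundTruth` records exactly what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from phylosym.datamodel import (
    CountTable, Lineage, SampleMetadata, TaxonomyMap,
)

__all__ = [
    "HeritableGenus", "EnvironmentalGenus", "Contaminant", "Association",
    "SimulationConfig", "GroundTruth", "simulate_host_tree",
    "assign_clades", "evolve_presence", "simulate_dataset",
    "strong_phylosymbiosis_config",
]

# substream tags for default_rng([seed, tag, ...])
_TREE, _PRESENCE, _LAYOUT, _ABUNDANCE, _COUNTS, _CONTROLS = range(6)


@dataclass
class HeritableGenus:
    """A genus whose presence tracks the host tree.

    gain/loss are transition rates per unit branch length of the two-state
    process; ``mean_abundance`` is the genus's expected relative-abundance
    weight when present; ``infection_prob`` the per-queen carriage
    probability given the species carries the genus.
    """

    name: str
    gain: float
    loss: float
    mean_abundance: float
    n_asvs: int = 2
    root_present: bool = False
    infection_prob: float = 0.9


@dataclass
class EnvironmentalGenus:
    """Sporadically acquired genus, independent of the host tree."""

    name: str
    occurrence_prob: float
    mean_abundance: float
    n_asvs: int = 1


@dataclass
class Contaminant:
    """Reagent contaminant ASV, planted in negative controls.

    kind="control_only": appears in controls and nowhere else (rule-a
    contaminant). kind="ubiquitous": appears in controls and in every
    non-control sample of each run (rule-b contaminant).
    """

    name: str
    kind: str
    control_abundance: float = 0.4
    sample_abundance: float = 0.03


@dataclass
class Association:
    """Planted pairwise co-presence: odds multiplier on the sample-level 2x2."""

    genus_a: str
    genus_b: str
    odds_multiplier: float


@dataclass
class SimulationConfig:
    n_species: int = 14
    n_clades: int = 5
    queens_per_species: tuple[int, int] = (6, 12)
    host_tree: TreeNode | None = None
    heritable: list[HeritableGenus] = field(default_factory=lambda: [
        HeritableGenus("Wolbachia", gain=0.30, loss=0.05,
                       mean_abundance=0.55, n_asvs=3, root_present=True,
                       infection_prob=0.90),
        HeritableGenus("Liliensternia", gain=0.08, loss=0.40,
                       mean_abundance=0.35, n_asvs=1, root_present=False,
                       infection_prob=0.95),
        HeritableGenus("Lactobacillus", gain=0.40, loss=0.30,
                       mean_abundance=0.12, n_asvs=4, root_present=True,
                       infection_prob=0.80),
        HeritableGenus("Spiroplasma", gain=0.12, loss=0.80,
                       mean_abundance=0.18, n_asvs=2, root_present=False,
                       infection_prob=0.70),
    ])
    environmental: list[EnvironmentalGenus] = field(default_factory=lambda: [
        EnvironmentalGenus("Acinetobacter", 0.15, 0.05),
        EnvironmentalGenus("Pseudomonas", 0.08, 0.04),
        EnvironmentalGenus("Serratia", 0.05, 0.06),
        EnvironmentalGenus("Stenotrophomonas", 0.05, 0.04),
        # ubiquitous low-level gut background so every queen yields
        # bacterial reads even when no focal symbiont is carried
        EnvironmentalGenus("Enterobacter", 1.0, 0.10),
    ])
    associations: list[Association] = field(default_factory=lambda: [
        Association("Lactobacillus", "Liliensternia", 0.15),
        Association("Lactobacillus", "Wolbachia", 4.0),
    ])
    contaminants: list[Contaminant] = field(default_factory=lambda: [
        Contaminant("Ralstonia", "ubiquitous"),
        Contaminant("Sphingomonas", "control_only"),
    ])
    n_trace_asvs: int = 2          # planted sub-1% ASV columns
    trace_abundance: float = 0.002
    trace_prevalence: float = 0.25
    mito_abundance: float = 0.08   # host mitochondrial reads, every sample
    include_chloroplast: bool = True
    include_eukaryote: bool = True
    depth_range: tuple[int, int] = (4500, 15000)
    n_low_depth_samples: int = 2
    low_depth_range: tuple[int, int] = (800, 2800)
    control_depth_range: tuple[int, int] = (600, 2000)
    runs: int = 2
    controls_per_run: int = 2
    batch_effect_sd: float = 0.3
    dirichlet_concentration: float | None = 60.0
    seed: int = 0

    def __post_init__(self):
        if not (self.n_species >= self.n_clades >= 1):
            raise ValueError("need n_species >= n_clades >= 1")
        for g in self.heritable:
            if g.gain < 0 or g.loss < 0 or g.mean_abundance < 0:
                raise ValueError(f"negative rate/abundance for {g.name}")
            if not 0 <= g.infection_prob <= 1:
                raise ValueError(f"infection_prob out of [0,1] for {g.name}")
        for g in self.environmental:
            if not 0 <= g.occurrence_prob <= 1 or g.mean_abundance < 0:
                raise ValueError(f"bad parameters for {g.name}")
        for a in self.associations:
            if a.odds_multiplier < 0:
                raise ValueError("odds multiplier must be >= 0")


@dataclass
class GroundTruth:
    host_tree: TreeNode = None
    clades: dict[str, str] = field(default_factory=dict)
    species_presence: pd.DataFrame = None     # species x genus bool
    sample_presence: pd.DataFrame = None      # sample x genus bool (planted)
    contaminant_taxa: set[str] = field(default_factory=set)
    nonbacterial_taxa: set[str] = field(default_factory=set)
    trace_taxa: set[str] = field(default_factory=set)
    shallow_samples: set[str] = field(default_factory=set)
    control_samples: set[str] = field(default_factory=set)
    associations: list[Association] = field(default_factory=list)

    @property
    def expected_removed_taxa(self) -> set[str]:
        return self.contaminant_taxa | self.nonbacterial_taxa | self.trace_taxa

    @property
    def expected_removed_samples(self) -> set[str]:
        return self.shallow_samples | self.control_samples


# ---------------------------------------------------------------------------
# Host tree
# ---------------------------------------------------------------------------

def simulate_host_tree(n_species: int, n_clades: int, seed=None
                       ) -> tuple[TreeNode, dict[str, str]]:
    """Pure-birth ultrametric tree with clade labels.

    Clades are the monophyletic groups obtained by cutting the tree at the
    height where exactly ``n_clades`` lineages exist (always possible on a
    binary tree with distinct speciation times). Returns (tree, mapping
    species -> clade label).
    """
    if not (n_species >= n_clades >= 1):
        raise ValueError("need n_species >= n_clades >= 1")
    rng = np.random.default_rng(seed)
    names = [f"sp{i + 1:02d}" for i in range(n_species)]
    if n_species == 1:
        return TreeNode(name=names[0]), {names[0]: "clade1"}
    # simulate speciation event times: k lineages wait Exp(k)
    root = TreeNode()
    root.birth = 0.0
    active = [root]
    t = 0.0
    event_times = []
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        event_times.append(t)
        node = active.pop(int(rng.integers(len(active))))
        node.split_time = t
        for _ in range(2):
            child = TreeNode()
            child.birth = t
            node.append(child)
            active.append(child)
    t_end = t + rng.exponential(1.0 / n_species)
    perm = rng.permutation(n_species)
    for node, j in zip(active, perm):
        node.name = names[j]
    for node in root.traverse(include_self=True):
        if node.is_tip():
            node.length = t_end - node.birth
        elif node is not root:
            node.length = node.split_time - node.birth
        else:
            node.length = None
    # clade cut: after event k there are k+1 lineages
    if n_clades == 1:
        cut = -1.0
    else:
        cut = (event_times[n_clades - 2]
               + (event_times[n_clades - 1] if n_clades - 1 < len(event_times)
                  else t_end)) / 2.0
    clades: dict[str, str] = {}
    label = 0
    for node in root.traverse(include_self=True):
        birth = getattr(node, "birth", 0.0)
        crosses = (birth <= cut
                   and (node.is_tip() or node.split_time > cut)) \
            if n_clades > 1 else (node is root)
        if n_clades == 1:
            crosses = node is root
        if crosses:
            label += 1
            for tip in ([node] if node.is_tip() else node.tips()):
                clades[tip.name] = f"clade{label}"
    assert len(clades) == n_species and label == n_clades
    return root, clades


def assign_clades(tree: TreeNode, n_clades: int) -> dict[str, str]:
    """Clade labels for an externally supplied ultrametric tree."""
    # compute node depths from root
    depths = {}
    for node in tree.traverse(include_self=True):
        depths[id(node)] = (0.0 if node.parent is None
                            else depths[id(node.parent)] + (node.length or 0.0))
    internal = sorted(depths[id(n)] for n in tree.non_tips(include_self=True))
    if n_clades == 1:
        return {tip.name: "clade1" for tip in tree.tips()}
    if n_clades - 1 > len(internal):
        raise ValueError("tree too small for requested clade count")
    lo = internal[n_clades - 2]
    hi = (internal[n_clades - 1] if n_clades - 1 < len(internal)
          else max(depths[id(t)] for t in tree.tips()))
    if hi <= lo:
        raise ValueError("no height yields the requested number of clades")
    cut = (lo + hi) / 2.0
    clades = {}
    label = 0
    for node in tree.traverse(include_self=True):
        start = depths[id(node)] - (node.length or 0.0)
        if start <= cut < depths[id(node)] or (
                node.parent is None and depths[id(node)] > cut):
            label += 1
            for tip in ([node] if node.is_tip() else node.tips()):
                clades[tip.name] = f"clade{label}"
    if label != n_clades:
        raise ValueError("clade cut failed; is the tree ultrametric?")
    return clades


# ---------------------------------------------------------------------------
# Presence evolution
# ---------------------------------------------------------------------------

def evolve_presence(tree: TreeNode, gain: float, loss: float,
                    root_state: bool, seed=None) -> dict[str, bool]:
    """Two-state Markov presence/absence along the tree's branches.

    Transition probabilities over a branch of length L follow the exact
    two-state solution: with total rate r = gain + loss the process relaxes
    toward the stationary frequency gain/r with factor exp(-rL). Returns
    the leaf states keyed by leaf name.
    """
    if gain < 0 or loss < 0:
        raise ValueError("rates must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    r = gain + loss
    states = {id(tree): bool(root_state)}
    out: dict[str, bool] = {}
    for node in tree.preorder(include_self=False):
        parent_state = states[id(node.parent)]
        length = node.length or 0.0
        if r == 0:
            state = parent_state
        else:
            pi1 = gain / r
            decay = np.exp(-r * length)
            p1 = pi1 + ((1.0 if parent_state else 0.0) - pi1) * decay
            state = bool(rng.random() < p1)
        states[id(node)] = state
        if node.is_tip():
            out[node.name] = state
    if tree.is_tip():
        out[tree.name] = bool(root_state)
    return out


def _plackett_p11(pa: float, pb: float, theta: float) -> float:
    """P(both present) for given margins and odds ratio theta (2x2 copula)."""
    if pa <= 0 or pb <= 0:
        return 0.0
    if pa >= 1 or pb >= 1:
        return min(pa, pb)
    if theta == 1.0:
        return pa * pb
    if theta == 0.0:
        return max(0.0, pa + pb - 1.0)
    s = 1.0 + (pa + pb) * (theta - 1.0)
    disc = s * s - 4.0 * theta * (theta - 1.0) * pa * pb
    return (s - np.sqrt(disc)) / (2.0 * (theta - 1.0))


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def _generic_lineage(genus: str, idx: int) -> Lineage:
    phyla = ["Proteobacteria", "Firmicutes", "Actinobacteriota",
             "Bacteroidota"]
    p = phyla[idx % len(phyla)]
    return Lineage(domain="Bacteria", phylum=p, class_=f"{p}_c",
                   order=f"{p}_o", family=f"{p}_f", genus=genus)


def _asv_ids(genus: str, n: int) -> list[str]:
    return [f"ASV_{genus}_{k + 1}" for k in range(n)]


def _asv_split(n: int) -> np.ndarray:
    """Fixed within-genus ASV proportions (geometric, normalized)."""
    w = 0.6 ** np.arange(n)
    return w / w.sum()


def simulate_dataset(cfg: SimulationConfig
                     ) -> tuple[CountTable, TaxonomyMap, SampleMetadata,
                                GroundTruth]:
    """Generate (CountTable, TaxonomyMap, SampleMetadata, GroundTruth)."""
    seed = int(cfg.seed)
    truth = GroundTruth(associations=list(cfg.associations))

    # --- host tree and clades ---
    if cfg.host_tree is not None:
        tree = cfg.host_tree
        clades = assign_clades(tree, cfg.n_clades)
    else:
        tree, clades = simulate_host_tree(cfg.n_species, cfg.n_clades,
                                          seed=[seed, _TREE])
    species = sorted(tip.name for tip in tree.tips())
    truth.host_tree = tree
    truth.clades = clades

    # --- species-level presence of heritable genera ---
    pres_rng = np.random.default_rng([seed, _PRESENCE])
    species_presence = pd.DataFrame(
        False, index=species,
        columns=[g.name for g in cfg.heritable]
        + [g.name for g in cfg.environmental],
    )
    for g in cfg.heritable:
        leaf_states = evolve_presence(tree, g.gain, g.loss,
                                      g.root_present, seed=pres_rng)
        for sp in species:
            species_presence.at[sp, g.name] = leaf_states[sp]
    for g in cfg.environmental:
        species_presence[g.name] = True      # available to every species
    truth.species_presence = species_presence

    # --- sample layout ---
    layout_rng = np.random.default_rng([seed, _LAYOUT])
    lo, hi = cfg.queens_per_species
    rows = []
    for sp in species:
        nq = int(layout_rng.integers(lo, hi + 1))
        for j in range(nq):
            rows.append({
                "sample_id": f"{sp}_q{j + 1:02d}",
                "species": sp, "clade": clades[sp],
                "colony": f"{sp}_c{j // 2 + 1}",
                "run": f"run{int(layout_rng.integers(cfg.runs)) + 1}",
                "is_control": False,
            })
    run_names = [f"run{r + 1}" for r in range(cfg.runs)]
    if cfg.contaminants:
        for run in run_names:
            for k in range(cfg.controls_per_run):
                rows.append({
                    "sample_id": f"ctrl_{run}_{k + 1}",
                    "species": "control", "clade": "control",
                    "colony": "control", "run": run, "is_control": True,
                })
    meta = pd.DataFrame(rows).set_index("sample_id")
    samples = [r["sample_id"] for r in rows if not r["is_control"]]
    controls = [r["sample_id"] for r in rows if r["is_control"]]
    truth.control_samples = set(controls)

    # depths: planted shallow samples below the QC threshold
    n_shallow = min(cfg.n_low_depth_samples, len(samples))
    shallow = layout_rng.choice(samples, size=n_shallow, replace=False)
    truth.shallow_samples = {str(s) for s in shallow}
    depth = {}
    for s in samples:
        if s in truth.shallow_samples:
            depth[s] = int(layout_rng.integers(*cfg.low_depth_range))
        else:
            depth[s] = int(layout_rng.integers(*cfg.depth_range))
    for s in controls:
        depth[s] = int(layout_rng.integers(*cfg.control_depth_range))

    # --- sample-level presence with planted associations ---
    genera = [g.name for g in cfg.heritable] + [g.name for g in
                                                cfg.environmental]
    base_prob = {}
    for g in cfg.heritable:
        base_prob[g.name] = {
            sp: (g.infection_prob if species_presence.at[sp, g.name] else 0.0)
            for sp in species
        }
    for g in cfg.environmental:
        base_prob[g.name] = {sp: g.occurrence_prob for sp in species}

    assoc_rng = np.random.default_rng([seed, _PRESENCE, 1])
    presence = pd.DataFrame(False, index=samples, columns=genera)
    for s in samples:
        sp = meta.at[s, "species"]
        drawn: dict[str, bool] = {}
        for a in cfg.associations:
            pa = base_prob[a.genus_a][sp]
            pb = base_prob[a.genus_b][sp]
            if a.genus_a in drawn and a.genus_b in drawn:
                continue
            if a.genus_a not in drawn and a.genus_b not in drawn:
                p11 = _plackett_p11(pa, pb, a.odds_multiplier)
                u = assoc_rng.random()
                if u < p11:
                    drawn[a.genus_a], drawn[a.genus_b] = True, True
                elif u < pa:
                    drawn[a.genus_a], drawn[a.genus_b] = True, False
                elif u < pa + pb - p11:
                    drawn[a.genus_a], drawn[a.genus_b] = False, True
                else:
                    drawn[a.genus_a], drawn[a.genus_b] = False, False
            else:
                known, other = ((a.genus_a, a.genus_b)
                                if a.genus_a in drawn
                                else (a.genus_b, a.genus_a))
                pk = base_prob[known][sp]
                po = base_prob[other][sp]
                p11 = _plackett_p11(pk, po, a.odds_multiplier) \
                    if known == a.genus_a else \
                    _plackett_p11(po, pk, a.odds_multiplier)
                if drawn[known]:
                    cond = p11 / pk if pk > 0 else 0.0
                else:
                    cond = (po - p11) / (1 - pk) if pk < 1 else 0.0
                drawn[other] = bool(assoc_rng.random() < cond)
        for gname in genera:
            if gname in drawn:
                presence.at[s, gname] = drawn[gname]
            else:
                presence.at[s, gname] = bool(
                    assoc_rng.random() < base_prob[gname][sp])
    truth.sample_presence = presence

    # --- taxonomy ---
    lineages: dict[str, Lineage] = {}
    asv_of_genus: dict[str, list[str]] = {}
    gi = 0
    for g in cfg.heritable + cfg.environmental:
        ids = _asv_ids(g.name, g.n_asvs)
        asv_of_genus[g.name] = ids
        for a in ids:
            lineages[a] = _generic_lineage(g.name, gi)
        gi += 1
    contaminant_asvs: dict[str, str] = {}
    for c in cfg.contaminants:
        aid = f"ASV_{c.name}_contam"
        contaminant_asvs[c.name] = aid
        lineages[aid] = _generic_lineage(c.name, gi)
        truth.contaminant_taxa.add(aid)
        gi += 1
    trace_ids = [f"ASV_trace_{k + 1}" for k in range(cfg.n_trace_asvs)]
    for k, a in enumerate(trace_ids):
        lineages[a] = _generic_lineage(f"TraceGenus{k + 1}", gi)
        truth.trace_taxa.add(a)
        gi += 1
    nonbact: list[tuple[str, Lineage, float]] = []
    if cfg.mito_abundance > 0:
        nonbact.append((
            "ASV_mito",
            Lineage(domain="Bacteria", phylum="Proteobacteria",
                    class_="Alphaproteobacteria", order="Rickettsiales",
                    family="Mitochondria"),
            cfg.mito_abundance,
        ))
    if cfg.include_chloroplast:
        nonbact.append((
            "ASV_chloro",
            Lineage(domain="Bacteria", phylum="Cyanobacteria",
                    class_="Cyanobacteriia", order="Chloroplast"),
            0.02,
        ))
    if cfg.include_eukaryote:
        nonbact.append((
            "ASV_euk",
            Lineage(domain="Eukaryota", phylum="Ascomycota",
                    genus="Candida"),
            0.015,
        ))
    for aid, lin, _ in nonbact:
        lineages[aid] = lin
        truth.nonbacterial_taxa.add(aid)

    all_asvs = ([a for ids in asv_of_genus.values() for a in ids]
                + list(contaminant_asvs.values()) + trace_ids
                + [aid for aid, _, _ in nonbact])

    # --- per-run batch effect on genus weights ---
    ab_rng = np.random.default_rng([seed, _ABUNDANCE])
    batch = {
        (run, g): float(np.exp(ab_rng.normal(0.0, cfg.batch_effect_sd)))
        for run in run_names for g in genera
    } if cfg.batch_effect_sd > 0 else {
        (run, g): 1.0 for run in run_names for g in genera
    }
    mean_ab = {g.name: g.mean_abundance
               for g in cfg.heritable + cfg.environmental}

    # --- compose and draw counts ---
    counts_rng = np.random.default_rng([seed, _COUNTS])
    trace_presence = {
        a: set(np.asarray(samples)[
            counts_rng.random(len(samples)) < cfg.trace_prevalence])
        for a in trace_ids
    }
    nonbact_presence = {}
    for aid, _, ab in nonbact:
        if aid == "ASV_mito":
            nonbact_presence[aid] = set(samples)
        else:
            nonbact_presence[aid] = set(np.asarray(samples)[
                counts_rng.random(len(samples)) < 0.3])
    ubiq = [c for c in cfg.contaminants if c.kind == "ubiquitous"]

    table = pd.DataFrame(0, index=samples + controls, columns=all_asvs,
                         dtype=np.int64)
    for s in samples:
        run = meta.at[s, "run"]
        fixed: dict[str, float] = {}
        for aid, _, ab in nonbact:
            if s in nonbact_presence[aid]:
                fixed[aid] = ab
        for c in ubiq:
            fixed[contaminant_asvs[c.name]] = c.sample_abundance
        for a in trace_ids:
            if s in trace_presence[a]:
                fixed[a] = cfg.trace_abundance
        present = [g for g in genera if presence.at[s, g]]
        remainder = max(0.0, 1.0 - sum(fixed.values()))
        frac: dict[str, float] = dict(fixed)
        if present:
            w = np.array([mean_ab[g] * batch[(run, g)] for g in present])
            w = w / w.sum()
            if cfg.dirichlet_concentration is not None:
                w = counts_rng.dirichlet(cfg.dirichlet_concentration * w)
            for g, wg in zip(present, w):
                share = remainder * float(wg)
                split = _asv_split(len(asv_of_genus[g]))
                for a, sw in zip(asv_of_genus[g], split):
                    frac[a] = share * float(sw)
        total = sum(frac.values())
        if total <= 0:
            continue
        asvs = list(frac)
        p = np.array([frac[a] for a in asvs]) / total
        draw = counts_rng.multinomial(depth[s], p)
        table.loc[s, asvs] = draw
    ctrl_rng = np.random.default_rng([seed, _CONTROLS])
    for s in controls:
        frac = {}
        for c in cfg.contaminants:
            frac[contaminant_asvs[c.name]] = c.control_abundance
        total = sum(frac.values())
        if total <= 0:
            continue
        asvs = list(frac)
        p = np.array([frac[a] for a in asvs]) / total
        table.loc[s, asvs] = ctrl_rng.multinomial(depth[s], p)

    # drop empty rows/columns (a sample with no reads does not exist);
    # keep truth consistent with what is emitted
    table = table.loc[table.sum(axis=1) > 0]
    dead = [c for c in table.columns if table[c].sum() == 0]
    table = table.drop(columns=dead)
    truth.contaminant_taxa -= set(dead)
    truth.nonbacterial_taxa -= set(dead)
    truth.trace_taxa -= set(dead)

    count_table = CountTable(table)
    taxonomy = TaxonomyMap({a: lineages[a] for a in table.columns})
    metadata = SampleMetadata(meta)
    return count_table, taxonomy, metadata, truth


def association_screen_config(seed: int = 0,
                              positive_odds: float = 15.0,
                              negative_odds: float = 1.0 / 15.0
                              ) -> SimulationConfig:
    """Scenario with one planted synergy and one planted antagonism.

    Sixty samples (6 species x 10 queens, one run), four facultative genera
    at 50% occurrence — SynA/SynB co-occur with the given positive odds
    multiplier, AntA/AntB with the negative one — plus the ubiquitous gut
    background. No contaminants or host reads, so the co-occurrence screen
    sees the planted structure directly.
    """
    return SimulationConfig(
        n_species=6, n_clades=2, queens_per_species=(10, 10),
        heritable=[],
        environmental=[
            EnvironmentalGenus("SynA", 0.5, 0.12),
            EnvironmentalGenus("SynB", 0.5, 0.12),
            EnvironmentalGenus("AntA", 0.5, 0.12),
            EnvironmentalGenus("AntB", 0.5, 0.12),
            EnvironmentalGenus("Enterobacter", 1.0, 0.10),
        ],
        associations=[
            Association("SynA", "SynB", positive_odds),
            Association("AntA", "AntB", negative_odds),
        ],
        contaminants=[], n_trace_asvs=0, mito_abundance=0.0,
        include_chloroplast=False, include_eukaryote=False,
        depth_range=(5000, 9000), n_low_depth_samples=0,
        runs=1, controls_per_run=0, batch_effect_sd=0.0,
        dirichlet_concentration=100.0, seed=seed,
    )


def null_cooccurrence_config(seed: int = 0) -> SimulationConfig:
    """Calibration scenario: two independent genera, no planted association.

    150 samples (5 species x 30 queens, one run) with two facultative genera
    at 50% occurrence and no association override — the per-pair
    false-positive rate of the screen at alpha should sit near (just below,
    given the exact test's discreteness) the nominal level.
    """
    return SimulationConfig(
        n_species=5, n_clades=2, queens_per_species=(30, 30),
        heritable=[],
        environmental=[
            EnvironmentalGenus("NullA", 0.5, 0.15),
            EnvironmentalGenus("NullB", 0.5, 0.15),
            EnvironmentalGenus("Enterobacter", 1.0, 0.10),
        ],
        associations=[], contaminants=[], n_trace_asvs=0,
        mito_abundance=0.0, include_chloroplast=False,
        include_eukaryote=False, depth_range=(5000, 9000),
        n_low_depth_samples=0, runs=1, controls_per_run=0,
        batch_effect_sd=0.0, dirichlet_concentration=100.0, seed=seed,
    )


def strong_phylosymbiosis_config(seed: int = 0,
                                 n_species: int = 14,
                                 n_clades: int = 5) -> SimulationConfig:
    """Scenario with strong vertical transmission and no nuisance structure.

    Many independently evolving heritable genera (moderate gain/loss around
    the stationary midpoint, full within-species carriage), no environmental
    genera, contaminants or host reads, and deep even sequencing — the
    regime where the phylobiome tree should track the host tree closely.
    """
    heritable = [
        HeritableGenus(f"Symbiont{k + 1:02d}", gain=0.25, loss=0.25,
                       mean_abundance=1.0, n_asvs=1,
                       root_present=bool(k % 2), infection_prob=1.0)
        for k in range(48)
    ]
    return SimulationConfig(
        n_species=n_species, n_clades=n_clades,
        queens_per_species=(2, 4),
        heritable=heritable, environmental=[], associations=[],
        contaminants=[], n_trace_asvs=0, mito_abundance=0.0,
        include_chloroplast=False, include_eukaryote=False,
        depth_range=(6000, 10000), n_low_depth_samples=0,
        runs=1, controls_per_run=0, batch_effect_sd=0.0,
        dirichlet_concentration=200.0, seed=seed,
    )
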
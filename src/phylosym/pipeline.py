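"""End-to-end workflow: QC -> community stats -> co-occurrence -> phylobiome
-> congruence, with a provenance manifest.

All stage parameters default to the study values (1% abundance cut, 3,000
read depth floor, 1,000 PERMANOVA permutations, 100 SIMPER permutations,
rarefaction depth 3,000 x 100 iterations, 1,000 random trees, alpha 0.05)
and flow from a single :class:`RunConfig` plus one master seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
from skbio import TreeNode

from phylosym import __version__
from phylosym.community import PERMANOVA, SIMPER, BetaDispersion, bray_curtis
from phylosym.cooccurrence import CooccurrenceScreen
from phylosym.datamodel import (
    CountTable, SampleMetadata, TaxonomyMap, collapse_by_genus,
    collapse_by_species, read_count_table, read_metadata, read_taxonomy,
    to_relative_abundance,
)
from phylosym.phylobiome import PhylobiomeSpec, build_phylobiome
from phylosym.congruence import TreeCongruence
from phylosym.qc import QCConfig, run_qc

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Paths plus stage parameters; defaults are the study values."""

    table: str = ""
    taxonomy: str = ""
    metadata: str = ""
    host_tree: str | None = None
    min_frac: float = 0.01
    trace_frac: float = 0.01
    ubiquity_frac: float = 1.0
    min_depth: int = 3000
    permanova_permutations: int = 1000
    simper_permutations: int = 100
    rarefaction_depth: int = 3000
    rarefaction_iterations: int = 100
    n_random_trees: int = 1000
    random_tree_model: str = "uniform"
    alpha: float = 0.05
    min_genus_samples: int = 3
    phylobiome_genera: list[str] = field(default_factory=list)
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_all(cfg: RunConfig, out_dir,
            inputs: tuple[CountTable, TaxonomyMap, SampleMetadata] | None
            = None) -> Path:
    """Execute the full workflow, writing every intermediate artifact.

    ``inputs`` may supply in-memory objects (as the simulator produces);
    otherwise the paths in ``cfg`` are read. Returns the output directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if inputs is not None:
        table, tax, meta = inputs
    else:
        for name in ("table", "taxonomy", "metadata"):
            p = getattr(cfg, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"missing input: {name} ({p!r})")
        table = read_count_table(cfg.table)
        tax = read_taxonomy(cfg.taxonomy)
        meta = read_metadata(cfg.metadata)
    host = None
    if cfg.host_tree:
        if not Path(cfg.host_tree).exists():
            raise FileNotFoundError(f"missing input: host_tree "
                                    f"({cfg.host_tree!r})")
        host = TreeNode.read(cfg.host_tree, format="newick")

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    qcfg = QCConfig(min_frac=cfg.min_frac, trace_frac=cfg.trace_frac,
                    ubiquity_frac=cfg.ubiquity_frac,
                    min_depth=cfg.min_depth)
    filtered, report = _stage("qc", lambda: run_qc(table, tax, meta, qcfg))
    filtered.write(out / "filtered.tsv")
    report.write(out / "qc_report.tsv")

    meta_kept = meta.subset(filtered.sample_ids)
    rel = to_relative_abundance(filtered)
    dm = _stage("distance", lambda: bray_curtis(rel))

    stats_frames = []
    for terms, strata, tag in [
        (["run"], None, "run"),
        (["run", "clade", "run:clade"], None, "run_x_clade"),
        (["clade"], "run", "clade_blocked"),
        (["species"], "run", "species_blocked"),
    ]:
        res = _stage(f"permanova:{tag}", lambda terms=terms, strata=strata:
                     PERMANOVA(dm, meta_kept.df, terms, strata=strata)
                     .fit(n_permutations=cfg.permanova_permutations,
                          seed=cfg.seed))
        frame = res.table.reset_index()
        frame.insert(0, "model", tag)
        stats_frames.append(frame)
    pd.concat(stats_frames).to_csv(out / "permanova.tsv", sep="\t",
                                   index=False)

    for factor in ("clade", "species"):
        disp = _stage(f"betadisper:{factor}", lambda factor=factor:
                      BetaDispersion(dm, meta_kept.df[factor]).fit())
        disp.distances.to_frame().assign(group=meta_kept.df[factor]) \
            .to_csv(out / f"dispersion_{factor}.tsv", sep="\t")
        simp = _stage(f"simper:{factor}", lambda factor=factor:
                      SIMPER(rel, meta_kept.df[factor])
                      .fit(n_permutations=cfg.simper_permutations,
                           seed=cfg.seed))
        pairs = []
        for (ga, gb), frame in simp.pairs.items():
            f = frame.reset_index()
            f.insert(0, "group_b", gb)
            f.insert(0, "group_a", ga)
            pairs.append(f)
        pd.concat(pairs).to_csv(out / f"simper_{factor}.tsv", sep="\t",
                                index=False)

    genus = _stage("collapse_genus", lambda: collapse_by_genus(filtered, tax))
    genus.write(out / "genus.tsv")
    cooc = _stage("cooccurrence", lambda:
                  CooccurrenceScreen(genus, meta_kept,
                                     cfg.min_genus_samples)
                  .fit(alpha=cfg.alpha))
    cooc.to_frame().to_csv(out / "cooccurrence.tsv", sep="\t", index=False)

    by_species = _stage("collapse_species",
                        lambda: collapse_by_species(filtered, meta_kept))
    congruence_rows = []
    targets = [None] + list(cfg.phylobiome_genera)
    for g in targets:
        tag = g or "full"
        spec = PhylobiomeSpec(genus=g, depth=cfg.rarefaction_depth,
                              iterations=cfg.rarefaction_iterations,
                              seed=cfg.seed)
        pb = _stage(f"phylobiome:{tag}", lambda spec=spec:
                    build_phylobiome(by_species, spec, tax=tax))
        pb.write_newick(out / f"phylobiome_{tag}.nwk")
        if host is not None:
            res = _stage(f"congruence:{tag}", lambda pb=pb:
                         TreeCongruence(pb.tree, host)
                         .fit(metrics=("RFC", "MC"),
                              n_random=cfg.n_random_trees,
                              model=cfg.random_tree_model, seed=cfg.seed))
            for metric in ("RFC", "MC"):
                congruence_rows.append({
                    "tree": tag, "metric": metric,
                    "observed": res.raw(metric),
                    "null_mean": res.null_mean(metric),
                    "normalized": res.normalized(metric),
                    "p": res.p_value(metric),
                    "n_random": res.n_random,
                    "n_leaves": len(res.leaf_set),
                })
    if congruence_rows:
        pd.DataFrame(congruence_rows).to_csv(out / "congruence.tsv",
                                             sep="\t", index=False)

    manifest = {
        "phylosym_version": __version__,
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_samples_in": table.shape[0],
        "n_samples_after_qc": filtered.shape[0],
        "n_taxa_after_qc": filtered.shape[1],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return out
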
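"""Post-denoising QC filters for ASV count tables.

Four order-defined steps, each returning the filtered table plus an audit
record, composed by :func:`run_qc`:

1. per-sample low-abundance zeroing (cells < 1% of their sample's total),
2. removal of mitochondrial / chloroplast / non-bacterial ASVs,
3. run-wise negative-control contaminant rules,
4. removal of samples below a minimum summed count (default 3,000).

The depth cut runs last, so that it is applied to the fully filtered table;
in a typical run it removes every negative control and any shallow samples.
The composition is idempotent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from phylosym.datamodel import CountTable, SampleMetadata, TaxonomyMap

__all__ = [
    "FilterStep", "FilterReport", "QCConfig",
    "filter_low_abundance", "filter_nonbacterial", "filter_contaminants",
    "filter_low_depth", "run_qc",
]


@dataclass
class FilterStep:
    name: str
    taxa_removed: list[str] = field(default_factory=list)
    samples_removed: list[str] = field(default_factory=list)
    cells_zeroed: int = 0
    notes: list[str] = field(default_factory=list)


@dataclass
class FilterReport:
    """Ordered audit trail of filtering; totals are checked for consistency."""

    steps: list[FilterStep] = field(default_factory=list)
    before_shape: tuple[int, int] = (0, 0)
    after_shape: tuple[int, int] = (0, 0)

    def merged(self, other: "FilterReport") -> "FilterReport":
        return FilterReport(
            steps=self.steps + other.steps,
            before_shape=self.before_shape,
            after_shape=other.after_shape,
        )

    @property
    def taxa_removed(self) -> list[str]:
        return [t for s in self.steps for t in s.taxa_removed]

    @property
    def samples_removed(self) -> list[str]:
        return [x for s in self.steps for x in s.samples_removed]

    def validate(self) -> None:
        n0, m0 = self.before_shape
        n1, m1 = self.after_shape
        if n0 - len(set(self.samples_removed)) != n1:
            raise AssertionError("sample totals inconsistent in FilterReport")
        if m0 - len(set(self.taxa_removed)) != m1:
            raise AssertionError("taxon totals inconsistent in FilterReport")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.steps:
            rows.append({
                "step": s.name,
                "taxa_removed": len(s.taxa_removed),
                "samples_removed": len(s.samples_removed),
                "cells_zeroed": s.cells_zeroed,
                "notes": "; ".join(s.notes),
            })
        return pd.DataFrame(
            rows,
            columns=["step", "taxa_removed", "samples_removed",
                     "cells_zeroed", "notes"],
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class QCConfig:
    """Thresholds for the QC chain; defaults follow the study design."""

    min_frac: float = 0.01        # per-sample relative-abundance cut
    trace_frac: float = 0.01      # "trace" level within a control (reporting)
    ubiquity_frac: float = 1.0    # fraction of a run's samples = "ubiquitous"
    min_depth: int = 3000         # minimum summed count per sample


def _report(step: FilterStep, before, after) -> FilterReport:
    return FilterReport(steps=[step], before_shape=before, after_shape=after)


def filter_low_abundance(
    t: CountTable, threshold: float = 0.01
) -> tuple[CountTable, FilterReport]:
    """Zero cells below ``threshold`` of their sample's total.

    The cut-off is computed from the row sum *before* any zeroing in this
    step, and the inequality is strict (< 1%, so a cell at exactly 1% stays).
    Columns that become all-zero everywhere are dropped.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0,1), got {threshold}")
    counts = t.counts().astype(float)
    cut = counts.sum(axis=1, keepdims=True) * threshold
    mask = counts < cut          # strict: exactly at threshold is retained
    zeroed = int((mask & (counts > 0)).sum())
    out = t.df.where(~mask, 0)
    dead = sorted(out.columns[out.sum(axis=0) == 0])
    out = out.drop(columns=dead)
    step = FilterStep("low_abundance", taxa_removed=dead, cells_zeroed=zeroed)
    return CountTable(out), _report(step, t.shape, out.shape)


def filter_nonbacterial(
    t: CountTable, tax: TaxonomyMap
) -> tuple[CountTable, FilterReport]:
    """Drop mitochondrial, chloroplast and non-bacterial ASV columns."""
    drop = []
    for tid in t.taxon_ids:
        if tid not in tax:
            raise ValueError(f"taxon {tid!r} missing from taxonomy")
        if (tax.is_mitochondrial(tid) or tax.is_chloroplast(tid)
                or not tax.is_bacterial(tid)):
            drop.append(tid)
    out = t.df.drop(columns=drop)
    step = FilterStep("nonbacterial", taxa_removed=drop)
    return CountTable(out), _report(step, t.shape, out.shape)


def filter_contaminants(
    t: CountTable,
    m: SampleMetadata,
    trace_fraction: float = 0.01,
    ubiquity_fraction: float = 1.0,
) -> tuple[CountTable, FilterReport]:
    """Apply the negative-control contaminant rules, run by run.

    The study filtered each sequencing run's table separately and combined
    the tables afterwards, so the rules act on each run's sub-table. Within a
    run, an ASV is treated as a contaminant iff

    (a) it occurs only in that run's controls (unique to controls), or
    (b) it occurs in a control AND in at least ``ubiquity_fraction`` of the
        run's non-control samples (reagent contaminant spread run-wide),

    in which case its counts are zeroed across that run's samples. ASVs
    present in a control but also present in some (not ubiquitous) samples
    are retained; the report notes whether their level inside the control was
    below ``trace_fraction`` relative abundance. Controls themselves are
    removed from the table afterwards, and columns left without any counts
    are dropped.
    """
    meta = m.df.reindex(t.sample_ids)
    if meta.isna().any(axis=1).any():
        missing = meta.index[meta.isna().any(axis=1)][0]
        raise ValueError(f"sample {missing!r} missing from metadata")
    step = FilterStep("contaminants")
    out = t.df.copy()
    for run in sorted(meta["run"].astype(str).unique()):
        in_run = meta.index[meta["run"].astype(str) == str(run)]
        ctrl = [s for s in in_run if meta.at[s, "is_control"]]
        samp = [s for s in in_run if not meta.at[s, "is_control"]]
        if not ctrl:
            msg = f"run {run!r} has no negative control; contaminant rules skipped"
            warnings.warn(msg, stacklevel=2)
            step.notes.append(msg)
            continue
        if not samp:
            continue
        ctrl_counts = t.df.loc[ctrl]
        samp_counts = t.df.loc[samp]
        in_ctrl = (ctrl_counts > 0).any(axis=0)
        prevalence = (samp_counts > 0).mean(axis=0)
        ctrl_totals = ctrl_counts.sum(axis=1).to_numpy(dtype=float)
        ctrl_rel = ctrl_counts.to_numpy(dtype=float) / np.where(
            ctrl_totals == 0, 1.0, ctrl_totals)[:, None]
        for j, asv in enumerate(t.df.columns):
            if not in_ctrl[asv]:
                continue
            if prevalence[asv] == 0:
                step.notes.append(f"run {run}: {asv} unique to controls")
            elif prevalence[asv] >= ubiquity_fraction:
                step.cells_zeroed += int((out.loc[samp, asv] > 0).sum())
                out.loc[samp, asv] = 0
                step.notes.append(f"run {run}: {asv} control+ubiquitous, zeroed")
            else:
                level = ("trace" if ctrl_rel[:, j].max() < trace_fraction
                         else "non-trace")
                step.notes.append(
                    f"run {run}: retained {asv} ({level} in control, "
                    f"prevalence {prevalence[asv]:.2f})"
                )
    controls = [s for s in t.sample_ids if bool(meta.at[s, "is_control"])]
    out = out.drop(index=controls)
    dead = sorted(out.columns[out.sum(axis=0) == 0])
    out = out.drop(columns=dead)
    step.taxa_removed = dead
    step.samples_removed = controls
    return CountTable(out), _report(step, t.shape, out.shape)


def filter_low_depth(
    t: CountTable, min_total: int = 3000
) -> tuple[CountTable, FilterReport]:
    """Drop samples whose summed count is strictly below ``min_total``."""
    totals = t.sample_totals()
    shallow = list(totals.index[totals < min_total])
    out = t.df.drop(index=shallow)
    step = FilterStep("low_depth", samples_removed=shallow)
    return CountTable(out), _report(step, t.shape, out.shape)


def run_qc(
    t: CountTable,
    tax: TaxonomyMap,
    m: SampleMetadata,
    config: QCConfig | None = None,
) -> tuple[CountTable, FilterReport]:
    """Full QC chain: abundance cut, taxon filter, contaminant rules, depth cut."""
    cfg = config or QCConfig()
    t1, r1 = filter_low_abundance(t, cfg.min_frac)
    t2, r2 = filter_nonbacterial(t1, tax)
    meta = m.df.reindex(t2.sample_ids)
    has_controls = bool(meta["is_control"].any())
    if has_controls:
        t3, r3 = filter_contaminants(
            t2, m, trace_fraction=cfg.trace_frac,
            ubiquity_fraction=cfg.ubiquity_frac,
        )
    else:
        t3, r3 = t2, FilterReport(
            steps=[FilterStep("contaminants",
                              notes=["no controls present; step skipped"])],
            before_shape=t2.shape, after_shape=t2.shape,
        )
    t4, r4 = filter_low_depth(t3, cfg.min_depth)
    if t4.shape[0] == 0:
        raise ValueError("no samples survive QC")
    report = r1.merged(r2).merged(r3).merged(r4)
    report.validate()
    return t4, report
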
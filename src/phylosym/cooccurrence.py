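"""Conditioned pairwise co-occurrence screen across bacterial genera.

Each genus pair is tested with a two-sided Fisher's exact test on a 2x2
presence table, but the samples entering the table are conditioned the way
the study design demands:

(i)   only genera found together in at least one (species, run) combination
      are compared;
(ii)  only samples from (species, run) combinations in which *both* genera
      occur are counted — combinations where only one of the two occurs are
      excluded;
(iii) only genera found in more than two samples overall enter the screen.

The odds ratio is the sample odds ratio n_both*n_neither / (n_a_only*n_b_only)
and is flagged undefined when any cell is zero. No multiplicity adjustment is
applied by default (each pair judged at alpha); a Benjamini-Hochberg option
is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats

from phylosym.datamodel import CountTable, SampleMetadata

__all__ = [
    "PairTable2x2", "build_pair_tables", "fisher_exact_2x2",
    "CooccurrenceScreen", "CooccurrenceResults", "screen_cooccurrence",
]


@dataclass
class PairTable2x2:
    """Presence/absence 2x2 for a genus pair over the included samples."""

    genus_a: str
    genus_b: str
    n_both: int
    n_a_only: int
    n_b_only: int
    n_neither: int
    combinations: list[tuple[str, str]] = field(default_factory=list)
    per_run: dict[str, tuple[int, int, int, int]] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.n_both + self.n_a_only + self.n_b_only + self.n_neither

    def as_array(self) -> np.ndarray:
        return np.array([[self.n_both, self.n_a_only],
                         [self.n_b_only, self.n_neither]])


def build_pair_tables(
    g: CountTable,
    m: SampleMetadata,
    min_genus_samples: int = 3,
) -> list[PairTable2x2]:
    """Build conditioned 2x2 tables for every eligible genus pair.

    ``g`` is a genus-collapsed, QC-filtered count table (controls removed);
    presence means any nonzero count. A pair (A, B) is emitted iff A and B
    each occur in at least ``min_genus_samples`` samples overall and share at
    least one (run, species) combination; its cells count only samples from
    combinations containing both genera.
    """
    meta = m.df.reindex(g.sample_ids)
    if meta.isna().any(axis=1).any():
        bad = meta.index[meta.isna().any(axis=1)][0]
        raise ValueError(f"sample {bad!r} missing from metadata")
    if meta["is_control"].any():
        bad = meta.index[meta["is_control"]][0]
        raise ValueError(f"control sample {bad!r} present; exclude controls")
    presence = g.df.to_numpy() > 0
    genera = list(g.df.columns)
    prevalence = presence.sum(axis=0)
    eligible = [j for j, p in enumerate(prevalence) if p >= min_genus_samples]

    combo_key = list(zip(meta["run"].astype(str),
                         meta["species"].astype(str)))
    combo_levels = list(dict.fromkeys(combo_key))
    combo_members = {
        c: np.array([i for i, k in enumerate(combo_key) if k == c])
        for c in combo_levels
    }
    # genus presence per combination
    combo_has = {
        c: presence[rows].any(axis=0) for c, rows in combo_members.items()
    }

    tables: list[PairTable2x2] = []
    for ja, jb in combinations(eligible, 2):
        shared = [c for c in combo_levels
                  if combo_has[c][ja] and combo_has[c][jb]]
        if not shared:
            continue
        rows = np.concatenate([combo_members[c] for c in shared])
        a = presence[rows, ja]
        b = presence[rows, jb]
        per_run: dict[str, tuple[int, int, int, int]] = {}
        runs = meta["run"].astype(str).to_numpy()[rows]
        for run in pd.unique(runs):
            sel = runs == run
            per_run[str(run)] = (
                int((a[sel] & b[sel]).sum()), int((a[sel] & ~b[sel]).sum()),
                int((~a[sel] & b[sel]).sum()), int((~a[sel] & ~b[sel]).sum()),
            )
        tables.append(PairTable2x2(
            genus_a=genera[ja], genus_b=genera[jb],
            n_both=int((a & b).sum()), n_a_only=int((a & ~b).sum()),
            n_b_only=int((~a & b).sum()), n_neither=int((~a & ~b).sum()),
            combinations=[(sp, run) for run, sp in shared],
            per_run=per_run,
        ))
    return tables


def fisher_exact_2x2(t: PairTable2x2 | np.ndarray) -> tuple[float, float | None]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns ``(p, odds_ratio)``; the odds ratio is ``None`` (undefined) when
    any cell is zero. The two-sided p sums hypergeometric point
    probabilities no larger than the observed table's.
    """
    arr = t.as_array() if isinstance(t, PairTable2x2) else np.asarray(t)
    if arr.sum() == 0:
        raise ValueError("all-zero 2x2 table")
    _, p = scipy.stats.fisher_exact(arr, alternative="two-sided")
    a, b, c, d = arr.ravel()
    odds = (a * d) / (b * c) if min(a, b, c, d) > 0 else None
    return float(p), odds


@dataclass
class PairResult:
    table: PairTable2x2
    p: float
    odds_ratio: float | None
    direction: str            # "positive" | "negative" | "none"
    significant: bool
    q: float | None = None    # BH-adjusted, when requested

    @property
    def or_defined(self) -> bool:
        return self.odds_ratio is not None


@dataclass
class CooccurrenceResults:
    """All tested pairs, sorted by p-value."""

    results: list[PairResult]
    alpha: float
    adjusted: bool

    def significant(self) -> list[PairResult]:
        return [r for r in self.results if r.significant]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            t = r.table
            rows.append({
                "genus_a": t.genus_a, "genus_b": t.genus_b,
                "n_both": t.n_both, "n_a_only": t.n_a_only,
                "n_b_only": t.n_b_only, "n_neither": t.n_neither,
                "odds_ratio": (np.nan if r.odds_ratio is None
                               else r.odds_ratio),
                "or_defined": r.or_defined,
                "p": r.p, "significant": r.significant,
                "direction": r.direction,
            })
        cols = ["genus_a", "genus_b", "n_both", "n_a_only", "n_b_only",
                "n_neither", "odds_ratio", "or_defined", "p", "significant",
                "direction"]
        return pd.DataFrame(rows, columns=cols)

    def summary(self) -> str:
        frame = self.to_frame()
        lines = [
            f"Co-occurrence screen: {len(self.results)} pairs tested, "
            f"{len(self.significant())} significant at alpha={self.alpha}"
            + (" (BH-adjusted)" if self.adjusted else ""),
        ]
        if len(frame):
            lines.append(frame.to_string(index=False,
                                         float_format=lambda x: f"{x:.4g}"))
        return "\n".join(lines)


class CooccurrenceScreen:
    """Fisher's-exact co-occurrence model over a genus table + metadata."""

    def __init__(self, genus_table: CountTable, metadata: SampleMetadata,
                 min_genus_samples: int = 3):
        self.table = genus_table
        self.metadata = metadata
        self.min_genus_samples = min_genus_samples

    def fit(self, alpha: float = 0.05, adjust: bool = False
            ) -> CooccurrenceResults:
        tables = build_pair_tables(self.table, self.metadata,
                                   self.min_genus_samples)
        results = []
        for t in tables:
            p, odds = fisher_exact_2x2(t)
            cross = t.n_both * t.n_neither - t.n_a_only * t.n_b_only
            direction = ("positive" if cross > 0
                         else "negative" if cross < 0 else "none")
            results.append(PairResult(table=t, p=p, odds_ratio=odds,
                                      direction=direction, significant=False))
        results.sort(key=lambda r: (r.p, r.table.genus_a, r.table.genus_b))
        if adjust and results:
            ps = np.array([r.p for r in results])
            order = np.argsort(ps)
            q = np.empty_like(ps)
            m = len(ps)
            prev = 1.0
            for rank_pos in range(m - 1, -1, -1):
                i = order[rank_pos]
                prev = min(prev, ps[i] * m / (rank_pos + 1))
                q[i] = prev
            for r, qi in zip(results, q):
                r.q = float(qi)
                r.significant = qi < alpha
        else:
            for r in results:
                r.significant = r.p < alpha
        return CooccurrenceResults(results=results, alpha=alpha,
                                   adjusted=adjust)


def screen_cooccurrence(g: CountTable, m: SampleMetadata, alpha: float = 0.05,
                        min_genus_samples: int = 3) -> CooccurrenceResults:
    """Functional wrapper over :class:`CooccurrenceScreen`."""
    return CooccurrenceScreen(g, m, min_genus_samples).fit(alpha=alpha)
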
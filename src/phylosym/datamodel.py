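"""Core data types for feature-table analysis.

A :class:`CountTable` is the central exchange object: an integer matrix of
read counts with samples as rows and taxa (ASVs or genera) as columns, backed
by a :class:`pandas.DataFrame`. Orientation is always explicit — tables are
serialized samples-as-rows and the reader takes an orientation flag rather
than guessing, because silent transposition is the classic feature-table bug.

Counts stay integral end-to-end; conversion to relative abundance is an
explicit, one-way step (rarefaction downstream requires integer counts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountTable", "RelAbundanceTable", "Lineage", "TaxonomyMap",
    "SampleMetadata", "read_count_table", "read_taxonomy", "read_metadata",
    "to_relative_abundance", "collapse_by_genus", "collapse_by_species",
]

RANKS = ("domain", "phylum", "class", "order", "family", "genus")
_RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__")


def _check_unique(labels, kind: str) -> None:
    seen = set()
    for x in labels:
        if x in seen:
            raise ValueError(f"duplicate {kind} identifier: {x!r}")
        seen.add(x)


class CountTable:
    """Samples x taxa matrix of non-negative integer read counts.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are samples, columns are taxa. Must be integral and >= 0.
    """

    def __init__(self, data: pd.DataFrame):
        _check_unique(data.index, "sample")
        _check_unique(data.columns, "taxon")
        values = data.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.integer):
                frac, _ = np.modf(values.astype(float))
                bad = np.argwhere(frac != 0)
                if bad.size:
                    i, j = bad[0]
                    raise ValueError(
                        f"non-integer count at sample {data.index[i]!r}, "
                        f"taxon {data.columns[j]!r}: {values[i, j]!r}"
                    )
            if (values < 0).any():
                i, j = np.argwhere(values < 0)[0]
                raise ValueError(
                    f"negative count at sample {data.index[i]!r}, "
                    f"taxon {data.columns[j]!r}: {values[i, j]!r}"
                )
        self.df = data.astype(np.int64)
        self.df.index = self.df.index.astype(str)
        self.df.columns = self.df.columns.astype(str)
        self.df.index.name = "sample_id"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def counts(self) -> np.ndarray:
        return self.df.to_numpy()

    def sample_totals(self) -> pd.Series:
        return self.df.sum(axis=1)

    def total(self) -> int:
        return int(self.df.to_numpy().sum())

    def __eq__(self, other) -> bool:
        return isinstance(other, CountTable) and self.df.equals(other.df)

    def __repr__(self) -> str:
        n, m = self.shape
        return f"<CountTable {n} samples x {m} taxa, {self.total()} reads>"

    def write(self, path) -> None:
        """Write as TSV, samples as rows, first column ``sample_id``."""
        self.df.to_csv(path, sep="\t")


@dataclass
class RelAbundanceTable:
    """Row-normalized abundance fractions; all-zero input rows stay zero."""

    df: pd.DataFrame
    zero_samples: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.df.columns)


@dataclass(frozen=True)
class Lineage:
    """Ranked lineage, domain through genus; unresolved ranks are None."""

    domain: str | None = None
    phylum: str | None = None
    class_: str | None = None
    order: str | None = None
    family: str | None = None
    genus: str | None = None

    def rank(self, name: str) -> str | None:
        return getattr(self, "class_" if name == "class" else name)

    def highest_resolved(self) -> tuple[str, str] | None:
        """Deepest (rank, label) that is resolved, or None."""
        for r in reversed(RANKS):
            v = self.rank(r)
            if v:
                return r, v
        return None

    def to_string(self) -> str:
        parts = []
        for pre, r in zip(_RANK_PREFIXES, RANKS):
            v = self.rank(r)
            parts.append(f"{pre}{v or ''}")
        return ";".join(parts)

    @classmethod
    def from_string(cls, s: str) -> "Lineage":
        vals: dict[str, str | None] = {}
        for token in s.split(";"):
            token = token.strip()
            for pre, r in zip(_RANK_PREFIXES, RANKS):
                if token.startswith(pre):
                    v = token[len(pre):].strip()
                    vals["class_" if r == "class" else r] = v or None
        return cls(**vals)


class TaxonomyMap:
    """taxon_id -> ranked lineage, with host/organelle flags.

    Flags are derived from the lineage strings (SILVA conventions): an ASV is
    mitochondrial if "Mitochondria" appears at family (or any) rank,
    chloroplast if "Chloroplast" appears, and bacterial iff its domain is
    "Bacteria".
    """

    def __init__(self, lineages: dict[str, Lineage]):
        self._lineages = dict(lineages)

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self._lineages

    def __len__(self) -> int:
        return len(self._lineages)

    def lineage(self, taxon_id: str) -> Lineage:
        return self._lineages[taxon_id]

    def genus(self, taxon_id: str) -> str | None:
        return self._lineages[taxon_id].genus

    def is_mitochondrial(self, taxon_id: str) -> bool:
        lin = self._lineages[taxon_id]
        return any((lin.rank(r) or "").lower() == "mitochondria" for r in RANKS)

    def is_chloroplast(self, taxon_id: str) -> bool:
        lin = self._lineages[taxon_id]
        return any((lin.rank(r) or "").lower() == "chloroplast" for r in RANKS)

    def is_bacterial(self, taxon_id: str) -> bool:
        return (self._lineages[taxon_id].domain or "") == "Bacteria"

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("taxon_id\tlineage\n")
            for tid, lin in self._lineages.items():
                fh.write(f"{tid}\t{lin.to_string()}\n")


class SampleMetadata:
    """Per-sample attributes: species, clade, colony, sequencing run, control flag.

    Invariants: every non-control sample carries species, clade and run; clade
    is a deterministic function of species (one clade per species).
    """

    COLUMNS = ("species", "clade", "colony", "run", "is_control")

    def __init__(self, data: pd.DataFrame):
        _check_unique(data.index, "sample")
        missing = [c for c in self.COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        df = data.loc[:, list(self.COLUMNS)].copy()
        df.index = df.index.astype(str)
        df.index.name = "sample_id"
        df["is_control"] = df["is_control"].astype(bool)
        noncontrol = df[~df["is_control"]]
        for col in ("species", "clade", "run"):
            bad = noncontrol.index[
                noncontrol[col].isna() | (noncontrol[col].astype(str) == "")
            ]
            if len(bad):
                raise ValueError(
                    f"non-control sample {bad[0]!r} lacks {col!r}"
                )
        clades_per_species = noncontrol.groupby("species")["clade"].nunique()
        multi = clades_per_species[clades_per_species > 1]
        if len(multi):
            raise ValueError(
                f"species {multi.index[0]!r} mapped to multiple clades"
            )
        self.df = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def subset(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.df.loc[list(sample_ids)])

    def controls(self) -> list[str]:
        return list(self.df.index[self.df["is_control"]])

    def noncontrols(self) -> list[str]:
        return list(self.df.index[~self.df["is_control"]])

    def species_of(self, sample_id: str) -> str:
        return str(self.df.at[sample_id, "species"])

    def run_of(self, sample_id: str) -> str:
        return str(self.df.at[sample_id, "run"])

    def runs(self) -> list[str]:
        return sorted(self.df["run"].astype(str).unique())

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_count_table(path, orientation: str = "rows-are-samples") -> CountTable:
    """Read a TSV feature table.

    Parameters
    ----------
    path : str or Path
        Tab-separated text with one header row and one identifier column.
    orientation : {"rows-are-samples", "rows-are-taxa"}
        Explicit layout of the file; ``rows-are-taxa`` files are transposed
        to the canonical samples x taxa layout.
    """
    if orientation not in ("rows-are-samples", "rows-are-taxa"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    if orientation == "rows-are-taxa":
        df = df.T
    return CountTable(df)


def read_taxonomy(path) -> TaxonomyMap:
    """Read a 2-column TSV: taxon_id <tab> SILVA-style lineage string."""
    lineages: dict[str, Lineage] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.lower().startswith("taxon_id"):
            fh.seek(0)
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            tid, _, lin = line.partition("\t")
            if tid in lineages:
                raise ValueError(f"duplicate taxon identifier: {tid!r}")
            lineages[tid] = Lineage.from_string(lin)
    return TaxonomyMap(lineages)


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df["is_control"] = df["is_control"].map(
        lambda s: str(s).strip().lower() in ("1", "true", "yes")
    )
    return SampleMetadata(df)


# ---------------------------------------------------------------------------
# Elementary transformations
# ---------------------------------------------------------------------------

def to_relative_abundance(t: CountTable) -> RelAbundanceTable:
    """Divide each sample row by its total; all-zero rows stay zero (flagged)."""
    counts = t.counts().astype(float)
    totals = counts.sum(axis=1)
    zero = totals == 0
    zero_samples = [s for s, z in zip(t.sample_ids, zero) if z]
    if zero_samples:
        warnings.warn(
            f"samples with zero total reads left as all-zero rows: "
            f"{zero_samples}", stacklevel=2,
        )
    safe = np.where(zero, 1.0, totals)
    rel = counts / safe[:, None]
    df = pd.DataFrame(rel, index=t.df.index, columns=t.df.columns)
    return RelAbundanceTable(df, zero_samples=zero_samples)


def collapse_by_genus(t: CountTable, tax: TaxonomyMap) -> CountTable:
    """Sum ASV columns sharing a genus label.

    ASVs lacking a genus assignment are pooled under
    ``unclassified_<highest-resolved-rank-label>`` so that "other" accounting
    stays possible downstream.
    """
    labels = []
    for tid in t.taxon_ids:
        if tid not in tax:
            raise ValueError(f"taxon {tid!r} missing from taxonomy")
        g = tax.genus(tid)
        if g:
            labels.append(g)
        else:
            hr = tax.lineage(tid).highest_resolved()
            labels.append(f"unclassified_{hr[1]}" if hr else "unclassified")
    grouped = t.df.T.groupby(pd.Index(labels, name="genus"), sort=True).sum().T
    return CountTable(grouped)


def collapse_by_species(t: CountTable, m: SampleMetadata) -> CountTable:
    """Sum queens of one species into a single row labeled by species.

    Controls must have been removed beforehand; every sample must carry a
    species annotation.
    """
    species = []
    for sid in t.sample_ids:
        if sid not in m.df.index:
            raise ValueError(f"sample {sid!r} missing from metadata")
        if m.df.at[sid, "is_control"]:
            raise ValueError(
                f"control sample {sid!r} present; remove controls before "
                f"collapsing by species"
            )
        species.append(m.species_of(sid))
    grouped = t.df.groupby(pd.Index(species, name="sample_id"), sort=True).sum()
    return CountTable(grouped)
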
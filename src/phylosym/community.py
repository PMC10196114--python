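"""Distance-based community statistics.

The three classical tests used on Bray-Curtis matrices, written in the
Model/Results style: construct the model from a distance matrix (or
abundance table) plus sample annotations, call ``fit()``, read the results
object.

* :class:`PERMANOVA` — Anderson's permutational MANOVA with sequential
  (Type-I) sums of squares for multi-term models, optional blocked
  permutations (``strata``), and automatic exact enumeration when the number
  of distinct relabelings is small.
* :class:`BetaDispersion` — homogeneity of multivariate dispersions:
  principal-coordinate embedding with negative-eigenvalue correction,
  distance of each sample to its group centroid, one-way ANOVA on those
  distances.
* :class:`SIMPER` — decomposition of the mean between-group Bray-Curtis
  dissimilarity into per-taxon contributions, with permutation p-values.

Permutation p-values use the plus-one correction (1+hits)/(1+P); ties
between a permuted and the observed statistic count as hits (conservative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from sympy.utilities.iterables import multiset_permutations

from phylosym.datamodel import CountTable, RelAbundanceTable

__all__ = [
    "bray_curtis", "PERMANOVA", "PermanovaResults",
    "BetaDispersion", "DispersionResults", "SIMPER", "SimperResults",
]


def _as_frame(a) -> pd.DataFrame:
    if isinstance(a, CountTable):
        return a.df.astype(float)
    if isinstance(a, RelAbundanceTable):
        return a.df
    return pd.DataFrame(a)


def bray_curtis(a) -> DistanceMatrix:
    """Bray-Curtis dissimilarity matrix, d(x,y) = sum|x-y| / sum(x+y).

    Accepts a :class:`CountTable`, :class:`RelAbundanceTable` or DataFrame
    (samples as rows). All-zero rows are an error, naming the sample.
    """
    df = _as_frame(a)
    if df.shape[0] < 2:
        raise ValueError("need at least two samples")
    totals = df.to_numpy().sum(axis=1)
    if (totals == 0).any():
        bad = df.index[totals == 0][0]
        raise ValueError(f"sample {bad!r} has zero total abundance")
    d = squareform(pdist(df.to_numpy(dtype=float), metric="braycurtis"))
    return DistanceMatrix(d, ids=[str(i) for i in df.index])


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    n = a.shape[0]
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _orthonormal_block(dummies: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Columns of `dummies` orthogonalized against `basis` and each other."""
    resid = dummies - basis @ (basis.T @ dummies)
    q, r = np.linalg.qr(resid)
    keep = np.abs(np.diag(r)) > 1e-9 * max(1.0, np.abs(np.diag(r)).max())
    return q[:, keep]


def _dummy(labels: np.ndarray) -> np.ndarray:
    levels = pd.unique(labels)
    return (labels[:, None] == levels[None, :]).astype(float)


@dataclass
class PermanovaResults:
    """Sequential PERMANOVA table plus permutation metadata."""

    table: pd.DataFrame
    n_permutations: int
    scheme: str
    exact: bool = False
    notes: list[str] = field(default_factory=list)

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]

    @property
    def f_statistics(self) -> pd.Series:
        return self.table["F"].dropna()

    @property
    def p_values(self) -> pd.Series:
        return self.table["Pr(>F)"].dropna()

    def summary(self) -> str:
        lines = [
            "PERMANOVA (sequential sums of squares)",
            f"Permutations: {self.n_permutations} ({self.scheme})",
        ]
        lines.append(self.table.to_string(float_format=lambda x: f"{x:.6g}"))
        lines.extend(self.notes)
        return "\n".join(lines)


class PERMANOVA:
    """Permutational MANOVA on a distance matrix.

    Parameters
    ----------
    distance_matrix : skbio DistanceMatrix
    metadata : pandas.DataFrame
        Indexed by sample id; must cover every id in the distance matrix.
    terms : sequence of str
        Factor columns, in model order. ``"A:B"`` denotes the interaction of
        A and B (cells = label combinations). Sums of squares are sequential,
        so order matters.
    strata : str, optional
        Blocking factor: permutations shuffle samples only within its levels.
    """

    def __init__(self, distance_matrix: DistanceMatrix, metadata: pd.DataFrame,
                 terms, strata: str | None = None):
        self.dm = distance_matrix
        ids = list(distance_matrix.ids)
        missing = [i for i in ids if i not in metadata.index]
        if missing:
            raise ValueError(f"ids missing from metadata: {missing[:5]}")
        self.metadata = metadata.loc[ids]
        self.terms = list(terms)
        self.strata = strata
        self._labels: dict[str, np.ndarray] = {}
        for term in self.terms:
            cols = term.split(":")
            for c in cols:
                if c not in metadata.columns:
                    raise ValueError(f"unknown factor {c!r}")
            if len(cols) == 1:
                lab = self.metadata[cols[0]].astype(str).to_numpy()
            else:
                lab = (self.metadata[cols]
                       .astype(str).agg(":".join, axis=1).to_numpy())
            if len(pd.unique(lab)) < 2 and len(cols) == 1:
                raise ValueError(f"factor {term!r} is constant across samples")
            self._labels[term] = lab
        if strata is not None:
            if strata not in metadata.columns:
                raise ValueError(f"unknown strata factor {strata!r}")
            self._strata_labels = self.metadata[strata].astype(str).to_numpy()
        else:
            self._strata_labels = None

    @classmethod
    def from_formula(cls, formula: str, distance_matrix: DistanceMatrix,
                     metadata: pd.DataFrame, strata: str | None = None
                     ) -> "PERMANOVA":
        """Expand an adonis-style RHS formula: ``A*B`` -> A, B, A:B; ``A+B``."""
        terms: list[str] = []
        for part in formula.replace(" ", "").split("+"):
            if "*" in part:
                facs = part.split("*")
                terms.extend(facs)
                for r in range(2, len(facs) + 1):
                    for combo in combinations(facs, r):
                        terms.append(":".join(combo))
            elif part:
                terms.append(part)
        return cls(distance_matrix, metadata, terms, strata=strata)

    # -- core decomposition -------------------------------------------------

    def _decompose(self):
        n = self.dm.shape[0]
        g = _gower_center(self.dm.data)
        basis = np.full((n, 1), 1.0 / np.sqrt(n))
        blocks = []
        dfs = []
        for term in self.terms:
            q = _orthonormal_block(_dummy(self._labels[term]), basis)
            blocks.append(q)
            dfs.append(q.shape[1])
            basis = np.hstack([basis, q])
        return g, blocks, dfs

    @staticmethod
    def _term_ss(g: np.ndarray, q: np.ndarray) -> float:
        return float(np.einsum("ik,ij,jk->", q, g, q))

    def _f_stats(self, g, blocks, dfs):
        ss_total = float(np.trace(g))
        ss_terms = [self._term_ss(g, q) for q in blocks]
        df_resid = g.shape[0] - 1 - sum(dfs)
        ss_resid = ss_total - sum(ss_terms)
        ms_resid = ss_resid / df_resid if df_resid > 0 else np.nan
        fs = [
            (ss / df) / ms_resid if df > 0 and ms_resid > 0 else np.nan
            for ss, df in zip(ss_terms, dfs)
        ]
        return ss_total, ss_terms, ss_resid, df_resid, fs

    def _permutation_indices(self, n, n_permutations, rng):
        idx = np.arange(n)
        perms = np.empty((n_permutations, n), dtype=np.intp)
        if self._strata_labels is None:
            for p in range(n_permutations):
                perms[p] = rng.permutation(n)
        else:
            blocks = [np.flatnonzero(self._strata_labels == lev)
                      for lev in pd.unique(self._strata_labels)]
            for p in range(n_permutations):
                row = idx.copy()
                for b in blocks:
                    row[b] = b[rng.permutation(len(b))]
                perms[p] = row
        return perms

    def _n_distinct_relabelings(self) -> int:
        lab = self._labels[self.terms[0]]
        _, counts = np.unique(lab, return_counts=True)
        m = factorial(int(counts.sum()))
        for c in counts:
            m //= factorial(int(c))
        return m

    def fit(self, n_permutations: int = 999, seed=None) -> PermanovaResults:
        """Run the test.

        A single-term unblocked model whose number of distinct label
        arrangements does not exceed ``n_permutations`` is evaluated by
        complete enumeration (p = fraction of arrangements, including the
        observed one, with F at least as large).
        """
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        g, blocks, dfs = self._decompose()
        ss_total, ss_terms, ss_resid, df_resid, fs = self._f_stats(
            g, blocks, dfs)
        notes = []
        n = g.shape[0]

        exact = False
        if (len(self.terms) == 1 and self._strata_labels is None
                and self._n_distinct_relabelings() <= n_permutations):
            exact = True
            pvals = [self._exact_p(g, fs[0])]
            n_used = self._n_distinct_relabelings()
            scheme = "complete enumeration of distinct relabelings"
            notes.append(
                f"fewer distinct relabelings ({n_used}) than requested "
                f"permutations ({n_permutations}); exact enumeration used"
            )
        else:
            rng = np.random.default_rng(seed)
            perms = self._permutation_indices(n, n_permutations, rng)
            hits = np.zeros(len(self.terms))
            chunk = max(1, int(2e7) // (n * n))
            for lo in range(0, n_permutations, chunk):
                sel = perms[lo:lo + chunk]
                gp = g[sel[:, :, None], sel[:, None, :]]
                ssp = np.stack([
                    np.einsum("pij,ik,jk->p", gp, q, q) for q in blocks
                ])  # (terms, chunk)
                ss_resid_p = np.trace(g) - ssp.sum(axis=0)
                ms_resid_p = ss_resid_p / df_resid
                for k, df in enumerate(dfs):
                    fp = (ssp[k] / df) / ms_resid_p
                    hits[k] += int(np.sum(fp >= fs[k] - 1e-12))
            pvals = [(1 + h) / (1 + n_permutations) if np.isfinite(f)
                     else np.nan for h, f in zip(hits, fs)]
            n_used = n_permutations
            scheme = ("free permutation" if self._strata_labels is None
                      else f"permutation within strata ({self.strata})")

        rows = []
        for term, df, ss, f, p in zip(self.terms, dfs, ss_terms, fs, pvals):
            rows.append((term, df, ss, ss / ss_total, f, p))
        rows.append(("Residual", df_resid, ss_resid,
                     ss_resid / ss_total, np.nan, np.nan))
        rows.append(("Total", n - 1, ss_total, 1.0, np.nan, np.nan))
        table = pd.DataFrame(
            rows, columns=["term", "Df", "SumOfSqs", "R2", "F", "Pr(>F)"]
        ).set_index("term")
        return PermanovaResults(table=table, n_permutations=n_used,
                                scheme=scheme, exact=exact, notes=notes)

    def _exact_p(self, g: np.ndarray, f_obs: float) -> float:
        """Complete enumeration over distinct arrangements of the labels."""
        lab = self._labels[self.terms[0]]
        levels, inv = np.unique(lab, return_inverse=True)
        d2m = self.dm.data ** 2
        n = len(lab)
        a = len(levels)
        ss_total = d2m.sum() / (2 * n)
        hits = 0
        total = 0
        for arrangement in multiset_permutations(list(inv)):
            arr = np.asarray(arrangement)
            ss_within = 0.0
            for lev in range(a):
                members = np.flatnonzero(arr == lev)
                if len(members) > 1:
                    sub = d2m[np.ix_(members, members)]
                    ss_within += sub.sum() / (2 * len(members))
            if ss_within == 0:          # all within-group pairs identical
                f = np.inf
            else:
                f = ((ss_total - ss_within) / (a - 1)) / (
                    ss_within / (n - a))
            total += 1
            if f >= f_obs - 1e-12:
                hits += 1
        return hits / total


# ---------------------------------------------------------------------------
# Beta-dispersion
# ---------------------------------------------------------------------------

@dataclass
class DispersionResults:
    """Distances to group centroids and the ANOVA on them."""

    distances: pd.Series
    group_means: pd.Series
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    permutation_p: float | None = None
    note: str | None = None

    @property
    def degenerate(self) -> bool:
        return self.note == "no dispersion"

    def summary(self) -> str:
        lines = ["Homogeneity of multivariate dispersions"]
        if self.degenerate:
            lines.append("All distances to centroids are zero: no dispersion.")
            return "\n".join(lines)
        lines.append(
            f"ANOVA: F[{self.df[0]},{self.df[1]}] = {self.f_statistic:.4f}, "
            f"p = {self.p_value:.4g}"
        )
        if self.permutation_p is not None:
            lines.append(f"Permutation p = {self.permutation_p:.4g}")
        lines.append("Group mean distance to centroid:")
        lines.append(self.group_means.to_string(float_format=lambda x: f"{x:.4f}"))
        return "\n".join(lines)


class BetaDispersion:
    """Multivariate homogeneity of group dispersions (centroid variant).

    The distance matrix is embedded by principal coordinates; axes with
    negative eigenvalues are kept as "imaginary" axes, and the distance of a
    sample to its group centroid is
    ``sqrt(max(0, dist^2 in real axes - dist^2 in imaginary axes))``.
    """

    def __init__(self, distance_matrix: DistanceMatrix, grouping):
        self.dm = distance_matrix
        ids = list(distance_matrix.ids)
        if isinstance(grouping, pd.Series):
            grouping = grouping.loc[ids]
        self.grouping = pd.Series(
            np.asarray(grouping, dtype=object), index=ids, name="group"
        ).astype(str)
        sizes = self.grouping.value_counts()
        small = sizes[sizes < 2]
        if len(small):
            raise ValueError(
                f"group {small.index[0]!r} has fewer than 2 members"
            )

    def fit(self, n_permutations: int | None = None, seed=None
            ) -> DispersionResults:
        g = _gower_center(self.dm.data)
        w, v = np.linalg.eigh(g)
        tol = max(1.0, np.abs(w).max()) * 1e-10
        pos = w > tol
        neg = w < -tol
        xr = v[:, pos] * np.sqrt(w[pos])
        xi = v[:, neg] * np.sqrt(-w[neg])
        groups = self.grouping.to_numpy()
        dist = np.empty(len(groups))
        for lev in pd.unique(groups):
            members = np.flatnonzero(groups == lev)
            cr = xr[members].mean(axis=0)
            ci = xi[members].mean(axis=0) if xi.size else np.zeros(0)
            d2 = ((xr[members] - cr) ** 2).sum(axis=1)
            if xi.size:
                d2 = d2 - ((xi[members] - ci) ** 2).sum(axis=1)
            dist[members] = np.sqrt(np.clip(d2, 0.0, None))
        distances = pd.Series(dist, index=self.dm.ids, name="dist_to_centroid")
        means = distances.groupby(self.grouping).mean()
        k = len(means)
        n = len(distances)
        dfp = (k - 1, n - k)
        if distances.max() < 1e-12:
            return DispersionResults(distances, means, np.nan, dfp, np.nan,
                                     note="no dispersion")
        f_obs = self._anova_f(dist, groups)
        p = float(scipy.stats.f.sf(f_obs, *dfp))
        perm_p = None
        if n_permutations:
            rng = np.random.default_rng(seed)
            hits = 0
            for _ in range(n_permutations):
                fp = self._anova_f(dist, groups[rng.permutation(n)])
                if fp >= f_obs - 1e-12:
                    hits += 1
            perm_p = (1 + hits) / (1 + n_permutations)
        return DispersionResults(distances, means, float(f_obs), dfp, p,
                                 permutation_p=perm_p)

    @staticmethod
    def _anova_f(values: np.ndarray, groups: np.ndarray) -> float:
        grand = values.mean()
        ss_b = 0.0
        ss_w = 0.0
        k = 0
        for lev in pd.unique(groups):
            members = values[groups == lev]
            ss_b += len(members) * (members.mean() - grand) ** 2
            ss_w += ((members - members.mean()) ** 2).sum()
            k += 1
        n = len(values)
        if ss_w == 0:
            return np.inf
        return (ss_b / (k - 1)) / (ss_w / (n - k))


# ---------------------------------------------------------------------------
# SIMPER
# ---------------------------------------------------------------------------

@dataclass
class SimperResults:
    """Per group-pair taxon contributions to between-group dissimilarity."""

    pairs: dict[tuple[str, str], pd.DataFrame]
    pair_dissimilarity: dict[tuple[str, str], float]
    n_permutations: int

    def top(self, pair: tuple[str, str], n: int = 10) -> pd.DataFrame:
        return self.pairs[pair].nlargest(n, "average")

    def summary(self, n: int = 5) -> str:
        lines = ["SIMPER: taxon contributions to between-group dissimilarity"]
        for pair, frame in self.pairs.items():
            lines.append(
                f"\n{pair[0]} vs {pair[1]} "
                f"(mean Bray-Curtis {self.pair_dissimilarity[pair]:.4f})"
            )
            lines.append(frame.nlargest(n, "average").to_string(
                float_format=lambda x: f"{x:.4f}"))
        return "\n".join(lines)


class SIMPER:
    """Similarity-percentage decomposition on relative abundances.

    For groups g, h the contribution of taxon k is the average over
    cross-group sample pairs (i, j) of |x_ik - x_jk| / sum_m(x_im + x_jm);
    summed over taxa this reconstructs the mean between-group Bray-Curtis
    dissimilarity exactly. Permutation p-values shuffle samples between the
    two groups of a pair.
    """

    def __init__(self, abundance, grouping):
        self.df = _as_frame(abundance)
        ids = list(self.df.index)
        if isinstance(grouping, pd.Series):
            grouping = grouping.loc[ids]
        self.grouping = pd.Series(
            np.asarray(grouping, dtype=object), index=ids).astype(str)
        sizes = self.grouping.value_counts()
        if len(sizes) < 2:
            raise ValueError("need at least two groups")
        if (sizes == 0).any():
            raise ValueError("empty group")

    @staticmethod
    def _contributions(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        denom = x.sum(axis=1)[:, None] + y.sum(axis=1)[None, :]
        diff = np.abs(x[:, None, :] - y[None, :, :])
        return (diff / denom[:, :, None]).mean(axis=(0, 1))

    def fit(self, n_permutations: int = 100, seed=None) -> SimperResults:
        rng = np.random.default_rng(seed)
        values = self.df.to_numpy(dtype=float)
        groups = self.grouping.to_numpy()
        levels = sorted(pd.unique(groups))
        pairs: dict[tuple[str, str], pd.DataFrame] = {}
        diss: dict[tuple[str, str], float] = {}
        for ga, gb in combinations(levels, 2):
            ia = np.flatnonzero(groups == ga)
            ib = np.flatnonzero(groups == gb)
            obs = self._contributions(values[ia], values[ib])
            total = obs.sum()
            hits = np.zeros_like(obs)
            pooled = np.concatenate([ia, ib])
            na = len(ia)
            for _ in range(n_permutations):
                perm = rng.permutation(pooled)
                c = self._contributions(values[perm[:na]], values[perm[na:]])
                hits += c >= obs - 1e-12
            pvals = (1 + hits) / (1 + n_permutations)
            frame = pd.DataFrame({
                "average": obs,
                "percent": 100 * obs / total if total > 0 else 0.0,
                "p": pvals,
            }, index=pd.Index(self.df.columns, name="taxon"))
            pairs[(ga, gb)] = frame.sort_values("average", ascending=False)
            diss[(ga, gb)] = float(total)
        return SimperResults(pairs=pairs, pair_dissimilarity=diss,
                             n_permutations=n_permutations)
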
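"""Community statistics: formula oracles, enumeration oracles, and a frozen
cross-validation against vegan (R) on a deterministic fixture."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
import skbio.stats.distance
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from phylosym.community import PERMANOVA, SIMPER, BetaDispersion, bray_curtis
from phylosym.datamodel import CountTable, to_relative_abundance

from conftest import random_count_frame


def euclid_dm(x: np.ndarray, ids=None) -> DistanceMatrix:
    ids = ids or [f"s{i:02d}" for i in range(len(x))]
    return DistanceMatrix(squareform(pdist(np.atleast_2d(x))), ids=ids)


class TestBrayCurtis:
    def test_formula_example(self):
        df = pd.DataFrame([[2, 2, 0], [0, 2, 2]], index=["a", "b"])
        assert bray_curtis(df)["a", "b"] == pytest.approx(0.5)

    def test_identical_rows_zero(self):
        df = pd.DataFrame([[1, 2, 3], [1, 2, 3]], index=["a", "b"])
        assert bray_curtis(df)["a", "b"] == 0.0

    def test_disjoint_supports_one(self):
        df = pd.DataFrame([[5, 0], [0, 9]], index=["a", "b"])
        assert bray_curtis(df)["a", "b"] == pytest.approx(1.0)

    def test_zero_row_names_sample(self):
        df = pd.DataFrame([[0, 0], [1, 1]], index=["empty", "b"])
        with pytest.raises(ValueError, match="empty"):
            bray_curtis(df)

    def test_invariant_to_normalization_at_equal_row_sums(self):
        rng = np.random.default_rng(5)
        counts = random_count_frame(rng, 6, 8)
        counts.iloc[:, 0] += 1000 - counts.sum(axis=1)  # equalize row sums
        t = CountTable(counts)
        d1 = bray_curtis(t)
        d2 = bray_curtis(to_relative_abundance(t))
        np.testing.assert_allclose(d1.data, d2.data, atol=1e-12)


def brute_force_permanova_p(d: np.ndarray, labels: list) -> tuple[float, float]:
    """Independent oracle: pseudo-F and p over ALL distinct relabelings."""
    labels = np.asarray(labels)
    n = len(labels)
    d2 = d ** 2
    ss_total = d2.sum() / (2 * n)
    levels = sorted(set(labels))

    def f_of(perm):
        ss_within = 0.0
        for lev in levels:
            members = np.flatnonzero(np.asarray(perm) == lev)
            if len(members) > 1:
                ss_within += d2[np.ix_(members, members)].sum() / (
                    2 * len(members))
        return (((ss_total - ss_within) / (len(levels) - 1))
                / (ss_within / (n - len(levels))))

    f_obs = f_of(labels)
    seen = set()
    fs = []
    for perm in itertools.permutations(labels):
        if perm in seen:
            continue
        seen.add(perm)
        fs.append(f_of(perm))
    fs = np.asarray(fs)
    return f_obs, float((fs >= f_obs - 1e-12).mean())


class TestPermanova:
    def test_four_point_analytic_example(self):
        """Univariate {0,1 | 2,3}: pseudo-F = 8, exhaustive p = 1/3."""
        dm = euclid_dm(np.array([[0.], [1.], [2.], [3.]]))
        meta = pd.DataFrame({"g": ["A", "A", "B", "B"]}, index=dm.ids)
        res = PERMANOVA(dm, meta, ["g"]).fit(n_permutations=999)
        assert res.exact
        assert res.table.at["g", "F"] == pytest.approx(8.0, abs=1e-9)
        assert res.table.at["g", "Pr(>F)"] == pytest.approx(1 / 3, abs=1e-12)

    def test_equals_classical_anova_on_euclidean(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        g = np.repeat(list("ABCD"), 5)
        dm = euclid_dm(x[:, None])
        meta = pd.DataFrame({"g": g}, index=dm.ids)
        f = PERMANOVA(dm, meta, ["g"]).fit(n_permutations=9).table.at["g", "F"]
        f_anova = scipy.stats.f_oneway(*(x[g == lev] for lev in "ABCD"))
        assert f == pytest.approx(f_anova.statistic, abs=1e-9)

    def test_matches_skbio_single_factor(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(15, 4))
        dm = euclid_dm(x)
        grouping = pd.Series(np.repeat(list("abc"), 5), index=dm.ids)
        meta = grouping.to_frame("g")
        ours = PERMANOVA(dm, meta, ["g"]).fit(n_permutations=9)
        ref = skbio.stats.distance.permanova(dm, list(grouping),
                                             permutations=9)
        assert ours.table.at["g", "F"] == pytest.approx(
            ref["test statistic"], abs=1e-9)

    @pytest.mark.parametrize("sizes", [(3, 3), (4, 3), (2, 2, 3)])
    def test_exact_p_matches_brute_force_enumeration(self, sizes):
        rng = np.random.default_rng(sum(sizes))
        n = sum(sizes)
        x = rng.normal(size=(n, 2))
        dm = euclid_dm(x)
        labels = [lev for lev, k in zip("ABC", sizes) for _ in range(k)]
        meta = pd.DataFrame({"g": labels}, index=dm.ids)
        res = PERMANOVA(dm, meta, ["g"]).fit(n_permutations=100000)
        assert res.exact
        f_obs, p_exact = brute_force_permanova_p(dm.data, labels)
        assert res.table.at["g", "F"] == pytest.approx(f_obs, abs=1e-9)
        assert res.table.at["g", "Pr(>F)"] == pytest.approx(p_exact, abs=1e-12)

    def test_duplicated_groups_give_zero_f(self):
        x = np.array([[0.0], [1.0], [0.0], [1.0]])
        dm = euclid_dm(x)
        meta = pd.DataFrame({"g": ["A", "A", "B", "B"]}, index=dm.ids)
        res = PERMANOVA(dm, meta, ["g"]).fit(n_permutations=99)
        assert res.table.at["g", "F"] == pytest.approx(0.0, abs=1e-9)
        assert res.table.at["g", "Pr(>F)"] == pytest.approx(1.0)

    def test_sequential_ss_decomposition(self):
        rng = np.random.default_rng(8)
        counts = random_count_frame(rng, 18, 10)
        dm = bray_curtis(to_relative_abundance(CountTable(counts)))
        meta = pd.DataFrame({
            "a": rng.choice(["x", "y"], size=18),
            "b": rng.choice(["u", "v", "w"], size=18),
        }, index=dm.ids)
        res = PERMANOVA(dm, meta, ["a", "b", "a:b"]).fit(n_permutations=9)
        tab = res.table
        terms_ss = tab.loc[["a", "b", "a:b", "Residual"], "SumOfSqs"].sum()
        assert terms_ss == pytest.approx(tab.at["Total", "SumOfSqs"],
                                         abs=1e-9)
        assert tab["R2"].drop("Total").sum() == pytest.approx(1.0, abs=1e-9)
        df_sum = tab.loc[["a", "b", "a:b", "Residual"], "Df"].sum()
        assert df_sum == tab.at["Total", "Df"]

    def test_strata_confounded_factor_is_never_significant(self):
        # factor constant within each stratum: within-block shuffles can
        # never change the labeling, so every permuted F equals the observed
        rng = np.random.default_rng(1)
        x = rng.normal(size=(12, 3))
        x[:6] += 4.0
        dm = euclid_dm(x)
        meta = pd.DataFrame({
            "g": ["A"] * 6 + ["B"] * 6,
            "block": ["r1"] * 6 + ["r2"] * 6,
        }, index=dm.ids)
        res = PERMANOVA(dm, meta, ["g"], strata="block").fit(
            n_permutations=99, seed=0)
        assert res.table.at["g", "Pr(>F)"] == pytest.approx(1.0)
        free = PERMANOVA(dm, meta, ["g"]).fit(n_permutations=99, seed=0)
        assert free.table.at["g", "Pr(>F)"] < 0.05

    def test_constant_factor_rejected(self):
        dm = euclid_dm(np.arange(4.0)[:, None])
        meta = pd.DataFrame({"g": ["A"] * 4}, index=dm.ids)
        with pytest.raises(ValueError, match="constant"):
            PERMANOVA(dm, meta, ["g"])

    def test_from_formula_expansion(self):
        dm = euclid_dm(np.arange(8.0)[:, None])
        meta = pd.DataFrame({"a": list("xyxyxyxy"), "b": list("uuvvuuvv")},
                            index=dm.ids)
        model = PERMANOVA.from_formula("a*b", dm, meta)
        assert model.terms == ["a", "b", "a:b"]


class TestBetaDispersion:
    def test_geometric_oracle_euclidean(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(10, 2))
        groups = np.repeat(["g1", "g2"], 5)
        dm = euclid_dm(pts)
        res = BetaDispersion(dm, pd.Series(groups, index=dm.ids)).fit()
        for lev in ("g1", "g2"):
            members = np.flatnonzero(groups == lev)
            centroid = pts[members].mean(axis=0)
            direct = np.linalg.norm(pts[members] - centroid, axis=1)
            got = res.distances.iloc[members].to_numpy()
            np.testing.assert_allclose(got, direct, atol=1e-9)

    def test_duplicated_points_reported_as_no_dispersion(self):
        pts = np.array([[0.0, 0], [0, 0], [1, 1], [1, 1]])
        dm = euclid_dm(pts)
        res = BetaDispersion(dm, pd.Series(["a", "a", "b", "b"],
                                           index=dm.ids)).fit()
        assert res.degenerate
        assert (res.distances < 1e-12).all()

    def test_singleton_group_rejected(self):
        dm = euclid_dm(np.arange(3.0)[:, None])
        with pytest.raises(ValueError, match="lone"):
            BetaDispersion(dm, pd.Series(["a", "a", "lone"], index=dm.ids))

    def test_planted_heteroscedasticity_detected(self):
        rng = np.random.default_rng(99)
        detected = 0
        for _ in range(20):
            tight = rng.normal(scale=0.05, size=(10, 3))
            spread = rng.normal(scale=1.0, size=(10, 3))
            dm = euclid_dm(np.vstack([tight, spread]))
            res = BetaDispersion(dm, pd.Series(
                ["t"] * 10 + ["s"] * 10, index=dm.ids)).fit()
            detected += res.p_value < 0.05
        assert detected >= 19


class TestSimper:
    def test_two_singleton_groups_split_evenly(self):
        df = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["a", "b"],
                          columns=["t1", "t2"])
        res = SIMPER(df, pd.Series(["A", "B"], index=df.index)).fit(
            n_permutations=10, seed=0)
        frame = res.pairs[("A", "B")]
        np.testing.assert_allclose(frame["average"].to_numpy(), [0.5, 0.5])
        np.testing.assert_allclose(frame["percent"].to_numpy(), [50.0, 50.0])

    def test_contributions_decompose_mean_bray_curtis(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            counts = random_count_frame(rng, 9, 7)
            rel = to_relative_abundance(CountTable(counts))
            groups = pd.Series(rng.choice(["A", "B", "C"], size=9),
                               index=rel.df.index)
            if groups.value_counts().min() == 0 or groups.nunique() < 2:
                continue
            res = SIMPER(rel, groups).fit(n_permutations=2, seed=0)
            dm = bray_curtis(rel)
            g = groups.to_numpy()
            for (ga, gb), frame in res.pairs.items():
                ia = np.flatnonzero(g == ga)
                ib = np.flatnonzero(g == gb)
                mean_bc = np.mean([dm.data[i, j] for i in ia for j in ib])
                assert frame["average"].sum() == pytest.approx(mean_bc,
                                                               abs=1e-9)

    def test_identical_groups_null_pvalues(self):
        base = np.array([[0.5, 0.5], [0.4, 0.6], [0.6, 0.4]])
        df = pd.DataFrame(np.vstack([base, base]),
                          index=[f"s{i}" for i in range(6)])
        res = SIMPER(df, pd.Series(["A"] * 3 + ["B"] * 3, index=df.index)
                     ).fit(n_permutations=50, seed=1)
        assert (res.pairs[("A", "B")]["p"] > 0.5).all()


class TestVeganFrozenOracle:
    """Cross-validation values computed once with vegan 2.7-1 (R 4.3)
    on this exact fixture and frozen here."""

    @pytest.fixture()
    def fixture_data(self):
        rng = np.random.default_rng(2024)
        counts = rng.integers(0, 50, size=(12, 6))
        counts[:4, 0] += 60
        counts[4:8, 1] += 40
        df = pd.DataFrame(counts, index=[f"s{i:02d}" for i in range(12)],
                          columns=[f"t{j}" for j in range(6)])
        meta = pd.DataFrame({"g": ["A"] * 4 + ["B"] * 4 + ["C"] * 4,
                             "r": ["r1", "r2"] * 6}, index=df.index)
        rel = to_relative_abundance(CountTable(df))
        return bray_curtis(rel), rel, meta

    def test_single_factor_f(self, fixture_data):
        dm, _, meta = fixture_data
        res = PERMANOVA(dm, meta, ["g"]).fit(n_permutations=9)
        assert res.table.at["g", "F"] == pytest.approx(3.00979, abs=5e-6)
        assert res.table.at["Total", "SumOfSqs"] == pytest.approx(
            0.7001729, abs=5e-7)

    def test_two_factor_sequential(self, fixture_data):
        dm, _, meta = fixture_data
        res = PERMANOVA(dm, meta, ["r", "g", "r:g"]).fit(n_permutations=9)
        expect = {"r": (0.05856, 1.6482), "g": (0.28062, 3.9493),
                  "r:g": (0.14783, 2.0806)}
        for term, (ss, f) in expect.items():
            assert res.table.at[term, "SumOfSqs"] == pytest.approx(ss,
                                                                   abs=5e-5)
            assert res.table.at[term, "F"] == pytest.approx(f, abs=5e-4)

    def test_betadisper_centroid(self, fixture_data):
        dm, _, meta = fixture_data
        res = BetaDispersion(dm, meta["g"]).fit()
        assert res.f_statistic == pytest.approx(0.0862900839, abs=1e-9)
        assert res.p_value == pytest.approx(0.9180777660, abs=1e-9)
        expected = [0.1474149848, 0.2333096134, 0.1966248934, 0.1606635701,
                    0.1844570146, 0.2285839808, 0.2090579458, 0.1297676230,
                    0.1728306724, 0.2480850805, 0.1719360100, 0.1054460410]
        np.testing.assert_allclose(res.distances.to_numpy(), expected,
                                   atol=1e-9)

    def test_simper_average_contributions(self, fixture_data):
        _, rel, meta = fixture_data
        res = SIMPER(rel, meta["g"]).fit(n_permutations=2, seed=0)
        expected = {"t0": 0.14541649, "t1": 0.11089176, "t2": 0.03633215,
                    "t3": 0.03907741, "t4": 0.04473146, "t5": 0.04193393}
        frame = res.pairs[("A", "B")]
        for taxon, val in expected.items():
            assert frame.at[taxon, "average"] == pytest.approx(val, abs=1e-8)
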
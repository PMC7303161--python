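"""Statistical operations against brute-force/textbook oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rvkinergy import cohort_stats as cs
from rvkinergy import synthetic_data as sd
from rvkinergy.errors import ParameterError, StatisticsError


# ---------------------------------------------------------------- oracles

def _midranks(x):
    """Mid-ranks computed by explicit enumeration (oracle)."""
    x = np.asarray(x, dtype=float)
    r = np.empty(x.size)
    for i, xi in enumerate(x):
        less = np.sum(x < xi)
        eq = np.sum(x == xi)
        r[i] = less + (eq + 1) / 2.0
    return r


def _spearman_oracle(x, y):
    rx, ry = _midranks(x), _midranks(y)
    r = np.corrcoef(rx, ry)[0, 1]
    n = len(x)
    t = r * np.sqrt((n - 2) / (1 - r ** 2))
    p = 2 * sps.t.sf(abs(t), n - 2)
    return r, p


def _ttest_oracle(a, b):
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) \
        / (na + nb - 2)
    t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * sps.t.sf(abs(t), na + nb - 2)
    return t, p


def _kruskal_oracle(groups):
    pooled = np.concatenate(groups)
    ranks = _midranks(pooled)
    N = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        rg = ranks[start:start + len(g)]
        h += len(g) * (rg.mean() - (N + 1) / 2.0) ** 2
        start += len(g)
    h *= 12.0 / (N * (N + 1))
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (counts ** 3 - counts).sum() / (N ** 3 - N)
    return h / correction


def _ccc_oracle(x, y):
    n = len(x)
    mx, my = np.mean(x), np.mean(y)
    sx2 = np.sum((x - mx) ** 2) / n
    sy2 = np.sum((y - my) ** 2) / n
    sxy = np.sum((x - mx) * (y - my)) / n
    return 2 * sxy / (sx2 + sy2 + (mx - my) ** 2)


# ------------------------------------------------------------------ tests

class TestSpearman:
    def test_monotone_series(self):
        x = np.arange(10.0)
        assert cs.spearman(x, x ** 3)[0] == pytest.approx(1.0)
        assert cs.spearman(x, -np.exp(x))[0] == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # rank differences d = (-1, 1, -1, 1, 0), sum d^2 = 4:
        # r = 1 - 6*4 / (5 * 24) = 0.8
        r, _ = cs.spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert r == pytest.approx(0.8)

    def test_constant_series_rejected(self):
        with pytest.raises(StatisticsError):
            cs.spearman(np.ones(5), np.arange(5.0))

    def test_oracle_equivalence_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = rng.integers(5, 30)
            x = np.round(rng.normal(size=n), 1)  # rounding induces ties
            y = np.round(rng.normal(size=n) + 0.3 * x, 1)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            r, p = cs.spearman(x, y)
            ro, po = _spearman_oracle(x, y)
            assert r == pytest.approx(ro, abs=1e-10)
            assert p == pytest.approx(po, abs=1e-10)

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        r1, _ = cs.spearman(x, y)
        r2, _ = cs.spearman(np.exp(x), y ** 3)
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestTTest:
    def test_identical_groups(self):
        t, p = cs.ttest_independent([1.0, 2, 3], [1.0, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_well_separated_groups(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, 20)
        _, p = cs.ttest_independent(a, a + 100.0)
        assert p < 1e-10

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            a = rng.normal(size=rng.integers(3, 15))
            b = rng.normal(0.5, 1.2, size=rng.integers(3, 15))
            t, p = cs.ttest_independent(a, b)
            to, po = _ttest_oracle(a, b)
            assert t == pytest.approx(to, abs=1e-12)
            assert p == pytest.approx(po, abs=1e-12)


class TestKruskalDunn:
    def test_identical_groups_null(self):
        g = [1.0, 2, 3, 4, 5]
        res = cs.kruskal_dunn([g, g, g])
        assert res.h == pytest.approx(0.0, abs=1e-9)
        assert all(letter == "" for letter in res.letters)

    def test_fully_separated_groups(self):
        # groups of 10 give every pairwise Dunn z enough power; at n=5 per
        # group the adjacent-pair z (~1.77) cannot reach p < 0.05
        res = cs.kruskal_dunn([np.arange(1.0, 11), np.arange(21.0, 31),
                               np.arange(41.0, 51)])
        assert all(p < 0.05 for p in res.pairwise_p.values())
        assert res.letters == ["b,c", "a,c", "a,b"]

    def test_h_matches_brute_force(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            groups = [np.round(rng.normal(m, 1, rng.integers(4, 10)), 1)
                      for m in (0.0, 0.4, 1.0)]
            if np.ptp(np.concatenate(groups)) == 0:
                continue
            res = cs.kruskal_dunn(groups)
            assert res.h == pytest.approx(_kruskal_oracle(groups), abs=1e-10)

    def test_monotone_decline_letters_pattern(self):
        # five groups with a strong programmed decline: the youngest group
        # differs from the two oldest, mirroring d,e-style annotation
        rng = np.random.default_rng(5)
        means = [2.1, 1.8, 1.5, 1.0, 0.7]
        groups = [rng.normal(m, 0.25, 11) for m in means]
        res = cs.kruskal_dunn(groups)
        assert "d" in res.letters[0] and "e" in res.letters[0]
        assert "a" in res.letters[4]

    def test_bonferroni_is_more_conservative(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(m, 1.0, 10) for m in (0, 0.8, 1.6)]
        un = cs.kruskal_dunn(groups)
        bo = cs.kruskal_dunn(groups, adjust="bonferroni")
        for k in un.pairwise_p:
            assert bo.pairwise_p_bonferroni[k] >= un.pairwise_p[k]


class TestForwardConditional:
    def test_recovers_single_true_predictor(self):
        rng = np.random.default_rng(2)
        x1 = rng.normal(size=60)
        x2 = rng.normal(size=60)
        y = 2.0 * x1 + rng.normal(0, 0.5, 60)
        tab = cs.forward_conditional_regression(
            pd.DataFrame({"x1": x1, "x2": x2}), y)
        assert list(tab["variable"]) == ["x1"]
        assert tab["beta"].iloc[0] == pytest.approx(2.0, abs=0.2)

    def test_independent_response_gives_empty_model(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        y = rng.normal(size=60)
        tab = cs.forward_conditional_regression(X, y)
        assert tab.empty

    def test_collinear_predictors_keep_exactly_one(self):
        rng = np.random.default_rng(6)
        x1 = rng.normal(size=80)
        x2 = x1 + rng.normal(0, 1e-3, 80)
        y = x1 + rng.normal(0, 0.3, 80)
        tab = cs.forward_conditional_regression(
            pd.DataFrame({"x1": x1, "x2": x2}), y)
        assert len(tab) == 1


class TestConcordance:
    def test_perfect_agreement(self):
        x = np.arange(10.0)
        ccc, prec, acc = cs.concordance(x, x)
        assert ccc == pytest.approx(1.0)
        assert prec == pytest.approx(1.0)
        assert acc == pytest.approx(1.0)

    def test_location_shift_degrades_accuracy_not_precision(self):
        x = np.arange(10.0)
        ccc, prec, acc = cs.concordance(x, x + 3.0)
        assert prec == pytest.approx(1.0)
        assert ccc < 1.0 and acc < 1.0

    def test_formula_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            x = rng.normal(10, 2, 15)
            y = 0.8 * x + rng.normal(0, 1, 15)
            ccc, prec, acc = cs.concordance(x, y)
            assert ccc == pytest.approx(_ccc_oracle(x, y), abs=1e-12)
            assert acc == pytest.approx(ccc / prec, abs=1e-12)

    def test_ccc_bounded_by_pearson(self):
        rng = np.random.default_rng(19)
        for _ in range(50):
            x = rng.normal(5, 2, 20)
            y = rng.normal(4, 3, 20) + 0.5 * x
            ccc, prec, _ = cs.concordance(x, y)
            assert abs(ccc) <= abs(prec) + 1e-12


class TestVariabilityAndBias:
    def test_identical_pairs(self):
        x = np.arange(1.0, 11)
        cov, bias = cs.variability_and_bias(x, x)
        assert cov == 0.0 and bias == 0.0

    def test_seven_percent_overreading(self):
        x = np.linspace(50, 150, 20)
        cov, bias = cs.variability_and_bias(x, 1.07 * x)
        assert bias == pytest.approx(-6.76, abs=0.02)

    def test_hand_formula(self):
        x = np.array([10.0, 12, 11, 13, 9])
        y = np.array([11.0, 11, 12, 12, 10])
        cov, bias = cs.variability_and_bias(x, y)
        d = x - y
        level = ((x + y) / 2).mean()
        assert bias == pytest.approx(100 * d.mean() / level, abs=1e-12)
        assert cov == pytest.approx(100 * d.std(ddof=1) / level, abs=1e-12)


class TestBuildReport:
    def test_null_cohort_has_small_correlations(self):
        effects = {f"m{i}": {"mean": 10.0, "sd": 2.0, "rho": 0.0}
                   for i in range(5)}
        df, _ = sd.make_cohort(sd.CohortSpec(effect_table=effects, seed=9))
        res = cs.build_report(df)
        assert (res.correlations["spearman_r"].abs() < 0.45).all()

    def test_explicit_bin_edges_reproduce_partition(self):
        # 53 subjects cut at given ages split 12/9/11/10/11
        ages = np.concatenate([np.linspace(21, 25, 12),
                               np.linspace(30, 34, 9),
                               np.linspace(43, 51, 11),
                               np.linspace(52, 56, 10),
                               np.linspace(63, 75, 11)])
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"age_years": ages,
                           "sex": rng.choice(["F", "M"], 53),
                           "metric": rng.normal(5, 1, 53)})
        res = cs.build_report(df, metrics=["metric"],
                              age_bin_edges=[20, 28, 40, 51.5, 60, 80])
        assert res.group_sizes == [12, 9, 11, 10, 11]

    def test_multivariate_subset_of_univariate_significant(self):
        df, _ = sd.make_cohort(sd.CohortSpec(seed=21))
        res = cs.build_report(df)
        uni = res.regression[res.regression["model"] == "univariate"]
        sig = set(uni.loc[uni["p"] < 0.05, "variable"])
        multi = set(res.regression.loc[
            res.regression["model"] == "multivariate", "variable"])
        assert multi <= sig

    def test_underpowered_cohort_rejected(self):
        with pytest.raises(ParameterError):
            cs.build_report(pd.DataFrame({"age_years": [30.0, 40.0],
                                          "sex": ["F", "M"],
                                          "m": [1.0, 2.0]}))


class TestReproducibilityReport:
    def test_table_shape_and_average_row(self):
        rng = np.random.default_rng(14)
        pairs = {}
        for name in ("global_kei", "peak_e_kei", "peak_a_kei"):
            x = rng.normal(5, 1.5, 20)
            pairs[name] = (x, x + rng.normal(0, 0.3, 20))
        tab = cs.reproducibility_report(pairs)
        assert list(tab["metric"])[-1] == "average"
        assert (tab["ccc"] > 0.8).all()
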
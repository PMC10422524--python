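"""ANOVA scoring, mutual information, MRMR and subset curves."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import bioradar as br
from bioradar.selection import (
    SCORE_CAP,
    anova_score,
    anova_table,
    evaluate_feature_subsets,
    mrmr_rank,
    mutual_information,
)


class TestAnova:
    def test_hand_computed_decomposition(self):
        # groups {1,2,3} / {4,5,6}: SSG = 13.5, SSE = 4, F = 13.5 / 1
        v = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        y = np.array([0, 0, 0, 1, 1, 1])
        r = anova_score(v, y)
        assert r.SSG == pytest.approx(13.5)
        assert r.SSE == pytest.approx(4.0)
        assert r.F == pytest.approx(13.5)
        assert r.dfG == 1 and r.dfE == 4

    def test_f_equals_squared_pooled_t(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n0, n1 = rng.integers(3, 30, size=2)
            v = np.concatenate([rng.normal(0, 1, n0), rng.normal(0.5, 1.3, n1)])
            y = np.array([0] * n0 + [1] * n1)
            r = anova_score(v, y)
            t = stats.ttest_ind(v[y == 0], v[y == 1], equal_var=True)
            assert r.F == pytest.approx(t.statistic**2, rel=1e-9)
            assert r.p == pytest.approx(t.pvalue, rel=1e-6)

    def test_score_is_minus_log_p(self):
        v = np.concatenate([np.random.default_rng(1).normal(0, 1, 40),
                            np.random.default_rng(2).normal(2, 1, 40)])
        y = np.array([0] * 40 + [1] * 40)
        r = anova_score(v, y)
        assert r.score == pytest.approx(-np.log(r.p), rel=1e-6)

    def test_huge_f_capped_not_overflowed(self):
        rng = np.random.default_rng(3)
        v = np.concatenate([rng.normal(0, 1e-4, 1000), rng.normal(100, 1e-4, 1000)])
        y = np.array([0] * 1000 + [1] * 1000)
        r = anova_score(v, y)
        assert r.score == SCORE_CAP and r.score_is_inf

    def test_separated_constants_capped(self):
        r = anova_score([1.0, 1.0, 2.0, 2.0], [0, 0, 1, 1])
        assert np.isinf(r.F) and r.score == SCORE_CAP

    def test_degenerate_identical_constants_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            anova_score([1.0, 1.0, 1.0, 1.0], [0, 0, 1, 1])

    def test_table_ranks_descending(self):
        rng = np.random.default_rng(4)
        y = np.array([0, 1] * 50)
        df = pd.DataFrame({
            "good": y + rng.normal(0, 0.1, 100),
            "weak": y + rng.normal(0, 2.0, 100),
            "noise": rng.normal(0, 1, 100),
        })
        t = anova_table(df, y)
        assert list(t["feature"]) == ["good", "weak", "noise"]
        assert list(t["rank"]) == [1, 2, 3]


class TestMutualInformation:
    def test_self_information_of_balanced_binary(self):
        u = np.array([0, 1] * 100)
        assert mutual_information(u, u) == pytest.approx(np.log(2), abs=1e-12)

    def test_discrete_table_matches_brute_force(self):
        # 2x2 joint counts {(0,0):40,(0,1):10,(1,0):10,(1,1):40}
        u = np.repeat([0, 0, 1, 1], [40, 10, 10, 40])
        v = np.repeat([0, 1, 0, 1], [40, 10, 10, 40])
        p = np.array([[0.4, 0.1], [0.1, 0.4]])
        expected = sum(
            p[i, j] * np.log(p[i, j] / (p[i].sum() * p[:, j].sum()))
            for i in range(2)
            for j in range(2)
        )
        assert expected == pytest.approx(0.1927, abs=1e-4)
        assert mutual_information(u, v) == pytest.approx(expected, abs=1e-12)

    def test_independent_continuous_near_zero(self):
        rng = np.random.default_rng(5)
        u, v = rng.normal(size=5000), rng.normal(size=5000)
        assert mutual_information(u, v) < 0.05

    def test_constant_column_zero(self):
        rng = np.random.default_rng(6)
        assert mutual_information(np.ones(50), rng.normal(size=50)) == 0.0

    @settings(deadline=None, max_examples=25)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_symmetry_and_nonnegativity(self, seed):
        rng = np.random.default_rng(seed)
        u = rng.integers(0, 4, 200).astype(float)
        v = u + rng.normal(0, 1, 200)
        a, b = mutual_information(u, v), mutual_information(v, u)
        assert a == pytest.approx(b, rel=1e-12)
        assert a >= 0


class TestMrmr:
    def _toy(self, n=400, seed=7):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        f1 = y + rng.normal(0, 0.3, n)
        df = pd.DataFrame({"informative": f1, "copy": f1.copy(),
                           "noise": rng.normal(size=n)})
        return df, y

    def test_redundant_copy_penalized_noise_last(self):
        df, y = self._toy()
        res = mrmr_rank(df, y)
        order = res.ranking
        assert order.index("informative") < order.index("copy")
        assert order[-1] == "noise"

    def test_zero_relevance_feature_scores_lowest(self):
        df, y = self._toy()
        t = res = mrmr_rank(df, y).table.set_index("feature")
        assert t.loc["noise", "MIQ"] == min(t["MIQ"])

    def test_mi_matrix_symmetric_nonnegative(self):
        df, y = self._toy()
        mi = mrmr_rank(df, y).mi_matrix
        assert np.allclose(mi, mi.T)
        assert (mi.to_numpy() >= 0).all()

    def test_removing_zero_relevance_feature_keeps_order(self):
        df, y = self._toy()
        full = mrmr_rank(df, y).ranking
        reduced = mrmr_rank(df[["informative", "copy"]], y).ranking
        kept = [f for f in full if f != "noise"]
        assert reduced == kept

    def test_requires_two_features(self):
        df, y = self._toy()
        with pytest.raises(ValueError):
            mrmr_rank(df[["noise"]], y)


class TestSubsetCurves:
    def _features(self, n=200, seed=8):
        rng = np.random.default_rng(seed)
        y = np.array([br.WITH_PERSON, br.WITHOUT_PERSON] * (n // 2))
        sep = np.where(y == br.WITH_PERSON, 5.0, -5.0) + rng.normal(0, 0.2, n)
        cols = {"sep": sep}
        for i in range(3):
            cols[f"n{i}"] = rng.normal(size=n)
        return pd.DataFrame(cols), y

    def test_perfectly_separable_single_feature(self):
        df, y = self._features()
        out = evaluate_feature_subsets(df, y, {"r": ["sep", "n0", "n1", "n2"]}, seed=0)
        m1 = out[(out["ranking"] == "r") & (out["m"] == 1)].iloc[0]
        assert m1["acc"] == 1.0 and m1["fnr"] == 0.0 and m1["fpr"] == 0.0

    def test_informative_features_beat_noise_prefix(self):
        rng = np.random.default_rng(9)
        n = 300
        y = np.array([br.WITH_PERSON, br.WITHOUT_PERSON] * (n // 2))
        target = (y == br.WITH_PERSON).astype(float)
        cols = {}
        for i in range(3):
            cols[f"inf{i}"] = target + rng.normal(0, 0.8, n)
        for i in range(6):
            cols[f"noise{i}"] = rng.normal(size=n)
        df = pd.DataFrame(cols)
        order = ["inf0", "inf1", "inf2"] + [f"noise{i}" for i in range(6)]
        out = evaluate_feature_subsets(df, y, {"r": order}, seed=1)
        acc = out.set_index("m")["acc"]
        assert acc[3] > acc[1]
        assert acc[9] >= acc[3] - 0.05  # plateau, no collapse

    def test_unknown_feature_rejected(self):
        df, y = self._features()
        with pytest.raises(ValueError, match="unknown"):
            evaluate_feature_subsets(df, y, {"r": ["sep", "missing"]})

    def test_rates_identity(self):
        df, y = self._features(seed=10)
        df["sep"] += np.random.default_rng(11).normal(0, 6, len(df))  # imperfect
        out = evaluate_feature_subsets(df, y, {"r": ["sep", "n0"]}, seed=2)
        n = len(df)
        for _, row in out.iterrows():
            n_pos = np.sum(y == br.WITH_PERSON)
            n_neg = n - n_pos
            err = row["fnr"] * n_pos + row["fpr"] * n_neg
            assert row["acc"] == pytest.approx(1 - err / n, abs=1e-9)
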
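import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asep.exceptions import EstimationError, ParameterError
from asep.screen import (
    CorrelationScreen,
    cluster_features,
    critical_r,
    spearman_screen,
    top_k,
)

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


class TestCriticalR:
    def test_single_test_threshold(self):
        # classic r_crit at n = 51, alpha = 0.05: t*/sqrt(df + t*^2)
        assert critical_r(51, 1).critical_r == pytest.approx(0.276, abs=1e-3)

    def test_study_scale_thresholds(self):
        assert critical_r(51, 12).critical_r == pytest.approx(0.3946, abs=1e-3)
        assert critical_r(51, 872).critical_r == pytest.approx(0.5326, abs=1e-3)

    def test_monotone_in_m_and_n(self):
        values = [critical_r(51, m).critical_r for m in (1, 5, 12, 100, 872)]
        assert values == sorted(values)
        assert critical_r(100, 12).critical_r < critical_r(51, 12).critical_r

    def test_small_n_rejected(self):
        with pytest.raises(ParameterError):
            critical_r(3, 12)

    def test_matches_null_simulation_quantile(self):
        # the threshold is, by construction, the null (1 - alpha/m) quantile
        # of |r|; check against simulated normal nulls at m = 1
        rng = np.random.default_rng(3)
        n = 51
        rs = []
        for _ in range(4000):
            x, y = rng.standard_normal(n), rng.standard_normal(n)
            rs.append(abs(np.corrcoef(x, y)[0, 1]))
        simulated = np.quantile(rs, 0.95)
        assert critical_r(n, 1).critical_r == pytest.approx(simulated, abs=0.02)


class TestSpearmanScreen:
    def test_identical_feature_ranks_first(self):
        rng = np.random.default_rng(0)
        asep = pd.Series(rng.uniform(0, 0.5, 20), index=range(20))
        feats = pd.DataFrame(
            {"same": asep.values, "noise": rng.standard_normal(20)}, index=asep.index
        )
        table = spearman_screen(feats, asep, m_for_bonferroni=2).set_index("feature_id")
        assert table.loc["same", "spearman_r"] == pytest.approx(1.0)
        assert table.loc["same", "rank_by_abs_r"] == 1

    def test_anti_monotone_feature(self):
        asep = pd.Series([0.1, 0.2, 0.3, 0.4, 0.5])
        feats = pd.DataFrame({"neg": -asep.values}, index=asep.index)
        table = spearman_screen(feats, asep, m_for_bonferroni=1)
        assert table["spearman_r"].iloc[0] == pytest.approx(-1.0)

    def test_constant_feature_reported_missing(self):
        asep = pd.Series([0.1, 0.2, 0.3, 0.4, 0.5])
        feats = pd.DataFrame({"flat": [1.0] * 5, "ok": [5, 4, 3, 2, 1]}, index=asep.index)
        with pytest.warns(UserWarning, match="constant"):
            table = spearman_screen(feats, asep, m_for_bonferroni=2)
        flat = table.set_index("feature_id").loc["flat"]
        assert np.isnan(flat["spearman_r"])
        assert not flat["significant"]
        assert np.isnan(flat["rank_by_abs_r"])

    def test_pairwise_complete_deletion(self):
        asep = pd.Series([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        feats = pd.DataFrame(
            {"gappy": [1.0, 2.0, np.nan, 4.0, 5.0, 6.0]}, index=asep.index
        )
        table = spearman_screen(feats, asep, m_for_bonferroni=1)
        assert table["n"].iloc[0] == 5
        assert table["spearman_r"].iloc[0] == pytest.approx(1.0)


@given(
    st.lists(
        st.integers(min_value=-50, max_value=50),
        min_size=8,
        max_size=20,
        unique=True,
    ),
    st.sampled_from(["exp", "cube", "affine"]),
)
def test_spearman_invariant_under_monotone_transforms(values, transform):
    rng = np.random.default_rng(7)
    asep = pd.Series(rng.uniform(0, 0.5, len(values)))
    feats = pd.DataFrame({"f": [float(v) for v in values]}, index=asep.index)
    base = spearman_screen(feats, asep, 1)["spearman_r"].iloc[0]
    fn = {
        "exp": lambda x: np.exp(x / 25.0),
        "cube": lambda x: x**3,
        "affine": lambda x: 3.0 * x + 2.0,
    }[transform]
    transformed = spearman_screen(
        feats.apply(fn), asep, 1
    )["spearman_r"].iloc[0]
    assert transformed == pytest.approx(base, abs=1e-9)


class TestTopK:
    def test_absolute_value_wins(self):
        asep = pd.Series(np.arange(10, dtype=float))
        rng = np.random.default_rng(1)
        feats = pd.DataFrame(
            {
                "pos": asep.values + rng.normal(0, 0.8, 10),
                "neg": -asep.values,
            },
            index=asep.index,
        )
        table = spearman_screen(feats, asep, 2)
        best = top_k(table, 1)
        assert best["feature_id"].iloc[0] == "neg"

    def test_k_equals_m_is_identity(self):
        asep = pd.Series(np.arange(8, dtype=float))
        rng = np.random.default_rng(2)
        feats = pd.DataFrame(rng.standard_normal((8, 5)), columns=list("abcde"))
        table = spearman_screen(feats, asep, 5)
        assert set(top_k(table, 5)["feature_id"]) == set("abcde")

    def test_matches_brute_force_sort(self, cohort, cohort_period_asep):
        feats = cohort.metabolites.set_index("participant_id").iloc[:, :50]
        table = spearman_screen(feats, cohort_period_asep, 872)
        got = top_k(table, 10)["feature_id"].tolist()
        # independent oracle: plain sort on (-|r|, id)
        expected = [
            fid
            for fid, _ in sorted(
                zip(table["feature_id"], table["spearman_r"]),
                key=lambda t: (-abs(t[1]), t[0]),
            )[:10]
        ]
        assert got == expected

    def test_ties_break_by_feature_id(self):
        asep = pd.Series([1.0, 2.0, 3.0, 4.0])
        feats = pd.DataFrame(
            {"b": [1.0, 2, 3, 4], "a": [1.0, 2, 3, 4]}, index=asep.index
        )
        table = spearman_screen(feats, asep, 2)
        assert top_k(table, 1)["feature_id"].iloc[0] == "a"


class TestClustering:
    def test_perfectly_correlated_merge_at_zero(self):
        x = np.arange(10, dtype=float)
        feats = pd.DataFrame({"a": x, "b": 2 * x + 1})
        tree = cluster_features(feats)
        assert tree.heights[0] == pytest.approx(0.0, abs=1e-12)

    def test_anti_correlated_merge_at_two(self):
        x = np.arange(10, dtype=float)
        feats = pd.DataFrame({"a": x, "b": -x})
        tree = cluster_features(feats)
        assert tree.heights[-1] == pytest.approx(2.0, abs=1e-12)

    def test_three_feature_complete_linkage_by_hand(self):
        # construct features with pairwise r {AB: ~0.9, AC/BC: ~0.1}; the
        # first merge joins A,B at 1 - r_AB and the last merge height is
        # the complete-linkage maximum 1 - min(r_AC, r_BC)
        rng = np.random.default_rng(5)
        base = rng.standard_normal(400)
        a = base
        b = 0.9 * base + np.sqrt(1 - 0.81) * rng.standard_normal(400)
        c = 0.1 * base + np.sqrt(1 - 0.01) * rng.standard_normal(400)
        feats = pd.DataFrame({"A": a, "B": b, "C": c})
        corr = np.corrcoef(feats.to_numpy(), rowvar=False)
        tree = cluster_features(feats)
        # first merge: the closest pair (A, B)
        assert tree.heights[0] == pytest.approx(1 - corr[0, 1], abs=1e-12)
        expected_final = max(1 - corr[0, 2], 1 - corr[1, 2])
        assert tree.heights[-1] == pytest.approx(expected_final, abs=1e-12)

    def test_heights_bounded_and_monotone(self, cohort, cohort_period_asep):
        feats = cohort.metabolites.set_index("participant_id").iloc[:, :12]
        tree = cluster_features(feats)
        assert (tree.heights >= -1e-12).all() and (tree.heights <= 2 + 1e-12).all()
        assert (np.diff(tree.heights) >= -1e-12).all()

    def test_permutation_invariance_of_heights(self):
        rng = np.random.default_rng(11)
        feats = pd.DataFrame(
            rng.standard_normal((30, 6)), columns=list("abcdef")
        )
        t1 = cluster_features(feats)
        t2 = cluster_features(feats[list("fceadb")])
        np.testing.assert_allclose(np.sort(t1.heights), np.sort(t2.heights), atol=1e-12)

    def test_constant_feature_named_in_error(self):
        feats = pd.DataFrame({"ok": [1.0, 2, 3], "flat": [5.0, 5, 5]})
        with pytest.raises(EstimationError, match="flat"):
            cluster_features(feats)

    def test_newick_export_round_trips(self, tmp_path):
        from skbio import TreeNode

        rng = np.random.default_rng(4)
        feats = pd.DataFrame(rng.standard_normal((25, 5)), columns=list("vwxyz"))
        tree = cluster_features(feats)
        path = tmp_path / "clusters.nwk"
        tree.write_newick(path)
        parsed = TreeNode.read(str(path))
        assert {leaf.name for leaf in parsed.tips()} == set("vwxyz")


class TestCorrelationScreenModel:
    def test_fit_results_surface(self, cohort, cohort_period_asep):
        feats = cohort.metabolites.set_index("participant_id").iloc[:, :30]
        res = CorrelationScreen(feats, cohort_period_asep, m_for_bonferroni=872).fit()
        assert res.threshold.m == 872
        assert len(res.top(5)) == 5
        tree = res.cluster_top(5)
        assert len(tree.leaves) == 5
        assert "critical |r|" in res.summary()
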
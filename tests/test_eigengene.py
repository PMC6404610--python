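"""Eigengenes, ANOVA/Tukey statistics and reaction-norm classification."""

import numpy as np
import pandas as pd
import pytest

import coexnet as cx
from coexnet.eigengene import AnovaResult
from coexnet.simulate import Category
from tests.conftest import make_metadata


class TestModuleEigengene:
    def test_identical_genes_explain_everything(self):
        rng = np.random.default_rng(0)
        profile = rng.standard_normal(12)
        data = pd.DataFrame([profile] * 5, index=[f"g{i}" for i in range(5)])
        row = cx.module_eigengene(data, data.index)
        assert row.pct_variance_pc1 == pytest.approx(100.0)

    def test_two_orthogonal_profiles_split_fifty_fifty(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])
        data = pd.DataFrame([a, b], index=["g1", "g2"])
        row = cx.module_eigengene(data, ["g1", "g2"])
        assert row.pct_variance_pc1 == pytest.approx(50.0)

    def test_matches_eigendecomposition_oracle(self):
        """PC1 variance share equals a brute-force eigendecomposition of
        the gene-gene correlation matrix."""
        rng = np.random.default_rng(1)
        data = pd.DataFrame(rng.standard_normal((40, 24)))
        row = cx.module_eigengene(data, data.index)
        z = data.to_numpy()
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, ddof=1)[:, None]
        evals = np.linalg.eigvalsh(z @ z.T)
        assert row.pct_variance_pc1 == pytest.approx(
            100 * evals[-1] / evals.sum(), abs=1e-8
        )
        assert row.pct_variance_pc2 == pytest.approx(
            100 * evals[-2] / evals.sum(), abs=1e-8
        )

    def test_orientation_deterministic_and_positive(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(rng.standard_normal((10, 16))
                            + np.linspace(-2, 2, 16))
        r1 = cx.module_eigengene(data, data.index)
        r2 = cx.module_eigengene(data, data.index)
        assert np.allclose(r1.scores, r2.scores)
        z = data.sub(data.mean(axis=1), axis=0).div(data.std(axis=1, ddof=1), axis=0)
        assert np.corrcoef(r1.scores, z.mean(axis=0))[0, 1] > 0

    def test_constant_module_rejected(self):
        data = pd.DataFrame(np.ones((3, 8)))
        with pytest.raises(ValueError, match="constant"):
            cx.module_eigengene(data, data.index)


class TestAncestorTtest:
    def test_equal_groups_give_zero_t(self, full_metadata):
        """Identical means and variances across environments: t = 0, p = 1."""
        eig = pd.Series(0.0, index=full_metadata.index)
        anc = full_metadata[full_metadata.population == "ancestor"]
        for temp in (20, 30):
            idx = anc.index[anc.temperature == temp]
            eig.loc[idx] = np.arange(len(idx), dtype=float)
        t, df, p = cx.ancestor_ttest(eig, full_metadata)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        """Groups of 6 with means 0 and 1, both SD 0.5: pooled
        t = -1 / (0.5 * sqrt(1/3)) = -3.4641, df = 10."""
        meta = make_metadata(populations=("ancestor",), n_replicates=6)
        base = np.array([-1, -0.6, -0.2, 0.2, 0.6, 1.0])
        g = base / base.std(ddof=1) * 0.5
        eig = pd.Series(np.concatenate([g, g + 1.0]), index=meta.index)
        t, df, p = cx.ancestor_ttest(eig, meta)
        assert t == pytest.approx(-2 * np.sqrt(3), abs=1e-6)
        assert df == 10

    def test_sign_antisymmetry_under_label_swap(self, full_metadata):
        rng = np.random.default_rng(3)
        eig = pd.Series(rng.standard_normal(48), index=full_metadata.index)
        t, _, p = cx.ancestor_ttest(eig, full_metadata)
        swapped = full_metadata.copy()
        swapped["temperature"] = swapped["temperature"].map({20: 30, 30: 20})
        t2, _, p2 = cx.ancestor_ttest(eig, swapped)
        assert t2 == pytest.approx(-t)
        assert p2 == pytest.approx(p)

    def test_tiny_group_rejected(self, full_metadata):
        meta = full_metadata.drop(
            index=[f"ancestor_30_r{i}" for i in range(2, 7)]
        )
        eig = pd.Series(0.0, index=meta.index)
        with pytest.raises(ValueError, match="fewer than 2"):
            cx.ancestor_ttest(eig, meta)


class TestEigengeneAnova:
    def test_matches_statsmodels_type1(self, full_metadata):
        """Cell-mean sums of squares agree with an independent OLS
        ANOVA fit (statsmodels, Type-I on the balanced design)."""
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(4)
        eig = pd.Series(rng.standard_normal(48), index=full_metadata.index)
        res = cx.eigengene_anova(eig, full_metadata)

        df = full_metadata.copy()
        df["y"] = eig
        df["temperature"] = df["temperature"].astype(str)
        fit = ols("y ~ C(population) * C(temperature)", data=df).fit()
        table = sm.stats.anova_lm(fit, typ=1)
        assert res.table.loc["population", "SS"] == pytest.approx(
            table.loc["C(population)", "sum_sq"], abs=1e-10
        )
        assert res.table.loc["temperature", "SS"] == pytest.approx(
            table.loc["C(temperature)", "sum_sq"], abs=1e-10
        )
        assert res.table.loc["interaction", "F"] == pytest.approx(
            table.loc["C(population):C(temperature)", "F"], abs=1e-8
        )
        assert res.p("interaction") == pytest.approx(
            table.loc["C(population):C(temperature)", "PR(>F)"], abs=1e-10
        )

    def test_degrees_of_freedom_for_full_design(self, full_metadata):
        eig = pd.Series(np.arange(48, dtype=float), index=full_metadata.index)
        res = cx.eigengene_anova(eig, full_metadata)
        assert res.table.loc["temperature", ["df_num", "df_den"]].tolist() == [1, 40]
        assert res.table.loc["population", ["df_num", "df_den"]].tolist() == [3, 40]
        assert res.table.loc["interaction", ["df_num", "df_den"]].tolist() == [3, 40]

    def test_sample_order_invariance(self, full_metadata):
        rng = np.random.default_rng(5)
        eig = pd.Series(rng.standard_normal(48), index=full_metadata.index)
        res = cx.eigengene_anova(eig, full_metadata)
        perm = rng.permutation(48)
        res2 = cx.eigengene_anova(eig.iloc[perm], full_metadata)
        assert np.allclose(res.table["F"].iloc[:3], res2.table["F"].iloc[:3])

    def test_degenerate_exact_fit_flagged(self, full_metadata):
        eig = pd.Series(
            (full_metadata["temperature"] == 30).astype(float).to_numpy(),
            index=full_metadata.index,
        )
        res = cx.eigengene_anova(eig, full_metadata)
        assert res.degenerate
        assert res.p("temperature") == 0.0
        assert res.table.loc["population", "F"] == 0.0

    def test_empty_cell_rejected(self, full_metadata):
        meta = full_metadata.drop(index=[f"heat_30_r{i}" for i in range(1, 7)])
        eig = pd.Series(0.0, index=meta.index)
        with pytest.raises(ValueError, match="balanced"):
            cx.eigengene_anova(eig, meta)


class TestTukeyHsd:
    def test_identical_groups_share_one_letter(self, full_metadata):
        rng = np.random.default_rng(6)
        eig = pd.Series(0.01 * rng.standard_normal(48), index=full_metadata.index)
        res = cx.tukey_hsd(eig, full_metadata)
        assert len(set(res.letters.values())) == 1
        assert (res.comparisons["p_adj"] > 0.05).all()

    def test_single_outlier_population(self, full_metadata):
        """Means (0,0,0,5) with small within-SD: only pairs involving
        the outlier are significant; letters are {a,a,a,b}."""
        rng = np.random.default_rng(7)
        shift = full_metadata["population"].eq("oxidative") * 5.0
        eig = pd.Series(shift.to_numpy() + 0.5 * rng.standard_normal(48),
                        index=full_metadata.index)
        res = cx.tukey_hsd(eig, full_metadata)
        sig = res.comparisons[res.comparisons["significant"]]
        assert all("oxidative" in {a, b}
                   for a, b in zip(sig["group1"], sig["group2"]))
        assert len(sig) == 3
        letters = res.letters
        assert letters["ancestor"] == letters["control"] == letters["heat"]
        assert letters["oxidative"] != letters["ancestor"]

    def test_letters_consistent_with_pairwise_significance(self, full_metadata):
        rng = np.random.default_rng(8)
        shift = full_metadata["population"].map(
            {"ancestor": 0.0, "control": 0.6, "heat": 1.2, "oxidative": 5.0}
        )
        eig = pd.Series(shift.to_numpy() + 0.7 * rng.standard_normal(48),
                        index=full_metadata.index)
        res = cx.tukey_hsd(eig, full_metadata)
        for _, row in res.comparisons.iterrows():
            shared = set(res.letters[row["group1"]]) & set(res.letters[row["group2"]])
            if row["significant"]:
                assert not shared
            else:
                assert shared


class TestClassifyReactionNorm:
    @staticmethod
    def _anova(p_temp, p_pop, p_int):
        table = pd.DataFrame(
            {
                "p": [p_temp, p_pop, p_int],
                "F": [1.0, 1.0, 1.0],
            },
            index=["temperature", "population", "interaction"],
        )
        return AnovaResult(table=table)

    @pytest.mark.parametrize(
        "pattern, expected",
        [
            # module 1-like: temperature only
            ((0.0005, 0.069, 0.942), Category.SHARED_PLASTICITY),
            # module 5-like: all three effects, interaction significant
            ((0.002, 0.0005, 0.044), Category.EVOLVED_PLASTICITY),
            # temperature + population, no interaction
            ((0.0005, 0.001, 0.472), Category.DIVERGENT_BASELINE),
            # population only
            ((0.931, 0.0005, 0.232), Category.NON_PLASTIC_DIVERGENCE),
            ((0.5, 0.5, 0.5), Category.NULL),
        ],
    )
    def test_decision_table(self, pattern, expected):
        assert cx.classify_reaction_norm(self._anova(*pattern)) is expected


def test_eigengene_table_end_to_end(small_simulation):
    _, counts, meta, truth = small_simulation
    expr = cx.vst(counts, metadata=meta)
    stats_df, eig_df, letters_df = cx.eigengene_table(
        expr, truth.gene_labels, meta
    )
    assert set(stats_df["module"]) == {"1", "2", "unassigned"}
    assert stats_df.groupby("module")["effect"].count().eq(3).all()
    m1 = stats_df[stats_df["module"] == "1"].iloc[0]
    assert m1["category"] == "SHARED_PLASTICITY"
    m2 = stats_df[stats_df["module"] == "2"].iloc[0]
    assert m2["category"] == "EVOLVED_PLASTICITY"
    assert eig_df.shape == (3, 48)
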
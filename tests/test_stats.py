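"""Comparative-inference layer: contrasts, Tukey letters, correlations,
root:branch ratios and the random-intercept height model."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from xylemflow import stats as xs


class TestAggregation:
    def test_tree_means_and_species_means(self):
        df = pd.DataFrame(
            dict(
                species=["A"] * 3 + ["A"],
                tree_id=[1, 1, 2, 2],
                organ=["root"] * 4,
                leaf_habit=["deciduous"] * 4,
                trait=["x"] * 4,
                value=[8.0, 12.0, 5.0, 5.0],
            )
        )
        tree = xs.aggregate_tree_means(df)
        assert sorted(tree["value"]) == [5.0, 10.0]
        sp = xs.species_means(tree)
        assert sp["value"].iloc[0] == pytest.approx(7.5)
        assert sp["leaf_habit"].iloc[0] == "deciduous"

    def test_matches_brute_force_groupby(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            dict(
                species=rng.choice(["A", "B"], 60),
                tree_id=rng.integers(1, 4, 60),
                organ=rng.choice(["root", "branch"], 60),
                trait="x",
                value=rng.normal(size=60),
            )
        )
        tree = xs.aggregate_tree_means(df)
        brute = df.groupby(["species", "tree_id", "organ", "trait"])["value"].mean()
        for _, row in tree.iterrows():
            key = (row["species"], row["tree_id"], row["organ"], row["trait"])
            assert row["value"] == pytest.approx(brute.loc[key])


class TestContrasts:
    def test_pooled_two_sample_frozen_example(self):
        dec = [10, 12, 14, 11, 13]
        eve = [8, 9, 10, 9, 9, 8, 10, 9]
        c = xs.two_group_contrast(dec, eve)
        assert c.contrast == pytest.approx(3.0)
        assert c.SE == pytest.approx(0.6431, rel=1e-3)
        assert c.df == 11
        assert c.t_ratio == pytest.approx(4.665, rel=1e-3)

    def test_matches_ols_marginal_means_to_1e10(self):
        """A one-factor linear model's group contrast is exactly the pooled
        two-sample computation; verified against statsmodels OLS."""
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        for _ in range(5):
            n1, n2 = rng.integers(3, 12, size=2)
            a = rng.normal(5, 2, n1)
            b = rng.normal(3, 2, n2)
            c = xs.two_group_contrast(a, b)
            x = np.concatenate([np.ones(n1), np.zeros(n2)])
            X = sm.add_constant(x)
            fit = sm.OLS(np.concatenate([a, b]), X).fit()
            assert c.contrast == pytest.approx(fit.params[1], abs=1e-10)
            assert c.SE == pytest.approx(fit.bse[1], abs=1e-10)
            assert c.t_ratio == pytest.approx(fit.tvalues[1], abs=1e-10)
            assert c.p_value == pytest.approx(fit.pvalues[1], abs=1e-10)
            assert c.df == int(fit.df_resid)

    def test_identical_groups(self):
        c = xs.two_group_contrast([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert c.contrast == 0.0
        assert c.p_value == pytest.approx(1.0)

    def test_habit_contrast_direction_and_exclusions(self):
        values = {"a": 10.0, "b": 12.0, "c": 7.0, "d": 8.0, "gym": 99.0}
        habits = {
            "a": "deciduous", "b": "deciduous",
            "c": "evergreen", "d": "evergreen", "gym": "gymnosperm",
        }
        c = xs.habit_contrast(values, habits)
        assert c.contrast == pytest.approx(11.0 - 7.5)  # deciduous − evergreen
        assert c.df == 2
        with pytest.raises(ValueError):
            xs.habit_contrast({"a": 1.0, "c": 2.0, "d": 3.0}, habits)

    def test_organ_df_bookkeeping(self):
        rng = np.random.default_rng(5)
        full = xs.organ_contrast(rng.normal(size=13), rng.normal(size=13))
        assert full.df == 24
        missing = xs.organ_contrast(rng.normal(size=12), rng.normal(size=13))
        assert missing.df == 23
        with pytest.raises(ValueError):
            xs.organ_contrast([], rng.normal(size=13))


class TestTukeyLetters:
    def test_full_separation(self):
        rng = np.random.default_rng(0)
        groups = {
            "lo": rng.normal(0, 0.1, 6),
            "mid": rng.normal(10, 0.1, 6),
            "hi": rng.normal(20, 0.1, 6),
        }
        ld = xs.tukey_letters(groups)
        assert {ld["hi"], ld["mid"], ld["lo"]} == {"a", "b", "c"}
        assert ld["hi"] == "a"  # highest mean labelled first

    def test_identical_groups_share_one_letter(self):
        rng = np.random.default_rng(1)
        base = rng.normal(5, 1, 8)
        groups = {k: base + rng.normal(0, 0.01, 8) for k in "xyz"}
        ld = xs.tukey_letters(groups)
        assert all(v == "a" for v in ld.letters.values())

    @pytest.mark.parametrize("k, seed", [(3, 2), (4, 3), (5, 4)])
    def test_pvalues_match_scipy_tukey_hsd(self, k, seed):
        """Pairwise adjusted p-values agree with scipy's independent
        Tukey HSD implementation on seeded instances."""
        rng = np.random.default_rng(seed)
        arrays = [rng.normal(rng.uniform(0, 3), 1.0, rng.integers(4, 9)) for _ in range(k)]
        groups = {f"g{i}": a for i, a in enumerate(arrays)}
        p = xs.tukey_pairwise(groups)
        ref = sps.tukey_hsd(*arrays)
        for i, j in itertools.combinations(range(k), 2):
            assert p.iloc[i, j] == pytest.approx(ref.pvalue[i, j], abs=1e-8)

    def test_letters_encode_pairwise_decisions(self):
        """Groups share a letter iff their adjusted p ≥ alpha (insert-absorb
        guarantee), on a randomized instance."""
        rng = np.random.default_rng(9)
        groups = {
            f"g{i}": rng.normal(rng.uniform(0, 4), 1.0, 6) for i in range(5)
        }
        ld = xs.tukey_letters(groups, alpha=0.05)
        for a, b in itertools.combinations(groups, 2):
            share = bool(set(ld[a]) & set(ld[b]))
            assert share == (ld.p_matrix.loc[a, b] >= 0.05)

    def test_letter_structure_order_invariant(self):
        rng = np.random.default_rng(12)
        groups = {f"g{i}": rng.normal(i * 1.2, 1.0, 5) for i in range(4)}
        ld1 = xs.tukey_letters(groups)
        shuffled = dict(reversed(list(groups.items())))
        ld2 = xs.tukey_letters(shuffled)
        for a, b in itertools.combinations(groups, 2):
            s1 = bool(set(ld1[a]) & set(ld1[b]))
            s2 = bool(set(ld2[a]) & set(ld2[b]))
            assert s1 == s2

    def test_degenerate_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            xs.tukey_pairwise({"a": [1.0, 1.0], "b": [2.0, 2.0]})


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        tab = pd.DataFrame({"x": x, "y": 2 * x})
        out = xs.pearson_matrix(tab)
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_textbook_five_points(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        out = xs.pearson_matrix(pd.DataFrame({"x": x, "y": y}))
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert out["r"].iloc[0] == pytest.approx(num / den, rel=1e-12)

    def test_null_noise_is_insignificant(self):
        rng = np.random.default_rng(21)
        tab = pd.DataFrame(rng.normal(size=(13, 2)), columns=["x", "y"])
        out = xs.pearson_matrix(tab)
        assert out["p"].iloc[0] > 0.05

    def test_insufficient_pairs_flagged(self):
        tab = pd.DataFrame({"x": [1.0, 2, np.nan], "y": [np.nan, 1, 2]})
        out = xs.pearson_matrix(tab)
        assert out["signif"].iloc[0] == "n.a."
        assert np.isnan(out["r"].iloc[0])


class TestRBRatio:
    def test_single_pair(self):
        ratios, mean = xs.rb_ratio({"t1": 9.5}, {"t1": 2.3})
        assert mean == pytest.approx(9.5 / 2.3, rel=1e-6)

    def test_equal_values_give_one(self):
        ratios, mean = xs.rb_ratio({"a": 3.0, "b": 5.0}, {"a": 3.0, "b": 5.0})
        assert mean == 1.0

    def test_mean_of_ratios_not_ratio_of_means(self):
        root = {"a": 10.0, "b": 2.0}
        branch = {"a": 2.0, "b": 10.0}
        _, mean = xs.rb_ratio(root, branch)
        assert mean == pytest.approx((5.0 + 0.2) / 2)
        assert mean != pytest.approx(sum(root.values()) / sum(branch.values()))

    def test_zero_branch_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            ratios, mean = xs.rb_ratio({"a": 1.0, "b": 2.0}, {"a": 0.0, "b": 1.0})
        assert len(ratios) == 1 and mean == 2.0


class TestHeightModel:
    def test_zero_between_species_variance_reduces_to_pooled_ols(self):
        rng = np.random.default_rng(30)
        h = rng.uniform(5, 20, 60)
        y = 1.5 * h + rng.normal(0, 1.0, 60)
        species = np.repeat([f"s{i}" for i in range(10)], 6)
        res = xs.height_model(y, h, species)
        slope_ols = np.polyfit(h, y, 1)[0]
        assert res.psi < 0.5  # near-boundary variance ratio
        assert res.slope == pytest.approx(slope_ols, rel=1e-2)

    def test_known_slope_recovery(self):
        rng = np.random.default_rng(31)
        species = np.repeat([f"s{i}" for i in range(12)], 8)
        effects = np.repeat(rng.normal(0, 2.0, 12), 8)
        h = rng.uniform(4, 18, 96)
        y = 3.0 + 0.8 * h + effects + rng.normal(0, 0.5, 96)
        res = xs.height_model(y, h, species)
        assert res.slope == pytest.approx(0.8, abs=0.1)
        assert res.slope_p < 1e-6
        assert res.psi > 1.0  # strong between-species variance detected

    def test_matches_statsmodels_mixedlm(self):
        """Profiled-ML fit agrees with statsmodels MixedLM (ML) on slope
        and log-likelihood."""
        import statsmodels.api as sm

        rng = np.random.default_rng(32)
        species = np.repeat([f"s{i}" for i in range(8)], 6)
        effects = np.repeat(rng.normal(0, 1.5, 8), 6)
        h = rng.uniform(4, 18, 48)
        y = 2.0 + 0.5 * h + effects + rng.normal(0, 1.0, 48)
        res = xs.height_model(y, h, species)
        md = sm.MixedLM(y, sm.add_constant(h), groups=species)
        fit = md.fit(reml=False)
        assert res.slope == pytest.approx(fit.fe_params[1], rel=1e-4)
        assert res.loglik == pytest.approx(fit.llf, abs=1e-4)

    def test_requires_two_species(self):
        with pytest.raises(ValueError):
            xs.height_model([1, 2, 3, 4], [1, 2, 3, 4], ["a"] * 4)
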
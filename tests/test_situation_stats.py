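"""Situation profiles, Ward dendrograms, association tests, valence models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pigletcalls as pc
from pigletcalls.situation_stats import _spearman


class TestProfiles:
    def test_matches_groupby_oracle(self, realistic_calls):
        profiles = pc.situation_profiles(realistic_calls, mode="acoustic")
        for code in ("CA", "IS"):
            subset = realistic_calls[realistic_calls["situation"] == code]
            assert np.allclose(profiles.loc[code], subset[pc.FEATURE_NAMES].mean())

    def test_single_call_situation_is_that_call(self):
        row = {name: float(i) for i, name in enumerate(pc.FEATURE_NAMES, start=1)}
        table = pd.DataFrame([{"situation": "CA", **row}])
        profiles = pc.situation_profiles(table, mode="acoustic")
        assert np.allclose(profiles.loc["CA"], list(row.values()))

    def test_type_proportions_sum_to_one(self, realistic_calls):
        typed = realistic_calls.rename(columns={"true_type": "type"})
        profiles = pc.situation_profiles(typed, mode="types")
        assert np.allclose(profiles.sum(axis=1), 1.0)


class TestWardDendrogram:
    def test_identical_profiles_merge_first_at_zero(self):
        profiles = pd.DataFrame(
            [[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]], index=["a", "b", "c"]
        )
        tree = pc.ward_dendrogram(profiles)
        assert tree.linkage[0, 2] == pytest.approx(0.0)
        assert set(tree.linkage[0, :2].astype(int)) == {0, 1}

    def test_lance_williams_hand_computation(self):
        # four points on a line: 0, 1, 10, 12
        profiles = pd.DataFrame([[0.0], [1.0], [10.0], [12.0]], index=list("abcd"))
        tree = pc.ward_dendrogram(profiles)
        Z = tree.linkage
        # first merges: (a,b) at sqrt(2*0.5)=1, (c,d) at sqrt(2*2)=2
        assert Z[0, 2] == pytest.approx(1.0)
        assert Z[1, 2] == pytest.approx(2.0)
        # final Ward merge of {a,b} and {c,d}: sqrt(2 * (2*2/4) * d(centroids)^2)
        d2 = (0.5 - 11.0) ** 2
        assert Z[2, 2] == pytest.approx(np.sqrt(2.0 * 1.0 * d2))

    def test_gross_blocks_form_clades(self, separated_calls):
        typed = separated_calls.rename(columns={"true_type": "type"})
        profiles = pc.situation_profiles(typed, mode="types")
        tree = pc.ward_dendrogram(profiles)
        cut = tree.cut(3)
        mapped = cut.groupby([pc.GROSS_CATEGORY[s] for s in cut.index]).nunique()
        assert (mapped == 1).all()  # each gross category is a single clade

    def test_cophenetic_round_trip(self, realistic_calls):
        profiles = pc.situation_profiles(realistic_calls, mode="acoustic")
        tree = pc.ward_dendrogram(profiles)
        coph = tree.cophenetic()
        heights = sorted(tree.linkage[:, 2])
        observed = sorted(set(np.round(coph.to_numpy()[np.triu_indices(11, 1)], 9)))
        assert np.allclose(observed, np.round(sorted(set(np.round(heights, 9))), 9))

    def test_newick_is_parseable_with_leaves(self, realistic_calls):
        import io

        from Bio import Phylo

        profiles = pc.situation_profiles(realistic_calls, mode="acoustic")
        newick = pc.ward_dendrogram(profiles).newick()
        clade = Phylo.read(io.StringIO(newick), "newick")
        assert sorted(t.name for t in clade.get_terminals()) == sorted(pc.SITUATION_CODES)

    def test_duplicate_codes_rejected(self):
        profiles = pd.DataFrame([[0.0], [1.0]], index=["CA", "CA"])
        with pytest.raises(ValueError, match="duplicate"):
            pc.ward_dendrogram(profiles)


class TestAssociation:
    def test_diagonal_table_closed_form(self):
        types = np.repeat(["t1", "t2"], 10)
        situations = np.repeat(["s1", "s2"], 10)
        out = pc.association_test(types, situations, seed=0)
        assert out.chi2 == pytest.approx(20.0)
        assert np.allclose(np.abs(out.residuals.to_numpy()), np.sqrt(5))
        # only the positive-residual (diagonal) cells are flagged at >2
        assert bool(out.flags2.to_numpy().sum()) and not out.flags4.to_numpy().any()
        assert not out.monte_carlo  # expected counts are exactly 5
        assert out.df == 1
        assert out.p == pytest.approx(float(stats.chi2.sf(20.0, 1)))

    def test_independent_table_zero_residuals(self):
        # counts exactly at the outer product of the margins
        types = np.array(["t1"] * 60 + ["t2"] * 40 + ["t1"] * 60 + ["t2"] * 40)
        situations = np.array(["s1"] * 100 + ["s2"] * 100)
        out = pc.association_test(types, situations)
        assert np.allclose(out.residuals.to_numpy(), 0.0, atol=1e-12)
        assert out.chi2 == pytest.approx(0.0)

    def test_residual_conservation(self, realistic_calls):
        out = pc.association_test(
            realistic_calls["true_type"], realistic_calls["situation"], seed=2
        )
        assert out.table.to_numpy().sum() == pytest.approx(out.expected.to_numpy().sum())

    def test_monte_carlo_close_to_asymptotic_on_large_table(self):
        rng = np.random.default_rng(3)
        types = rng.choice(["t1", "t2", "t3"], size=2000, p=[0.5, 0.3, 0.2])
        situations = rng.choice(["s1", "s2", "s3", "s4"], size=2000)
        asym = pc.association_test(types, situations)
        assert not asym.monte_carlo
        # force the Monte-Carlo path on the same counts via scipy oracle
        sampler = stats.random_table(
            asym.table.sum(axis=1).to_numpy(), asym.table.sum(axis=0).to_numpy()
        )
        tables = sampler.rvs(4000, random_state=np.random.default_rng(4))
        exp = asym.expected.to_numpy()
        null = ((tables - exp) ** 2 / exp).sum(axis=(1, 2))
        mc_p = (1 + np.sum(null >= asym.chi2)) / 4001
        assert abs(mc_p - asym.p) < 0.02

    def test_agrees_with_scipy_chi2_contingency(self, realistic_calls):
        out = pc.association_test(realistic_calls["true_type"], realistic_calls["situation"])
        chi2, p, df, _ = stats.chi2_contingency(out.table, correction=False)
        assert out.chi2 == pytest.approx(chi2)
        if not out.monte_carlo:
            assert out.p == pytest.approx(p) and out.df == df

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            pc.association_test(["t1", "t1"], ["s1", "s2"])


class TestMeanValence:
    def test_unanimous_experts_zero_width(self):
        ranks = pc.generate_expert_ranks(list("ABCD"), n_experts=6, swap_noise=0.0, seed=0)
        out = pc.mean_valence(ranks)
        assert np.array_equal(out["mean_rank"], [1, 2, 3, 4])
        assert np.allclose(out["ci_high"] - out["ci_low"], 0.0)

    def test_matches_column_mean_oracle(self):
        ranks = pc.generate_expert_ranks(list("ABCDE"), n_experts=9, swap_noise=0.4, seed=1)
        out = pc.mean_valence(ranks)
        assert np.allclose(out["mean_rank"], ranks.mean(axis=0))
        assert out["mean_rank"].between(1, 5).all()

    def test_invalid_row_rejected(self):
        bad = pd.DataFrame([[1, 2, 2]], columns=list("ABC"))
        with pytest.raises(ValueError, match="permutation"):
            pc.mean_valence(bad)


class TestSpearman:
    def test_perfect_and_reversed(self):
        profiles = pd.DataFrame(
            {"up": np.arange(11.0), "down": -np.arange(11.0)},
            index=list(pc.SITUATION_CODES),
        )
        valence = pd.Series(np.arange(11.0), index=list(pc.SITUATION_CODES))
        out = pc.valence_feature_correlation(profiles, valence, seed=0)
        assert out.loc["up", "rho"] == pytest.approx(1.0)
        assert out.loc["down", "rho"] == pytest.approx(-1.0)
        assert out.loc["up", "p_raw"] <= 0.001

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(2)
        x, yv = rng.normal(size=11), rng.normal(size=11)
        rho, _ = _spearman(x, yv, seed=3)
        oracle = stats.pearsonr(stats.rankdata(x), stats.rankdata(yv)).statistic
        assert rho == pytest.approx(oracle)
        assert rho == pytest.approx(stats.spearmanr(x, yv).statistic)

    def test_exact_small_n_matches_scipy_exact(self):
        rng = np.random.default_rng(4)
        x, yv = rng.normal(size=7), rng.normal(size=7)
        _, p = _spearman(x, yv)
        # scipy uses a t-approximation; exact enumeration should land close
        scipy_p = stats.spearmanr(x, yv).pvalue
        assert abs(p - scipy_p) < 0.05

    def test_constant_variable_flagged(self):
        profiles = pd.DataFrame(
            {"flat": np.ones(11), "up": np.arange(11.0)}, index=list(pc.SITUATION_CODES)
        )
        valence = pd.Series(np.arange(11.0), index=list(pc.SITUATION_CODES))
        out = pc.valence_feature_correlation(profiles, valence, seed=5)
        assert np.isnan(out.loc["flat", "rho"]) and out.loc["flat", "note"] == "constant"


class TestBenjaminiHochberg:
    def test_monotone_and_above_raw(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=20)
        adj = pc.benjamini_hochberg(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_matches_hand_stepup(self):
        p = np.array([0.01, 0.04, 0.03, 0.005])
        adj = pc.benjamini_hochberg(p)
        # hand step-up: sorted p (.005,.01,.03,.04) * 4/(1..4), cummin from top
        assert np.allclose(adj, [0.02, 0.04, 0.04, 0.02])


class TestTypeRegression:
    @staticmethod
    def counts_from_props(props, totals):
        props = np.asarray(props, dtype=float)
        hf = np.round(props * totals).astype(int)
        return pd.DataFrame(
            {"HF": hf, "LF": totals - hf}, index=list(pc.SITUATION_CODES)[: len(props)]
        )

    def test_constant_proportion_zero_slope(self):
        totals = np.full(11, 100)
        counts = self.counts_from_props(np.full(11, 0.4), totals)
        valence = pd.Series(np.arange(1.0, 12.0), index=counts.index)
        out = pc.valence_type_regression(counts, valence)
        assert abs(out.loc["HF", "b"]) < 1e-8
        assert not out.loc["HF", "significant"]

    def test_exact_logistic_curve_recovered(self):
        ranks = np.arange(1.0, 12.0)
        b0, b1 = 1.0, -0.4
        props = 1 / (1 + np.exp(-(b0 + b1 * ranks)))
        totals = np.full(11, 10**6)  # rounding error negligible
        counts = self.counts_from_props(props, totals)
        valence = pd.Series(ranks, index=counts.index)
        out = pc.valence_type_regression(counts, valence)
        assert out.loc["HF", "b"] == pytest.approx(b1, abs=1e-5)

    def test_binomial_data_dispersion_near_one(self):
        rng = np.random.default_rng(7)
        ranks = np.arange(1.0, 12.0)
        p_true = 1 / (1 + np.exp(0.3 * (ranks - 6)))
        disp = []
        for rep in range(40):
            totals = np.full(11, 200)
            hf = rng.binomial(totals, p_true)
            counts = pd.DataFrame(
                {"HF": hf, "LF": totals - hf}, index=list(pc.SITUATION_CODES)
            )
            valence = pd.Series(ranks, index=counts.index)
            out = pc.valence_type_regression(counts, valence)
            disp.append(out.loc["HF", "dispersion"])
        assert abs(np.mean(disp) - 1.0) < 0.25

    def test_matches_statsmodels_quasibinomial_F(self):
        """Drop-in-deviance F with Pearson dispersion, df = S - 2."""
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        ranks = np.arange(1.0, 12.0)
        totals = np.full(11, 120)
        hf = rng.binomial(totals, 1 / (1 + np.exp(0.5 * (ranks - 6))))
        counts = pd.DataFrame({"HF": hf, "LF": totals - hf}, index=list(pc.SITUATION_CODES))
        valence = pd.Series(ranks, index=counts.index)
        out = pc.valence_type_regression(counts, valence)
        fit = sm.GLM(
            hf / totals, sm.add_constant(ranks), family=sm.families.Binomial(),
            var_weights=totals,
        ).fit()
        assert out.loc["HF", "b"] == pytest.approx(fit.params[1])
        null = sm.GLM(
            hf / totals, np.ones((11, 1)), family=sm.families.Binomial(),
            var_weights=totals,
        ).fit()
        F = (null.deviance - fit.deviance) / (fit.pearson_chi2 / 9)
        assert out.loc["HF", "F"] == pytest.approx(F)
        assert out.loc["HF", "p_raw"] == pytest.approx(float(stats.f.sf(F, 1, 9)))

    def test_separation_warns(self):
        counts = pd.DataFrame(
            {"HF": np.zeros(11, dtype=int), "LF": np.full(11, 50)},
            index=list(pc.SITUATION_CODES),
        )
        valence = pd.Series(np.arange(1.0, 12.0), index=counts.index)
        with pytest.warns(UserWarning, match="all-zero"):
            out = pc.valence_type_regression(counts, valence)
        assert out.loc["HF", "note"] == "separation"
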
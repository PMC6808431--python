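"""Probe collapsing, GSEA running sum, eigengenes, membership test."""

import itertools

import numpy as np
import pandas as pd
import pytest

from glycadecomp import expression as ge, synth


class TestCollapseProbes:
    def _fixture(self):
        """10 genes on 14 probes (4 genes duplicated)."""
        rng = np.random.default_rng(0)
        probes = [f"pr{i}" for i in range(14)]
        genes = [f"g{i}" for i in range(10)] + ["g0", "g1", "g2", "g3"]
        expr = pd.DataFrame(rng.normal(7, 1, (14, 6)), index=probes,
                            columns=[f"s{i}" for i in range(6)])
        ann = pd.DataFrame({"gene": genes}, index=pd.Index(probes, name="probe_id"))
        return expr, ann

    def test_row_count_and_values_match_brute_force_max(self):
        expr, ann = self._fixture()
        out = ge.collapse_probes(expr, ann)
        assert len(out) == 10
        for gene in out.index:
            members = ann.index[ann["gene"] == gene]
            for s in expr.columns:
                assert out.loc[gene, s] == expr.loc[members, s].max()

    def test_single_probe_gene_copied_unchanged(self):
        expr, ann = self._fixture()
        out = ge.collapse_probes(expr, ann)
        pd.testing.assert_series_equal(out.loc["g5"], expr.loc["pr5"], check_names=False)

    def test_unannotated_probes_dropped_and_counted(self):
        expr, ann = self._fixture()
        ann.loc["pr13", "gene"] = np.nan
        out = ge.collapse_probes(expr, ann)
        assert out.attrs["n_unannotated"] == 1


class TestRankGenes:
    def _data(self, n=50, seed=1):
        rng = np.random.default_rng(seed)
        samples = [f"s{i}" for i in range(n)]
        age = pd.Series(rng.uniform(25, 74, n), index=samples)
        sex = pd.Series(rng.integers(1, 3, n).astype(float), index=samples)
        aat_log = 0.01 * age + 0.2 * sex + rng.standard_normal(n)
        aat = pd.Series(np.exp(aat_log), index=samples)
        genes = pd.DataFrame(rng.standard_normal((20, n)),
                             index=[f"g{i:02d}" for i in range(20)], columns=samples)
        return genes, aat, age, sex

    def test_gene_equal_to_adjusted_aat_ranks_first(self):
        genes, aat, age, sex = self._data()
        resid = ge._residualize(np.log(aat.to_numpy())[None, :],
                                np.column_stack([age, sex]))[0]
        genes.loc["g00"] = resid
        ranked = ge.rank_genes(genes, aat, age, sex)
        assert ranked.index[0] == "g00"
        assert ranked.iloc[0] == pytest.approx(1.0)

    def test_adjustment_is_noop_without_covariate_effects(self):
        rng = np.random.default_rng(2)
        n = 40
        samples = [f"s{i}" for i in range(n)]
        aat = pd.Series(np.exp(rng.standard_normal(n)), index=samples)
        genes = pd.DataFrame(rng.standard_normal((15, n)),
                             index=[f"g{i}" for i in range(15)], columns=samples)
        # covariates carrying no signal at all (constant-free random noise)
        age = pd.Series(rng.uniform(25, 74, n), index=samples)
        sex = pd.Series(rng.integers(1, 3, n).astype(float), index=samples)
        plain = ge.rank_genes(genes, aat)
        adj = ge.rank_genes(genes, aat, age, sex)
        # rankings agree except possibly for near-tied neighbours
        assert (plain.index == adj.index).mean() > 0.8
        assert np.abs(plain.sort_index() - adj.sort_index()).max() < 0.25

    def test_matches_partial_correlation_oracle(self):
        from scipy.stats import pearsonr

        genes, aat, age, sex = self._data()
        ranked = ge.rank_genes(genes, aat, age, sex)
        C = np.column_stack([np.ones(50), age, sex])
        proj = np.eye(50) - C @ np.linalg.pinv(C)
        y_res = proj @ np.log(aat.to_numpy())
        for g in genes.index:
            r_oracle = pearsonr(proj @ genes.loc[g].to_numpy(), y_res).statistic
            assert ranked.loc[g] == pytest.approx(r_oracle, abs=1e-10)

    def test_constant_gene_gets_zero_by_convention(self):
        genes, aat, age, sex = self._data()
        genes.loc["g00"] = 5.0
        ranked = ge.rank_genes(genes, aat)
        assert ranked.loc["g00"] == 0.0


class TestEnrichmentScore:
    def test_hand_walked_worked_example(self):
        ranked = pd.Series([0.5, 0.4, 0.3, -0.2, -0.4], index=list("abcde"))
        # running sum: 0.5, 0.3, 0.1, −0.1, −0.3 (miss decrement 1/5)
        assert ge.enrichment_score(ranked, {"a"}) == pytest.approx(0.5)

    def test_full_set_gives_max_prefix_sum(self):
        ranked = pd.Series([0.5, -0.1, 0.3, -0.4], index=list("abcd"))
        assert ge.enrichment_score(ranked, set("abcd")) == pytest.approx(0.7)

    def test_all_zero_correlations_give_zero(self):
        ranked = pd.Series([0.0, 0.0, 0.0], index=list("abc"))
        assert ge.enrichment_score(ranked, {"a", "b"}) == pytest.approx(0.0)

    def test_empty_intersection_rejected(self):
        ranked = pd.Series([0.5], index=["a"])
        with pytest.raises(ValueError, match="overlap"):
            ge.enrichment_score(ranked, {"zzz"})

    def test_invariant_to_tie_order(self):
        r = pd.Series([0.5, 0.2, 0.2, -0.1], index=list("abcd"))
        r2 = pd.Series([0.5, 0.2, 0.2, -0.1], index=list("acbd"))
        assert ge.enrichment_score(r, {"b", "c"}) == pytest.approx(
            ge.enrichment_score(r2, {"b", "c"}))


def _exhaustive_oracle(expr, aat_values, gene_set):
    """Enumerate every sample permutation; recompute correlation ranking
    and literal running-sum ES each time. Returns (observed, null list)."""
    samples = list(expr.columns)
    E = expr.to_numpy(dtype=float)
    Ec = E - E.mean(axis=1, keepdims=True)

    def es_for(y):
        yc = y - y.mean()
        r = Ec @ yc / (np.linalg.norm(Ec, axis=1) * np.linalg.norm(yc))
        s = pd.Series(r, index=expr.index).sort_values(ascending=False, kind="stable")
        inc = np.where(s.index.isin(gene_set), s.to_numpy(), -1.0 / len(s))
        run = np.cumsum(inc)
        mx, mn = run.max(), run.min()
        return mx if abs(mx) >= abs(mn) else mn

    observed = es_for(np.log(aat_values))
    null = [es_for(np.log(aat_values[list(perm)]))
            for perm in itertools.permutations(range(len(samples)))]
    return observed, np.array(null)


class TestPermutationGSEA:
    def test_exhaustive_permutation_p_equals_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        samples = [f"s{i}" for i in range(6)]
        expr = pd.DataFrame(rng.standard_normal((8, 6)),
                            index=[f"g{i}" for i in range(8)], columns=samples)
        aat = pd.Series(np.exp(rng.standard_normal(6)), index=samples)
        gene_set = {"g0", "g3", "g5"}
        perms = np.array(list(itertools.permutations(range(6))))
        res = ge.normalise_and_test(expr, aat, {"set": sorted(gene_set)},
                                    permutations=perms)[0]
        observed, null = _exhaustive_oracle(expr, aat.to_numpy(), gene_set)
        assert res.es == pytest.approx(observed)
        b = (np.abs(null) >= abs(observed)).sum()
        assert res.p == pytest.approx((b + 1) / (len(null) + 1))
        assert res.nes == pytest.approx(observed / np.abs(null).mean())

    def test_planted_signal_detected_and_decoys_not(self):
        cfg = synth.GeneratorConfig(seed=12, expr_n_samples=100,
                                    expr_module_sizes=(20, 20),
                                    expr_aat_betas=(0.6, 0.0))
        ed = synth.generate_expression(cfg)
        genes = ge.collapse_probes(ed.expr, ed.annotation)
        sets = {m: sorted(ed.annotation.loc[[p for p in probes], "gene"].unique())
                for m, probes in ed.modules.items()}
        res = ge.normalise_and_test(genes, ed.aat, sets, n_perm=200, seed=0)
        byname = {r.name: r for r in res}
        assert byname["module_01"].fdr < 0.05
        assert byname["module_02"].p > 0.05

    def test_null_sets_have_nes_near_one(self):
        rng = np.random.default_rng(4)
        samples = [f"s{i}" for i in range(40)]
        expr = pd.DataFrame(rng.standard_normal((60, 40)),
                            index=[f"g{i}" for i in range(60)], columns=samples)
        aat = pd.Series(np.exp(rng.standard_normal(40)), index=samples)
        sets = {f"set{k}": [f"g{i}" for i in rng.choice(60, 8, replace=False)]
                for k in range(10)}
        res = ge.normalise_and_test(expr, aat, sets, n_perm=150, seed=1)
        mean_abs_nes = np.mean([abs(r.nes) for r in res])
        assert 0.6 < mean_abs_nes < 1.5


class TestSummaryExpression:
    def test_identical_probes_give_perfectly_correlated_summary(self):
        rng = np.random.default_rng(5)
        profile = rng.standard_normal(30)
        expr = pd.DataFrame([profile, profile, profile],
                            index=["a", "b", "c"], columns=[f"s{i}" for i in range(30)])
        eig = ge.summary_expression(expr, ["a", "b", "c"])
        assert abs(np.corrcoef(eig, profile)[0, 1]) == pytest.approx(1.0)

    def test_two_probe_closed_form_loading(self):
        rng = np.random.default_rng(6)
        x1 = rng.standard_normal(200)
        x2 = 0.6 * x1 + 0.8 * rng.standard_normal(200)
        expr = pd.DataFrame([x1, x2], index=["a", "b"], columns=[f"s{i}" for i in range(200)])
        eig = ge.summary_expression(expr, ["a", "b"])
        # PC1 of a 2x2 correlation matrix loads (1/√2, 1/√2): the score is
        # proportional to the sum of the standardised probes
        z1 = (x1 - x1.mean()) / x1.std(ddof=1)
        z2 = (x2 - x2.mean()) / x2.std(ddof=1)
        assert abs(np.corrcoef(eig, z1 + z2)[0, 1]) == pytest.approx(1.0, abs=1e-10)

    def test_coherent_module_recovers_latent(self):
        rng = np.random.default_rng(7)
        n = 500
        latent = rng.standard_normal(n)
        rows = [0.8 * latent + 0.6 * rng.standard_normal(n) for _ in range(12)]
        expr = pd.DataFrame(rows, index=[f"p{i}" for i in range(12)],
                            columns=[f"s{i}" for i in range(n)])
        eig = ge.summary_expression(expr, list(expr.index))
        assert np.corrcoef(eig, latent)[0, 1] > 0.9

    def test_sign_aligned_to_mean_module_expression(self):
        rng = np.random.default_rng(8)
        n = 100
        latent = rng.standard_normal(n)
        rows = [0.9 * latent + 0.3 * rng.standard_normal(n) for _ in range(5)]
        expr = pd.DataFrame(rows, index=[f"p{i}" for i in range(5)],
                            columns=[f"s{i}" for i in range(n)])
        eig = ge.summary_expression(expr, list(expr.index))
        assert np.corrcoef(eig, expr.mean(axis=0))[0, 1] > 0

    def test_missing_module_rejected(self):
        expr = pd.DataFrame(np.ones((2, 5)), index=["a", "b"])
        with pytest.raises(ValueError):
            ge.summary_expression(expr, ["x", "y"])


class TestModuleRegression:
    def test_recovers_generative_effect_size(self):
        cfg = synth.GeneratorConfig(seed=13, expr_n_samples=10_000,
                                    expr_module_sizes=(30,), expr_aat_betas=(0.23,))
        ed = synth.generate_expression(cfg)
        eig = ge.summary_expression(ed.expr, ed.modules["module_01"])
        a = ge.module_regression(ed.aat, eig, ed.covariates["age"], ed.covariates["sex"],
                                 family_size=20)
        assert a.beta == pytest.approx(0.23, abs=0.05)

    def test_bonferroni_thresholds_for_study_family_sizes(self):
        a = ge.ModuleAssociation("m", 0.1, 0.05, 0.01, family_size=20)
        assert a.bonferroni_threshold == pytest.approx(0.0025)
        b = ge.ModuleAssociation("m", 0.1, 0.05, 0.01, family_size=346)
        assert b.bonferroni_threshold == pytest.approx(1.445e-4, rel=5e-3)

    def test_null_module_not_significant(self):
        rng = np.random.default_rng(9)
        n = 300
        samples = [f"s{i}" for i in range(n)]
        aat = pd.Series(np.exp(rng.standard_normal(n)), index=samples)
        eig = pd.Series(rng.standard_normal(n), index=samples)
        a = ge.module_regression(aat, eig, family_size=20)
        assert a.p > 0.0025 or abs(a.beta) < 0.2  # no systematic signal

    def test_beta_negates_with_eigengene_flip(self):
        rng = np.random.default_rng(10)
        n = 200
        samples = [f"s{i}" for i in range(n)]
        eig = pd.Series(rng.standard_normal(n), index=samples)
        aat = pd.Series(np.exp(0.3 * eig + rng.standard_normal(n) * 0.5), index=samples)
        a = ge.module_regression(aat, eig)
        b = ge.module_regression(aat, -eig)
        assert a.beta == pytest.approx(-b.beta, abs=1e-12)


class TestCoreMembership:
    def _matrix(self, seed=11, n=80, coupled=True):
        rng = np.random.default_rng(seed)
        latent = rng.standard_normal(n)
        module_rows, names = [], []
        for i in range(6):
            load = 0.9 if coupled else 0.0
            module_rows.append(load * latent + np.sqrt(1 - load**2) * rng.standard_normal(n))
            names.append(f"mod{i}")
        bg = rng.standard_normal((120, n))
        expr = pd.DataFrame(np.vstack([module_rows, bg]),
                            index=names + [f"bg{i}" for i in range(120)],
                            columns=[f"s{i}" for i in range(n)])
        return expr, names

    def test_tracking_probe_gets_minimal_p_and_is_core(self):
        expr, names = self._matrix()
        res = ge.core_membership(expr, names)
        assert res["core"].all()
        assert res["p"].min() == pytest.approx(1 / 121)

    def test_uncorrelated_probe_excluded(self):
        expr, names = self._matrix()
        rng = np.random.default_rng(12)
        expr.loc["mod5"] = rng.standard_normal(expr.shape[1])
        res = ge.core_membership(expr, names)
        assert not res.loc["mod5", "core"]

    def test_empirical_p_matches_brute_force_quantile(self):
        expr, names = self._matrix(seed=13)
        res = ge.core_membership(expr, names)
        eig = ge.summary_expression(expr, names)
        null = []
        for probe in expr.index.difference(names):
            null.append(abs(np.corrcoef(expr.loc[probe], eig)[0, 1]))
        null = np.array(null)
        for probe in names:
            r = abs(np.corrcoef(expr.loc[probe], eig)[0, 1])
            assert res.loc[probe, "p"] == pytest.approx(((null >= r).sum() + 1) / (len(null) + 1))

    def test_noise_module_probes_carry_selection_bias(self):
        """The eigengene is fit on the module's own probes, so even pure
        noise probes correlate with it well above the out-of-module null
        (the first-eigenvalue inflation of a white-noise submatrix). The
        membership test is therefore anti-conservative on noise modules;
        this documents the direction and magnitude of that bias."""
        in_r, null_r = [], []
        for seed in range(10):
            expr, names = self._matrix(seed=100 + seed, coupled=False)
            eig = ge.summary_expression(expr, names)
            for probe in names:
                in_r.append(abs(np.corrcoef(expr.loc[probe], eig)[0, 1]))
            for probe in list(expr.index.difference(names))[:20]:
                null_r.append(abs(np.corrcoef(expr.loc[probe], eig)[0, 1]))
        assert np.mean(in_r) > 2 * np.mean(null_r)

    def test_too_few_null_probes_rejected(self):
        rng = np.random.default_rng(14)
        expr = pd.DataFrame(rng.standard_normal((10, 30)),
                            index=[f"p{i}" for i in range(10)])
        with pytest.raises(ValueError, match="out-of-module"):
            ge.core_membership(expr, [f"p{i}" for i in range(8)])
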
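"""Trait concordance, PCA, weighted association, multiple testing, annotation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from loadnet.assoc import (
    TraitAssociation,
    adjust_pvalues,
    annotate_and_filter,
    associate,
    outlier_trim,
    pc_weight,
    term_overrepresentation,
    trait_correlation_matrix,
    trait_pca,
)
from loadnet.containers import TraitTable
from conftest import expr_from_array


def make_traits(arr, names):
    arr = np.asarray(arr, dtype=float)
    return TraitTable(
        pd.DataFrame(
            arr,
            index=[f"S{i:03d}" for i in range(arr.shape[0])],
            columns=names,
        )
    )


class TestTraitCorrelation:
    def test_duplicate_and_negated_columns(self, rng):
        x = rng.normal(size=40)
        T = make_traits(np.c_[x, x, -x], ["a", "b", "c"])
        r = trait_correlation_matrix(T)
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert r.loc["a", "c"] == pytest.approx(-1.0)

    def test_constant_trait_flagged_not_zeroed(self, rng):
        T = make_traits(np.c_[rng.normal(size=20), np.ones(20)], ["a", "k"])
        with pytest.warns(UserWarning, match="constant"):
            r = trait_correlation_matrix(T)
        assert np.isnan(r.loc["a", "k"])

    def test_shared_factor_block_is_concordant(self, small_bundle):
        r = trait_correlation_matrix(small_bundle.traits)
        block = ["CDR", "Braak", "PLQ_Mn", "NTr_Sum", "NPr_Sum"]
        sub = r.loc[block, block].to_numpy()
        assert sub[np.triu_indices_from(sub, 1)].min() > 0


class TestTraitPca:
    def test_identical_traits_concentrate_on_pc1(self, rng):
        x = rng.normal(size=50)
        T = make_traits(np.c_[x, x], ["a", "b"])
        pca = trait_pca(T)
        assert pca.explained_variance.iloc[0] == pytest.approx(2.0)

    def test_scores_reconstruct_standardized_data(self, small_bundle):
        pca = trait_pca(small_bundle.traits)
        df = small_bundle.traits.traits
        z = ((df - df.mean()) / df.std(ddof=1)).to_numpy()
        recon = pca.scores.to_numpy() @ pca.loadings.to_numpy().T
        assert np.abs(recon - z).max() < 1e-10

    def test_loadings_are_orthonormal(self, small_bundle):
        L = trait_pca(small_bundle.traits).loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)

    def test_more_traits_than_samples_flagged(self, rng):
        T = make_traits(rng.normal(size=(4, 6)), list("abcdef"))
        with pytest.warns(UserWarning, match="exceed"):
            trait_pca(T)


class TestPcWeight:
    def test_scale_times_absolute_loading(self, rng):
        T = make_traits(rng.normal(size=(30, 3)), ["a", "b", "c"])
        pca = trait_pca(T)
        w = pc_weight(pca, "a", scale=0.5)
        assert w == pytest.approx(0.5 * abs(pca.loadings.loc["a", "PC2"]))
        assert w >= 0  # sign-flip proof by construction

    def test_unknown_trait_rejected(self, rng):
        T = make_traits(rng.normal(size=(30, 3)), ["a", "b", "c"])
        with pytest.raises(KeyError):
            pc_weight(trait_pca(T), "nope")


class TestAssociate:
    def test_orthogonal_score_gives_null_statistics(self):
        x = np.array([1.0, -1.0] * 4)
        score = pd.Series(
            [1.0, 1.0, -1.0, -1.0] * 2,
            index=[f"S{i:03d}" for i in range(8)],
        )
        X = expr_from_array(x[None, :], transformed=True)
        rec = associate(X, score, weight=0.5)
        assert rec.loc[0, "cor"] == pytest.approx(0.0, abs=1e-12)
        assert rec.loc[0, "p"] == pytest.approx(1.0)
        assert rec.loc[0, "cor_weighted"] == pytest.approx(0.0, abs=1e-12)

    def test_identity_weight_matches_fisher_normal_p(self, rng):
        X = expr_from_array(rng.normal(size=(50, 30)), transformed=True)
        score = pd.Series(rng.normal(size=30), index=X.sample_ids)
        rec = associate(X, score, weight=1.0)
        z = np.sqrt(30 - 3) * np.arctanh(rec["cor"])
        expect = 2 * stats.norm.sf(np.abs(z))
        assert np.allclose(rec["p_weighted"], expect)

    def test_larger_weight_never_increases_weighted_p(self, rng):
        X = expr_from_array(rng.normal(size=(20, 40)), transformed=True)
        score = pd.Series(rng.normal(size=40), index=X.sample_ids)
        p_small = associate(X, score, weight=0.2)["p_weighted"]
        p_big = associate(X, score, weight=0.8)["p_weighted"]
        assert (p_big <= p_small + 1e-15).all()

    def test_perfect_correlation_flagged_with_tiny_p(self):
        x = np.arange(10.0)
        X = expr_from_array(x[None, :], transformed=True)
        score = pd.Series(2 * x + 1, index=X.sample_ids)
        rec = associate(X, score, weight=0.5)
        assert rec.loc[0, "flag_perfect"]
        assert 0 < rec.loc[0, "p"] < 1e-300

    def test_analytic_p_agrees_with_permutation_null(self, rng):
        # one fixed gene/score pair; 10,000 label shuffles
        n = 30
        x = rng.normal(size=n)
        y = 0.45 * x + rng.normal(size=n)
        r_obs = np.corrcoef(x, y)[0, 1]
        t = r_obs * np.sqrt(n - 2) / np.sqrt(1 - r_obs**2)
        p_analytic = 2 * stats.t.sf(abs(t), df=n - 2)
        perm = np.empty(10000)
        for i in range(10000):
            perm[i] = np.corrcoef(x, rng.permutation(y))[0, 1]
        p_perm = (1 + (np.abs(perm) >= abs(r_obs)).sum()) / (1 + 10000)
        mc_sd = np.sqrt(p_analytic * (1 - p_analytic) / 10000)
        assert abs(p_perm - p_analytic) < 4 * mc_sd + 1e-4


class TestOutlierTrim:
    def test_equal_statistics_drop_nothing(self):
        rec = pd.DataFrame({"z": np.ones(10)})
        out, n = outlier_trim(rec)
        assert n == 0 and len(out) == 10

    def test_constructed_outlier_removed(self, rng):
        z = rng.standard_normal(100)
        z[17] = z.mean() + 10 * z.std()
        out, n = outlier_trim(pd.DataFrame({"z": z}))
        assert n >= 1
        assert z[17] not in out["z"].to_numpy()

    def test_reported_count_matches_rows_removed(self, rng):
        rec = pd.DataFrame({"z": rng.standard_normal(500)})
        out, n = outlier_trim(rec)
        assert len(rec) - len(out) == n


class TestAdjustPvalues:
    def test_bonferroni_with_external_m(self):
        assert adjust_pvalues([0.001], "bonferroni", m=100)[0] == pytest.approx(0.1)
        assert adjust_pvalues([1.0], "bonferroni", m=7)[0] == 1.0

    def test_bh_step_up_hand_case(self):
        out = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh", m=4)
        assert np.allclose(out, 0.04)

    def test_bh_matches_statsmodels_for_internal_m(self, rng):
        p = rng.uniform(size=37)
        mine = adjust_pvalues(p, "bh")
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(mine, ref)

    def test_bonferroni_dominates_bh(self, rng):
        p = rng.uniform(size=25)
        assert (
            adjust_pvalues(p, "bonferroni") >= adjust_pvalues(p, "bh") - 1e-15
        ).all()

    def test_bh_monotone_in_sorted_order(self, rng):
        p = np.sort(rng.uniform(size=50))
        q = adjust_pvalues(p, "bh")
        assert (np.diff(q) >= -1e-15).all()

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5], "bh", m=0)
        with pytest.raises(ValueError):
            adjust_pvalues([1.5], "bonferroni")


class TestAnnotation:
    @staticmethod
    def records_for(genes):
        return pd.DataFrame(
            {
                "gene_id": genes,
                "score_id": "PLQ_Mn",
                "p_weighted": 0.01,
            }
        )

    def test_substring_match_retains_and_drops(self):
        ann = {"g1": {"sphingolipid metabolic process"}, "g2": set()}
        out = annotate_and_filter(
            self.records_for(["g1", "g2"]), ann, ["sphingolipid"]
        )
        assert list(out["gene_id"]) == ["g1"]

    def test_twelve_of_twenty_annotated_genes_survive(self):
        genes = [f"g{i:02d}" for i in range(20)]
        ann = {}
        for i, g in enumerate(genes):
            if i < 6:
                ann[g] = {"myelin sheath maintenance"}
            elif i < 12:
                ann[g] = {"sphingolipid biosynthetic process"}
            else:
                ann[g] = {"oxidative phosphorylation"}
        out = annotate_and_filter(
            self.records_for(genes), ann, ["myelin", "sphingolipid"]
        )
        assert out["gene_id"].nunique() == 12

    def test_empty_annotation_warns_and_empties(self):
        with pytest.warns(UserWarning, match="empty annotation"):
            out = annotate_and_filter(self.records_for(["g1"]), {}, ["myelin"])
        assert len(out) == 0


class TestOverrepresentation:
    def test_certain_event_and_depletion(self):
        genes = {f"g{i}" for i in range(10)}
        assert term_overrepresentation(genes, genes, genes) == pytest.approx(1.0)
        bg = {f"g{i}" for i in range(40)}
        hits = {f"g{i}" for i in range(20)}
        term = {f"g{i}" for i in range(20, 40)}
        assert term_overrepresentation(hits, bg, term) > 0.99

    def test_matches_brute_force_enumeration(self):
        # N=12 background, K=5 term genes, n=6 hits, observed overlap k=3
        from math import comb

        N, K, n, k = 12, 5, 6, 3
        p_brute = sum(
            comb(K, i) * comb(N - K, n - i) / comb(N, n)
            for i in range(k, min(K, n) + 1)
        )
        bg = {f"g{i}" for i in range(N)}
        term = {f"g{i}" for i in range(K)}
        hits = {f"g{i}" for i in range(3)} | {f"g{i}" for i in range(5, 8)}
        assert term_overrepresentation(hits, bg, term) == pytest.approx(p_brute)


class TestModelInterface:
    def test_fit_produces_trimmed_corrected_records(self, small_bundle):
        from loadnet.qc import run_qc

        Xq, _ = run_qc(
            small_bundle.expression, threshold_bits=3.0, k_min=5.0, beta=6.0
        )
        res = TraitAssociation(Xq, small_bundle.traits).fit()
        assert {"cor", "p", "z", "p_weighted", "fdr", "p_weighted_bonferroni"} <= set(
            res.records.columns
        )
        assert res.records["p_weighted"].between(0, 1).all()
        assert res.records["fdr"].between(0, 1).all()
        t = res.table()
        assert list(t.columns) == [
            "GENE",
            "P.WEIGHTED",
            "FDR",
            "COR.WEIGHTED",
            "#OF TRAITS",
        ]
        assert (t["#OF TRAITS"] <= 9).all()
        assert "Association screen" in res.summary()
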
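"""GSEA: ranking metric, running-sum ES, permutation null, NES, FDR, GMT IO."""

import numpy as np
import pandas as pd
import pytest

from loadnet.gsea import (
    GeneSetCollection,
    Gsea,
    enrichment_score,
    gsea_fdr,
    normalize_es,
    permutation_null,
    rank_metric_log2_ratio,
    read_gmt,
    write_gmt,
)
from conftest import expr_from_array


def brute_force_es(metrics: dict, members, exponent=1.0):
    """Independent running-sum oracle on an explicit gene -> metric map."""
    ranked = sorted(metrics, key=lambda g: (-metrics[g], g))
    nh = sum(g in members for g in ranked)
    denom_hit = sum(abs(metrics[g]) ** exponent for g in ranked if g in members)
    run, best, path = 0.0, 0.0, []
    for g in ranked:
        if g in members:
            run += (
                abs(metrics[g]) ** exponent / denom_hit
                if denom_hit > 0
                else 1.0 / nh
            )
        else:
            run -= 1.0 / (len(ranked) - nh)
        path.append(run)
        if abs(run) > abs(best):
            best = run
    return best, path


def labelled(n_case, n_ctrl):
    ids = [f"S{i:03d}" for i in range(n_case + n_ctrl)]
    return pd.Series(
        ["case"] * n_case + ["control"] * n_ctrl, index=ids, name="class"
    )


class TestRankMetric:
    def test_doubled_and_equal_class_means(self):
        case = np.full((2, 3), 4.0)
        ctrl = np.full((2, 3), 2.0)
        vals = np.hstack([case, ctrl])
        vals[1] = 2.0
        X = expr_from_array(vals)
        m = rank_metric_log2_ratio(X, labelled(3, 3))
        assert m["G000"] == pytest.approx(1.0)
        assert m["G001"] == pytest.approx(0.0)

    def test_swapping_labels_negates_metric(self, rng):
        X = expr_from_array(rng.lognormal(size=(20, 12)))
        cls = labelled(6, 6)
        swapped = cls.map({"case": "control", "control": "case"})
        m1 = rank_metric_log2_ratio(X, cls)
        m2 = rank_metric_log2_ratio(X, swapped)
        assert np.allclose(
            m1.sort_index().to_numpy(), -m2.sort_index().to_numpy()
        )

    def test_tiny_class_rejected(self, rng):
        X = expr_from_array(rng.lognormal(size=(5, 4)))
        with pytest.raises(ValueError, match="at least 2"):
            rank_metric_log2_ratio(X, labelled(1, 3))


class TestEnrichmentScore:
    def test_single_top_gene_peaks_immediately(self):
        ranked = pd.Series([3.0, 2.0, 1.0, 0.5], index=list("abcd"))
        es, run, hits = enrichment_score(ranked, {"a"})
        assert es == pytest.approx(1.0)
        assert run[0] == pytest.approx(1.0)
        assert hits.tolist() == [0]

    def test_bottom_heavy_set_scores_negative(self):
        ranked = pd.Series([3.0, 2.0, 1.0, -1.0, -2.0], index=list("abcde"))
        es, _, _ = enrichment_score(ranked, {"d", "e"})
        assert es < 0

    def test_matches_brute_force_on_toy_list(self, rng):
        genes = [f"g{i:02d}" for i in range(20)]
        metrics = dict(zip(genes, np.round(rng.normal(size=20), 3)))
        members = set(rng.choice(genes, size=5, replace=False))
        ranked = pd.Series(metrics).sort_values(ascending=False)
        order = np.lexsort((ranked.index, -ranked.to_numpy()))
        ranked = ranked.iloc[order]
        es, run, _ = enrichment_score(ranked, members)
        es_bf, path_bf = brute_force_es(metrics, members)
        assert es == pytest.approx(es_bf, abs=1e-12)
        assert np.allclose(run, path_bf, atol=1e-12)

    def test_label_swap_negates_es_via_oracle(self, rng):
        genes = [f"g{i:02d}" for i in range(15)]
        metrics = dict(zip(genes, rng.normal(size=15)))
        members = set(genes[2:7])
        es_fwd, _ = brute_force_es(metrics, members)
        es_rev, _ = brute_force_es({g: -m for g, m in metrics.items()}, members)
        ranked = pd.Series(metrics).sort_values(ascending=False)
        es, _, _ = enrichment_score(ranked, members)
        assert es == pytest.approx(es_fwd, abs=1e-12)
        # unweighted walk is exactly antisymmetric; |metric| weighting is
        # checked against the oracle on both orientations
        es0_f, _ = brute_force_es(metrics, members, exponent=0.0)
        es0_r, _ = brute_force_es(
            {g: -m for g, m in metrics.items()}, members, exponent=0.0
        )
        assert es0_f == pytest.approx(-es0_r, abs=1e-12)
        assert abs(es_rev) <= 1.0

    def test_unweighted_running_sum_returns_to_zero(self, rng):
        genes = [f"g{i}" for i in range(30)]
        metrics = dict(zip(genes, rng.normal(size=30)))
        _, path = brute_force_es(metrics, set(genes[:6]), exponent=0.0)
        assert path[-1] == pytest.approx(0.0, abs=1e-12)

    def test_es_bounded(self, rng):
        for _ in range(20):
            ranked = pd.Series(
                rng.normal(size=25), index=[f"g{i:02d}" for i in range(25)]
            ).sort_values(ascending=False)
            members = set(rng.choice(ranked.index, size=6, replace=False))
            es, _, _ = enrichment_score(ranked, members)
            assert -1.0 <= es <= 1.0

    def test_disjoint_set_rejected(self):
        ranked = pd.Series([1.0, 0.5], index=["a", "b"])
        with pytest.raises(ValueError, match="no overlap"):
            enrichment_score(ranked, {"zzz"})


class TestPermutationNull:
    def test_seeded_runs_reproduce(self, rng):
        X = expr_from_array(rng.lognormal(size=(40, 16)))
        cls = labelled(8, 8)
        s = set(X.gene_ids[:8])
        n1 = permutation_null(X, cls, s, n_perm=50, seed=9)
        n2 = permutation_null(X, cls, s, n_perm=50, seed=9)
        assert np.array_equal(n1, n2)

    def test_null_es_centers_near_zero_for_decoy(self, rng):
        X = expr_from_array(rng.lognormal(size=(60, 20)))
        cls = labelled(10, 10)
        decoy = set(rng.choice(X.gene_ids, size=15, replace=False))
        null = permutation_null(X, cls, decoy, n_perm=300, seed=1)
        assert abs(null.mean()) < 0.1

    def test_exhausted_permutations_warn(self, rng):
        X = expr_from_array(rng.lognormal(size=(10, 5)))
        cls = labelled(3, 2)
        with pytest.warns(UserWarning, match="with replacement"):
            permutation_null(X, cls, set(X.gene_ids[:3]), n_perm=100, seed=0)


class TestNormalizeEs:
    def test_direct_ratios_and_signs(self):
        null = np.array([0.3, 0.3, 0.3, -0.2, -0.4])
        nes, _ = normalize_es(0.6, null)
        assert nes == pytest.approx(2.0)
        nes_neg, _ = normalize_es(-0.6, np.array([0.5, -0.3, -0.3]))
        assert nes_neg == pytest.approx(-2.0)
        nes_unit, _ = normalize_es(0.3, np.array([0.3, 0.3]))
        assert nes_unit == pytest.approx(1.0)

    def test_no_same_sign_null_flags(self):
        with pytest.warns(UserWarning, match="undefined"):
            nes, p = normalize_es(0.5, np.array([-0.1, -0.2]))
        assert np.isnan(nes) and p == 1.0

    def test_nominal_p_is_add_one_corrected(self):
        null = np.array([0.1, 0.2, 0.7, 0.9])
        _, p = normalize_es(0.6, null)
        assert p == pytest.approx((1 + 2) / (1 + 4))


class TestGseaFdr:
    def test_identical_distributions_give_high_q(self, rng):
        obs = pd.Series({f"s{i}": x for i, x in enumerate(rng.normal(size=40))})
        perm = {k: rng.normal(size=200) for k in obs.index}
        q = gsea_fdr(obs, perm)
        typical = q[np.abs(obs) < 1.0]
        assert typical.median() > 0.5
        assert q.between(0, 1).all()

    def test_clear_outlier_has_small_q(self, rng):
        obs = pd.Series({"signal": 5.0, "null1": 0.5, "null2": -0.4})
        perm = {k: rng.normal(scale=0.5, size=300) for k in obs.index}
        q = gsea_fdr(obs, perm)
        assert q["signal"] < 0.05

    def test_monotone_with_extremity(self, rng):
        obs = pd.Series({f"s{i}": x for i, x in enumerate(rng.normal(size=20))})
        perm = {k: rng.normal(size=100) for k in obs.index}
        q = gsea_fdr(obs, perm)
        pos = obs[obs > 0].sort_values()
        qs = q[pos.index].to_numpy()
        assert (np.diff(qs) <= 1e-12).all()


class TestGmtIo:
    def test_three_line_file_parses(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text(
            "A\tdesc\tg1\tg2\tg3\tg4\tg5\n"
            "B\tdesc\tg1\tg6\tg7\tg8\tg9\tg10\n"
            "C\tdesc\tg2\tg3\tg4\tg6\tg7\n"
        )
        coll = read_gmt(p)
        assert set(coll.sets) == {"A", "B", "C"}
        assert coll.sets["B"] == ["g1", "g6", "g7", "g8", "g9", "g10"]

    def test_undersized_set_dropped_with_report(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("tiny\td\tg1\tg2\nok\td\tg1\tg2\tg3\tg4\tg5\n")
        coll = read_gmt(p, min_size=5)
        assert "tiny" in coll.dropped and coll.dropped["tiny"] == 2
        assert set(coll.sets) == {"ok"}

    def test_duplicate_names_and_empty_file_rejected(self, tmp_path):
        dup = tmp_path / "dup.gmt"
        dup.write_text("A\td\tg1\tg2\tg3\tg4\tg5\nA\td\tg1\tg2\tg3\tg4\tg5\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_gmt(dup)
        empty = tmp_path / "empty.gmt"
        empty.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_gmt(empty)

    def test_write_read_roundtrip(self, tmp_path):
        sets = {"A": ["g1", "g2", "g3", "g4", "g5"], "B": list("vwxyz")}
        p = tmp_path / "rt.gmt"
        write_gmt(GeneSetCollection(sets=sets), p)
        assert read_gmt(p).sets == sets


class TestModelInterface:
    def test_planted_class_linked_set_is_detected(self, small_bundle):
        t = small_bundle.truth
        sets = {
            "planted": t.module_genes(1),
            "other": t.module_genes(2),
            "decoy": sorted(t.module_labels.index[t.module_labels == 0][:80]),
        }
        res = Gsea(small_bundle.expression, t.class_labels, sets).fit(
            n_perm=300, seed=4
        )
        tbl = res.table().set_index("set")
        assert tbl.loc["planted", "nominal_p"] < 0.05
        assert tbl.loc["planted", "ES"] > 0
        assert np.sign(tbl["NES"]).equals(np.sign(tbl["ES"]))
        assert "GSEA" in res.summary()

    def test_profile_exports_are_consistent(self, small_bundle, tmp_path):
        t = small_bundle.truth
        res = Gsea(
            small_bundle.expression,
            t.class_labels,
            {"planted": t.module_genes(1), "other": t.module_genes(2)},
        ).fit(n_perm=100, seed=5)
        res.running_sum_tsv("planted", tmp_path / "run.tsv")
        prof = pd.read_csv(tmp_path / "run.tsv", sep="\t")
        assert len(prof) == small_bundle.expression.n_genes
        assert prof["hit"].sum() == res.results["planted"].size
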
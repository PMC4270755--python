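"""Expression normalization, KS/EASE enrichment, subgroup selection, hubs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from exopair.models import ValidationError
from exopair.enrichment import (
    GeneSetCollection,
    compare_mt_wt_expression,
    differential_go_selection,
    ease_score,
    ease_table,
    enrichment_matrix,
    interaction_degree,
    ks_enrichment,
    normalize_expression,
    quantile_normalize,
    select_mutated_go_terms,
)

from oracles import fisher_greater_oracle, ks_one_sided_oracle


class TestNormalization:
    def test_two_sample_worked_example(self):
        # already-logged values [1,2,3] and [4,5,6]: sorted row means are
        # 2.5/3.5/4.5, and centering brings both samples to [-1, 0, 1]
        raw = pd.DataFrame({"s1": 2.0 ** np.array([1, 2, 3]),
                            "s2": 2.0 ** np.array([4, 5, 6])},
                           index=list("abc"))
        out = normalize_expression(raw)
        assert np.allclose(out["s1"], [-1, 0, 1])
        assert np.allclose(out["s2"], [-1, 0, 1])

    def test_identical_samples_are_fixed_point(self):
        df = pd.DataFrame({"s1": [3.0, 1.0, 2.0], "s2": [3.0, 1.0, 2.0]})
        assert np.allclose(quantile_normalize(df), df)

    def test_all_samples_share_sorted_vector(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(200, 6)))
        out = quantile_normalize(df)
        ref = np.sort(out[0].to_numpy())
        for c in out.columns:
            assert np.allclose(np.sort(out[c].to_numpy()), ref)

    def test_quantile_normalization_idempotent(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(150, 5)))
        once = quantile_normalize(df)
        assert np.allclose(quantile_normalize(once), once, atol=1e-9)

    def test_ties_receive_mean_of_tied_quantiles(self):
        df = pd.DataFrame({"s1": [1.0, 1.0, 5.0], "s2": [2.0, 4.0, 6.0]})
        out = quantile_normalize(df)
        ref = np.sort((np.sort(df.s1) + np.sort(df.s2)) / 2)
        assert out.s1[0] == out.s1[1] == pytest.approx((ref[0] + ref[1]) / 2)

    def test_centered_sample_means_are_zero(self):
        rng = np.random.default_rng(2)
        raw = pd.DataFrame(rng.uniform(1, 100, size=(80, 4)))
        out = normalize_expression(raw)
        assert np.allclose(out.mean(axis=0), 0.0, atol=1e-9)

    def test_nonpositive_intensity_named(self):
        raw = pd.DataFrame({"s1": [1.0, -2.0]}, index=["g1", "g2"])
        with pytest.raises(ValidationError, match="g2"):
            normalize_expression(raw)


class TestKsEnrichment:
    def test_whole_profile_set_is_flagged_zero(self):
        profile = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        r = ks_enrichment(profile, ["a", "b", "c"])
        assert r.flagged and r.score == 0.0

    def test_disjoint_set_is_flagged(self):
        profile = pd.Series([1.0, 2.0], index=list("ab"))
        assert ks_enrichment(profile, ["z"]).flagged

    def test_top_ranked_set_matches_enumeration_oracle(self):
        profile = pd.Series(np.arange(10, dtype=float) + 1,
                            index=[f"g{i}" for i in range(10)])
        members = ["g7", "g8", "g9"]  # the three largest values
        r = ks_enrichment(profile, members)
        inside = profile[members].to_numpy()
        outside = profile.drop(members).to_numpy()
        d_up, p_up = ks_one_sided_oracle(inside, outside, "larger")
        d_dn, p_dn = ks_one_sided_oracle(inside, outside, "smaller")
        assert r.p_plus == pytest.approx(p_up, abs=1e-12)
        assert r.p_minus == pytest.approx(p_dn, abs=1e-12)
        assert r.d_plus == pytest.approx(d_up) and r.d_minus == pytest.approx(d_dn)
        assert r.score == pytest.approx(-np.log10(p_up))

    def test_sign_flips_when_profile_negated(self):
        rng = np.random.default_rng(5)
        profile = pd.Series(rng.normal(size=40),
                            index=[f"g{i}" for i in range(40)])
        members = [f"g{i}" for i in range(8)]
        a = ks_enrichment(profile, members)
        b = ks_enrichment(-profile, members)
        assert a.score == pytest.approx(-b.score)

    def test_planted_shift_raises_subgroup_scores(self, small_bundle):
        scores = enrichment_matrix(small_bundle.expression, small_bundle.gene_sets)
        grades = small_bundle.cohort.grades
        adv = [p for p, g in grades.items() if g == "advanced"]
        early = [p for p, g in grades.items() if g == "early"]
        planted = small_bundle.config.go_effect[0][0]
        assert scores.loc[planted, adv].mean() > scores.loc[planted, early].mean() + 2


class TestEase:
    def test_overlap_of_zero_or_one_gives_p_one(self):
        assert ease_score(100, 50, 0, 20000) == 1.0
        assert ease_score(100, 50, 1, 20000) == 1.0

    def test_matches_decremented_tail_oracle(self):
        p = ease_score(280, 500, 15, 20000)
        oracle = fisher_greater_oracle(14, 280 - 15, 500 - 15, 20000 - 280 - 500 + 15)
        assert p == pytest.approx(oracle, abs=1e-12)
        assert 0 < p < 1

    def test_monotone_non_increasing_in_overlap(self):
        prev = 1.0
        for k in range(2, 16):
            p = ease_score(280, 500, k, 20000)
            assert p <= prev + 1e-15
            prev = p

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValidationError):
            ease_score(10, 5, 7, 1000)

    def test_table_format(self):
        collection = GeneSetCollection(sets={
            "cytoskeleton organization": tuple(f"g{i}" for i in range(30)),
            "cell adhesion": tuple(f"g{i}" for i in range(25, 60)),
        })
        table = ease_table([f"g{i}" for i in range(12)], collection, background=500)
        assert list(table.columns)[:4] == ["term", "set_size", "gene_count", "ease_p"]
        row = table[table.term == "cytoskeleton organization"].iloc[0]
        assert row.gene_count == 12


class TestSelectMutatedTerms:
    def test_no_mutations_select_nothing(self):
        coll = GeneSetCollection(sets={"S1": ("a", "b")})
        selected, hits = select_mutated_go_terms(coll, [])
        assert len(selected) == 0 and hits == {}

    def test_full_coverage_selects_everything(self):
        coll = GeneSetCollection(sets={"S1": ("a", "b"), "S2": ("b", "c")})
        selected, hits = select_mutated_go_terms(coll, ["b"])
        assert set(selected.sets) == {"S1", "S2"}
        assert hits["S1"] == ("b",)

    def test_matches_membership_scan(self, small_bundle):
        mutated = set(small_bundle.cohort.truth.gene[:40])
        selected, hits = select_mutated_go_terms(small_bundle.gene_sets, mutated)
        for name, genes in small_bundle.gene_sets.sets.items():
            assert (name in selected.sets) == bool(mutated & set(genes))


class TestMtWt:
    def test_copied_values_give_t_zero_p_one(self):
        expr = pd.DataFrame({"P1": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]},
                            index=[f"g{i}" for i in range(6)])
        r = compare_mt_wt_expression(expr, {"P1": {"g0", "g1", "g2"}})
        assert r.statistic == pytest.approx(0.0)
        assert r.pvalue == pytest.approx(1.0)

    def test_null_calibration_uniform(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(300)]
        pvals = []
        for _ in range(150):
            expr = pd.DataFrame(rng.normal(size=(300, 4)), index=genes,
                                columns=list("ABCD"))
            mutated = {c: set(rng.choice(genes, 25, replace=False))
                       for c in "ABCD"}
            pvals.append(compare_mt_wt_expression(expr, mutated).pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_empty_side_rejected(self):
        expr = pd.DataFrame({"P1": [1.0, 2.0]}, index=["g0", "g1"])
        with pytest.raises(ValidationError):
            compare_mt_wt_expression(expr, {"P1": set()})


class TestDifferentialSelection:
    GRADES = {f"P{i}": ("early" if i < 4 else "advanced") for i in range(8)}

    def test_identical_groups_select_nothing(self):
        rng = np.random.default_rng(0)
        row = rng.normal(size=4)
        scores = pd.DataFrame([np.concatenate([row, row])], index=["T1"],
                              columns=list(self.GRADES))
        table, genes = differential_go_selection(scores, self.GRADES)
        assert not table.selected.any() and genes == []

    def test_vacuous_thresholds_select_everything(self):
        rng = np.random.default_rng(1)
        scores = pd.DataFrame(rng.normal(size=(6, 8)),
                              index=[f"T{i}" for i in range(6)],
                              columns=list(self.GRADES))
        table, _ = differential_go_selection(scores, self.GRADES,
                                             alpha=1.0, fold=1.0)
        assert table.selected.all()

    def test_constant_tied_term_dropped(self):
        scores = pd.DataFrame([[2.0] * 8], index=["T1"], columns=list(self.GRADES))
        table, _ = differential_go_selection(scores, self.GRADES)
        assert table.loc["T1", "pvalue"] == 1.0
        assert not table.loc["T1", "selected"]

    def test_signed_diff_mode(self):
        scores = pd.DataFrame(
            [[0.0, 0.1, -0.1, 0.0, 5.0, 5.2, 4.9, 5.1]],
            index=["T1"], columns=list(self.GRADES))
        table, _ = differential_go_selection(scores, self.GRADES,
                                             fold_mode="signed_diff", fold=2.0)
        assert table.loc["T1", "selected"]
        with pytest.raises(ValidationError):
            differential_go_selection(scores, self.GRADES, fold_mode="bogus")

    def test_hits_propagate_to_selected_genes(self):
        scores = pd.DataFrame(
            [[0.0, 0.1, -0.1, 0.0, 5.0, 5.2, 4.9, 5.1],
             [0.0, 0.1, -0.1, 0.0, 0.1, 0.0, -0.1, 0.1]],
            index=["T1", "T2"], columns=list(self.GRADES))
        table, genes = differential_go_selection(
            scores, self.GRADES, hits={"T1": ("CTNNB1",), "T2": ("TP53",)})
        assert table.loc["T1", "selected"] and not table.loc["T2", "selected"]
        assert genes == ["CTNNB1"]


class TestInteractionDegree:
    def test_star_graph(self):
        genes = ["hub", "a", "b", "c", "d"]
        edges = [("hub", g) for g in "abcd"]
        table = interaction_degree(genes, edges)
        assert table.iloc[0].gene == "hub" and table.iloc[0].degree == 4
        assert (table.degree.iloc[1:] == 1).all()

    def test_empty_edge_list_all_zero(self):
        table = interaction_degree(["a", "b"], [])
        assert (table.degree == 0).all()
        assert list(table.gene) == ["a", "b"]  # lexicographic ties

    def test_self_loops_and_duplicates_handled(self):
        with pytest.warns(UserWarning):
            table = interaction_degree(["a", "b"], [("a", "a"), ("a", "b"),
                                                    ("a", "b")])
        assert table[table.gene == "a"].degree.iloc[0] == 1

    def test_matches_adjacency_recount(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(30)]
        edges = {tuple(sorted(rng.choice(genes, 2, replace=False)))
                 for _ in range(120)}
        table = interaction_degree(genes, sorted(edges))
        for g in genes:
            expected = sum(1 for e in edges if g in e)
            assert table[table.gene == g].degree.iloc[0] == expected


class TestGeneSetCollection:
    def test_min_size_filter_is_strict(self):
        coll = GeneSetCollection(sets={
            "small": tuple(f"g{i}" for i in range(10)),
            "big": tuple(f"g{i}" for i in range(11)),
        })
        kept = coll.filter_min_size(10)
        assert set(kept.sets) == {"big"}

    def test_duplicates_rejected(self):
        with pytest.raises(ValidationError):
            GeneSetCollection(sets={"S": ("a", "a")})
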
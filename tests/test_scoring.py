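import math

import numpy as np
import pytest

from helpers import pair_score_brute, score_table_brute
from phenomatch.corpus import AnnotationCorpus
from phenomatch.ontology import TermNode, Ontology
from phenomatch.scoring import (
    PairScorer,
    ScoringConfig,
    best_matches,
    combine_directions,
    drug_burden_weights,
    drug_to_gene_similarity,
    gene_to_drug_similarity,
    score_all_pairs,
    term_pair_score,
)
from phenomatch.synthetic import SimConfig, generate_study

from conftest import TOY_DRUG_ANN, TOY_GENE_ANN, TOY_PARENTS


@pytest.fixture()
def toy_scorer(toy_ontology, toy_drug_corpus, toy_gene_corpus) -> PairScorer:
    return PairScorer(toy_ontology, toy_drug_corpus, toy_gene_corpus)


class TestTermPairScore:
    def test_universal_term_scores_zero(self, toy_ontology):
        drugs = AnnotationCorpus(
            {"D1": {"A1a"}, "D2": {"A1a"}}, entity_class="drug"
        )
        genes = AnnotationCorpus(
            {"G1": {"A1a"}, "G2": {"A1a"}}, entity_class="gene"
        )
        tps = term_pair_score(toy_ontology, drugs, genes, "A1a", "A1a")
        assert tps.s == 0.0  # f = 0 on both sides

    def test_root_only_common_ancestor_scores_zero(self, toy_scorer):
        tps = toy_scorer.term_pair_score("A1a", "B1a")
        assert tps.mica.term_id == "R"
        assert tps.s == 0.0

    def test_identical_rare_leaf_matches_hand_computation(self, toy_scorer):
        # A1a on 2/4 drugs and 2/3 genes; identity co-occurrence takes the
        # corpus supremum -ln(1/(n+1))
        tps = toy_scorer.term_pair_score("A1a", "A1a")
        drug_prod = math.log(4 / 2) * math.log(5)
        gene_prod = math.log(3 / 2) * math.log(4)
        assert tps.mica.ic_value == 1.0
        assert tps.drug_side_product == pytest.approx(drug_prod)
        assert tps.gene_side_product == pytest.approx(gene_prod)
        assert tps.s == pytest.approx(min(drug_prod, gene_prod))

    def test_matches_brute_force_on_all_toy_pairs(self, toy_scorer):
        for se in sorted({t for ts in TOY_DRUG_ANN.values() for t in ts}):
            for trait in sorted({t for ts in TOY_GENE_ANN.values() for t in ts}):
                expected = pair_score_brute(
                    TOY_PARENTS, TOY_DRUG_ANN, TOY_GENE_ANN, se, trait
                )
                assert toy_scorer.score(se, trait) == pytest.approx(expected)

    def test_unannotated_term_scores_zero_not_error(self, toy_scorer):
        # "A1" is in the ontology but annotates no drug
        assert toy_scorer.term_pair_score("A1", "A1a").s == 0.0


class TestBestMatches:
    def test_rows_equal_exhaustive_maxima(self, toy_scorer):
        anchors = sorted(TOY_DRUG_ANN["D4"])  # 3 side effects
        partners = sorted(TOY_GENE_ANN["G3"])
        rows = best_matches(anchors, partners, toy_scorer, anchor_side="drug")
        assert len(rows) == 3
        by_anchor = {r.anchor_term: r for r in rows}
        for a in anchors:
            want = max(toy_scorer.score(a, p) for p in partners)
            assert by_anchor[a].best_score == pytest.approx(want)
        scores = [r.best_score for r in rows]
        assert scores == sorted(scores, reverse=True)

    def test_identical_profiles_self_match_when_maximal(self, toy_scorer):
        prof = sorted(TOY_GENE_ANN["G1"])
        rows = best_matches(prof, prof, toy_scorer, anchor_side="gene")
        for r in rows:
            assert r.best_score >= max(
                toy_scorer.score(r.anchor_term, p) for p in prof
            ) - 1e-12

    def test_single_term_profiles(self, toy_scorer):
        rows = best_matches(["A1a"], ["A1b"], toy_scorer, anchor_side="drug")
        assert len(rows) == 1
        assert rows[0].best_score == pytest.approx(toy_scorer.score("A1a", "A1b"))

    def test_empty_profile_rejected(self, toy_scorer):
        with pytest.raises(ValueError):
            best_matches([], ["A1a"], toy_scorer)


class TestDirectionalSimilarity:
    def test_gene_direction_is_mean_over_all_traits(self, toy_scorer):
        traits = sorted(TOY_GENE_ANN["G3"])
        ses = sorted(TOY_DRUG_ANN["D4"])
        got = gene_to_drug_similarity(traits, ses, toy_scorer)
        want = np.mean([max(toy_scorer.score(se, t) for se in ses) for t in traits])
        assert got == pytest.approx(want)

    def test_drug_direction_below_k_uses_all_side_effects(self, toy_scorer):
        ses = sorted(TOY_DRUG_ANN["D4"])
        traits = sorted(TOY_GENE_ANN["G3"])
        mean_k, values, terms = drug_to_gene_similarity(ses, traits, toy_scorer, top_k=20)
        assert len(values) == len(ses)
        assert set(terms) == set(ses)
        mean_all, _, _ = drug_to_gene_similarity(ses, traits, toy_scorer, top_k=None)
        assert mean_k == pytest.approx(mean_all)

    def test_top_k_one_returns_single_maximum(self, toy_scorer):
        ses = sorted(TOY_DRUG_ANN["D4"])
        traits = sorted(TOY_GENE_ANN["G3"])
        mean1, values, _ = drug_to_gene_similarity(ses, traits, toy_scorer, top_k=1)
        best = max(max(toy_scorer.score(se, t) for t in traits) for se in ses)
        assert values == [pytest.approx(best)]
        assert mean1 == pytest.approx(best)

    def test_cutoff_excludes_zero_scoring_noise(self):
        # drug: 10 side effects matching the gene + 20 unrelated noise terms;
        # with top_k=20 the mean covers the 10 positives and 10 zeros and
        # beats the uncorrected 30-term mean
        study = generate_study(
            SimConfig(
                seed=3,
                branching=4,
                n_drugs=8,
                n_genes=8,
                traits_per_gene=(10, 10),
                targets_per_drug=(1, 1),
                copy_fraction=1.0,
                sibling_swap_prob=0.0,
                total_side_effects=30,
            )
        )
        scorer = PairScorer(study.ontology, study.drug_corpus, study.gene_corpus)
        d, g = sorted(study.truth.planted_pairs)[0]
        ses = sorted(study.drug_corpus.profile(d))
        traits = sorted(study.gene_corpus.profile(g))
        mean20, v20, _ = drug_to_gene_similarity(ses, traits, scorer, top_k=20)
        mean_all, v_all, _ = drug_to_gene_similarity(ses, traits, scorer, top_k=None)
        assert len(v20) == 20 and len(v_all) == 30
        assert mean20 > mean_all


def test_combine_directions_modes():
    gene_vals = [0.5, 0.1, 0.3]
    drug_vals = [1.0, 0.0]
    pooled = combine_directions(gene_vals, drug_vals, "pooled")
    momo = combine_directions(gene_vals, drug_vals, "mean_of_means")
    assert pooled == pytest.approx(sum(gene_vals + drug_vals) / 5)
    assert momo == pytest.approx((np.mean(gene_vals) + np.mean(drug_vals)) / 2)
    same = [0.2, 0.4]
    assert combine_directions(same, same, "pooled") == pytest.approx(
        combine_directions(same, same, "mean_of_means")
    )
    assert combine_directions([0.0], [0.0, 0.0], "pooled") == 0.0


class TestBurdenWeights:
    @staticmethod
    def _corpus_with_counts(counts):
        leaves = [f"t{i}" for i in range(max(counts))]
        return AnnotationCorpus(
            {f"D{i}": set(leaves[:c]) for i, c in enumerate(counts)},
            entity_class="drug",
        )

    def test_low_medium_high_bins(self):
        corpus = self._corpus_with_counts([5, 50, 500])
        w = drug_burden_weights(corpus)
        assert [w["D0"], w["D1"], w["D2"]] == [1.0, 0.66, 0.33]

    def test_equal_counts_all_low(self):
        corpus = self._corpus_with_counts([7, 7, 7, 7])
        assert set(drug_burden_weights(corpus).values()) == {1.0}

    def test_six_drugs_match_quantile_oracle(self):
        counts = [1, 2, 3, 4, 5, 6]
        corpus = self._corpus_with_counts(counts)
        w = drug_burden_weights(corpus)
        q33, q66 = np.quantile(counts, [0.33, 0.66])
        for i, c in enumerate(counts):
            expected = 1.0 if c <= q33 else 0.66 if c <= q66 else 0.33
            assert w[f"D{i}"] == expected


class TestScoreAllPairs:
    def test_matches_quadruple_loop_reference(self, toy_ontology):
        table = score_all_pairs(
            toy_ontology,
            AnnotationCorpus(TOY_DRUG_ANN, entity_class="drug"),
            AnnotationCorpus(TOY_GENE_ANN, entity_class="gene"),
        )
        ref = score_table_brute(TOY_PARENTS, TOY_DRUG_ANN, TOY_GENE_ANN)
        assert len(table) == len(ref)
        for row in table.itertuples():
            want = ref[(row.drug_id, row.gene_id)]
            for col in ("raw", "gene_scale", "burden_weight", "scaled", "normalized"):
                assert getattr(row, col) == pytest.approx(want[col], rel=1e-12)

    def test_reference_agreement_on_synthetic_instance(self):
        study = generate_study(
            SimConfig(seed=5, n_drugs=8, n_genes=9, traits_per_gene=(2, 4))
        )
        drug_ann = {d: set(ts) for d, ts in study.drug_corpus.annotations.items()}
        gene_ann = {g: set(ts) for g, ts in study.gene_corpus.annotations.items()}
        parents = {t: set(n.parent_ids) for t, n in study.ontology.terms.items()}
        table = score_all_pairs(study.ontology, study.drug_corpus, study.gene_corpus)
        ref = score_table_brute(parents, drug_ann, gene_ann)
        for row in table.itertuples():
            assert row.scaled == pytest.approx(
                ref[(row.drug_id, row.gene_id)]["scaled"], rel=1e-12, abs=1e-15
            )

    def test_single_trait_gene_scales_to_zero(self, toy_ontology):
        drugs = AnnotationCorpus(TOY_DRUG_ANN, entity_class="drug")
        genes = AnnotationCorpus(
        {"G1": {"A1a"}, "G2": {"A1b", "B1a"}}, entity_class="gene"
        )
        table = score_all_pairs(toy_ontology, drugs, genes)
        g1 = table[table.gene_id == "G1"]
        assert (g1.gene_scale == 0.0).all()
        assert (g1.scaled == 0.0).all()
        retained = score_all_pairs(
            toy_ontology, drugs, genes, ScoringConfig(gene_scale_mode="ln_n_plus_1")
        )
        assert (retained[retained.gene_id == "G1"].gene_scale > 0).all()

    def test_argmax_rows_have_normalized_one(self, toy_ontology, toy_drug_corpus, toy_gene_corpus):
        table = score_all_pairs(toy_ontology, toy_drug_corpus, toy_gene_corpus)
        top = table[table.normalized == 1.0]
        assert not top.empty
        assert (top.scaled == table.scaled.max()).all()

    def test_normalization_scale_invariance(self, toy_ontology, toy_drug_corpus, toy_gene_corpus):
        table = score_all_pairs(toy_ontology, toy_drug_corpus, toy_gene_corpus)
        rescaled = table.scaled * 7.3
        assert np.allclose(rescaled / rescaled.max(), table.normalized)

    def test_row_order_deterministic(self, toy_ontology, toy_drug_corpus, toy_gene_corpus):
        table = score_all_pairs(toy_ontology, toy_drug_corpus, toy_gene_corpus)
        keys = list(zip(table.drug_id, table.gene_id))
        assert keys == sorted(keys)


def test_adding_zero_noise_cannot_raise_drug_direction_mean():
    """With >= top_k positive matches, a side effect scoring 0 against the
    gene never increases the drug-direction mean."""
    study = generate_study(
        SimConfig(
            seed=3,
            branching=4,
            n_drugs=6,
            n_genes=6,
            traits_per_gene=(8, 8),
            copy_fraction=1.0,
            sibling_swap_prob=0.0,
            total_side_effects=12,
        )
    )
    scorer = PairScorer(study.ontology, study.drug_corpus, study.gene_corpus)
    d, g = sorted(study.truth.planted_pairs)[0]
    ses = sorted(study.drug_corpus.profile(d))
    traits = sorted(study.gene_corpus.profile(g))
    k = 5
    base, _, _ = drug_to_gene_similarity(ses, traits, scorer, top_k=k)
    # a term that only shares the root with every trait scores exactly 0
    zero_term = next(
        t
        for t in sorted(study.ontology.leaves)
        if all(scorer.score(t, tr) == 0.0 for tr in traits)
    )
    augmented, _, _ = drug_to_gene_similarity(
        sorted(set(ses) | {zero_term}), traits, scorer, top_k=k
    )
    assert augmented <= base + 1e-12
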
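"""Table intersection, lexicon filtering, item ranking and seed-term queries."""

from __future__ import annotations

import pytest

from ddslice.cooc import DescriptorPair, FrequencyTable, count_frequencies
from ddslice.corpus_io import Corpus, HerbLexicon, corpus_from_pairs
from ddslice.crosscorpus import (
    CombinePolicy,
    cross_query,
    filter_by_lexicon,
    intersect_tables,
    rank_items,
)
from ddslice.synthetic import GeneratorConfig, generate_corpus

HERBS = HerbLexicon(("Angelica", "Salvia", "Safflower", "Astragalus"))


def table(mapping, label=""):
    return FrequencyTable.from_mapping(mapping, label)


class TestIntersectTables:
    def test_disjoint_tables_intersect_to_empty(self):
        left = table({("A", "B"): 2}, "L")
        right = table({("C", "D"): 3}, "R")
        assert len(intersect_tables(left, right)) == 0

    def test_self_intersection_under_min_is_identity(self):
        t = table({("A", "B"): 2, ("C", "D"): 7}, "L")
        assert intersect_tables(t, t, "min").entries == t.entries

    @pytest.mark.parametrize(
        "policy,expected", [("min", 7), ("sum", 26), ("left", 7), ("right", 19)]
    )
    def test_policies_combine_shared_pair(self, policy, expected):
        left = table({("X", "Y"): 7, ("A", "B"): 1}, "L")
        right = table({("X", "Y"): 19, ("C", "D"): 1}, "R")
        result = intersect_tables(left, right, policy)
        assert result.entries == {DescriptorPair("X", "Y"): expected}

    def test_commutative_up_to_label(self):
        left = table({("X", "Y"): 7, ("A", "B"): 2}, "L")
        right = table({("X", "Y"): 19, ("A", "B"): 5}, "R")
        for policy in ("min", "sum"):
            assert (
                intersect_tables(left, right, policy).entries
                == intersect_tables(right, left, policy).entries
            )

    def test_label_concatenated(self):
        left = table({("X", "Y"): 1}, "CHD")
        right = table({("X", "Y"): 1}, "RA")
        assert intersect_tables(left, right).source_label == "CHD_RA"

    def test_size_bounded_by_smaller_table(self):
        a, _ = generate_corpus(GeneratorConfig(n_records=60, vocab_size=20, seed=1))
        b, _ = generate_corpus(GeneratorConfig(n_records=60, vocab_size=20, seed=2))
        ta, tb = count_frequencies(a), count_frequencies(b)
        assert len(intersect_tables(ta, tb)) <= min(len(ta), len(tb))


class TestFilterByLexicon:
    def test_mode_both_keeps_herb_herb_pairs(self):
        t = table(
            {
                ("Angelica", "Salvia"): 4,
                ("Angelica", "Safflower"): 5,
                ("Angelica", "Inflammation"): 9,
                ("T1", "T2"): 3,
            }
        )
        result = filter_by_lexicon(t, HERBS, "both")
        assert result.pairs() == {
            DescriptorPair("Angelica", "Salvia"),
            DescriptorPair("Angelica", "Safflower"),
        }

    def test_mode_either_keeps_herb_concept_links(self):
        t = table({("Angelica", "Inflammation"): 9, ("T1", "T2"): 3})
        result = filter_by_lexicon(t, HERBS, "either")
        assert result.pairs() == {DescriptorPair("Angelica", "Inflammation")}

    def test_both_subset_of_either(self):
        corpus, _ = generate_corpus(
            GeneratorConfig(
                n_records=100,
                vocab_size=40,
                seed=3,
                planted_pairs=(
                    (("Angelica", "Salvia"), 5),
                    (("Angelica", "T005"), 4),
                ),
            )
        )
        t = count_frequencies(corpus)
        both = filter_by_lexicon(t, HERBS, "both").pairs()
        either = filter_by_lexicon(t, HERBS, "either").pairs()
        assert both <= either

    def test_matching_is_case_insensitive_exact_term(self):
        t = table({("angelica", "SALVIA"): 2, ("Angelicaroot", "Salvia"): 2})
        result = filter_by_lexicon(t, HERBS, "both")
        assert result.pairs() == {DescriptorPair("SALVIA", "angelica")}

    def test_no_lexicon_terms_present_gives_empty(self):
        t = table({("T1", "T2"): 3})
        assert len(filter_by_lexicon(t, HERBS, "both")) == 0

    def test_empty_lexicon_warns_and_returns_empty(self, tmp_path):
        lexicon = HerbLexicon(())
        t = table({("A", "B"): 1})
        with pytest.warns(UserWarning, match="empty lexicon"):
            assert len(filter_by_lexicon(t, lexicon, "both")) == 0

    def test_planted_herb_pairs_recovered_among_noise(self):
        planted = (
            (("Angelica", "Salvia"), 6),
            (("Angelica", "Astragalus"), 5),
            (("Safflower", "Salvia"), 4),
        )
        corpus, truth = generate_corpus(
            GeneratorConfig(n_records=120, vocab_size=60, seed=7, planted_pairs=planted)
        )
        result = filter_by_lexicon(count_frequencies(corpus), HERBS, "both")
        assert result.entries == dict(truth.pair_freqs)


class TestRankItems:
    def test_counts_records_mentioning_each_term(self):
        rows = [("r%d" % i, "Angelica") for i in range(10)]
        rows += [("r%d" % i, "Salvia") for i in range(7)]
        rows += [("r%d" % i, "Filler") for i in range(12)]
        corpus = corpus_from_pairs(rows)
        assert rank_items(corpus, HERBS, 4) == [("Angelica", 10), ("Salvia", 7)]

    def test_empty_corpus_gives_empty_ranking(self):
        assert rank_items(Corpus([]), HERBS, 4) == []

    def test_ties_break_lexicographically(self):
        rows = [("r1", "Salvia"), ("r1", "Angelica")]
        corpus = corpus_from_pairs(rows)
        assert rank_items(corpus, HERBS, 4) == [("Angelica", 1), ("Salvia", 1)]

    def test_counts_bounded_by_corpus_size(self):
        corpus, _ = generate_corpus(
            GeneratorConfig(
                n_records=50,
                vocab_size=20,
                seed=4,
                planted_pairs=((("Angelica", "Salvia"), 9),),
            )
        )
        for _, count in rank_items(corpus, HERBS, 10):
            assert 1 <= count <= len(corpus)

    def test_planted_counts_recovered(self):
        # record-level occurrence of each planted endpoint >= planted frequency
        corpus, truth = generate_corpus(
            GeneratorConfig(
                n_records=80,
                vocab_size=30,
                seed=6,
                planted_pairs=((("Angelica", "Salvia"), 11),),
            )
        )
        ranking = dict(rank_items(corpus, HERBS, 4))
        assert ranking["Angelica"] == 11
        assert ranking["Salvia"] == 11


class TestCrossQuery:
    def test_planted_star_recovered_by_seed_query(self):
        corpus, truth = generate_corpus(
            GeneratorConfig(
                n_records=150,
                vocab_size=200,
                vocabulary_skew=0.8,
                seed=9,
                planted_stars=(("Inflammation", 6, 19),),
            )
        )
        t = count_frequencies(corpus)
        result = cross_query(t, {"Inflammation"}, min_freq=19)
        assert result.entries == truth.star_edge_freqs["Inflammation"]

    def test_whole_vocabulary_seeds_at_min_freq_one_is_identity(self):
        corpus, _ = generate_corpus(GeneratorConfig(n_records=40, vocab_size=15, seed=2))
        t = count_frequencies(corpus)
        assert cross_query(t, t.vocabulary(), 1).entries == t.entries

    def test_absent_seeds_give_empty_result(self):
        t = table({("A", "B"): 3})
        assert len(cross_query(t, {"Zetraxin"}, 1)) == 0

    def test_empty_seed_set_rejected(self):
        with pytest.raises(ValueError):
            cross_query(table({("A", "B"): 1}), set(), 1)


def test_combine_policy_accepts_string_names():
    assert CombinePolicy("min") is CombinePolicy.MIN
    with pytest.raises(ValueError):
        CombinePolicy("median")
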
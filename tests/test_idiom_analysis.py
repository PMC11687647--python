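import pandas as pd
import pytest

from zipfadapt import (
    CompletionEngine,
    IdiomLexicon,
    Label,
    Terminology,
    idiom_proportion_by_seniority,
    is_idiom,
    labels_with_idiom_queries,
    query_case_study,
    top_idioms,
)


@pytest.fixture(scope="module")
def lexicon():
    return IdiomLexicon.from_strings(["hta", "avc", "bpco"])


def enriched(rows):
    """rows: (user, query, label_id, seniority)"""
    return pd.DataFrame(rows, columns=["user", "query", "label_id", "seniority"])


class TestIsIdiom:
    def test_exact_member(self, lexicon):
        assert is_idiom("hta", lexicon)

    def test_full_word_is_not_jargon(self, lexicon):
        assert not is_idiom("hypertension", lexicon)

    def test_case_and_whitespace_variants_normalize(self, lexicon):
        assert is_idiom("HTA ", lexicon)
        assert is_idiom("  Avc", lexicon)

    def test_substring_is_not_membership(self, lexicon):
        assert not is_idiom("htax", lexicon)

    def test_lexicon_rejects_empty_expression(self):
        with pytest.raises(ValueError):
            IdiomLexicon(frozenset({""}))

    def test_lexicon_roundtrip(self, tmp_path, lexicon):
        path = tmp_path / "lex.txt"
        lexicon.save(path)
        assert IdiomLexicon.load(path) == lexicon


class TestLabelsWithIdiomQueries:
    def test_no_idioms_gives_empty_set(self, lexicon):
        df = enriched([("u", "diab", 1, 1), ("u", "doul", 2, 1)])
        assert labels_with_idiom_queries(df, lexicon) == set()

    def test_hand_worked_six_record_log(self, lexicon):
        df = enriched(
            [
                ("u", "hta", 10, 1),
                ("u", "hypertension", 10, 2),
                ("v", "diab", 20, 1),
                ("v", "avc", 30, 1),
                ("w", "doul", 20, 1),
                ("w", "diab", 20, 2),
            ]
        )
        assert labels_with_idiom_queries(df, lexicon) == {10, 30}

    def test_result_is_subset_of_log_labels(self, lexicon):
        df = enriched([("u", "hta", 10, 1), ("u", "x", 20, 1)])
        assert labels_with_idiom_queries(df, lexicon) <= set(df["label_id"])


class TestIdiomProportionBySeniority:
    def test_all_idiomatic_gives_unit_proportion(self, lexicon):
        df = enriched([("u", "hta", 1, s) for s in (1, 2, 3)])
        out = idiom_proportion_by_seniority(df, lexicon, 3)
        assert out["proportion"].tolist() == [1.0, 1.0, 1.0]

    def test_hand_computed_proportions(self, lexicon):
        rows = [("u%d" % i, "hta", 1, 1) for i in range(4)]
        rows += [("u9", "hyper", 1, 1)]
        rows += [("u%d" % i, "hypertension", 1, 2) for i in range(4)]
        rows += [("u9", "hta", 1, 2)]
        out = idiom_proportion_by_seniority(enriched(rows), lexicon, 2)
        assert out.loc[out.level == 1, "proportion"].iloc[0] == pytest.approx(0.8)
        assert out.loc[out.level == 2, "proportion"].iloc[0] == pytest.approx(0.2)
        assert out["n"].tolist() == [5, 5]

    def test_restriction_drops_labels_never_queried_by_idiom(self, lexicon):
        df = enriched([("u", "hta", 1, 1), ("v", "diab", 2, 1), ("v", "diab", 2, 2)])
        out = idiom_proportion_by_seniority(df, lexicon, 2)
        # label 2 never used an idiom, so level 2 has no records at all
        assert out["level"].tolist() == [1]
        assert out["n"].tolist() == [1]

    def test_numerator_and_denominator_recompute_proportion(self, lexicon):
        rows = [("u", "hta", 1, 1), ("v", "hyper", 1, 1), ("w", "hta", 1, 2)]
        out = idiom_proportion_by_seniority(enriched(rows), lexicon, 2)
        assert (out["proportion"] == out["n_idiom"] / out["n"]).all()
        assert out["proportion"].between(0, 1).all()


@pytest.fixture(scope="module")
def hta_setup():
    terminology = Terminology(
        (
            Label(1, "Hypertension artérielle", ("hta",)),
            Label(2, "Hypertension artérielle pulmonaire", ("hta",)),
            Label(3, "Hystérectomie totale abdominale", ("hta",)),
        )
    )
    engine = CompletionEngine(terminology, J=30)
    lexicon = IdiomLexicon.from_strings(["hta"])
    rows = [("u%d" % i, "hta", 2, s) for i, s in enumerate([1, 2, 3, 4, 5])]
    rows += [("v%d" % i, "hypertension a", 2, s) for i, s in enumerate([6, 7, 8, 9])]
    rows += [("w", "hypertension a", 2, 11), ("w", "hypertension a", 2, 12)]
    return enriched(rows), lexicon, engine


class TestQueryCaseStudy:

    def test_single_query_log_is_one_row(self, lexicon):
        df = enriched([("u", "hta", 1, s) for s in (1, 2, 3)])
        out = query_case_study(df, 1, [], lexicon)
        assert len(out) == 1
        assert out.iloc[0]["count"] == 3 and out.iloc[0]["zone"] == "A"

    def test_idiom_switch_across_zones(self, hta_setup):
        df, lexicon, engine = hta_setup
        out = query_case_study(df, 2, [5, 10], lexicon, engine=engine)
        top_a = out[out.zone == "A"].iloc[0]
        assert top_a["query"] == "hta" and top_a["is_idiom"]
        for zone in ("B", "C"):
            top = out[out.zone == zone].iloc[0]
            assert top["query"] == "hypertension a" and not top["is_idiom"]
        # the distinctive query retrieves the label at a better rank
        rank_idiom = out[out["query"] == "hta"]["current_rank"].iloc[0]
        rank_switch = out[out["query"] == "hypertension a"]["current_rank"].iloc[0]
        assert rank_switch < rank_idiom

    def test_zone_counts_conserve_label_records(self, hta_setup):
        df, lexicon, engine = hta_setup
        out = query_case_study(df, 2, [5, 10], lexicon)
        assert out["count"].sum() == len(df[df.label_id == 2])

    def test_unknown_label_rejected(self, lexicon):
        df = enriched([("u", "hta", 1, 1)])
        with pytest.raises(ValueError):
            query_case_study(df, 99, [5], lexicon)

    def test_nonincreasing_boundaries_rejected(self, lexicon):
        df = enriched([("u", "hta", 1, 1)])
        with pytest.raises(ValueError):
            query_case_study(df, 1, [5, 5], lexicon)


class TestTopIdioms:
    def test_empty_idiom_usage(self, lexicon):
        df = enriched([("u", "diab", 1, 1)])
        assert len(top_idioms(df, lexicon)) == 0

    def test_hand_counted_table(self, lexicon):
        df = enriched(
            [
                ("u", "hta", 1, 1),
                ("v", "hta", 1, 1),
                ("w", "hta", 2, 1),
                ("u", "avc", 3, 1),
                ("u", "diab", 4, 1),
            ]
        )
        out = top_idioms(df, lexicon, n=10)
        assert out.iloc[0].tolist() == ["hta", 3, 1]
        assert out.iloc[1].tolist() == ["avc", 1, 3]

    def test_occurrences_bounded_by_log_size(self, lexicon):
        df = enriched([("u", "hta", 1, 1), ("u", "x", 1, 2)])
        assert top_idioms(df, lexicon)["occurrences"].sum() <= len(df)
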
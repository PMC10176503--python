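import numpy as np
import pytest

from hedkit.core import MISSING, is_missing
from hedkit.transform import (
    NA_KEY,
    FreeTextSpec,
    MergeSpec,
    assert_all_numeric,
    encode_binary,
    encode_by_frequency,
    encode_onehot,
    encode_ordinal,
    extract_freetext,
    merge_variables,
    skipgrams,
    tokenise,
)

from conftest import make_table
from _oracles import recoverable


def crohns_scoring_table():
    """Two scorings of the same phenomenon on disjoint record subsets:
    input 1 uses levels 1/2/3, input 2 uses the coarser 1-2/3."""
    input1 = ["1", "2", "3", "1", "2", "3", MISSING, MISSING, MISSING]
    input2 = [MISSING] * 6 + ["1-2", "1-2", "3"]
    return make_table({"score_a": input1, "score_b": input2})


class TestMergeVariables:
    def test_collapsing_levels_is_lossy_for_fine_input(self):
        table = crohns_scoring_table()
        spec = MergeSpec(
            inputs=["score_a", "score_b"],
            value_map={
                ("1", NA_KEY): "1-2", ("2", NA_KEY): "1-2", ("3", NA_KEY): "3",
                (NA_KEY, "1-2"): "1-2", (NA_KEY, "3"): "3",
            },
            name="merged",
        )
        _, assessment = merge_variables(table, spec)
        fine = assessment.per_input["score_a"]
        coarse = assessment.per_input["score_b"]
        assert fine["mic"] < fine["ic"] and not fine["lossless"]
        assert coarse["lossless"]

    def test_intermediate_ordinal_level_is_lossless(self):
        table = crohns_scoring_table()
        spec = MergeSpec(
            inputs=["score_a", "score_b"],
            value_map={
                ("1", NA_KEY): "1", ("2", NA_KEY): "2", ("3", NA_KEY): "3",
                (NA_KEY, "1-2"): "1-2", (NA_KEY, "3"): "3",
            },
            name="merged",
            merged_levels=["1", "1-2", "2", "3"],
        )
        _, assessment = merge_variables(table, spec)
        assert assessment.lossless
        assert assessment.per_input["score_a"]["mic"] == \
               pytest.approx(assessment.per_input["score_a"]["ic"])

    def test_lossless_merge_retains_more_information(self):
        table = crohns_scoring_table()
        lossy_map = {
            ("1", NA_KEY): "1-2", ("2", NA_KEY): "1-2", ("3", NA_KEY): "3",
            (NA_KEY, "1-2"): "1-2", (NA_KEY, "3"): "3",
        }
        fine_map = {
            ("1", NA_KEY): "1", ("2", NA_KEY): "2", ("3", NA_KEY): "3",
            (NA_KEY, "1-2"): "1-2", (NA_KEY, "3"): "3",
        }
        _, lossy = merge_variables(
            table, MergeSpec(["score_a", "score_b"], lossy_map, "m1"))
        _, lossless = merge_variables(
            table, MergeSpec(["score_a", "score_b"], fine_map, "m2"))
        assert lossless.merged_ic > lossy.merged_ic

    def test_self_merge_identity_is_lossless(self):
        table = make_table({"x": ["a", "b", "a"], "y": ["a", "b", "a"]})
        spec = MergeSpec(
            inputs=["x", "y"],
            value_map={("a", "a"): "a", ("b", "b"): "b"},
            name="merged",
        )
        _, assessment = merge_variables(table, spec)
        assert assessment.lossless
        assert assessment.merged_ic == \
               pytest.approx(assessment.per_input["x"]["ic"])

    def test_unmapped_observed_combination_error(self):
        table = make_table({"x": ["a", "b"], "y": ["u", "v"]})
        spec = MergeSpec(inputs=["x", "y"],
                         value_map={("a", "u"): "m"}, name="merged")
        with pytest.raises(ValueError, match="'b'"):
            merge_variables(table, spec)

    def test_merge_loss_soundness_against_recoverability_oracle(self):
        # lossless flag == brute-force recoverability, over random surjective maps
        rng = np.random.default_rng(11)
        agree = 0
        for _ in range(200):
            n = int(rng.integers(4, 30))
            x = [f"x{v}" for v in rng.integers(0, rng.integers(2, 5), size=n)]
            y = [f"y{v}" for v in rng.integers(0, 3, size=n)]
            n_merged = int(rng.integers(1, 5))
            keys = sorted(set(zip(x, y)))
            value_map = {k: f"m{rng.integers(0, n_merged)}" for k in keys}
            table = make_table({"x": x, "y": y})
            _, assessment = merge_variables(
                table, MergeSpec(["x", "y"], value_map, "merged"))
            merged = [value_map[k] for k in zip(x, y)]
            assert assessment.per_input["x"]["lossless"] == recoverable(x, merged)
            assert assessment.per_input["y"]["lossless"] == recoverable(y, merged)
            agree += 1
        assert agree == 200


class TestEncodeOrdinal:
    def test_n_stage_codes(self):
        table = make_table({"n_stage": ["N0", "N1", "N2", MISSING]})
        out, mapping = encode_ordinal(table, "n_stage", ["N0", "N1", "N2"])
        assert list(out.values("n_stage"))[:3] == [1, 2, 3]
        assert is_missing(out.values("n_stage")["p4"])
        assert mapping.decode("n_stage") == {1: "N0", 2: "N1", 3: "N2"}

    def test_uncovered_label_error(self):
        table = make_table({"x": ["low", "mid", "high"]})
        with pytest.raises(ValueError, match="mid"):
            encode_ordinal(table, "x", ["low", "high"])

    def test_round_trip_via_mapping(self):
        labels = ["low", "low", "high", "mid", MISSING]
        table = make_table({"x": labels})
        out, mapping = encode_ordinal(table, "x", ["low", "mid", "high"])
        back = mapping.decode("x")
        decoded = [MISSING if is_missing(v) else back[v]
                   for v in out.values("x")]
        assert all((is_missing(a) and is_missing(b)) or a == b
                   for a, b in zip(decoded, labels))


class TestEncodeBinary:
    def test_yes_no(self):
        table = make_table({"x": ["yes", "no", MISSING]})
        out = encode_binary(table, "x", "yes")
        assert list(out.values("x"))[:2] == [1, 0]
        assert is_missing(out.values("x")["p3"])

    def test_single_label(self):
        table = make_table({"x": ["no", "no"]})
        out = encode_binary(table, "x", "yes")
        assert list(out.values("x")) == [0, 0]

    def test_three_labels_error(self):
        table = make_table({"x": ["a", "b", "c"]})
        with pytest.raises(ValueError):
            encode_binary(table, "x", "a")


class TestEncodeOnehot:
    def test_expansion_with_missing_indicator(self):
        table = make_table({"marital": ["married", "single", MISSING]})
        out = encode_onehot(table, "marital")
        assert "marital" not in out.variables
        assert set(out.variables) == {
            "marital_married", "marital_single", "marital_NA"}
        assert list(out.values("marital_NA")) == [0, 0, 1]
        assert not out.data.map(is_missing).any().any()

    def test_partition_property(self):
        rng = np.random.default_rng(2)
        values = [MISSING if rng.random() < 0.2
                  else str(rng.choice(["a", "b", "c"])) for _ in range(50)]
        table = make_table({"x": values})
        out = encode_onehot(table, "x")
        sums = out.data.sum(axis=1)
        assert (sums == 1).all()

    def test_no_missing_no_na_column(self):
        table = make_table({"x": ["a", "a"]})
        out = encode_onehot(table, "x")
        assert out.variables == ["x_a"]
        assert list(out.values("x_a")) == [1, 1]


class TestEncodeByFrequency:
    def test_most_common_gets_zero(self):
        values = ["WT"] * 30 + ["Het"] * 5 + ["Hom"] * 1
        table = make_table({"mut": values})
        out, mapping = encode_by_frequency(table, "mut")
        assert mapping.decode("mut") == {0: "WT", 1: "Het", 2: "Hom"}
        assert out.values("mut")["p1"] == 0

    def test_tie_broken_lexicographically(self):
        table = make_table({"x": ["b", "a", "b", "a"]})
        _, mapping = encode_by_frequency(table, "x")
        assert mapping.decode("x") == {0: "a", 1: "b"}

    def test_single_label_code_zero(self):
        table = make_table({"x": ["only", "only"]})
        out, mapping = encode_by_frequency(table, "x")
        assert mapping.decode("x") == {0: "only"}
        assert list(out.values("x")) == [0, 0]


class TestFreeText:
    def test_unigram_doc_frequencies(self):
        table = make_table({"notes": [
            "mother breast cancer",
            "father lung cancer",
            "mother breast cancer",
        ]})
        spec = FreeTextSpec(variable="notes", min_record_frequency=2,
                            ngram_length=1)
        out = extract_freetext(table, spec)
        new = sorted(v for v in out.variables if v != "notes")
        assert new == ["notes_breast", "notes_cancer", "notes_mother"]
        assert sum(out.values("notes_cancer")) == 3
        assert sum(out.values("notes_mother")) == 2

    def test_stopwords_removed(self):
        assert tokenise("a cancer in the colon") == ["cancer", "colon"]

    def test_skipgrams_with_window(self):
        grams = skipgrams(["x", "y", "z"], n=2, skip_window=1)
        assert grams == ["x_y", "x_z", "y_z"]
        assert skipgrams(["x", "y", "z"], n=2, skip_window=0) == ["x_y", "y_z"]

    def test_min_frequency_above_n_records_yields_nothing(self):
        table = make_table({"notes": ["alpha beta", "gamma delta"]})
        spec = FreeTextSpec(variable="notes", min_record_frequency=3)
        out = extract_freetext(table, spec)
        assert out.variables == ["notes"]

    def test_missing_text_propagates(self):
        table = make_table({"notes": [
            "breast cancer", "breast cancer", MISSING]})
        spec = FreeTextSpec(variable="notes", min_record_frequency=2)
        out = extract_freetext(table, spec)
        assert is_missing(out.values("notes_breast")["p3"])

    def test_doc_frequency_floor_property(self):
        rng = np.random.default_rng(8)
        words = ["breast", "lung", "skin", "colon", "cancer", "history"]
        texts = [" ".join(rng.choice(words, size=4)) for _ in range(30)]
        table = make_table({"notes": texts})
        spec = FreeTextSpec(variable="notes", min_record_frequency=5)
        out = extract_freetext(table, spec)
        for var in out.variables:
            if var == "notes":
                continue
            assert sum(out.values(var)) >= 5

    def test_substitution_hook(self):
        table = make_table({"notes": ["melanoma found", "melanoma again"]})
        spec = FreeTextSpec(variable="notes", min_record_frequency=2,
                            ngram_length=1)
        out = extract_freetext(table, spec,
                               substitutions=[("melanoma", "skin cancer")])
        assert "notes_skin" in out.variables
        assert "notes_melanoma" not in out.variables

    def test_wrong_type_error(self):
        table = make_table({"x": ["1", "2"]})
        table.meta["x"].vtype = "integer"
        with pytest.raises(ValueError, match="free_text"):
            extract_freetext(table, FreeTextSpec(variable="x"))


class TestAssertAllNumeric:
    def test_encoded_table_passes(self):
        table = make_table({"a": [1, 2], "b": [0.5, MISSING]})
        assert assert_all_numeric(table) == []

    def test_raw_string_column_reported(self):
        table = make_table({"a": [1, 2], "b": ["yes", "no"]})
        assert assert_all_numeric(table) == ["b"]

    def test_empty_table_passes(self):
        table = make_table({"a": []}, ids=[])
        assert assert_all_numeric(table) == []
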
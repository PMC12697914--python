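from itertools import permutations

import pytest

from qoverlap.assignment import (DEFAULT_PROMPT_TEMPLATE, ConsensusResult,
                                 RaterLabeling, apply_adjudication,
                                 assign_items, consensus_labeling,
                                 match_response, read_adjudication,
                                 read_rater_labelings, render_prompt,
                                 write_rater_labelings)
from qoverlap.agreement import pairwise_rater_ari
from qoverlap.clustering import Clustering
from qoverlap.errors import ValidationError
from qoverlap.item_bank import Item, SymptomCatalog


class EchoBackend:
    """Returns a canned response per item id; default: a given mapping."""

    name = "echo"
    deterministic = True

    def __init__(self, responses):
        self.responses = responses
        self.calls = 0

    def respond(self, item, prompt):
        self.calls += 1
        return self.responses[item.item_id]


def item(text="I feel sad", iid="q:1"):
    return Item(item_id=iid, questionnaire_id="q", text=text)


class TestRenderPrompt:
    def test_contains_item_and_labels(self, toy_catalog):
        prompt = render_prompt(item(), toy_catalog, DEFAULT_PROMPT_TEMPLATE)
        assert prompt.count("I feel sad") == 1
        for label in toy_catalog.symptoms:
            assert label in prompt

    def test_symptoms_one_per_line_in_order(self, toy_catalog):
        prompt = render_prompt(item(), toy_catalog, "{item_text}|{symptom_list}")
        assert prompt.split("|")[1] == "\n".join(toy_catalog.symptoms)

    def test_missing_placeholder(self, toy_catalog):
        with pytest.raises(ValidationError, match="symptom_list"):
            render_prompt(item(), toy_catalog, "Item: {item_text}")

    def test_deterministic(self, toy_catalog):
        a = render_prompt(item(), toy_catalog, DEFAULT_PROMPT_TEMPLATE)
        b = render_prompt(item(), toy_catalog, DEFAULT_PROMPT_TEMPLATE)
        assert a == b


class TestMatchResponse:
    def test_exact_after_normalization(self, toy_catalog):
        assert match_response("Sadness.", toy_catalog) == "sadness"
        assert match_response("  SLEEP  PROBLEMS ", toy_catalog) == "sleep problems"

    def test_unique_substring(self, toy_catalog):
        assert match_response("The best match is appetite here",
                              toy_catalog) == "appetite"

    def test_ambiguous_substring_rejected(self):
        catalog = SymptomCatalog("d", ["sleep onset", "sleep maintenance"])
        assert match_response("sleep onset and sleep maintenance",
                              catalog) is None

    def test_no_match(self, toy_catalog):
        assert match_response("psychomotor agitation", toy_catalog) is None


class TestAssignItems:
    def make_bank(self):
        from conftest import make_bank
        return make_bank({"q": [("I feel sad", "SR", False),
                                ("I cannot sleep", "SR", False)]})

    def test_exact_lookup_zero_failures(self, toy_catalog):
        bank = self.make_bank()
        backend = EchoBackend({"q:1": "sadness", "q:2": "sleep problems"})
        clustering, failures, transcript = assign_items(bank, toy_catalog, backend)
        assert failures == set()
        assert clustering.method == "llm"
        assert clustering.assignments == {"q:1": "sadness", "q:2": "sleep problems"}
        assert len(transcript) == 2

    def test_normalized_match_accepted(self, toy_catalog):
        bank = self.make_bank()
        backend = EchoBackend({"q:1": "Sadness.", "q:2": "Sleep problems"})
        clustering, failures, _ = assign_items(bank, toy_catalog, backend)
        assert failures == set()
        assert clustering.assignments["q:1"] == "sadness"

    def test_persistent_off_catalog_goes_to_failures(self, toy_catalog):
        bank = self.make_bank()
        backend = EchoBackend({"q:1": "sadness", "q:2": "not a symptom at all"})
        clustering, failures, transcript = assign_items(
            bank, toy_catalog, backend, max_retries=2)
        assert failures == {"q:2"}
        assert "q:2" not in clustering.assignments
        assert sum(t.item_id == "q:2" for t in transcript) == 3  # 1 + 2 retries

    def test_idempotent_with_deterministic_backend(self, toy_catalog):
        bank = self.make_bank()
        backend = EchoBackend({"q:1": "sadness", "q:2": "appetite"})
        a, _, _ = assign_items(bank, toy_catalog, backend)
        b, _, _ = assign_items(bank, toy_catalog, backend)
        assert a.assignments == b.assignments


def rater(rid, labels, items=("i1", "i2", "i3")):
    return RaterLabeling(rater_id=rid, assignments=dict(zip(items, labels)))


class TestConsensus:
    catalog = SymptomCatalog("d", ["s1", "s2", "s3"])

    def test_majority_two_of_three(self):
        result = consensus_labeling(
            [rater("a", ["s1"] * 3), rater("b", ["s1"] * 3),
             rater("c", ["s2", "s1", "s1"])], self.catalog)
        assert result.unresolved == set()
        assert result.clustering.assignments["i1"] == "s1"

    def test_three_way_disagreement_unresolved(self):
        result = consensus_labeling(
            [rater("a", ["s1", "s1", "s1"]), rater("b", ["s2", "s1", "s1"]),
             rater("c", ["s3", "s1", "s1"])], self.catalog)
        assert result.unresolved == {"i1"}
        assert "i1" not in result.clustering.assignments

    def test_unanimous_everywhere_pairwise_ari_one(self):
        labelings = [rater(r, ["s1", "s2", "s3"]) for r in "abc"]
        result = consensus_labeling(labelings, self.catalog)
        assert result.unresolved == set()
        matrix, mean = pairwise_rater_ari(labelings)
        assert mean == 1.0
        assert (matrix == 1.0).all()

    def test_symmetric_in_rater_order(self):
        labelings = [rater("a", ["s1", "s2", "s1"]), rater("b", ["s1", "s3", "s2"]),
                     rater("c", ["s2", "s2", "s2"])]
        expected = consensus_labeling(labelings, self.catalog)
        for perm in permutations(labelings):
            result = consensus_labeling(list(perm), self.catalog)
            assert result.unresolved == expected.unresolved
            assert (result.clustering.assignments
                    == expected.clustering.assignments)

    def test_differing_item_coverage(self):
        with pytest.raises(ValidationError, match="i3"):
            consensus_labeling(
                [rater("a", ["s1", "s1", "s1"]), rater("b", ["s1", "s1", "s1"]),
                 rater("c", ["s1", "s1"], items=("i1", "i2"))], self.catalog)

    def test_wrong_rater_count(self):
        with pytest.raises(ValidationError, match="exactly 3"):
            consensus_labeling([rater("a", ["s1"] * 3)], self.catalog)

    def test_off_catalog_rater_label(self):
        with pytest.raises(ValidationError, match="off-catalog"):
            consensus_labeling(
                [rater("a", ["bogus", "s1", "s1"]), rater("b", ["s1"] * 3),
                 rater("c", ["s1"] * 3)], self.catalog)


class TestAdjudication:
    catalog = SymptomCatalog("d", ["s1", "s2", "s3"])

    def base_result(self):
        return ConsensusResult(
            clustering=Clustering(assignments={"i1": "s1"}, method="expert"),
            unresolved={"i2", "i3"})

    def test_complete_clustering(self):
        clustering = apply_adjudication(
            self.base_result(), {"i2": "s2", "i3": "s3"}, self.catalog)
        assert clustering.assignments == {"i1": "s1", "i2": "s2", "i3": "s3"}
        assert clustering.method == "expert"

    def test_empty_unresolved_unchanged(self):
        result = ConsensusResult(
            clustering=Clustering(assignments={"i1": "s1"}, method="expert"),
            unresolved=set())
        clustering = apply_adjudication(result, {}, self.catalog)
        assert clustering.assignments == {"i1": "s1"}

    def test_off_catalog_adjudication(self):
        with pytest.raises(ValidationError, match="fatigue"):
            apply_adjudication(self.base_result(),
                               {"i2": "fatigue", "i3": "s3"}, self.catalog)

    def test_uncovered_unresolved(self):
        with pytest.raises(ValidationError, match="i3"):
            apply_adjudication(self.base_result(), {"i2": "s2"}, self.catalog)


class TestRaterIO:
    def test_round_trip(self, tmp_path):
        labelings = [rater("r1", ["s1", "s2", "s1"]), rater("r2", ["s2"] * 3)]
        path = tmp_path / "raters.csv"
        write_rater_labelings(labelings, path)
        back = read_rater_labelings(path)
        assert [lab.rater_id for lab in back] == ["r1", "r2"]
        assert back[0].assignments == labelings[0].assignments

    def test_adjudication_csv(self, tmp_path):
        path = tmp_path / "adj.csv"
        path.write_text("item_id,symptom\ni1,s2\ni2,s3\n")
        assert read_adjudication(path) == {"i1": "s2", "i2": "s3"}

    def test_missing_columns(self, tmp_path):
        path = tmp_path / "raters.csv"
        path.write_text("rater_id,item_id\nr1,i1\n")
        with pytest.raises(ValidationError, match="symptom"):
            read_rater_labelings(path)
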
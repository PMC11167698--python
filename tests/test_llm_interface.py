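import random

import numpy as np
import pytest

from chef.corpus_io import MoleculeRecord
from chef.llm_interface import (
    CLUSTER_SYSTEM_PROMPT,
    CLUSTER_USER_PROMPT_TEMPLATE,
    COMMUNITY_USER_PROMPT_TEMPLATE,
    SUMMARIZATION_SYSTEM_PROMPT,
    SUMMARIZATION_USER_PROMPT,
    ExtractionConfig,
    MockTextModelBackend,
    PatentDocument,
    build_summarization_prompt,
    extract_labels_for_molecule,
    parse_label_response,
    summarize_label_cluster,
)

# Golden copies of the operational prompt strings: a byte changed here is a
# method change, so the test pins them verbatim.
GOLDEN_SUMMARIZATION_SYSTEM = "You are an organic chemist summarizing chemical patents"
GOLDEN_SUMMARIZATION_USER = (
    "Return a short set of three 1-3 word descriptors that best describe the "
    "chemical or pharmacological function(s) of the molecule described by the "
    "given patent title, abstract, and partial description (giving more weight "
    "to title & abstract). Be specific and concise, but not necessarily "
    "comprehensive (choose a small number of great descriptor). Follow the "
    "syntax '{descriptor_1}/{descriptor_2}/{etc}', writing 'NA' if nothing is "
    "provided. DO NOT BREAK THIS SYNTAX. The following is the patent:"
)
GOLDEN_CLUSTER_SYSTEM = "You are a PhD pharmaceutical chemist"


class TestPromptTemplates:
    def test_summarization_prompts_match_golden_strings(self):
        assert SUMMARIZATION_SYSTEM_PROMPT == GOLDEN_SUMMARIZATION_SYSTEM
        assert SUMMARIZATION_USER_PROMPT == GOLDEN_SUMMARIZATION_USER

    def test_cluster_prompt_golden_fragments(self):
        assert CLUSTER_SYSTEM_PROMPT == GOLDEN_CLUSTER_SYSTEM
        assert "single descriptor representing the centroid" in CLUSTER_USER_PROMPT_TEMPLATE
        assert "example 2 average descriptor: antiviral" in CLUSTER_USER_PROMPT_TEMPLATE
        assert "__INSERT_DESCRIPTORS_HERE__" in CLUSTER_USER_PROMPT_TEMPLATE

    def test_community_prompt_golden_fragments(self):
        assert "summarize the terms into appropriate categories" in COMMUNITY_USER_PROMPT_TEMPLATE
        assert "example summarization: antiviral & cancer" in COMMUNITY_USER_PROMPT_TEMPLATE

    def test_description_truncated_to_3500_chars(self):
        patent = PatentDocument("P1", "t", "a", "x" * 5000)
        _, user = build_summarization_prompt(patent, ExtractionConfig())
        desc = user.split("Description: ", 1)[1]
        assert len(desc) == 3500

    def test_short_description_kept_whole(self):
        patent = PatentDocument("P1", "t", "a", "y" * 100)
        _, user = build_summarization_prompt(patent)
        assert user.endswith("Description: " + "y" * 100)

    def test_empty_fields_no_error(self):
        system, user = build_summarization_prompt(PatentDocument("P1"))
        assert system == SUMMARIZATION_SYSTEM_PROMPT
        assert user.startswith(SUMMARIZATION_USER_PROMPT)


class TestParseLabelResponse:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("antiviral/kinase inhibitor/anticancer", ["antiviral", "kinase inhibitor", "anticancer"]),
            ("NA", []),
            ("na", []),
            ("  {antiviral} / {hcv} ", ["antiviral", "hcv"]),
            ("antiviral/NA/hcv", ["antiviral", "hcv"]),
            ("antiviral//hcv", ["antiviral", "hcv"]),
            ("single descriptor", ["single descriptor"]),
        ],
    )
    def test_slash_syntax_examples(self, text, expected):
        parsed = parse_label_response(text)
        assert parsed == expected
        assert not parsed.failed

    def test_newline_recovery_is_flagged(self):
        parsed = parse_label_response("1. antiviral\n2. hcv inhibitor\n")
        assert parsed == ["antiviral", "hcv inhibitor"]
        assert parsed.failed

    def test_unparseable_prose_flags_failure(self):
        long_prose = " ".join(["word"] * 40)
        parsed = parse_label_response(long_prose)
        assert parsed.failed

    @pytest.mark.parametrize("text", ["a/b/c", "x / /y", "NA/na/Na", "one//two/three/"])
    def test_token_bound_and_never_na_or_empty(self, text):
        parsed = parse_label_response(text)
        assert len(parsed) <= text.count("/") + 1
        assert all(tok and tok.lower() != "na" for tok in parsed)


def _molecule(patents):
    return MoleculeRecord(smiles="CCO", inchikey="KEY", patent_ids=set(patents))


class _CountingBackend(MockTextModelBackend):
    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        self.calls = 0

    def summarize(self, system_prompt, user_prompt):
        self.calls += 1
        return super().summarize(system_prompt, user_prompt)


class TestExtraction:
    TABLE = {"antiviral": ["antiviral"], "hcv": ["hcv"], "protease": ["protease"]}

    def _corpus(self):
        return {
            "P1": PatentDocument("P1", "Antiviral agents", "Compounds with antiviral and hcv activity", ""),
            "P2": PatentDocument("P2", "HCV drugs", "hcv protease inhibitors", ""),
        }

    def test_union_and_provenance_over_patents(self):
        backend = MockTextModelBackend(self.TABLE)
        labels, prov = extract_labels_for_molecule(_molecule(["P1", "P2"]), self._corpus(), backend)
        assert labels == {"antiviral", "hcv", "protease"}
        assert prov["hcv"] == ["P1", "P2"]
        assert prov["antiviral"] == ["P1"]

    def test_missing_patents_skipped_with_warning(self, caplog):
        backend = MockTextModelBackend(self.TABLE)
        with caplog.at_level("WARNING"):
            labels, _ = extract_labels_for_molecule(_molecule(["NOPE"]), {}, backend)
        assert labels == set()
        assert any("not in corpus" in r.message for r in caplog.records)

    def test_templated_patent_yields_exactly_planted_labels(self):
        backend = MockTextModelBackend(self.TABLE)
        corpus = {"P1": PatentDocument("P1", "Useful compounds", "antiviral and hcv uses", "")}
        labels, _ = extract_labels_for_molecule(_molecule(["P1"]), corpus, backend)
        assert labels == {"antiviral", "hcv"}

    def test_shared_patents_summarized_once(self):
        backend = _CountingBackend(self.TABLE)
        corpus = self._corpus()
        cache: dict = {}
        for _ in range(3):
            extract_labels_for_molecule(_molecule(["P1", "P2"]), corpus, backend, cache=cache)
        assert backend.calls == 2  # one per distinct patent, served from cache after

    def test_backend_failure_skips_patent_not_molecule(self):
        class FailingOnP2(MockTextModelBackend):
            def summarize(self, system_prompt, user_prompt):
                if "protease" in user_prompt:
                    raise RuntimeError("boom")
                return super().summarize(system_prompt, user_prompt)

        labels, _ = extract_labels_for_molecule(
            _molecule(["P1", "P2"]), self._corpus(), FailingOnP2(self.TABLE)
        )
        assert labels == {"antiviral", "hcv"}

    def test_deterministic_and_order_invariant(self):
        backend = MockTextModelBackend(self.TABLE)
        corpus = self._corpus()
        results = set()
        for seed in range(3):
            pids = ["P1", "P2"]
            random.Random(seed).shuffle(pids)
            labels, _ = extract_labels_for_molecule(_molecule(pids), corpus, backend)
            results.add(frozenset(labels))
        assert len(results) == 1


class TestClusterSummarization:
    def test_synonym_cluster_maps_to_canonical(self, mock_backend):
        name = summarize_label_cluster(["antiviral", "antivirus", "anti-viral"], mock_backend)
        assert name == "antiviral"

    def test_singleton_returned_as_is(self, mock_backend):
        assert summarize_label_cluster(["hcv"], mock_backend) == "hcv"

    def test_most_frequent_canonical_wins(self):
        backend = MockTextModelBackend({"analgesic": ["painkiller", "analgesic"]})
        assert summarize_label_cluster(["painkiller", "analgesic"], backend) == "analgesic"

    def test_backend_failure_falls_back_to_shortest_member(self):
        class Broken:
            def summarize(self, *_):
                raise RuntimeError("down")

            def embed(self, text):
                return np.ones(4) / 2

        assert summarize_label_cluster(["longest-label", "tiny"], Broken()) == "tiny"

    def test_empty_cluster_rejected(self, mock_backend):
        with pytest.raises(ValueError):
            summarize_label_cluster([], mock_backend)


class TestMockEmbeddings:
    def test_deterministic(self, mock_backend):
        a = mock_backend.embed("antiviral")
        b = mock_backend.embed("antiviral")
        assert np.array_equal(a, b)

    def test_unit_norm(self, mock_backend):
        for text in ["antiviral", "totally-unknown-token", "painkillers"]:
            assert np.linalg.norm(mock_backend.embed(text)) == pytest.approx(1.0)
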
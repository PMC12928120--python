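"""Vocabulary extraction: splitting, verification, normalization, merging."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from litkg import (
    AcronymPair,
    Document,
    PlantedWorldBackend,
    ScriptedBackend,
    ValidationError,
    build_vocabulary,
    extract_acronyms,
    extract_terms,
    normalize_term,
    split_sentences,
)
from litkg.backend import GenerationRequest

# hand-segmented reference passage for the rule-based splitter
_SEGMENTED = [
    "Single Atom Catalysts (SACs) maximize metal utilization.",
    "Each active site is an isolated atom, e.g. Pt or Pd, anchored on a support.",
    "Anchoring prevents aggregation.",
    "Several supports have been studied, i.e. oxides, carbons, and zeolites.",
    "Nitrogen-doped carbon is common.",
    "Characterization relies on microscopy (cf. aberration correction).",
    "Spectroscopy is complementary.",
    "Loadings are low, ca. 1 wt%.",
    "Stability varies with temperature.",
    "Selectivity can exceed that of nanoparticles.",
    "Synthesis routes include wet impregnation.",
    "Pyrolysis is another route.",
    "Metal-support interactions tune activity.",
    "Electronic structure shifts with coordination.",
    "Applications span hydrogenation and oxidation.",
    "CO oxidation is a benchmark reaction.",
    "Water-gas shift has also been reported.",
    "Durability remains a challenge.",
    "Scale-up is an open question.",
    "The field is growing rapidly.",
]


class TestSplitSentences:
    def test_terminal_punctuation_variants(self):
        assert split_sentences("A. B? C.") == ["A.", "B?", "C."]

    def test_abbreviation_not_split(self):
        out = split_sentences("Metals, e.g. Pt, are active. Supports matter.")
        assert out == ["Metals, e.g. Pt, are active.", "Supports matter."]

    def test_hand_segmented_reference_passage(self):
        assert split_sentences(" ".join(_SEGMENTED)) == _SEGMENTED

    def test_no_terminal_punctuation_single_sentence(self):
        assert split_sentences("no boundary here") == ["no boundary here"]

    def test_lossless_modulo_whitespace(self):
        text = " ".join(_SEGMENTED)
        joined = " ".join(split_sentences(text))
        assert joined.split() == text.split()

    def test_empty_text_rejected(self):
        with pytest.raises(ValidationError):
            split_sentences("   ")


class TestNormalizeTerm:
    @pytest.mark.parametrize(
        "surface,expected",
        [
            ("Single-Atom Catalysts", "single atom catalyst"),
            ("Single Atom Catalyst", "single atom catalyst"),
            ("alkanes", "alkane"),
            ("thing", "thing"),
            ("Noble Gases", "noble gas"),
            ("catalytic properties", "catalytic property"),
            ("X-ray analyses", "x ray analysis"),
        ],
    )
    def test_examples(self, surface, expected):
        assert normalize_term(surface) == expected

    @settings(max_examples=200, deadline=None)
    @given(
        st.text(
            alphabet=st.characters(
                whitelist_categories=("Lu", "Ll", "Nd"),
                whitelist_characters=" -'.",
            ),
            min_size=1,
        ).filter(lambda s: any(ch.isalnum() for ch in s))
    )
    def test_idempotent(self, surface):
        once = normalize_term(surface)
        assert normalize_term(once) == once

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            normalize_term("  ")


def scripted_for(role: str, payload: dict, response) -> ScriptedBackend:
    store = {}
    ScriptedBackend.record(
        store, GenerationRequest(prompt_role=role, payload=payload), response
    )
    return ScriptedBackend(store)


class TestExtractTerms:
    SENTENCE = "The single atom catalyst showed high activity."

    def _backend(self, proposals):
        return scripted_for(
            "term_extract",
            {"text": self.SENTENCE, "paper_id": "p1"},
            proposals,
        )

    def test_verification_drops_absent_terms(self):
        backend = self._backend(["single atom catalyst", "unicorn"])
        assert extract_terms(self.SENTENCE, backend, paper_id="p1") == {
            "single atom catalyst"
        }

    def test_hyphen_variant_kept_under_normalized_matching(self):
        backend = self._backend(["single-atom catalyst"])
        assert extract_terms(self.SENTENCE, backend, paper_id="p1") == {
            "single-atom catalyst"
        }

    def test_hyphen_variant_dropped_in_raw_mode(self):
        backend = self._backend(["single-atom catalyst"])
        assert (
            extract_terms(
                self.SENTENCE, backend, paper_id="p1", matching="raw"
            )
            == set()
        )

    def test_empty_proposals_give_empty_set(self):
        backend = self._backend([])
        assert extract_terms(self.SENTENCE, backend, paper_id="p1") == set()


class TestExtractAcronyms:
    TEXT = "Single Atom Catalysts (SACs) are efficient. SACs resist sintering."

    def test_defined_pair_kept(self):
        backend = scripted_for(
            "acronym_extract",
            {"text": self.TEXT, "paper_id": "p1"},
            [["SACs", "Single Atom Catalysts"]],
        )
        assert extract_acronyms(self.TEXT, backend, paper_id="p1") == {
            AcronymPair("SACs", "Single Atom Catalysts")
        }

    def test_absent_expansion_dropped(self):
        backend = scripted_for(
            "acronym_extract",
            {"text": self.TEXT, "paper_id": "p1"},
            [["SACs", "Strongly Anchored Clusters"]],
        )
        assert extract_acronyms(self.TEXT, backend, paper_id="p1") == set()

    def test_honest_empty_answer(self):
        backend = scripted_for(
            "acronym_extract", {"text": self.TEXT, "paper_id": "p1"}, []
        )
        assert extract_acronyms(self.TEXT, backend, paper_id="p1") == set()


class TestBuildVocabulary:
    def _two_paper_backend(self):
        docs = [
            Document("p1", "Single-Atom Catalysts are active."),
            Document("p2", "A single atom catalyst resists sintering."),
        ]
        store = {}
        ScriptedBackend.record(
            store,
            GenerationRequest(
                prompt_role="term_extract",
                payload={"text": docs[0].text, "paper_id": "p1"},
            ),
            ["Single-Atom Catalysts"],
        )
        ScriptedBackend.record(
            store,
            GenerationRequest(
                prompt_role="term_extract",
                payload={"text": docs[1].text, "paper_id": "p2"},
            ),
            ["single atom catalyst"],
        )
        for doc in docs:
            ScriptedBackend.record(
                store,
                GenerationRequest(
                    prompt_role="acronym_extract",
                    payload={"text": doc.text, "paper_id": doc.paper_id},
                ),
                [],
            )
        return docs, ScriptedBackend(store)

    def test_variants_merge_into_one_entry(self):
        docs, backend = self._two_paper_backend()
        vocab = build_vocabulary(docs, backend)
        assert len(vocab) == 1
        entry = vocab.entries["single atom catalyst"]
        assert entry.surface_forms == [
            "Single-Atom Catalysts",
            "single atom catalyst",
        ]
        assert entry.canonical_surface == "Single-Atom Catalysts"
        assert entry.paper_ids == ["p1", "p2"]

    def test_empty_corpus_rejected(self):
        _, backend = self._two_paper_backend()
        with pytest.raises(ValidationError):
            build_vocabulary([], backend)

    def test_merge_idempotence(self):
        docs, backend = self._two_paper_backend()
        v1 = build_vocabulary(docs, backend)
        v2 = build_vocabulary(docs, ScriptedBackend(backend.responses))
        assert v1 == v2

    def test_split_disabled_ablation_runs(self, planted_small):
        backend = PlantedWorldBackend(planted_small.world)
        vocab = build_vocabulary(planted_small.corpus, backend, split=False)
        assert len(vocab) > 0

    def test_planted_noise_free_covers_all_mentioned_terms(self, planted_small):
        backend = PlantedWorldBackend(planted_small.world)
        vocab = build_vocabulary(planted_small.corpus, backend)
        mentioned = {
            lemma
            for facts in planted_small.world.paper_facts.values()
            for lemma in facts.term_surfaces
        }
        assert mentioned <= vocab.lemma_keys()
        # per-paper provenance holds too
        for pid, facts in planted_small.world.paper_facts.items():
            assert set(facts.term_surfaces) <= vocab.paper_vocab(pid)

    def test_acronym_alias_resolution(self, planted_small):
        backend = PlantedWorldBackend(planted_small.world)
        vocab = build_vocabulary(planted_small.corpus, backend)
        for facts in planted_small.world.paper_facts.values():
            for acr, expansion in facts.acronyms:
                assert vocab.resolve(
                    normalize_term(acr)
                ) == normalize_term(expansion)

    def test_no_hallucinated_surface_survives_adversarial_backend(
        self, planted_small
    ):
        """Every vocabulary surface form is verifiably present in its papers."""
        world = planted_small.world
        noisy = type(world)(
            schema=world.schema,
            kg=world.kg,
            paper_facts=world.paper_facts,
            omission_rate=0.0,
            hallucination_rate=1.0,  # one fabricated term per true term
            rng_seed=23,
        )
        vocab = build_vocabulary(
            planted_small.corpus, PlantedWorldBackend(noisy)
        )
        texts = {d.paper_id: d.text for d in planted_small.corpus}
        from litkg.vocabulary import occurs_in

        for entry in vocab.entries.values():
            for surface in entry.surface_forms:
                assert any(
                    occurs_in(surface, texts[pid]) for pid in entry.paper_ids
                )
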
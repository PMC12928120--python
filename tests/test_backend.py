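"""Backends and self-consistency: replay, planted-world noise, majority voting."""

import math

import pytest

from litkg import (
    GenerationRequest,
    PlantedWorldBackend,
    ScriptedBackend,
    self_consistent,
)
from litkg.backend import ConfigurationError


def binomial_tail(m: int, p: float, k_min: int) -> float:
    """P(Bin(m, p) >= k_min) in closed form."""
    return sum(
        math.comb(m, k) * p**k * (1 - p) ** (m - k) for k in range(k_min, m + 1)
    )


def make_backend(planted_small, omission=0.0, hallucination=0.0, seed=0):
    world = planted_small.world
    world = type(world)(
        schema=world.schema,
        kg=world.kg,
        paper_facts=world.paper_facts,
        omission_rate=omission,
        hallucination_rate=hallucination,
        rng_seed=seed,
    )
    return PlantedWorldBackend(world)


def single_pair_request(planted_small) -> GenerationRequest:
    """A relationship query whose noise-free answer is that paper's facts."""
    world = planted_small.world
    pid = next(
        p for p, f in sorted(world.paper_facts.items()) if f.isa_facts
    )
    facts = world.paper_facts[pid]
    return GenerationRequest(
        prompt_role="relationship_query",
        payload={
            "paper_id": pid,
            "taxonomy_terms": sorted(
                {parent for _, parent in facts.isa_facts}
                | {world.schema.taxonomy.root}
            ),
            "vocabulary": sorted({child for child, _ in facts.isa_facts}),
        },
    )


class TestScriptedBackend:
    def test_replays_recorded_answer_exactly(self):
        req = GenerationRequest(
            prompt_role="term_extract", payload={"text": "alkanes burn"}
        )
        store = {}
        ScriptedBackend.record(store, req, ["alkanes"])
        backend = ScriptedBackend(store)
        assert backend.generate(req) == ["alkanes"]
        # a content-level recording answers every sample index
        assert backend.generate(req.model_copy(update={"sample_index": 4})) == [
            "alkanes"
        ]

    def test_missing_recording_raises(self):
        backend = ScriptedBackend({})
        with pytest.raises(KeyError):
            backend.generate(
                GenerationRequest(prompt_role="term_extract", payload={})
            )


class TestPlantedBackend:
    def test_noise_free_relationship_query_is_exact(self, planted_small):
        backend = make_backend(planted_small)
        req = single_pair_request(planted_small)
        facts = planted_small.world.paper_facts[req.payload["paper_id"]]
        expected = sorted(
            [p, c]
            for c, p in facts.isa_facts
            if p in set(req.payload["taxonomy_terms"])
        )
        assert sorted(backend.generate(req)) == expected

    def test_reproducible_response_stream(self, planted_small):
        req = single_pair_request(planted_small)
        b1 = make_backend(planted_small, omission=0.4, hallucination=0.4, seed=5)
        b2 = make_backend(planted_small, omission=0.4, hallucination=0.4, seed=5)
        stream1 = [
            b1.generate(req.model_copy(update={"sample_index": i}))
            for i in range(20)
        ]
        stream2 = [
            b2.generate(req.model_copy(update={"sample_index": i}))
            for i in range(20)
        ]
        assert stream1 == stream2

    def test_omission_rate_drives_bernoulli_retention(self, planted_small):
        """Per-sample retention of one true pair ~ 0.70 at omission 0.3."""
        backend = make_backend(planted_small, omission=0.3, seed=2)
        req = single_pair_request(planted_small)
        facts = planted_small.world.paper_facts[req.payload["paper_id"]]
        child, parent = facts.isa_facts[0]
        hits = 0
        n = 2000
        for i in range(n):
            resp = backend.generate(
                req.model_copy(update={"sample_index": i, "seed": i})
            )
            if [parent, child] in resp:
                hits += 1
        assert abs(hits / n - 0.70) < 0.02

    def test_spurious_pool_is_stable_across_samples(self, planted_small):
        backend = make_backend(planted_small, hallucination=1.0, seed=3)
        req = single_pair_request(planted_small)
        facts = planted_small.world.paper_facts[req.payload["paper_id"]]
        true_pairs = {(p, c) for c, p in facts.isa_facts}
        spurious_per_sample = []
        for i in range(5):
            resp = backend.generate(req.model_copy(update={"sample_index": i}))
            spurious_per_sample.append(
                {tuple(x) for x in resp} - true_pairs
            )
        assert all(s == spurious_per_sample[0] for s in spurious_per_sample)


class TestSelfConsistency:
    def test_even_m_rejected(self, planted_small):
        backend = make_backend(planted_small)
        with pytest.raises(ConfigurationError):
            self_consistent(
                backend, single_pair_request(planted_small), m=4
            )

    def test_strict_majority_keeps_and_drops(self):
        req = GenerationRequest(prompt_role="term_extract", payload={"x": 1})
        store = {}
        for i, sample in enumerate(
            [["kept", "dropped"], ["kept"], ["other"]]
        ):
            ScriptedBackend.record(
                store,
                req.model_copy(update={"sample_index": i}),
                sample,
                per_sample=True,
            )
        out = self_consistent(ScriptedBackend(store), req, m=3)
        assert out == ["kept"]  # 2/3 kept; 1/3 dropped

    def test_unanimity_returns_the_sample(self, planted_small):
        backend = make_backend(planted_small)
        req = single_pair_request(planted_small)
        single = backend.generate(req)
        assert sorted(
            tuple(x) for x in self_consistent(backend, req, m=5)
        ) == sorted(tuple(x) for x in single)

    def test_majority_survival_matches_binomial_tail(self, planted_small):
        """Empirical survival under voting tracks P(Bin(m, 1-omission) > m/2)."""
        req = single_pair_request(planted_small)
        facts = planted_small.world.paper_facts[req.payload["paper_id"]]
        child, parent = facts.isa_facts[0]
        previous = 0.0
        for m in (1, 3, 5, 7, 9):
            backend = make_backend(planted_small, omission=0.3, seed=13)
            hits = 0
            trials = 400
            for t in range(trials):
                out = self_consistent(
                    backend, req.model_copy(update={"seed": 10_000 + t}), m=m
                )
                if [parent, child] in out:
                    hits += 1
            expected = binomial_tail(m, 0.7, m // 2 + 1)
            assert abs(hits / trials - expected) < 0.06
            assert hits / trials >= previous - 0.05  # monotone up (noise slack)
            previous = hits / trials

    def test_hallucination_suppressed_as_m_grows(self, planted_small):
        """Items with per-sample probability < 0.5 vanish under large-m voting."""
        req = single_pair_request(planted_small)
        facts = planted_small.world.paper_facts[req.payload["paper_id"]]
        true_pairs = {(p, c) for c, p in facts.isa_facts}
        backend = make_backend(planted_small, hallucination=0.3, seed=17)
        survivors = 0
        trials = 200
        for t in range(trials):
            out = self_consistent(
                backend, req.model_copy(update={"seed": 50_000 + t}), m=9
            )
            survivors += sum(
                1 for item in out if tuple(item) not in true_pairs
            )
        rate = survivors / (
            trials * backend.world.hallucination_pool_size
        )
        assert rate < binomial_tail(9, 0.3, 5) + 0.04


class TestLedger:
    def test_every_call_recorded_with_stage(self, planted_small):
        backend = make_backend(planted_small)
        req = single_pair_request(planted_small)
        self_consistent(backend, req, m=3)
        assert len(backend.ledger.entries) == 3
        assert backend.ledger.stage_counts() == {"taxonomy": 3}
        assert all(e.payload_chars > 0 for e in backend.ledger.entries)
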
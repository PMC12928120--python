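"""Text-generation backends and the self-consistency aggregator.

Every pipeline stage talks to a :class:`GenerationBackend` through typed
:class:`GenerationRequest` objects, so the whole method runs against a live
OpenAI-compatible chat endpoint, a scripted replay fixture, or a
planted-world oracle interchangeably.

The planted-world backend answers from a known ground-truth ontology with
controllable omission noise (a true fact is dropped from a sample with
probability ``omission_rate``) and hallucination noise (a spurious candidate
fact is injected with probability ``hallucination_rate`` per sample).
Spurious candidates are drawn from a pool that depends on the request but
not on the sample index, so repeated sampling sees the *same* spurious
items — the regime in which majority voting provably suppresses them: a
candidate appearing with per-sample probability h survives an m-sample
strict-majority vote with probability P(Bin(m, h) > m/2), which vanishes
with m when h < 1/2.

Self-consistency (:func:`self_consistent`) draws m samples of one request
and keeps the items occurring in a strict majority of them.
"""

from __future__ import annotations

import hashlib
import json
import logging
import random
import time
from abc import ABC, abstractmethod
from collections import Counter
from dataclasses import dataclass, field
from typing import Any, Literal

from pydantic import BaseModel, Field

from .model import KnowledgeGraph, OntologySchema, Triple

logger = logging.getLogger("litkg")

PromptRole = Literal[
    "sentence_split",
    "term_extract",
    "acronym_extract",
    "category_generate",
    "category_refine",
    "relationship_query",
    "triple_extract",
]

#: Roles whose responses are unordered item sets (majority-votable).
SET_ROLES = {
    "term_extract",
    "acronym_extract",
    "relationship_query",
    "triple_extract",
}
#: Roles whose responses are ordered label sequences.
SEQUENCE_ROLES = {"category_generate", "category_refine"}

#: Stage attribution of each prompt role for complexity accounting.
ROLE_STAGE = {
    "sentence_split": "vocabulary",
    "term_extract": "vocabulary",
    "acronym_extract": "vocabulary",
    "category_generate": "categories",
    "category_refine": "categories",
    "relationship_query": "taxonomy",
    "triple_extract": "relations",
}


class ConfigurationError(ValueError):
    """Invalid backend or sampling configuration (e.g. even sample count)."""


class TransportError(RuntimeError):
    """Retryable live-endpoint failure."""


class ParseError(RuntimeError):
    """Model output could not be parsed; carries the raw text."""

    def __init__(self, message: str, raw_text: str = "") -> None:
        super().__init__(message)
        self.raw_text = raw_text


class GenerationRequest(BaseModel):
    """One typed backend call.

    ``payload`` is structured content whose shape depends on ``prompt_role``
    (text and paper id for extraction roles, taxonomy term inventory and
    vocabulary for relationship queries, shuffled texts for category
    generation).  ``seed`` and ``sample_index`` fully determine the response
    of the deterministic backends.
    """

    prompt_role: PromptRole
    payload: dict[str, Any] = Field(default_factory=dict)
    sample_index: int = 0
    seed: int = 0

    def content_digest(self, with_sample: bool = False) -> str:
        """Stable digest of role + payload (optionally + sample index)."""
        body: dict[str, Any] = {
            "role": self.prompt_role,
            "payload": self.payload,
        }
        if with_sample:
            body["sample_index"] = self.sample_index
        blob = json.dumps(body, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()

    def payload_chars(self) -> int:
        return len(json.dumps(self.payload, default=str))


@dataclass
class LedgerEntry:
    role: str
    stage: str
    payload_chars: int
    sample_index: int
    paper_id: str | None = None


@dataclass
class CallLedger:
    """Append-only record of backend invocations for complexity accounting.

    ``stage_counts`` gives total calls per pipeline stage; for the
    vocabulary stage both prompting granularities are reported: the
    per-sentence call count and the number of distinct papers touched.
    """

    entries: list[LedgerEntry] = field(default_factory=list)

    def record(self, request: GenerationRequest) -> None:
        self.entries.append(
            LedgerEntry(
                role=request.prompt_role,
                stage=ROLE_STAGE[request.prompt_role],
                payload_chars=request.payload_chars(),
                sample_index=request.sample_index,
                paper_id=request.payload.get("paper_id"),
            )
        )

    def stage_counts(self) -> dict[str, int]:
        counts: Counter[str] = Counter(e.stage for e in self.entries)
        return dict(counts)

    def role_counts(self) -> dict[str, int]:
        return dict(Counter(e.role for e in self.entries))

    def stage_payload_chars(self) -> dict[str, int]:
        out: Counter[str] = Counter()
        for e in self.entries:
            out[e.stage] += e.payload_chars
        return dict(out)

    def vocabulary_granularity(self) -> dict[str, int]:
        """Vocabulary-stage call counts at sentence and paper granularity."""
        vocab = [e for e in self.entries if e.stage == "vocabulary"]
        papers = {e.paper_id for e in vocab if e.paper_id is not None}
        return {
            "per_sentence_calls": sum(
                1 for e in vocab if e.role == "term_extract"
            ),
            "acronym_calls": sum(
                1 for e in vocab if e.role == "acronym_extract"
            ),
            "papers_touched": len(papers),
        }

    def to_dict(self) -> dict:
        return {
            "total_calls": len(self.entries),
            "stage_counts": self.stage_counts(),
            "role_counts": self.role_counts(),
            "stage_payload_chars": self.stage_payload_chars(),
            "vocabulary_granularity": self.vocabulary_granularity(),
        }


class GenerationBackend(ABC):
    """Contract for any text-generation engine.

    Subclasses implement :meth:`_respond`; :meth:`generate` wraps it with
    ledger accounting.  Responses are plain Python structures whose type is
    fixed by the prompt role: a sorted list of strings (terms), a list of
    (acronym, expansion) pairs, a label sequence (categories), a list of
    (parent, child) pairs, a list of (subject, predicate, object) triples,
    or an ordered sentence list.
    """

    def __init__(self) -> None:
        self.ledger = CallLedger()

    def generate(self, request: GenerationRequest):
        self.ledger.record(request)
        return self._respond(request)

    @abstractmethod
    def _respond(self, request: GenerationRequest):
        ...


# ---------------------------------------------------------------------------
# Self-consistency
# ---------------------------------------------------------------------------


def _freeze(item):
    return tuple(item) if isinstance(item, (list, tuple)) else item


def self_consistent(
    backend: GenerationBackend,
    request: GenerationRequest,
    m: int,
    threshold: float = 0.5,
):
    """Aggregate m samples of one request by strict-majority voting.

    m must be odd (an even m admits ties under the default threshold and is
    rejected with :class:`ConfigurationError`).  Set-valued responses keep
    exactly the items occurring in more than ``threshold * m`` samples;
    sequence-valued category responses are ranked by occurrence count
    (ties lexicographic) and then majority-filtered.
    """
    if m < 1:
        raise ConfigurationError("sample count m must be >= 1")
    if m % 2 == 0:
        raise ConfigurationError(f"sample count m must be odd, got {m}")
    samples = []
    for i in range(m):
        req = request.model_copy(update={"sample_index": i})
        samples.append(backend.generate(req))
    cutoff = threshold * m
    role = request.prompt_role
    if role in SET_ROLES or role in SEQUENCE_ROLES:
        counts: Counter = Counter()
        for sample in samples:
            for item in dict.fromkeys(_freeze(x) for x in sample):
                counts[item] += 1
        kept = [item for item, c in counts.items() if c > cutoff]
        if role in SEQUENCE_ROLES:
            kept.sort(key=lambda it: (-counts[it], it))
        else:
            kept.sort()
        return [list(it) if isinstance(it, tuple) else it for it in kept]
    # ordered text responses (sentence_split): take the modal sample
    blobs = Counter(json.dumps(s) for s in samples)
    return json.loads(blobs.most_common(1)[0][0])


# ---------------------------------------------------------------------------
# Scripted replay backend
# ---------------------------------------------------------------------------


class ScriptedBackend(GenerationBackend):
    """Replays recorded responses keyed by request digest.

    The fixture maps a content digest (with or without the sample index) to
    the stored response; a digest recorded without the sample index answers
    every sample of that request identically.
    """

    def __init__(self, responses: dict[str, Any]) -> None:
        super().__init__()
        self.responses = dict(responses)

    @classmethod
    def from_yaml(cls, path) -> "ScriptedBackend":
        import yaml

        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    @staticmethod
    def record(
        store: dict[str, Any],
        request: GenerationRequest,
        response,
        per_sample: bool = False,
    ) -> None:
        store[request.content_digest(with_sample=per_sample)] = response

    def _respond(self, request: GenerationRequest):
        for with_sample in (True, False):
            key = request.content_digest(with_sample=with_sample)
            if key in self.responses:
                return self.responses[key]
        raise KeyError(
            f"no scripted response for role={request.prompt_role} "
            f"digest={request.content_digest()}"
        )


# ---------------------------------------------------------------------------
# Planted-world oracle backend
# ---------------------------------------------------------------------------


@dataclass
class PaperFacts:
    """Ground-truth content of one rendered paper."""

    paper_id: str
    term_surfaces: dict[str, str]  # lemma key -> surface form used in text
    isa_facts: list[tuple[str, str]]  # (child, parent) lemma pairs
    acronyms: list[tuple[str, str]]  # (acronym, expansion) surfaces
    relations: list[Triple] = field(default_factory=list)


@dataclass
class PlantedWorld:
    """A known ontology/KG plus the per-paper facts its corpus asserts."""

    schema: OntologySchema
    kg: KnowledgeGraph
    paper_facts: dict[str, PaperFacts]
    omission_rate: float = 0.0
    hallucination_rate: float = 0.0
    rng_seed: int = 0
    hallucination_pool_size: int = 3

    def __post_init__(self) -> None:
        for name in ("omission_rate", "hallucination_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")

    @property
    def categories(self) -> list[str]:
        """Level-1 nodes: direct children of the root."""
        return sorted(self.schema.taxonomy.children(self.schema.taxonomy.root))

    @property
    def term_pool(self) -> list[str]:
        return sorted(self.schema.taxonomy.nodes - {self.schema.taxonomy.root})


def _stable_rng(*parts) -> random.Random:
    blob = json.dumps([str(p) for p in parts])
    seed = int.from_bytes(hashlib.sha256(blob.encode()).digest()[:8], "big")
    return random.Random(seed)


class PlantedWorldBackend(GenerationBackend):
    """Answers every prompt role from a planted ground truth, with noise.

    Noise-free (both rates 0) it is an exact oracle: term extraction returns
    precisely the planted surface forms present in the text, relationship
    queries return precisely the paper's asserted isA facts whose parent is
    already in the presented taxonomy, and so on.  With noise, each true
    item is independently dropped per sample with probability
    ``omission_rate`` and each spurious pool candidate is independently
    injected with probability ``hallucination_rate``.
    """

    def __init__(self, world: PlantedWorld) -> None:
        super().__init__()
        self.world = world

    # -- noise helpers ------------------------------------------------------

    def _sample_rng(self, request: GenerationRequest, key: str) -> random.Random:
        return _stable_rng(
            self.world.rng_seed,
            request.seed,
            request.prompt_role,
            key,
            request.sample_index,
        )

    def _pool_rng(self, request: GenerationRequest, key: str) -> random.Random:
        # no sample_index: the spurious pool is shared across samples
        return _stable_rng(
            self.world.rng_seed, request.seed, request.prompt_role, key, "pool"
        )

    def _apply_noise(self, true_items: list, pool: list, rng: random.Random):
        kept = [
            x for x in true_items if rng.random() >= self.world.omission_rate
        ]
        injected = [
            x for x in pool if rng.random() < self.world.hallucination_rate
        ]
        return kept + injected

    # -- role handlers ------------------------------------------------------

    def _respond(self, request: GenerationRequest):
        handler = getattr(self, f"_on_{request.prompt_role}")
        return handler(request)

    def _facts(self, request: GenerationRequest) -> PaperFacts:
        pid = request.payload.get("paper_id")
        if pid not in self.world.paper_facts:
            raise ParseError(f"planted world has no paper {pid!r}")
        return self.world.paper_facts[pid]

    def _on_sentence_split(self, request: GenerationRequest) -> list[str]:
        text = request.payload.get("text", "")
        parts = [s.strip() for s in text.replace("\n", " ").split(". ")]
        return [p if p.endswith((".", "?", "!")) else p + "." for p in parts if p]

    def _on_term_extract(self, request: GenerationRequest) -> list[str]:
        facts = self._facts(request)
        sentence = request.payload.get("text", "")
        low = " " + sentence.lower().replace("-", " ") + " "
        present = [
            surf
            for _, surf in sorted(facts.term_surfaces.items())
            if surf.lower().replace("-", " ") in low
        ]
        pool_rng = self._pool_rng(request, sentence)
        pool = [
            f"fabricated {pool_rng.randrange(10**6)} compound"
            for _ in range(max(1, len(present)))
        ]
        rng = self._sample_rng(request, sentence)
        return self._apply_noise(present, pool, rng)

    def _on_acronym_extract(self, request: GenerationRequest) -> list:
        facts = self._facts(request)
        pool_rng = self._pool_rng(request, facts.paper_id)
        pool = [
            (f"ZQX{pool_rng.randrange(100)}", f"zephyrium quexide {pool_rng.randrange(100)}")
            for _ in range(self.world.hallucination_pool_size)
        ]
        rng = self._sample_rng(request, facts.paper_id)
        items = self._apply_noise(sorted(facts.acronyms), pool, rng)
        return [list(p) for p in items]

    def _on_category_generate(self, request: GenerationRequest) -> list[str]:
        pids = request.payload.get("paper_ids", [])
        cats: set[str] = set()
        tax = self.world.schema.taxonomy
        level1 = set(tax.children(tax.root))
        for pid in pids:
            facts = self.world.paper_facts.get(pid)
            if facts is None:
                continue
            for child, parent in facts.isa_facts:
                for node in (child, parent):
                    if tax.has_node(node):
                        cats |= (
                            tax.ancestors(node, include_self=True) & level1
                        )
        true_cats = sorted(cats)
        key = json.dumps(sorted(pids))
        pool_rng = self._pool_rng(request, key)
        pool = [
            f"spurious category {pool_rng.randrange(10**6)}"
            for _ in range(self.world.hallucination_pool_size)
        ]
        rng = self._sample_rng(request, key)
        noisy = self._apply_noise(true_cats, pool, rng)
        rng.shuffle(noisy)
        return noisy

    def _on_category_refine(self, request: GenerationRequest) -> list[str]:
        samples = request.payload.get("samples", [])
        counts: Counter[str] = Counter()
        for sample in samples:
            for label in dict.fromkeys(sample):
                counts[label] += 1
        ranked = sorted(counts, key=lambda c: (-counts[c], c))
        key = json.dumps(samples, sort_keys=True)
        rng = self._sample_rng(request, key)
        return [c for c in ranked if rng.random() >= self.world.omission_rate]

    def _on_relationship_query(self, request: GenerationRequest) -> list:
        facts = self._facts(request)
        taxonomy_terms = set(request.payload.get("taxonomy_terms", []))
        vocab = set(request.payload.get("vocabulary", []))
        true_pairs = [
            (parent, child)
            for child, parent in facts.isa_facts
            if parent in taxonomy_terms and (not vocab or child in vocab)
        ]
        key = json.dumps([facts.paper_id, sorted(taxonomy_terms)], sort_keys=True)
        pool_rng = self._pool_rng(request, key)
        gt_edges = self.world.schema.taxonomy.edges()
        pool = []
        candidates = self.world.term_pool
        for _ in range(self.world.hallucination_pool_size * 4):
            if len(pool) >= self.world.hallucination_pool_size:
                break
            a, b = pool_rng.sample(candidates, 2)
            if (b, a) not in gt_edges and (a, b) not in gt_edges:
                pool.append((a, b))  # (parent, child) spurious pair
        rng = self._sample_rng(request, key)
        items = self._apply_noise(sorted(true_pairs), pool, rng)
        return [list(p) for p in items]

    def _on_triple_extract(self, request: GenerationRequest) -> list:
        facts = self._facts(request)
        true_triples = sorted(
            (t.subject, t.predicate, t.object) for t in facts.relations
        )
        pool_rng = self._pool_rng(request, facts.paper_id)
        candidates = self.world.term_pool
        pool = []
        for _ in range(self.world.hallucination_pool_size):
            a, b = pool_rng.sample(candidates, 2)
            pool.append((a, f"spurious relation {pool_rng.randrange(100)}", b))
        rng = self._sample_rng(request, facts.paper_id)
        items = self._apply_noise(true_triples, pool, rng)
        return [list(t) for t in items]


# ---------------------------------------------------------------------------
# Live OpenAI-compatible backend
# ---------------------------------------------------------------------------

#: Editable per-role prompt templates; ``{payload_*}`` keys are formatted in.
DEFAULT_PROMPT_TEMPLATES: dict[str, str] = {
    "sentence_split": (
        "Split the following text into sentences, one per line.\n\n{text}"
    ),
    "term_extract": (
        "List every domain-specific term in this sentence, one per line, "
        "verbatim as written.\n\nSentence: {text}"
    ),
    "acronym_extract": (
        "List every acronym defined in this text as 'ACRONYM<TAB>expansion', "
        "one per line.\n\n{text}"
    ),
    "category_generate": (
        "Across the following papers, list the main high-level categories of "
        "the field, one per line.\n\n{text}"
    ),
    "category_refine": (
        "Given these candidate category lists, output a curated list of the "
        "most frequently occurring categories, one per line.\n\n{text}"
    ),
    "relationship_query": (
        "Given the paper, the current taxonomy terms and the vocabulary, "
        "output isA relationships as 'parent<TAB>term', one per line, where "
        "parent is an existing taxonomy term.\n\nPaper:\n{text}\n\n"
        "Taxonomy terms: {taxonomy_terms}\n\nVocabulary: {vocabulary}"
    ),
    "triple_extract": (
        "Extract subject<TAB>predicate<TAB>object triples from this text "
        "using only vocabulary terms, one per line.\n\n{text}\n\n"
        "Vocabulary: {vocabulary}"
    ),
}


class LiveBackend(GenerationBackend):
    """OpenAI-compatible chat-completions client (stdlib HTTP, line parser).

    Responses are requested in a line-delimited format and parsed tolerantly:
    blank lines, bullets and numbering are stripped; tab-separated roles
    (acronyms, relationships, triples) skip malformed lines.  Transport
    failures retry with backoff and raise :class:`TransportError` when
    exhausted.
    """

    def __init__(
        self,
        endpoint_url: str,
        model: str,
        api_key: str = "",
        temperature: float = 0.7,
        max_tokens: int = 1024,
        max_attempts: int = 3,
        templates: dict[str, str] | None = None,
    ) -> None:
        super().__init__()
        self.endpoint_url = endpoint_url
        self.model = model
        self.api_key = api_key
        self.temperature = temperature
        self.max_tokens = max_tokens
        self.max_attempts = max_attempts
        self.templates = dict(DEFAULT_PROMPT_TEMPLATES)
        if templates:
            self.templates.update(templates)

    def _prompt(self, request: GenerationRequest) -> str:
        tmpl = self.templates[request.prompt_role]
        payload = dict(request.payload)
        if "samples" in payload:
            payload.setdefault(
                "text",
                "\n\n".join(
                    ", ".join(s) for s in payload["samples"]
                ),
            )
        payload.setdefault("text", "")
        payload.setdefault("taxonomy_terms", "")
        payload.setdefault("vocabulary", "")
        return tmpl.format(
            text=payload["text"],
            taxonomy_terms=", ".join(payload.get("taxonomy_terms") or []),
            vocabulary=", ".join(payload.get("vocabulary") or []),
        )

    def _post(self, body: dict) -> dict:
        import urllib.request

        data = json.dumps(body).encode()
        req = urllib.request.Request(
            self.endpoint_url,
            data=data,
            headers={
                "Content-Type": "application/json",
                **(
                    {"Authorization": f"Bearer {self.api_key}"}
                    if self.api_key
                    else {}
                ),
            },
        )
        with urllib.request.urlopen(req, timeout=120) as resp:
            return json.loads(resp.read().decode())

    def _respond(self, request: GenerationRequest):
        body = {
            "model": self.model,
            "temperature": self.temperature,
            "max_tokens": self.max_tokens,
            "seed": request.seed + request.sample_index,
            "messages": [
                {"role": "user", "content": self._prompt(request)}
            ],
        }
        last_err: Exception | None = None
        for attempt in range(1, self.max_attempts + 1):
            try:
                raw = self._post(body)
                text = raw["choices"][0]["message"]["content"]
                return self._parse(request.prompt_role, text)
            except ParseError:
                raise
            except Exception as err:  # transport / schema failure
                last_err = err
                logger.warning(
                    "live backend attempt %d/%d failed: %s",
                    attempt,
                    self.max_attempts,
                    err,
                )
                time.sleep(min(2**attempt, 8))
        raise TransportError(f"live backend failed: {last_err}")

    @staticmethod
    def _parse(role: str, text: str):
        lines = []
        for raw_line in text.splitlines():
            line = raw_line.strip().lstrip("-*•").strip()
            line = line.lstrip("0123456789.").strip() if line[:1].isdigit() else line
            if line:
                lines.append(line)
        if role in ("sentence_split", "term_extract") or role in SEQUENCE_ROLES:
            return lines
        n_fields = {"acronym_extract": 2, "relationship_query": 2, "triple_extract": 3}[role]
        out = []
        skipped = 0
        for line in lines:
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) != n_fields:
                skipped += 1
                continue
            out.append(parts)
        if skipped:
            logger.warning("%s: skipped %d malformed lines", role, skipped)
        if not out and lines:
            raise ParseError(f"no parsable {role} lines", raw_text=text)
        return out
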
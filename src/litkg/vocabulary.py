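"""Stage 1: domain vocabulary extraction — terms, acronyms, lemmas.

Each paper is split into sentences, a backend proposes the terms present in
every sentence, and a verification filter discards any proposal that does
not actually occur in the source text — the guarantee that no hallucinated
surface form ever enters the vocabulary, whatever the backend emits.
Acronyms are extracted per paper and verified the same way; they become
aliases of their expansion's entry rather than independent concepts.

Surface forms are reduced to lemma keys (punctuation stripped, case-folded,
each token lemmatized by deterministic suffix rules) so spelling variants
such as "Single-Atom Catalysts" and "single atom catalyst" merge into one
concept.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .backend import (
    GenerationBackend,
    GenerationRequest,
    ParseError,
    self_consistent,
)
from .model import ValidationError

logger = logging.getLogger("litkg")


@dataclass(frozen=True)
class Document:
    """One corpus paper: an identifier and its plain text."""

    paper_id: str
    text: str


@dataclass(frozen=True, order=True)
class AcronymPair:
    """An acronym and its full expansion, both verbatim from the paper."""

    acronym: str
    expansion: str

    def __post_init__(self) -> None:
        if len(self.acronym) >= len(self.expansion):
            raise ValidationError(
                f"acronym {self.acronym!r} must be shorter than its expansion"
            )


# ---------------------------------------------------------------------------
# Normalization / lemmatization
# ---------------------------------------------------------------------------

#: Irregular inflections the suffix rules would mangle.
_LEMMA_EXCEPTIONS = {
    "species": "species",
    "gases": "gas",
    "analyses": "analysis",
    "syntheses": "synthesis",
    "hypotheses": "hypothesis",
    "matrices": "matrix",
    "vertices": "vertex",
    "indices": "index",
    "nuclei": "nucleus",
    "spectra": "spectrum",
    "media": "medium",
    "criteria": "criterion",
    "phenomena": "phenomenon",
    "data": "data",
    "series": "series",
}

_PUNCT_RE = re.compile(r"[^\w\s]|_")
_WS_RE = re.compile(r"\s+")


def _lemmatize_token(token: str) -> str:
    """Reduce an English token to a singular root by suffix rules."""
    if token in _LEMMA_EXCEPTIONS:
        return _LEMMA_EXCEPTIONS[token]
    n = len(token)
    if n > 4 and token.endswith("ies"):
        return token[:-3] + "y"
    if n > 4 and token.endswith(("sses", "shes", "ches", "xes", "zes", "oes")):
        return token[:-2]
    if n > 3 and token.endswith("s") and not token.endswith(("ss", "us", "is")):
        return token[:-1]
    return token


def normalize_term(surface: str) -> str:
    """Lemma key of a surface form: punctuation→space, case-fold, lemmatize.

    Deterministic and idempotent; "Single-Atom Catalysts" and "single atom
    catalyst" map to the same key.
    """
    if not surface or not surface.strip():
        raise ValidationError("cannot normalize an empty surface form")
    text = _PUNCT_RE.sub(" ", surface.casefold())
    tokens = [_lemmatize_token(t) for t in text.split()]
    if not tokens:
        raise ValidationError(f"surface form {surface!r} has no word content")
    return " ".join(tokens)


def _match_normalize(text: str) -> str:
    """Looser normalization used for verification matching (no lemmas)."""
    return _WS_RE.sub(" ", text.casefold().replace("-", " ")).strip()


def occurs_in(surface: str, text: str, matching: str = "normalized") -> bool:
    """Whether a proposed surface form occurs in the source text.

    ``normalized`` matching case-folds, maps hyphens to spaces and collapses
    whitespace on both sides before the substring test (the pipeline
    default, since hyphenated variants denote the same term); ``raw`` is an
    exact substring test.
    """
    if matching == "raw":
        return surface in text
    if matching == "normalized":
        return _match_normalize(surface) in _match_normalize(text)
    raise ValidationError(f"unknown matching mode {matching!r}")


# ---------------------------------------------------------------------------
# Sentence splitting
# ---------------------------------------------------------------------------

#: Dotted tokens that never end a sentence.
_ABBREVIATIONS = {
    "e.g", "i.e", "et al", "al", "etc", "cf", "vs", "ca", "approx",
    "fig", "figs", "eq", "eqs", "ref", "refs", "sec", "no", "dr", "prof",
    "mr", "ms",
}

_BOUNDARY_RE = re.compile(r"[.?!]+(?=\s)")


def _is_abbreviation(prefix: str) -> bool:
    tail = prefix.rstrip()
    word = tail.split()[-1] if tail.split() else ""
    word = word.lstrip("([\"'")
    if "." in word:  # dotted token like "e.g" mid-way
        return True
    if word.lower() in _ABBREVIATIONS:
        return True
    two = " ".join(tail.split()[-2:]).lower()
    return two in _ABBREVIATIONS


def split_sentences(
    paper_text: str, backend: GenerationBackend | None = None
) -> list[str]:
    """Ordered sentences of the text; abbreviation-aware and lossless.

    The default is a deterministic rule-based splitter (terminal
    punctuation followed by whitespace, with a guard list of dotted
    abbreviations); passing a backend delegates to its ``sentence_split``
    role instead.  Text without any boundary comes back as one sentence.
    """
    if not paper_text or not paper_text.strip():
        raise ValidationError("cannot split empty text")
    if backend is not None:
        return backend.generate(
            GenerationRequest(
                prompt_role="sentence_split", payload={"text": paper_text}
            )
        )
    cuts: list[int] = []
    for m in _BOUNDARY_RE.finditer(paper_text):
        if not _is_abbreviation(paper_text[: m.start()]):
            cuts.append(m.end())
    sentences = []
    start = 0
    for cut in cuts:
        chunk = paper_text[start:cut].strip()
        if chunk:
            sentences.append(chunk)
        start = cut
    tail = paper_text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences if sentences else [paper_text.strip()]


# ---------------------------------------------------------------------------
# Backend-driven extraction with verification
# ---------------------------------------------------------------------------


def extract_terms(
    sentence: str,
    backend: GenerationBackend,
    paper_id: str | None = None,
    m: int = 1,
    matching: str = "normalized",
    seed: int = 0,
) -> set[str]:
    """Verified surface forms the backend finds in one sentence.

    Every proposal failing the occurs-in verification is dropped and
    logged; a backend parse failure yields an empty set with a warning
    rather than aborting the stage.
    """
    request = GenerationRequest(
        prompt_role="term_extract",
        payload={"text": sentence, "paper_id": paper_id},
        seed=seed,
    )
    try:
        proposals = self_consistent(backend, request, m)
    except ParseError as err:
        logger.warning("term extraction parse failure (%s): %s", paper_id, err)
        return set()
    verified = set()
    for surface in proposals:
        if not isinstance(surface, str) or not surface.strip():
            continue
        if occurs_in(surface, sentence, matching):
            verified.add(surface.strip())
        else:
            logger.debug(
                "dropped hallucinated term %r (paper %s)", surface, paper_id
            )
    return verified


def extract_acronyms(
    paper_text: str,
    backend: GenerationBackend,
    paper_id: str | None = None,
    m: int = 1,
    matching: str = "normalized",
    seed: int = 0,
) -> set[AcronymPair]:
    """Verified (acronym, expansion) pairs for one paper.

    Both members must occur in the text and the acronym must be shorter
    than its expansion; anything else is dropped.
    """
    request = GenerationRequest(
        prompt_role="acronym_extract",
        payload={"text": paper_text, "paper_id": paper_id},
        seed=seed,
    )
    try:
        proposals = self_consistent(backend, request, m)
    except ParseError as err:
        logger.warning("acronym parse failure (%s): %s", paper_id, err)
        return set()
    pairs: set[AcronymPair] = set()
    for item in proposals:
        if not (isinstance(item, (list, tuple)) and len(item) == 2):
            continue
        acronym, expansion = (str(item[0]).strip(), str(item[1]).strip())
        if not acronym or not expansion or len(acronym) >= len(expansion):
            continue
        if occurs_in(acronym, paper_text, matching) and occurs_in(
            expansion, paper_text, matching
        ):
            pairs.add(AcronymPair(acronym, expansion))
        else:
            logger.debug("dropped unverified acronym pair %r (paper %s)", item, paper_id)
    return pairs


# ---------------------------------------------------------------------------
# Vocabulary container
# ---------------------------------------------------------------------------


@dataclass
class VocabularyEntry:
    """One merged concept: a lemma key with its surface forms and aliases."""

    lemma_key: str
    surface_forms: list[str] = field(default_factory=list)
    acronym_aliases: list[str] = field(default_factory=list)
    paper_ids: list[str] = field(default_factory=list)

    @property
    def canonical_surface(self) -> str:
        """Earliest-seen surface form in corpus order."""
        return self.surface_forms[0] if self.surface_forms else self.lemma_key


class Vocabulary:
    """Per-paper and merged vocabulary with acronym alias resolution."""

    def __init__(self) -> None:
        self.entries: dict[str, VocabularyEntry] = {}
        self.per_paper: dict[str, set[str]] = {}
        self.alias_map: dict[str, str] = {}  # acronym lemma -> expansion lemma

    def add_surface(self, surface: str, paper_id: str) -> str:
        key = normalize_term(surface)
        entry = self.entries.setdefault(key, VocabularyEntry(lemma_key=key))
        if surface not in entry.surface_forms:
            entry.surface_forms.append(surface)
        if paper_id not in entry.paper_ids:
            entry.paper_ids.append(paper_id)
        self.per_paper.setdefault(paper_id, set()).add(key)
        return key

    def add_acronym(self, pair: AcronymPair, paper_id: str) -> None:
        expansion_key = self.add_surface(pair.expansion, paper_id)
        acronym_key = normalize_term(pair.acronym)
        self.alias_map[acronym_key] = expansion_key
        entry = self.entries[expansion_key]
        if pair.acronym not in entry.acronym_aliases:
            entry.acronym_aliases.append(pair.acronym)

    def resolve(self, lemma_key: str) -> str:
        """Map an acronym lemma to its expansion lemma; identity otherwise."""
        return self.alias_map.get(lemma_key, lemma_key)

    def lemma_keys(self) -> set[str]:
        return set(self.entries)

    def paper_vocab(self, paper_id: str) -> set[str]:
        return set(self.per_paper.get(paper_id, set()))

    def __contains__(self, lemma_key: str) -> bool:
        return lemma_key in self.entries or lemma_key in self.alias_map

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Vocabulary):
            return NotImplemented
        return self.to_dict() == other.to_dict()

    def to_dict(self) -> dict:
        return {
            "entries": {
                k: {
                    "surface_forms": e.surface_forms,
                    "acronym_aliases": e.acronym_aliases,
                    "paper_ids": e.paper_ids,
                }
                for k, e in sorted(self.entries.items())
            },
            "alias_map": dict(sorted(self.alias_map.items())),
            "per_paper": {
                p: sorted(v) for p, v in sorted(self.per_paper.items())
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Vocabulary":
        v = cls()
        for key, body in d.get("entries", {}).items():
            v.entries[key] = VocabularyEntry(
                lemma_key=key,
                surface_forms=list(body.get("surface_forms", [])),
                acronym_aliases=list(body.get("acronym_aliases", [])),
                paper_ids=list(body.get("paper_ids", [])),
            )
        v.alias_map = dict(d.get("alias_map", {}))
        v.per_paper = {
            p: set(keys) for p, keys in d.get("per_paper", {}).items()
        }
        return v

    def to_tsv(self) -> str:
        lines = ["lemma_key\tcanonical_surface\tsurface_forms\tpaper_ids"]
        for key, e in sorted(self.entries.items()):
            lines.append(
                "\t".join(
                    [
                        key,
                        e.canonical_surface,
                        ";".join(e.surface_forms),
                        ";".join(e.paper_ids),
                    ]
                )
            )
        return "\n".join(lines) + "\n"


def build_vocabulary(
    papers: list[Document],
    backend: GenerationBackend,
    m: int = 1,
    matching: str = "normalized",
    split: bool = True,
    seed: int = 0,
) -> Vocabulary:
    """Extract, verify and merge the vocabulary of a whole corpus.

    Surface forms sharing a lemma key merge into one entry; acronym pairs
    attach as aliases of their expansion's entry; per-paper subsets are
    retained for the taxonomy stage.  ``split=False`` disables sentence
    splitting (whole-paper prompts), the ablation configuration.
    """
    if not papers:
        raise ValidationError("build_vocabulary requires a non-empty corpus")
    vocab = Vocabulary()
    for doc in papers:
        units = split_sentences(doc.text) if split else [doc.text]
        for sentence in units:
            for surface in sorted(
                extract_terms(
                    sentence,
                    backend,
                    paper_id=doc.paper_id,
                    m=m,
                    matching=matching,
                    seed=seed,
                )
            ):
                vocab.add_surface(surface, doc.paper_id)
        for pair in sorted(
            extract_acronyms(
                doc.text,
                backend,
                paper_id=doc.paper_id,
                m=m,
                matching=matching,
                seed=seed,
            )
        ):
            vocab.add_acronym(pair, doc.paper_id)
    return vocab
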
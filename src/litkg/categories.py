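"""Stage 2: top-level category extraction across the corpus.

The first taxonomy level cannot be read off a single paper, so a
long-context prompt presents a (shuffled, character-budgeted) sample of the
corpus and asks for the field's main categories.  Because long-context
models are order-sensitive, several samples are generated with independently
shuffled paper orders; a refinement pass then majority-votes the candidates
across repeated runs, and an explicit curation step selects the final set
that will seed the taxonomy as the root's direct children.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass

from .backend import (
    ConfigurationError,
    GenerationBackend,
    GenerationRequest,
    self_consistent,
)
from .model import ValidationError
from .vocabulary import Document, normalize_term

logger = logging.getLogger("litkg")


@dataclass
class CategoryCandidate:
    """A normalized category label with its cross-sample support count."""

    label: str
    support: int
    kept: bool = False


def _truncate(text: str, budget: int) -> str:
    """First ``budget`` characters, cut at a sentence boundary when possible.

    Papers enter the long-context prompt lead-section first (the corpus
    loader stores abstract+introduction up front), so a prefix keeps the
    category-bearing content.
    """
    if len(text) <= budget:
        return text
    cut = text.rfind(". ", 0, budget)
    return text[: cut + 1] if cut > 0 else text[:budget]


def generate_category_samples(
    papers: list[Document],
    backend: GenerationBackend,
    s_g: int,
    seed: int = 0,
    char_budget: int = 20000,
) -> tuple[list[list[str]], list[list[str]]]:
    """S_G category sequences, one per independently shuffled paper order.

    Returns ``(samples, permutations)`` where each sample is a list of
    normalized category labels and each permutation records the paper order
    presented, so runs are auditable and reproducible.
    """
    if s_g < 1:
        raise ConfigurationError("S_G must be >= 1")
    if not papers:
        raise ValidationError("category generation requires a non-empty corpus")
    per_paper_budget = max(200, char_budget // len(papers))
    samples: list[list[str]] = []
    permutations: list[list[str]] = []
    for i in range(s_g):
        rng = random.Random((seed, "category_shuffle", i).__repr__())
        order = list(papers)
        rng.shuffle(order)
        permutations.append([d.paper_id for d in order])
        request = GenerationRequest(
            prompt_role="category_generate",
            payload={
                "paper_ids": [d.paper_id for d in order],
                "texts": [_truncate(d.text, per_paper_budget) for d in order],
            },
            sample_index=i,
            seed=seed,
        )
        raw = backend.generate(request)
        labels = []
        for label in raw:
            if isinstance(label, str) and label.strip():
                key = normalize_term(label)
                if key not in labels:
                    labels.append(key)
        samples.append(labels)
    return samples, permutations


def refine_categories(
    samples: list[list[str]],
    backend: GenerationBackend,
    s_r: int,
    seed: int = 0,
) -> list[CategoryCandidate]:
    """Majority-voted, support-ranked candidates from the generation samples.

    The same refinement prompt (carrying the raw sample lists) runs S_R
    times; a label is kept iff it appears in a strict majority of the
    refinement answers.  Support is the label's occurrence count across the
    *generation* samples, and the returned sequence is ranked by
    non-increasing support (ties lexicographic) so manual curation can
    truncate at any rank.
    """
    if not samples:
        raise ValidationError("refinement requires at least one sample")
    if s_r < 1 or s_r % 2 == 0:
        raise ConfigurationError(f"S_R must be odd and >= 1, got {s_r}")
    request = GenerationRequest(
        prompt_role="category_refine",
        payload={"samples": [list(s) for s in samples]},
        seed=seed,
    )
    kept_labels = {
        normalize_term(label)
        for label in self_consistent(backend, request, s_r)
        if isinstance(label, str) and label.strip()
    }
    support: dict[str, int] = {}
    for sample in samples:
        for label in set(sample):
            support[label] = support.get(label, 0) + 1
    for label in kept_labels - set(support):
        support[label] = 1  # refinement may rephrase; still reportable
    ranked = sorted(support, key=lambda lb: (-support[lb], lb))
    return [
        CategoryCandidate(label=lb, support=support[lb], kept=lb in kept_labels)
        for lb in ranked
    ]


def curate(
    candidates: list[CategoryCandidate],
    keep: int | list[str] | str = "all",
) -> list[str]:
    """Deterministic final category selection.

    ``keep`` is either ``"all"`` (every kept candidate), an integer top-k
    over the kept candidates in rank order, or an explicit label subset
    (which must all be known candidates).  The selection is what the run
    manifest records and what becomes the root's children.
    """
    kept_ranked = [c.label for c in candidates if c.kept]
    if keep == "all":
        return kept_ranked
    if isinstance(keep, int):
        if keep < 1:
            raise ValidationError("top-k curation requires k >= 1")
        return kept_ranked[:keep]
    known = {c.label for c in candidates}
    requested = [normalize_term(lb) for lb in keep]
    unknown = [lb for lb in requested if lb not in known]
    if unknown:
        raise ValidationError(f"unknown category labels: {unknown}")
    order = {c.label: i for i, c in enumerate(candidates)}
    return sorted(set(requested), key=lambda lb: order[lb])


def candidates_tsv(candidates: list[CategoryCandidate]) -> str:
    lines = ["label\tsupport\tkept"]
    lines += [
        f"{c.label}\t{c.support}\t{int(c.kept)}" for c in candidates
    ]
    return "\n".join(lines) + "\n"
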
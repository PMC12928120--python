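"""End-to-end pipeline runner: config, stage orchestration, run artifacts.

The five stages (vocabulary → categories → taxonomy → KG instantiation →
relations) execute in order against a configured backend and serialize every
artifact into a run directory.  Stage completion is recorded in the run
manifest; ``resume=True`` reloads completed stages from disk instead of
recomputing them, which is the checkpoint mechanism for aborted runs.

A single config seed fans out into independent per-stage substreams, so any
stage is reproducible in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Literal

import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .backend import (
    CallLedger,
    GenerationBackend,
    LiveBackend,
    PlantedWorldBackend,
    ScriptedBackend,
)
from .categories import (
    candidates_tsv,
    curate,
    generate_category_samples,
    refine_categories,
)
from .evaluation import evaluate
from .kg import (
    extract_corpus_relations,
    instantiate_kg,
    merge_kg_ontology,
    merged_to_graphml,
    merged_to_ntriples,
)
from .model import KnowledgeGraph, Taxonomy, ValidationError
from .simulate import PlantedSpec, PlantedWorldResult, generate_planted_world
from .taxonomy import build_taxonomy, stats_tsv, unplaced_terms
from .vocabulary import Document, Vocabulary, build_vocabulary

logger = logging.getLogger("litkg")

STAGES = ("vocabulary", "categories", "taxonomy", "kg")


class PlantedConfig(BaseModel):
    depth: int = 4
    branching: float = 3.0
    multiparent_rate: float = 0.0
    n_terms: int = 60
    n_papers: int = 12
    facts_per_paper: int = 6
    coverage: float = 1.0
    relations_per_paper: int = 1
    fact_distribution: str = "by_level"
    omission_rate: float = 0.0
    hallucination_rate: float = 0.0


class LiveConfig(BaseModel):
    endpoint_url: str = "http://localhost:8000/v1/chat/completions"
    model: str = ""
    api_key: str = ""
    temperature: float = 0.7
    max_tokens: int = 1024


class PipelineConfig(BaseModel):
    """Validated run configuration (YAML-loadable; CLI flags mirror keys)."""

    backend: Literal["planted", "scripted", "live"] = "planted"
    out_dir: str = "runs/run"
    corpus_dir: str | None = None
    scripted_path: str | None = None
    k_iterations: int = Field(default=3, alias="K")
    m_samples: int = Field(default=3, alias="m")
    s_g: int = 5
    s_r: int = 3
    seed: int = 0
    split_sentences: bool = True
    matching: Literal["normalized", "raw"] = "normalized"
    curate_keep: int | list[str] | str = "all"
    quiet: bool = False
    planted: PlantedConfig = Field(default_factory=PlantedConfig)
    live: LiveConfig = Field(default_factory=LiveConfig)

    model_config = {"populate_by_name": True}

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if self.k_iterations < 1:
            raise ValueError("K (taxonomy iterations) must be >= 1")
        if self.m_samples < 1 or self.m_samples % 2 == 0:
            raise ValueError("m (self-consistency samples) must be odd, >= 1")
        if self.s_g < 1:
            raise ValueError("S_G must be >= 1")
        if self.s_r < 1 or self.s_r % 2 == 0:
            raise ValueError("S_R must be odd, >= 1")
        if self.backend == "scripted" and not self.scripted_path:
            raise ValueError("scripted backend requires scripted_path")
        if self.backend in ("scripted", "live") and not self.corpus_dir:
            raise ValueError(f"{self.backend} backend requires corpus_dir")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (below 2^31)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def load_corpus(corpus_dir: str) -> list[Document]:
    """One paper per UTF-8 text/Markdown file, in sorted filename order."""
    root = Path(corpus_dir)
    files = sorted(
        p for p in root.iterdir() if p.suffix.lower() in (".txt", ".md")
    )
    if not files:
        raise ValidationError(f"no .txt/.md papers found in {corpus_dir}")
    return [
        Document(paper_id=p.stem, text=p.read_text(encoding="utf-8"))
        for p in files
    ]


@dataclass
class RunResult:
    run_dir: Path
    vocabulary: Vocabulary
    categories: list[str]
    taxonomy: Taxonomy
    kg: KnowledgeGraph
    stats: list
    ledger: CallLedger
    metrics: dict | None = None
    planted: PlantedWorldResult | None = None
    manifest: dict = field(default_factory=dict)


def _build_backend(
    config: PipelineConfig,
) -> tuple[GenerationBackend, PlantedWorldResult | None, list[Document]]:
    if config.backend == "planted":
        spec = PlantedSpec(seed=config.seed, **config.planted.model_dump())
        result = generate_planted_world(spec)
        return PlantedWorldBackend(result.world), result, result.corpus
    corpus = load_corpus(config.corpus_dir)
    if config.backend == "scripted":
        return ScriptedBackend.from_yaml(config.scripted_path), None, corpus
    live = config.live
    return (
        LiveBackend(
            endpoint_url=live.endpoint_url,
            model=live.model,
            api_key=live.api_key,
            temperature=live.temperature,
            max_tokens=live.max_tokens,
        ),
        None,
        corpus,
    )


def _write(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(text, encoding="utf-8")


def run_pipeline(
    config: PipelineConfig,
    stages: tuple[str, ...] = STAGES,
    resume: bool = False,
) -> RunResult:
    """Execute the pipeline stages in order and serialize every artifact.

    ``stages`` restricts execution to a prefix-closed subset of
    vocabulary/categories/taxonomy/kg (earlier artifacts are loaded from
    the run directory when not recomputed); ``resume`` skips any stage
    whose artifacts already exist.
    """
    if config.quiet:
        logging.getLogger("litkg").setLevel(logging.WARNING)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValidationError(f"unknown stages: {sorted(unknown)}")
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    backend, planted, corpus = _build_backend(config)
    if planted is not None:
        for doc in planted.corpus:
            _write(run_dir / "corpus" / f"{doc.paper_id}.txt", doc.text)

    manifest: dict[str, Any] = {
        "package_version": __version__,
        "config": config.model_dump(),
        "config_hash": config.config_hash(),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "completed_stages": [],
    }

    def done(stage: str) -> bool:
        return resume and (run_dir / _STAGE_MARKER[stage]).exists()

    # -- stage 1: vocabulary ------------------------------------------------
    vocab_path = run_dir / "vocabulary.json"
    if "vocabulary" in stages and not done("vocabulary"):
        vocabulary = build_vocabulary(
            corpus,
            backend,
            m=1,
            matching=config.matching,
            split=config.split_sentences,
            seed=stage_seed(config.seed, "vocabulary"),
        )
        _write(vocab_path, json.dumps(vocabulary.to_dict(), indent=2))
        _write(run_dir / "vocabulary.tsv", vocabulary.to_tsv())
        manifest["completed_stages"].append("vocabulary")
    else:
        if not vocab_path.exists():
            raise ValidationError("vocabulary stage artifact missing; run it first")
        vocabulary = Vocabulary.from_dict(json.loads(vocab_path.read_text()))

    # -- stage 2: categories ------------------------------------------------
    cat_path = run_dir / "categories.json"
    if "categories" in stages and not done("categories"):
        samples, permutations = generate_category_samples(
            corpus,
            backend,
            s_g=config.s_g,
            seed=stage_seed(config.seed, "categories"),
        )
        candidates = refine_categories(
            samples,
            backend,
            s_r=config.s_r,
            seed=stage_seed(config.seed, "categories"),
        )
        categories = curate(candidates, config.curate_keep)
        if not categories:
            raise ValidationError("category stage produced no categories")
        _write(
            cat_path,
            json.dumps(
                {
                    "categories": categories,
                    "samples": samples,
                    "permutations": permutations,
                    "curate_keep": config.curate_keep,
                },
                indent=2,
            ),
        )
        _write(run_dir / "categories.tsv", candidates_tsv(candidates))
        manifest["category_permutations"] = permutations
        manifest["completed_stages"].append("categories")
    else:
        if not cat_path.exists():
            raise ValidationError("categories stage artifact missing; run it first")
        categories = json.loads(cat_path.read_text())["categories"]

    # -- stage 3: taxonomy --------------------------------------------------
    tax_path = run_dir / "taxonomy.json"
    stats: list = []
    if "taxonomy" in stages and not done("taxonomy"):

        def snapshot(k: int, tax: Taxonomy, _stats) -> None:
            _write(run_dir / f"taxonomy_iter_{k}.json", tax.to_json())

        taxonomy, stats = build_taxonomy(
            corpus,
            vocabulary,
            categories,
            backend,
            k_iterations=config.k_iterations,
            m=config.m_samples,
            seed=stage_seed(config.seed, "taxonomy"),
            on_iteration=snapshot,
        )
        surface_forms = {
            k: e.surface_forms
            for k, e in vocabulary.entries.items()
            if taxonomy.has_node(k)
        }
        _write(
            tax_path,
            taxonomy.to_json(
                instances=sorted(taxonomy.leaves() - {taxonomy.root}),
                surface_forms=surface_forms,
            ),
        )
        _write(run_dir / "stats.tsv", stats_tsv(stats))
        _write(
            run_dir / "unplaced_terms.json",
            json.dumps(sorted(unplaced_terms(vocabulary, taxonomy)), indent=2),
        )
        manifest["completed_stages"].append("taxonomy")
    else:
        if not tax_path.exists():
            raise ValidationError("taxonomy stage artifact missing; run it first")
        taxonomy = Taxonomy.from_json(tax_path.read_text())

    # -- stages 4+5: KG instantiation and relations -------------------------
    kg_path = run_dir / "kg.json"
    if "kg" in stages and not done("kg"):
        schema, kg = instantiate_kg(taxonomy)
        kg.relations = extract_corpus_relations(
            corpus,
            vocabulary,
            backend,
            m=config.m_samples,
            seed=stage_seed(config.seed, "kg"),
        )
        _write(kg_path, kg.to_json())
        _write(run_dir / "relations.tsv", kg.relations_tsv())
        merged = merge_kg_ontology(kg, taxonomy)
        merged_to_graphml(merged, str(run_dir / "merged.graphml"))
        _write(run_dir / "merged.nt", merged_to_ntriples(merged))
        manifest["completed_stages"].append("kg")
    else:
        if not kg_path.exists():
            raise ValidationError("kg stage artifact missing; run it first")
        kg = KnowledgeGraph.from_json(kg_path.read_text())

    # -- evaluation against the planted truth, ledger, manifest -------------
    metrics_dict = None
    if planted is not None and {"taxonomy", "kg"} <= set(stages):
        report = evaluate(
            planted.schema.taxonomy, taxonomy, planted.kg, kg
        )
        metrics_dict = report.to_dict()
        _write(run_dir / "metrics.json", report.to_json())
        _write(run_dir / "metrics.txt", report.format_table() + "\n")

    _write(run_dir / "ledger.json", json.dumps(backend.ledger.to_dict(), indent=2))
    _write(run_dir / "manifest.json", json.dumps(manifest, indent=2, default=str))
    return RunResult(
        run_dir=run_dir,
        vocabulary=vocabulary,
        categories=categories,
        taxonomy=taxonomy,
        kg=kg,
        stats=stats,
        ledger=backend.ledger,
        metrics=metrics_dict,
        planted=planted,
        manifest=manifest,
    )


_STAGE_MARKER = {
    "vocabulary": "vocabulary.json",
    "categories": "categories.json",
    "taxonomy": "taxonomy.json",
    "kg": "kg.json",
}
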
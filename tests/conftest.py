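import pytest

from litkg import GenerationBackend, PlantedSpec, Taxonomy, generate_planted_world


class StaticBackend(GenerationBackend):
    """Returns a fixed response per prompt role, regardless of payload."""

    def __init__(self, responses: dict):
        super().__init__()
        self.responses = responses

    def _respond(self, request):
        return self.responses.get(request.prompt_role, [])


@pytest.fixture
def chain_taxonomy() -> Taxonomy:
    """thing -> a -> b -> c"""
    return Taxonomy.from_edges([("a", "thing"), ("b", "a"), ("c", "b")])


@pytest.fixture
def diamond_taxonomy() -> Taxonomy:
    """c reachable from the root through both a and b."""
    return Taxonomy.from_edges(
        [("a", "thing"), ("b", "thing"), ("c", "a"), ("c", "b")]
    )


@pytest.fixture(scope="session")
def planted_small():
    """A small noise-free planted world (depth 3) for fast stage tests."""
    spec = PlantedSpec(
        depth=3,
        branching=2.5,
        n_terms=20,
        n_papers=6,
        facts_per_paper=5,
        seed=7,
    )
    return generate_planted_world(spec)


@pytest.fixture(scope="session")
def planted_default():
    """The study-condition world: depth 4, ~60 terms, full coverage,
    facts staged adversarially by depth level."""
    return generate_planted_world(PlantedSpec(seed=11))
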
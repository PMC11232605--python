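import numpy as np
import pytest

from sepsaki.kg import KnowledgeGraph
from sepsaki.simulate import KGSpec, make_kg


@pytest.fixture
def rng():
    return np.random.default_rng(20240628)


@pytest.fixture
def toy_graph():
    """3 entities, 2 relations, hand-written triples."""
    return KnowledgeGraph.from_triples([
        ("a", "r0", "b"),
        ("b", "r1", "c"),
        ("a", "r1", "c"),
    ])


@pytest.fixture(scope="session")
def planted_kg():
    """Default planted-community graph plus its community assignment."""
    return make_kg(KGSpec(seed=11))


def random_small_graph(rng, max_entities=10):
    """Random multigraph for oracle comparisons (>=2 entities)."""
    n = int(rng.integers(2, max_entities + 1))
    n_rel = int(rng.integers(1, 4))
    ents = [f"e{i}" for i in range(n)]
    rels = [f"r{k}" for k in range(n_rel)]
    triples = set()
    for r in rels:
        for i in range(n):
            for j in range(n):
                if i != j and rng.random() < 0.3:
                    triples.add((ents[i], r, ents[j]))
    if not triples:
        triples.add((ents[0], rels[0], ents[1]))
    return KnowledgeGraph(tuple(ents), tuple(rels), frozenset(triples))
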
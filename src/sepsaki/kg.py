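"""Knowledge-graph container, triple-list I/O and negative sampling.

The graph g = (ε, R) is a set of typed triples (head, relation, tail) over
clinical concept entities.  Neighbourhoods N_i^r are undirected: j is a
neighbour of i under relation r if either (i, r, j) or (j, r, i) is a
triple — the graph convolution aggregates information regardless of edge
direction, while the DistMult scorer keeps direction (its diagonal
relation matrix makes scores head/tail symmetric anyway).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import GraphLookupError, SamplingError, ValidationError

Triple = tuple[str, str, str]

__all__ = ["KnowledgeGraph", "TripleBatch", "read_triples", "write_triples",
           "sample_negatives"]


@dataclass(frozen=True)
class KnowledgeGraph:
    """Entities, relations and the triple set, with per-relation
    neighbourhood lookup."""

    entities: tuple[str, ...]
    relations: tuple[str, ...]
    triples: frozenset[Triple]
    _neighbors: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        ents, rels = set(self.entities), set(self.relations)
        for h, r, t in self.triples:
            if h not in ents or t not in ents:
                raise ValidationError(
                    f"triple ({h}, {r}, {t}) references unknown entity")
            if r not in rels:
                raise ValidationError(
                    f"triple ({h}, {r}, {t}) references unknown relation")
        nbrs: dict[tuple[str, str], set[str]] = {}
        for h, r, t in self.triples:
            nbrs.setdefault((h, r), set()).add(t)
            nbrs.setdefault((t, r), set()).add(h)
        object.__setattr__(self, "_neighbors", nbrs)

    @classmethod
    def from_triples(cls, triples) -> "KnowledgeGraph":
        """Build a graph whose entity/relation sets are exactly those
        appearing in `triples` (sorted for determinism)."""
        triples = frozenset(tuple(t) for t in triples)
        if not triples:
            raise ValidationError("cannot build a graph from zero triples")
        ents = sorted({h for h, _, _ in triples}
                      | {t for _, _, t in triples})
        rels = sorted({r for _, r, _ in triples})
        return cls(tuple(ents), tuple(rels), triples)

    @property
    def n_entities(self) -> int:
        return len(self.entities)

    @property
    def n_relations(self) -> int:
        return len(self.relations)

    def neighbors(self, entity: str, relation: str) -> frozenset:
        """N_i^r — undirected neighbours of `entity` under `relation`."""
        if entity not in set(self.entities):
            raise GraphLookupError(f"unknown entity {entity!r}")
        if relation not in set(self.relations):
            raise GraphLookupError(f"unknown relation {relation!r}")
        return frozenset(self._neighbors.get((entity, relation), set()))

    def entity_index(self) -> dict[str, int]:
        return {e: i for i, e in enumerate(self.entities)}

    def relation_index(self) -> dict[str, int]:
        return {r: i for i, r in enumerate(self.relations)}


@dataclass(frozen=True)
class TripleBatch:
    """Labelled triples for training: y = 1 for true triples, 0 for
    corrupted ones."""
    items: tuple[tuple[Triple, int], ...]

    def __post_init__(self):
        for (_, _, _), y in self.items:
            if y not in (0, 1):
                raise ValidationError(f"triple label must be 0/1, got {y}")

    def __len__(self) -> int:
        return len(self.items)


def read_triples(path) -> KnowledgeGraph:
    """Read a 3-column, tab-separated, headerless triple list (UTF-8)."""
    triples = []
    for lineno, line in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValidationError(
                f"{path}:{lineno}: expected 3 tab-separated columns "
                f"(head, relation, tail), got {len(parts)}")
        triples.append(tuple(p.strip() for p in parts))
    return KnowledgeGraph.from_triples(triples)


def write_triples(graph: KnowledgeGraph, path) -> None:
    """Write the triple list as sorted 3-column TSV (deterministic)."""
    lines = [f"{h}\t{r}\t{t}" for h, r, t in sorted(graph.triples)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def sample_negatives(graph: KnowledgeGraph, k_per_positive: int,
                     seed: int, max_retries: int = 100) -> TripleBatch:
    """Uniform head-or-tail corruption with filtering.

    For every true triple, draw `k_per_positive` corruptions by replacing
    the head or the tail (coin flip) with an entity chosen uniformly;
    corruptions that are themselves true triples, or identical to the
    original, are rejected and redrawn up to `max_retries` times.
    """
    if graph.n_entities < 2:
        raise ValidationError("need at least 2 entities to corrupt triples")
    rng = np.random.default_rng(seed)
    entities = graph.entities
    items: list[tuple[Triple, int]] = []
    for h, r, t in sorted(graph.triples):
        for _ in range(k_per_positive):
            for attempt in range(max_retries):
                corrupt_head = rng.random() < 0.5
                e = entities[rng.integers(len(entities))]
                cand = (e, r, t) if corrupt_head else (h, r, e)
                if cand != (h, r, t) and cand not in graph.triples:
                    items.append((cand, 0))
                    break
            else:
                raise SamplingError(
                    f"could not corrupt triple ({h}, {r}, {t}) in "
                    f"{max_retries} attempts; graph too dense")
    return TripleBatch(tuple(items))
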
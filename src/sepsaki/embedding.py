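"""Entity embeddings on a clinical knowledge graph.

Two relational graph-convolution layers propagate entity vectors along
typed edges,

    h_i <- ReLU( sum_r sum_{j in N_i^r} (1/|N_i^r|) W_r h_j  +  W_o h_i ),

triples are scored by DistMult with a diagonal relation matrix,

    s(e_i, r, e_j) = sigmoid( h_{e_i}^T R_r h_{e_j} ),

and all parameters (initial vectors, layer weights, relation diagonals)
are trained to separate true triples from uniformly corrupted ones under
the cross-entropy triple loss

    L_g = -(1/(2|Gamma|)) * sum [ y log s + (1-y) log(1-s) ].

A patient's knowledge feature x^k is the mean of the final-layer
embeddings of the concepts linked to that patient.

`KGEmbeddingModel` is the statsmodels-style entry point: construct it
from a `KnowledgeGraph`, call `fit()` and work with the returned
`KGEmbeddingResults`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from ._autodiff import Tensor, gather_rows
from ._util import atomic_write_text, child_seed
from .exceptions import (ConfigError, GraphLookupError, TrainingError,
                         ValidationError)
from .kg import KnowledgeGraph, TripleBatch, sample_negatives

EPS = 1e-12  # probability clipping inside logs

__all__ = ["EmbeddingState", "init_embeddings", "relu", "gcn_layer",
           "propagate", "distmult_score", "kg_loss", "train_kg",
           "extract_knowledge_features", "KGEmbeddingModel",
           "KGEmbeddingResults"]


@dataclass
class EmbeddingState:
    """All trainable arrays of the embedding model.

    `g` holds the initial entity vectors, `h` the current (after
    propagation, final-layer) vectors; `w_rel[l, r]` and `w_self[l]` are
    the relation/self weight matrices of layer l; `r_diag[r]` the
    diagonal of the DistMult relation matrix R_r.
    """
    entities: tuple[str, ...]
    relations: tuple[str, ...]
    d_e: int
    n_layers: int
    seed: int
    g: np.ndarray        # (n_entities, d_e)
    w_rel: np.ndarray    # (n_layers, n_relations, d_e, d_e)
    w_self: np.ndarray   # (n_layers, d_e, d_e)
    r_diag: np.ndarray   # (n_relations, d_e)
    h: np.ndarray = field(default=None)  # (n_entities, d_e)
    _ent_idx: dict = field(init=False, repr=False)
    _rel_idx: dict = field(init=False, repr=False)

    def __post_init__(self):
        if self.h is None:
            self.h = self.g.copy()
        for arr in (self.g, self.w_rel, self.w_self, self.r_diag, self.h):
            if not np.all(np.isfinite(arr)):
                raise ValidationError("embedding state has non-finite entries")
        self._ent_idx = {e: i for i, e in enumerate(self.entities)}
        self._rel_idx = {r: i for i, r in enumerate(self.relations)}

    def entity_vector(self, entity: str) -> np.ndarray:
        try:
            return self.h[self._ent_idx[entity]]
        except KeyError:
            raise GraphLookupError(f"unknown entity {entity!r}") from None

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "format": "sepsaki-kg-state", "version": 1,
            "d_e": self.d_e, "n_layers": self.n_layers, "seed": self.seed,
            "entities": list(self.entities),
            "relations": list(self.relations),
            "g": self.g.tolist(), "w_rel": self.w_rel.tolist(),
            "w_self": self.w_self.tolist(), "r_diag": self.r_diag.tolist(),
            "h": self.h.tolist(),
        }
        return json.dumps(payload)

    def save(self, path) -> None:
        atomic_write_text(path, self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "EmbeddingState":
        d = json.loads(text)
        if d.get("format") != "sepsaki-kg-state":
            raise ValidationError("not a sepsaki knowledge-graph state file")
        return cls(entities=tuple(d["entities"]),
                   relations=tuple(d["relations"]),
                   d_e=d["d_e"], n_layers=d["n_layers"], seed=d["seed"],
                   g=np.array(d["g"]), w_rel=np.array(d["w_rel"]),
                   w_self=np.array(d["w_self"]),
                   r_diag=np.array(d["r_diag"]), h=np.array(d["h"]))

    @classmethod
    def load(cls, path) -> "EmbeddingState":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def relu(x):
    """ReLU activation: 0 for x < 0, x otherwise."""
    return np.maximum(x, 0.0)


def init_embeddings(graph: KnowledgeGraph, d_e: int, seed: int,
                    n_layers: int = 2) -> EmbeddingState:
    """Random initial state: zero-mean normals with scale 1/sqrt(d_e)."""
    if d_e < 1:
        raise ConfigError(f"embedding dimension must be >= 1, got {d_e}")
    if n_layers < 1:
        raise ConfigError(f"need at least one layer, got {n_layers}")
    if graph.n_entities == 0:
        raise ValidationError("cannot embed an empty graph")
    rng = np.random.default_rng(seed)
    scale = 1.0 / np.sqrt(d_e)
    n, nr = graph.n_entities, graph.n_relations
    return EmbeddingState(
        entities=graph.entities, relations=graph.relations,
        d_e=d_e, n_layers=n_layers, seed=seed,
        g=rng.normal(0.0, scale, (n, d_e)),
        w_rel=rng.normal(0.0, scale, (n_layers, nr, d_e, d_e)),
        w_self=rng.normal(0.0, scale, (n_layers, d_e, d_e)),
        r_diag=rng.normal(0.0, scale, (nr, d_e)),
    )


def _norm_adjacency(graph: KnowledgeGraph) -> np.ndarray:
    """Per-relation row-normalised adjacency A[r, i, j] = 1/|N_i^r| for
    j in N_i^r (undirected neighbourhoods); empty rows stay zero."""
    n = graph.n_entities
    ent_idx = graph.entity_index()
    out = np.zeros((graph.n_relations, n, n))
    for ri, rel in enumerate(graph.relations):
        for ei, ent in enumerate(graph.entities):
            nbrs = graph.neighbors(ent, rel)
            if nbrs:
                w = 1.0 / len(nbrs)
                for nb in nbrs:
                    out[ri, ei, ent_idx[nb]] = w
    return out


def gcn_layer(state: EmbeddingState, graph: KnowledgeGraph,
              layer: int, h: Optional[np.ndarray] = None) -> np.ndarray:
    """One relational graph-convolution layer applied to `h` (defaults to
    the state's current vectors).  Returns the updated (n, d_e) array;
    does not mutate the state."""
    if not 0 <= layer < state.n_layers:
        raise ConfigError(f"no weights for layer {layer}")
    h = state.h if h is None else np.asarray(h, dtype=float)
    if h.shape != (len(state.entities), state.d_e):
        raise ConfigError(
            f"entity-vector array has shape {h.shape}, expected "
            f"{(len(state.entities), state.d_e)}")
    adj = _norm_adjacency(graph)
    pre = h @ state.w_self[layer].T
    for ri in range(graph.n_relations):
        pre = pre + adj[ri] @ h @ state.w_rel[layer, ri].T
    return relu(pre)


def propagate(state: EmbeddingState, graph: KnowledgeGraph) -> np.ndarray:
    """Run all layers from the initial vectors; stores and returns the
    final-layer embeddings."""
    h = state.g
    for layer in range(state.n_layers):
        h = gcn_layer(state, graph, layer, h)
    state.h = h
    return h


def distmult_score(state: EmbeddingState, head: str, relation: str,
                   tail: str) -> float:
    """sigmoid(h_head^T diag(r_diag) h_tail) using the final-layer
    embeddings."""
    hi = state.entity_vector(head)
    hj = state.entity_vector(tail)
    try:
        rd = state.r_diag[state._rel_idx[relation]]
    except KeyError:
        raise GraphLookupError(f"unknown relation {relation!r}") from None
    return float(1.0 / (1.0 + np.exp(-np.sum(hi * rd * hj))))


def kg_loss(batch: TripleBatch, state: EmbeddingState) -> float:
    """Cross-entropy triple loss with the 1/(2|Gamma|) normalisation."""
    if len(batch) == 0:
        raise ValidationError("empty triple batch")
    total = 0.0
    for (h, r, t), y in batch.items:
        s = np.clip(distmult_score(state, h, r, t), EPS, 1.0 - EPS)
        total += y * np.log(s) + (1 - y) * np.log(1.0 - s)
    return float(-total / (2.0 * len(batch)))


# -- training ------------------------------------------------------------

def _forward_loss(params: dict[str, Tensor], adj: np.ndarray,
                  n_layers: int, heads, rels, tails, labels) -> Tensor:
    """Autodiff forward pass: propagate, score the batch, Eq.-style loss."""
    h = params["g"]
    for layer in range(n_layers):
        pre = h @ params[f"w_self_{layer}"].T
        for ri in range(adj.shape[0]):
            pre = pre + Tensor(adj[ri]) @ h @ params[
                f"w_rel_{layer}_{ri}"].T
        h = pre.relu()
    hi = gather_rows(h, heads)
    hj = gather_rows(h, tails)
    rd = gather_rows(params["r_diag"], rels)
    logits = (hi * rd * hj).sum(axis=1)
    s = logits.sigmoid().clip(EPS, 1.0 - EPS)
    y = np.asarray(labels, dtype=float)
    ll = Tensor(y) * s.log() + Tensor(1.0 - y) * (1.0 - s).log()
    return -ll.sum() / (2.0 * len(labels))


@dataclass
class KGEmbeddingResults:
    """Fitted embedding results: the trained state, the per-epoch loss
    trace and held-out triple-classification quality."""
    state: EmbeddingState
    loss_trace: np.ndarray
    holdout_auc: Optional[float]
    holdout_accuracy: Optional[float]
    config: dict

    def knowledge_features(
            self, links: Sequence[str]) -> np.ndarray:
        return extract_knowledge_features(links, self.state)

    def summary(self) -> str:
        lines = [
            "Knowledge-graph embedding (relational GCN + DistMult)",
            "=" * 54,
            f"entities:            {len(self.state.entities)}",
            f"relations:           {len(self.state.relations)}",
            f"embedding dim d_e:   {self.state.d_e}",
            f"layers:              {self.state.n_layers}",
            f"epochs:              {len(self.loss_trace)}",
            f"final triple loss:   {self.loss_trace[-1]:.6f}",
        ]
        if self.holdout_auc is not None:
            lines.append(f"held-out triple AUC: {self.holdout_auc:.4f}")
            lines.append(
                f"held-out accuracy:   {self.holdout_accuracy:.4f}")
        return "\n".join(lines)


class KGEmbeddingModel:
    """Knowledge-graph embedding model over a fixed graph.

    Parameters
    ----------
    graph : KnowledgeGraph
        The triple set to embed.
    d_e : int
        Embedding dimension (default 16).
    n_layers : int
        Number of graph-convolution layers (default 2).
    """

    def __init__(self, graph: KnowledgeGraph, d_e: int = 16,
                 n_layers: int = 2):
        if graph.n_entities < 2:
            raise ValidationError("graph needs at least 2 entities")
        self.graph = graph
        self.d_e = d_e
        self.n_layers = n_layers

    def fit(self, epochs: int = 200, learning_rate: float = 2.0,
            negatives_per_positive: int = 2, seed: int = 0,
            holdout_fraction: float = 0.1) -> KGEmbeddingResults:
        """Full-batch SGD on the triple cross-entropy loss.

        A `holdout_fraction` of true triples is held out before training
        (with matched corruptions) to report triple-classification AUC
        and accuracy; set it to 0 to train on everything.
        """
        if epochs < 0 or learning_rate < 0:
            raise ConfigError("epochs and learning rate must be >= 0")
        rng = np.random.default_rng(child_seed(seed, "kg-split"))
        all_triples = sorted(self.graph.triples)
        perm = rng.permutation(len(all_triples))
        n_hold = int(round(holdout_fraction * len(all_triples)))
        n_hold = min(n_hold, len(all_triples) - 1)
        hold = [all_triples[i] for i in perm[:n_hold]]
        train = [all_triples[i] for i in perm[n_hold:]]
        train_graph = KnowledgeGraph(self.graph.entities,
                                     self.graph.relations,
                                     frozenset(train))
        state = init_embeddings(train_graph, self.d_e,
                                child_seed(seed, "kg-init"),
                                self.n_layers)
        adj = _norm_adjacency(train_graph)
        ent_idx = train_graph.entity_index()
        rel_idx = train_graph.relation_index()

        params = {"g": Tensor(state.g, requires_grad=True),
                  "r_diag": Tensor(state.r_diag, requires_grad=True)}
        for layer in range(self.n_layers):
            params[f"w_self_{layer}"] = Tensor(state.w_self[layer],
                                               requires_grad=True)
            for ri in range(train_graph.n_relations):
                params[f"w_rel_{layer}_{ri}"] = Tensor(
                    state.w_rel[layer, ri], requires_grad=True)

        trace: list[float] = []
        for epoch in range(epochs):
            neg = sample_negatives(train_graph, negatives_per_positive,
                                   child_seed(seed, f"kg-neg-{epoch}"))
            batch = [((h, r, t), 1) for h, r, t in train] + list(neg.items)
            heads = [ent_idx[h] for (h, _, _), _ in batch]
            rels = [rel_idx[r] for (_, r, _), _ in batch]
            tails = [ent_idx[t] for (_, _, t), _ in batch]
            labels = [y for _, y in batch]
            for p in params.values():
                p.grad = None
            loss = _forward_loss(params, adj, self.n_layers,
                                 heads, rels, tails, labels)
            if not np.isfinite(loss.value):
                raise TrainingError(
                    f"non-finite triple loss at epoch {epoch}",
                    trace=np.array(trace))
            loss.backward()
            if learning_rate > 0:
                for p in params.values():
                    p.value = p.value - learning_rate * p.grad
            trace.append(float(loss.value))

        # write trained arrays back into the state and propagate
        state.g = params["g"].value
        state.r_diag = params["r_diag"].value
        for layer in range(self.n_layers):
            state.w_self[layer] = params[f"w_self_{layer}"].value
            for ri in range(train_graph.n_relations):
                state.w_rel[layer, ri] = params[f"w_rel_{layer}_{ri}"].value
        propagate(state, train_graph)

        holdout_auc = holdout_acc = None
        if hold:
            neg = sample_negatives(
                self.graph, 1, child_seed(seed, "kg-holdout-neg"))
            neg_items = list(neg.items)[:len(hold)]
            scores, labels = [], []
            for h, r, t in hold:
                scores.append(distmult_score(state, h, r, t))
                labels.append(1)
            for (h, r, t), _ in neg_items:
                scores.append(distmult_score(state, h, r, t))
                labels.append(0)
            holdout_auc = float(roc_auc_score(labels, scores))
            holdout_acc = float(np.mean(
                (np.array(scores) >= 0.5).astype(int) == np.array(labels)))

        config = {"d_e": self.d_e, "n_layers": self.n_layers,
                  "epochs": epochs, "learning_rate": learning_rate,
                  "negatives_per_positive": negatives_per_positive,
                  "seed": seed, "holdout_fraction": holdout_fraction}
        return KGEmbeddingResults(state=state,
                                  loss_trace=np.array(trace),
                                  holdout_auc=holdout_auc,
                                  holdout_accuracy=holdout_acc,
                                  config=config)


def train_kg(graph: KnowledgeGraph, config: dict) -> KGEmbeddingResults:
    """Functional wrapper: `config` supplies d_e, n_layers, epochs,
    learning_rate, negatives_per_positive, seed, holdout_fraction."""
    model = KGEmbeddingModel(graph, d_e=config.get("d_e", 16),
                             n_layers=config.get("n_layers", 2))
    return model.fit(
        epochs=config.get("epochs", 200),
        learning_rate=config.get("learning_rate", 2.0),
        negatives_per_positive=config.get("negatives_per_positive", 2),
        seed=config.get("seed", 0),
        holdout_fraction=config.get("holdout_fraction", 0.1))


def extract_knowledge_features(patient_links: Sequence[str],
                               state: EmbeddingState) -> np.ndarray:
    """Patient knowledge feature x^k: the mean of the final-layer
    embeddings of the linked concepts; a zero vector (with a warning)
    when the patient has no links."""
    if len(patient_links) == 0:
        warnings.warn("patient has no concept links; knowledge feature "
                      "is the zero vector", stacklevel=2)
        return np.zeros(state.d_e)
    vecs = [state.entity_vector(e) for e in patient_links]
    return np.mean(vecs, axis=0)
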
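"""Translational graph embeddings and similarity-based retrieval.

Entities and relation types are embedded in a common real vector space
such that for an observed triple (h, r, t) the translated head vector
v_h + v_r lies close to the tail vector v_t; plausibility is scored as
the negative distance -||v_h + v_r - v_t||.  Training minimizes the
margin ranking loss

    sum over observed triples of  max(0, margin + d(h,r,t) - d(h',r,t'))

against corrupted negatives, by mini-batch stochastic gradient
descent.  Negatives corrupt the head or the tail with equal
probability, sampling uniformly over nodes of the type the relation's
schema permits at that endpoint — stricter than uniform corruption
over all nodes, and appropriate for a strongly typed graph.  Entity
vectors are renormalized to unit norm after every epoch.  Training is
deterministic given the seed.

Retrieval ranks entity pairs by cosine similarity of their embeddings;
repurposing candidates are condition/drug-term pairs ranked the same
way after excluding pairs already connected through a shared study.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import KnowledgeGraph

__all__ = [
    "TrainConfig",
    "EmbeddingTable",
    "train",
    "score_triple",
    "topk_similar",
    "repurposing_candidates",
    "hits_at_k",
    "costudied_pairs",
]


@dataclass
class TrainConfig:
    """TransE training hyperparameters.

    Defaults are desk-scale: 200-dimensional embeddings, L2 distance,
    margin 1.0, learning rate 0.01, 200 epochs, one negative per
    positive.  ``seed`` fixes initialization and all sampling.
    """

    dim: int = 200
    margin: float = 1.0
    norm_order: int = 2
    learning_rate: float = 0.01
    epochs: int = 200
    negatives_per_positive: int = 1
    batch_size: int = 256
    seed: int = 0

    def validate(self) -> None:
        if min(self.dim, self.epochs, self.negatives_per_positive,
               self.batch_size) <= 0:
            raise ValueError("dim/epochs/negatives/batch size must be positive")
        if self.margin <= 0 or self.learning_rate <= 0:
            raise ValueError("margin and learning rate must be positive")
        if self.norm_order not in (1, 2):
            raise ValueError("norm_order must be 1 or 2")


@dataclass
class EmbeddingTable:
    """Per-entity and per-relation vectors plus the node-type map."""

    entity_ids: list[str]
    entity_vectors: np.ndarray          # (n_entities, dim)
    relation_names: list[str]
    relation_vectors: np.ndarray        # (n_relations, dim)
    entity_types: dict[str, str]
    config: TrainConfig
    loss_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._entity_index = {e: i for i, e in enumerate(self.entity_ids)}
        self._relation_index = {r: i for i, r in enumerate(self.relation_names)}

    def vector(self, entity_id: str) -> np.ndarray:
        return self.entity_vectors[self._entity_index[entity_id]]

    def relation_vector(self, relation: str) -> np.ndarray:
        return self.relation_vectors[self._relation_index[relation]]

    def ids_of_type(self, node_type: str) -> list[str]:
        return sorted(e for e, t in self.entity_types.items()
                      if t == node_type)

    def save(self, path) -> None:
        dim = self.entity_vectors.shape[1]
        cols = [f"d{i}" for i in range(dim)]
        rows = []
        for i, eid in enumerate(self.entity_ids):
            rows.append(["entity", eid, self.entity_types[eid],
                         *self.entity_vectors[i]])
        for i, rel in enumerate(self.relation_names):
            rows.append(["relation", rel, "", *self.relation_vectors[i]])
        pd.DataFrame(rows, columns=["kind", "id", "node_type", *cols]).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "EmbeddingTable":
        df = pd.read_csv(path, sep="\t", dtype={"kind": str, "id": str,
                                                "node_type": str})
        dims = [c for c in df.columns if c.startswith("d")]
        ent = df[df["kind"] == "entity"]
        rel = df[df["kind"] == "relation"]
        return cls(
            entity_ids=list(ent["id"]),
            entity_vectors=ent[dims].to_numpy(float),
            relation_names=list(rel["id"]),
            relation_vectors=rel[dims].to_numpy(float),
            entity_types=dict(zip(ent["id"], ent["node_type"])),
            config=TrainConfig(dim=len(dims)),
        )


def _distance(diff: np.ndarray, order: int) -> np.ndarray:
    if order == 1:
        return np.abs(diff).sum(axis=-1)
    return np.sqrt((diff ** 2).sum(axis=-1))


def score_triple(e: EmbeddingTable, h: str, r: str, t: str) -> float:
    """Plausibility score -||v_h + v_r - v_t|| (higher = more plausible).

    Raises KeyError for unknown entities or relations.
    """
    diff = e.vector(h) + e.relation_vector(r) - e.vector(t)
    return -float(_distance(diff, e.config.norm_order))


def train(kg: KnowledgeGraph, cfg: TrainConfig | None = None) -> EmbeddingTable:
    """Train translational embeddings on the graph's edge set."""
    cfg = cfg or TrainConfig()
    cfg.validate()
    if not kg.edges:
        raise ValueError("cannot train on a graph with no edges")

    entity_ids = sorted(kg.nodes)
    ent_index = {e: i for i, e in enumerate(entity_ids)}
    relation_names = sorted({e.relation for e in kg.edges})
    rel_index = {r: i for i, r in enumerate(relation_names)}

    triples = np.array(
        [(ent_index[e.head_id], rel_index[e.relation], ent_index[e.tail_id])
         for e in kg.edges], dtype=np.int64)
    n_ent, n_rel, dim = len(entity_ids), len(relation_names), cfg.dim

    # candidate pools per relation endpoint, respecting the schema type
    by_type: dict[str, np.ndarray] = {}
    for t in {n.node_type for n in kg.nodes.values()}:
        by_type[t] = np.array(
            [ent_index[n.node_id] for n in kg.nodes.values()
             if n.node_type == t], dtype=np.int64)
    head_pool, tail_pool = {}, {}
    for r in relation_names:
        spec = kg.schema.relations.get(r)
        if spec is not None:
            head_pool[rel_index[r]] = by_type[spec.head]
            tail_pool[rel_index[r]] = by_type[spec.tail]
        else:  # relation outside the schema: corrupt over all entities
            head_pool[rel_index[r]] = np.arange(n_ent)
            tail_pool[rel_index[r]] = np.arange(n_ent)

    rng = np.random.default_rng(cfg.seed)
    bound = 6.0 / np.sqrt(dim)
    ent = rng.uniform(-bound, bound, size=(n_ent, dim))
    rel = rng.uniform(-bound, bound, size=(n_rel, dim))
    rel /= np.maximum(np.linalg.norm(rel, axis=1, keepdims=True), 1e-12)

    loss_history: list[float] = []
    n_triples = len(triples)
    for _ in range(cfg.epochs):
        ent /= np.maximum(np.linalg.norm(ent, axis=1, keepdims=True), 1e-12)
        order = rng.permutation(n_triples)
        epoch_loss = 0.0
        for start in range(0, n_triples, cfg.batch_size):
            batch = triples[order[start:start + cfg.batch_size]]
            reps = np.repeat(batch, cfg.negatives_per_positive, axis=0)
            h, r, t = reps[:, 0], reps[:, 1], reps[:, 2]

            corrupt_head = rng.random(len(reps)) < 0.5
            neg_h, neg_t = h.copy(), t.copy()
            for rid in np.unique(r):
                mask = r == rid
                hp, tp = head_pool[rid], tail_pool[rid]
                m = int(mask.sum())
                picks_h = hp[rng.integers(len(hp), size=m)]
                picks_t = tp[rng.integers(len(tp), size=m)]
                neg_h[mask] = np.where(corrupt_head[mask], picks_h, h[mask])
                neg_t[mask] = np.where(corrupt_head[mask], t[mask], picks_t)

            pos_diff = ent[h] + rel[r] - ent[t]
            neg_diff = ent[neg_h] + rel[r] - ent[neg_t]
            pos_d = _distance(pos_diff, cfg.norm_order)
            neg_d = _distance(neg_diff, cfg.norm_order)
            viol = cfg.margin + pos_d - neg_d > 0
            epoch_loss += float(np.maximum(
                0.0, cfg.margin + pos_d - neg_d).sum())
            if not viol.any():
                continue

            if cfg.norm_order == 1:
                g_pos = np.sign(pos_diff[viol])
                g_neg = np.sign(neg_diff[viol])
            else:
                g_pos = pos_diff[viol] / np.maximum(
                    pos_d[viol, None], 1e-12)
                g_neg = neg_diff[viol] / np.maximum(
                    neg_d[viol, None], 1e-12)
            lr = cfg.learning_rate
            hv, rv, tv = h[viol], r[viol], t[viol]
            nhv, ntv = neg_h[viol], neg_t[viol]
            np.add.at(ent, hv, -lr * g_pos)
            np.add.at(ent, tv, lr * g_pos)
            np.add.at(rel, rv, -lr * (g_pos - g_neg))
            np.add.at(ent, nhv, lr * g_neg)
            np.add.at(ent, ntv, -lr * g_neg)
        loss_history.append(epoch_loss / max(
            1, n_triples * cfg.negatives_per_positive))
    ent /= np.maximum(np.linalg.norm(ent, axis=1, keepdims=True), 1e-12)

    return EmbeddingTable(
        entity_ids=entity_ids,
        entity_vectors=ent,
        relation_names=relation_names,
        relation_vectors=rel,
        entity_types={n.node_id: n.node_type for n in kg.nodes.values()},
        config=cfg,
        loss_history=loss_history,
    )


def _unit(x: np.ndarray) -> np.ndarray:
    return x / np.maximum(np.linalg.norm(x, axis=-1, keepdims=True), 1e-12)


def _cosine_matrix(e: EmbeddingTable, ids_a: list[str],
                   ids_b: list[str]) -> np.ndarray:
    a = _unit(np.stack([e.vector(i) for i in ids_a]))
    b = _unit(np.stack([e.vector(i) for i in ids_b]))
    return a @ b.T


def topk_similar(
    e: EmbeddingTable, query_type: str, target_type: str, k: int,
    exclude: set[tuple[str, str]] | None = None,
):
    """Exact top-k most cosine-similar (query, target) node pairs.

    Ties broken by id pair.  Also returns the mean pairwise similarity
    between the two types (self-pairs excluded when the types match).
    Returns (ranked list of (id_a, id_b, cosine), mean_similarity).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    ids_a = e.ids_of_type(query_type)
    ids_b = e.ids_of_type(target_type)
    if not ids_a or not ids_b:
        raise ValueError(
            f"no nodes of type {query_type!r} and/or {target_type!r}")
    sims = _cosine_matrix(e, ids_a, ids_b)

    same = query_type == target_type
    pairs = []
    total, count = 0.0, 0
    for i, a in enumerate(ids_a):
        for j, b in enumerate(ids_b):
            if same and a >= b:
                continue
            total += float(sims[i, j])
            count += 1
            if exclude and (a, b) in exclude:
                continue
            pairs.append((a, b, float(sims[i, j])))
    mean_sim = total / count if count else float("nan")
    pairs.sort(key=lambda p: (-p[2], p[0], p[1]))
    return pairs[:k], mean_sim


def costudied_pairs(kg: KnowledgeGraph) -> set[tuple[str, str]]:
    """(condition id, drug-term id) pairs connected through a shared
    study via Study-Condition and Study-StudiedDrug/UsedDrug edges."""
    by_study_cond: dict[str, set[str]] = {}
    by_study_drug: dict[str, set[str]] = {}
    for edge in kg.edges:
        if edge.relation == "Study-Condition":
            by_study_cond.setdefault(edge.head_id, set()).add(edge.tail_id)
        elif edge.relation in ("Study-StudiedDrug", "Study-UsedDrug"):
            by_study_drug.setdefault(edge.head_id, set()).add(edge.tail_id)
    out: set[tuple[str, str]] = set()
    for study, conds in by_study_cond.items():
        for c in conds:
            for d in by_study_drug.get(study, ()):
                out.add((c, d))
    return out


def repurposing_candidates(e: EmbeddingTable, kg: KnowledgeGraph, k: int):
    """Top-k condition/drug-term pairs by cosine similarity, excluding
    pairs already studied together in any study of the graph.

    Returns (ranked list of (condition id, drug id, cosine),
    mean type-pair similarity)."""
    return topk_similar(e, "Condition", "DrugTerm", k,
                        exclude=costudied_pairs(kg))


def hits_at_k(
    e: EmbeddingTable, kg: KnowledgeGraph, k: int = 10,
    n_corruptions: int = 50, n_triples: int | None = None, seed: int = 0,
) -> float:
    """Fraction of (sampled) true triples ranked within the top k
    against ``n_corruptions`` random same-type tail corruptions."""
    rng = np.random.default_rng(seed)
    edges = kg.edges
    if n_triples is not None and n_triples < len(edges):
        idx = rng.choice(len(edges), size=n_triples, replace=False)
        edges = [edges[int(i)] for i in idx]
    by_type: dict[str, list[str]] = {}
    for n in kg.nodes.values():
        by_type.setdefault(n.node_type, []).append(n.node_id)
    for t in by_type:
        by_type[t].sort()

    hits = 0
    for edge in edges:
        spec = kg.schema.relations.get(edge.relation)
        pool = by_type[spec.tail] if spec else sorted(kg.nodes)
        true_score = score_triple(e, edge.head_id, edge.relation, edge.tail_id)
        rank = 1
        for _ in range(n_corruptions):
            cand = pool[int(rng.integers(len(pool)))]
            if score_triple(e, edge.head_id, edge.relation, cand) > true_score:
                rank += 1
        if rank <= k:
            hits += 1
    return hits / len(edges)
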
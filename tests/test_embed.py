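"""Translational embedding: scoring arithmetic, training behaviour,
retrieval against a brute-force oracle, and repurposing exclusions."""

import numpy as np
import pytest

from trialkg.datamodel import (
    EdgeRecord,
    KnowledgeGraph,
    NodeRecord,
)
from trialkg.embed import (
    EmbeddingTable,
    TrainConfig,
    costudied_pairs,
    hits_at_k,
    repurposing_candidates,
    score_triple,
    topk_similar,
    train,
)


def _table(entities, relations, entity_types=None):
    ids = sorted(entities)
    rels = sorted(relations)
    return EmbeddingTable(
        entity_ids=ids,
        entity_vectors=np.stack([np.asarray(entities[i], float) for i in ids]),
        relation_names=rels,
        relation_vectors=np.stack([np.asarray(relations[r], float)
                                   for r in rels]),
        entity_types=entity_types or {i: "Study" for i in ids},
        config=TrainConfig(dim=len(next(iter(entities.values())))),
    )


class TestScore:
    def test_exact_translation_scores_zero(self):
        t = _table({"a": [1.0, 0.0], "b": [1.0, 1.0]}, {"r": [0.0, 1.0]})
        assert score_triple(t, "a", "r", "b") == pytest.approx(0.0)

    def test_hand_arithmetic_l2(self):
        t = _table({"h": [1.0, 0.0], "t": [0.0, 0.0]}, {"r": [0.0, 1.0]})
        assert score_triple(t, "h", "r", "t") == pytest.approx(-np.sqrt(2))

    def test_invariant_under_joint_rotation(self):
        rng = np.random.default_rng(0)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        ents = {"h": rng.normal(size=2), "t": rng.normal(size=2)}
        rels = {"r": rng.normal(size=2)}
        t1 = _table(ents, rels)
        t2 = _table({k: rot @ v for k, v in ents.items()},
                    {k: rot @ v for k, v in rels.items()})
        assert score_triple(t1, "h", "r", "t") == pytest.approx(
            score_triple(t2, "h", "r", "t"))

    def test_unknown_id_raises(self):
        t = _table({"a": [1.0, 0.0]}, {"r": [0.0, 1.0]})
        with pytest.raises(KeyError):
            score_triple(t, "a", "r", "ghost")


def _toy_graph(n_conditions=4, n_drugs=4, costudy=None):
    """Small typed graph: studies linked to conditions and drugs."""
    kg = KnowledgeGraph()
    conds = [f"condition:c{i}" for i in range(n_conditions)]
    drugs = [f"drugterm:d{i}" for i in range(n_drugs)]
    for c in conds:
        kg.add_node(NodeRecord(c, "Condition", {"name": c}))
    for d in drugs:
        kg.add_node(NodeRecord(d, "DrugTerm", {"term": d}))
    costudy = costudy if costudy is not None else []
    for i, (c, d) in enumerate(costudy):
        sid = f"study:NCT{i}"
        kg.add_node(NodeRecord(sid, "Study", {"nct_id": f"NCT{i}"}))
        kg.add_edge(EdgeRecord(sid, "Study-Condition", c))
        kg.add_edge(EdgeRecord(sid, "Study-StudiedDrug", d))
    return kg, conds, drugs


class TestTrain:
    def test_empty_edge_set_rejected(self):
        kg = KnowledgeGraph()
        kg.add_node(NodeRecord("study:x", "Study", {"nct_id": "x"}))
        with pytest.raises(ValueError):
            train(kg)

    def test_loss_non_increasing_in_moving_average(self):
        kg, _, _ = _toy_graph(costudy=[("condition:c0", "drugterm:d0"),
                                       ("condition:c1", "drugterm:d1"),
                                       ("condition:c0", "drugterm:d1")])
        table = train(kg, TrainConfig(dim=8, epochs=60, seed=0,
                                      learning_rate=0.05))
        losses = np.array(table.loss_history)
        first = losses[:10].mean()
        last = losses[-10:].mean()
        assert last <= first + 1e-9

    def test_same_seed_reproduces_embeddings_exactly(self):
        kg, _, _ = _toy_graph(costudy=[("condition:c0", "drugterm:d0")])
        cfg = TrainConfig(dim=8, epochs=10, seed=3)
        a = train(kg, cfg)
        b = train(kg, cfg)
        np.testing.assert_array_equal(a.entity_vectors, b.entity_vectors)
        np.testing.assert_array_equal(a.relation_vectors, b.relation_vectors)

    def test_entity_vectors_unit_norm_after_training(self):
        kg, _, _ = _toy_graph(costudy=[("condition:c0", "drugterm:d0")])
        table = train(kg, TrainConfig(dim=8, epochs=5, seed=0))
        norms = np.linalg.norm(table.entity_vectors, axis=1)
        np.testing.assert_allclose(norms, 1.0, rtol=1e-9)

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(dim=0).validate()
        with pytest.raises(ValueError):
            TrainConfig(norm_order=3).validate()


class TestRetrieve:
    def test_identical_and_orthogonal_vectors(self):
        t = _table(
            {"condition:a": [1.0, 0.0], "drugterm:b": [1.0, 0.0],
             "drugterm:c": [0.0, 1.0]},
            {"r": [0.0, 1.0]},
            entity_types={"condition:a": "Condition",
                          "drugterm:b": "DrugTerm",
                          "drugterm:c": "DrugTerm"})
        pairs, _ = topk_similar(t, "Condition", "DrugTerm", 2)
        assert pairs[0] == ("condition:a", "drugterm:b", pytest.approx(1.0))
        assert pairs[1][2] == pytest.approx(0.0)

    def test_matches_brute_force_ranking(self):
        rng = np.random.default_rng(4)
        ents = {f"condition:c{i}": rng.normal(size=3) for i in range(5)}
        ents.update({f"drugterm:d{i}": rng.normal(size=3) for i in range(5)})
        types = {k: ("Condition" if k.startswith("condition") else "DrugTerm")
                 for k in ents}
        t = _table(ents, {"r": [0.0, 0.0, 1.0]}, entity_types=types)
        pairs, _ = topk_similar(t, "Condition", "DrugTerm", 25)
        brute = []
        for a in sorted(k for k in ents if k.startswith("condition")):
            for b in sorted(k for k in ents if k.startswith("drugterm")):
                va, vb = ents[a], ents[b]
                brute.append((a, b, float(
                    va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))))
        brute.sort(key=lambda p: (-p[2], p[0], p[1]))
        assert [(a, b) for a, b, _ in pairs] == [(a, b) for a, b, _ in brute]
        for (_, _, s1), (_, _, s2) in zip(pairs, brute):
            assert s1 == pytest.approx(s2)

    def test_nonpositive_k_rejected(self):
        t = _table({"condition:a": [1.0, 0.0], "drugterm:b": [0.0, 1.0]},
                   {"r": [1.0, 0.0]},
                   entity_types={"condition:a": "Condition",
                                 "drugterm:b": "DrugTerm"})
        with pytest.raises(ValueError):
            topk_similar(t, "Condition", "DrugTerm", 0)

    def test_cosine_symmetric_and_bounded(self):
        rng = np.random.default_rng(1)
        ents = {f"study:s{i}": rng.normal(size=4) for i in range(6)}
        t = _table(ents, {"r": [0, 0, 0, 1.0]})
        pairs, mean = topk_similar(t, "Study", "Study", 15)
        for a, b, s in pairs:
            assert -1.0 - 1e-9 <= s <= 1.0 + 1e-9
        assert -1.0 <= mean <= 1.0


class TestRepurposing:
    def test_costudied_pairs_derived_from_shared_study(self):
        kg, conds, drugs = _toy_graph(
            costudy=[("condition:c0", "drugterm:d0")])
        assert costudied_pairs(kg) == {("condition:c0", "drugterm:d0")}

    def test_costudied_pair_excluded_regardless_of_similarity(self):
        kg, conds, drugs = _toy_graph(
            costudy=[("condition:c0", "drugterm:d0")])
        vecs = {n: np.random.default_rng(7).normal(size=4)
                for n in kg.nodes}
        # make the excluded pair maximally similar
        vecs["condition:c0"] = np.array([1.0, 0, 0, 0])
        vecs["drugterm:d0"] = np.array([1.0, 0, 0, 0])
        t = _table(vecs, {"r": [0, 0, 0, 1.0]},
                   entity_types={n: kg.nodes[n].node_type for n in kg.nodes})
        pairs, _ = repurposing_candidates(t, kg, 100)
        assert ("condition:c0", "drugterm:d0") not in \
            [(a, b) for a, b, _ in pairs]

    def test_without_costudy_links_equals_plain_topk(self):
        kg, _, _ = _toy_graph(costudy=[])
        rng = np.random.default_rng(2)
        vecs = {n: rng.normal(size=4) for n in kg.nodes}
        t = _table(vecs, {"r": [0, 0, 0, 1.0]},
                   entity_types={n: kg.nodes[n].node_type for n in kg.nodes})
        assert repurposing_candidates(t, kg, 5) == \
            topk_similar(t, "Condition", "DrugTerm", 5)


@pytest.fixture(scope="module")
def trained(assembled_graph):
    cfg = TrainConfig(dim=48, epochs=120, seed=7, learning_rate=0.05)
    return train(assembled_graph, cfg)


class TestStructureRecovery:
    def test_hits_at_10_beats_chance(self, trained, assembled_graph):
        h = hits_at_k(trained, assembled_graph, k=10, n_corruptions=50,
                      n_triples=300, seed=2)
        assert h > 10 / 51  # chance level for rank among 51 candidates

    def test_planted_condition_twins_above_mean_similarity(
            self, trained, corpus):
        ca, cb = corpus.truth.similar_condition_pair
        va = trained.vector(f"condition:{ca.casefold()}")
        vb = trained.vector(f"condition:{cb.casefold()}")
        cos = float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))
        _, mean = topk_similar(trained, "Condition", "Condition", 1)
        assert cos > mean

    def test_planted_repurposing_pair_ranks_in_topk(
            self, trained, corpus, assembled_graph):
        cond, drug = corpus.truth.repurposing_pair
        pairs, _ = repurposing_candidates(trained, assembled_graph, 10)
        names = [(a.split(":", 1)[1], b.split(":", 1)[1])
                 for a, b, _ in pairs]
        assert (cond.casefold(), drug.casefold()) in names

    def test_repurposing_output_never_contains_costudied(
            self, trained, assembled_graph):
        excluded = costudied_pairs(assembled_graph)
        pairs, _ = repurposing_candidates(trained, assembled_graph, 50)
        assert not any((a, b) in excluded for a, b, _ in pairs)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        ents = {f"condition:c{i}": rng.normal(size=3) for i in range(3)}
        t = _table(ents, {"Study-Condition": rng.normal(size=3)},
                   entity_types={k: "Condition" for k in ents})
        path = tmp_path / "emb.tsv"
        t.save(path)
        loaded = EmbeddingTable.load(path)
        assert loaded.entity_ids == t.entity_ids
        np.testing.assert_allclose(loaded.entity_vectors, t.entity_vectors)
        assert loaded.entity_types == t.entity_types
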
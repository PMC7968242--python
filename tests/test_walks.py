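import networkx as nx
import numpy as np
import pytest

from coexalign.anchoring import attach_danglings, is_artificial, select_anchors
from coexalign.synth_fixtures import make_topology
from coexalign.walks import (
    PAD,
    build_token_map,
    generate_walks,
    transition_probabilities,
)


def weighted_path(weights, tag="net"):
    g = nx.Graph(tag=tag)
    nodes = [f"n{i}" for i in range(len(weights) + 1)]
    g.add_nodes_from(nodes)
    for i, w in enumerate(weights):
        g.add_edge(nodes[i], nodes[i + 1], weight=w)
    return g


class TestTransitionProbabilities:
    def test_normalisation_cases(self):
        g = nx.Graph(tag="t")
        g.add_edge("c", "a", weight=1.0)
        g.add_edge("c", "b", weight=1.0)
        g.add_edge("c", "d", weight=0.9)
        tables = transition_probabilities(g)
        nbrs, probs = tables["c"]
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        lookup = dict(zip(nbrs, probs))
        assert lookup["a"] == pytest.approx(1.0 / 2.9)
        assert lookup["d"] == pytest.approx(0.9 / 2.9)

    def test_uneven_weights_kept_as_given(self):
        g = nx.Graph(tag="t")
        g.add_edge("c", "a", weight=0.9)
        g.add_edge("c", "b", weight=0.1)
        nbrs, probs = transition_probabilities(g)["c"]
        assert dict(zip(nbrs, probs)) == pytest.approx({"a": 0.9, "b": 0.1})

    def test_zero_weight_edges_carry_no_mass(self):
        g = nx.Graph(tag="t")
        g.add_edge("a", "b", weight=0.0)
        tables = transition_probabilities(g)
        assert tables["a"] == ([], pytest.approx(np.empty(0)))
        g.add_node("iso")
        assert transition_probabilities(g)["iso"][0] == []


class TestTokenMap:
    def make_augmented_pair(self):
        nets = [make_topology("line", 5, tag="a"), make_topology("line", 5, tag="b")]
        anchors = select_anchors(["g3"], nets, 1, 0)
        augmented, _ = attach_danglings(nets, anchors, gamma=4, seed=0)
        return augmented, anchors

    def test_dangling_only_vocabulary_size(self):
        augmented, anchors = self.make_augmented_pair()
        tm = build_token_map(augmented, "dangling-only", anchors)
        # 5 private genes per network + 4 shared artificial nodes
        assert len(tm) == 5 + 5 + 4
        assert tm.token("a", "g1") != tm.token("b", "g1")
        dangle = next(n for n in augmented[0] if is_artificial(n))
        assert tm.token("a", dangle) == tm.token("b", dangle)

    def test_dangling_anchors_ties_anchor_tokens(self):
        augmented, anchors = self.make_augmented_pair()
        tm = build_token_map(augmented, "dangling-anchors", anchors)
        assert len(tm) == 4 + 4 + 4 + 1  # private non-anchors + shared
        assert tm.token("a", "g3") == tm.token("b", "g3")

    def test_round_trip_identity_and_json(self, tmp_path):
        augmented, anchors = self.make_augmented_pair()
        tm = build_token_map(augmented, "dangling-only", anchors)
        for key, tok in tm.forward.items():
            assert tm.backward[tok] == key
        path = tmp_path / "map.json"
        tm.save(path)
        loaded = type(tm).load(path)
        assert loaded.forward == tm.forward
        assert loaded.tying_policy == tm.tying_policy
        assert loaded.anchors == tm.anchors

    def test_gene_id_namespace_collision_rejected(self):
        g = nx.Graph(tag="t")
        g.add_node("weird::gene")
        with pytest.raises(ValueError, match="reserved"):
            build_token_map([g])


class TestGenerateWalks:
    def test_corpus_size_contract(self):
        net = make_topology("line", 10, tag="only")
        tm = build_token_map([net])
        corpus = generate_walks([net], walks_per_node=7, walk_length=5, token_map=tm, seed=0)
        assert corpus.n_walks == 10 * 7
        assert corpus.tokens.shape == (70, 5)

    def test_walks_follow_edges(self):
        net = make_topology("cross", 9, tag="x")
        tm = build_token_map([net])
        corpus = generate_walks([net], 20, 8, tm, seed=1)
        back = tm.backward
        edges = {frozenset((u, v)) for u, v in net.edges()}
        for walk in corpus.walks:
            names = [back[t].split("::", 1)[1] for t in walk]
            for u, v in zip(names, names[1:]):
                assert frozenset((u, v)) in edges

    def test_isolated_node_yields_length_one_walks(self):
        net = make_topology("line", 4, tag="t")
        net.add_node("lonely")
        tm = build_token_map([net])
        corpus = generate_walks([net], 3, 6, tm, seed=0)
        iso_token = tm.token("t", "lonely")
        iso_walks = [w for w in corpus.walks if w[0] == iso_token]
        assert len(iso_walks) == 3
        assert all(w == [iso_token] for w in iso_walks)

    def test_deterministic_given_seed(self):
        net = make_topology("circle", 8, tag="t")
        tm = build_token_map([net])
        c1 = generate_walks([net], 10, 6, tm, seed=9)
        c2 = generate_walks([net], 10, 6, tm, seed=9)
        assert np.array_equal(c1.tokens, c2.tokens)
        c3 = generate_walks([net], 10, 6, tm, seed=10)
        assert not np.array_equal(c1.tokens, c3.tokens)

    def test_first_step_split_matches_weights(self):
        # center of a 3-node path with weights 0.9 / 0.1: binomial oracle
        g = weighted_path([0.9, 0.1], tag="t")
        tm = build_token_map([g])
        corpus = generate_walks([g], walks_per_node=10000, walk_length=2, token_map=tm, seed=2)
        center = tm.token("t", "n1")
        heavy = tm.token("t", "n0")
        firsts = [w[1] for w in corpus.walks if w[0] == center and len(w) > 1]
        assert len(firsts) == 10000
        p_hat = sum(t == heavy for t in firsts) / len(firsts)
        se = np.sqrt(0.9 * 0.1 / 10000)
        assert abs(p_hat - 0.9) < 3 * se

    def test_joint_corpus_shares_only_artificial_tokens(self):
        nets = [make_topology("line", 6, tag="a"), make_topology("line", 6, tag="b")]
        anchors = select_anchors(["g3"], nets, 1, 0)
        augmented, _ = attach_danglings(nets, anchors, gamma=4, seed=0)
        tm = build_token_map(augmented, "dangling-only", anchors)
        corpus = generate_walks(augmented, 50, 10, tm, seed=0)
        toks_a = {t for w, tag in zip(corpus.walks, corpus.origin_network)
                  if tag == "a" for t in w}
        toks_b = {t for w, tag in zip(corpus.walks, corpus.origin_network)
                  if tag == "b" for t in w}
        shared = toks_a & toks_b
        artificial = {tok for key, tok in tm.forward.items() if is_artificial(key)}
        assert shared == artificial
        assert len(shared) == 4
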
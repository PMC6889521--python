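"""Candidate generation: alignment, blinding, dependency graphs, SDPs."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bbrex import candidates as cand
from bbrex.corpus_io import (
    Document,
    EntityCategory,
    EntityMention,
    ParsedSentence,
    Token,
    attach_parses,
)
from bbrex.synthetic import (
    SynthConfig,
    generate_corpus,
    helicobacter_japan_example,
    mycobacteria_queensland_example,
)


def brute_force_shortest(graph: nx.Graph, a: int, b: int) -> int | None:
    """Minimum simple-path length by exhaustive enumeration."""
    best = None
    for path in nx.all_simple_paths(graph, a, b):
        if best is None or len(path) < best:
            best = len(path)
    return best


# -- alignment ---------------------------------------------------------------


def _doc_with(text, mentions):
    tokens = [
        Token(surf, "NN", 0 if i == 0 else 1) for i, surf in enumerate(text.split())
    ]
    doc = Document(doc_id="d", text=text, mentions=mentions)
    return attach_parses(doc, [ParsedSentence(0, tokens)])


def test_single_token_mention_aligns_to_one_token():
    text = "Bacillus lives here"
    doc = _doc_with(text, [EntityMention("T1", EntityCategory.BACTERIA, 0, 8, "Bacillus")])
    alignment, failures = cand.align_mentions_to_tokens(doc)
    assert alignment["T1"] == (0, (0, 1)) and not failures


def test_two_token_mention_spans_two_tokens():
    doc = helicobacter_japan_example()
    alignment, _ = cand.align_mentions_to_tokens(doc)
    sent, (start, stop) = alignment["T1"]
    assert stop - start == 2  # "Helicobacter pylori"


def test_cross_sentence_mention_skipped_with_warning(caplog):
    text = "aaa bbb ccc ddd"
    sents = [
        ParsedSentence(0, [Token("aaa", "NN", 0), Token("bbb", "NN", 1)]),
        ParsedSentence(1, [Token("ccc", "NN", 0), Token("ddd", "NN", 1)]),
    ]
    doc = Document(
        doc_id="d", text=text,
        mentions=[EntityMention("T1", EntityCategory.HABITAT, 4, 11, "bbb ccc")],
    )
    doc = attach_parses(doc, sents)
    with caplog.at_level("WARNING"):
        alignment, failures = cand.align_mentions_to_tokens(doc)
    assert failures == ["T1"] and "T1" not in alignment


# -- blinding ----------------------------------------------------------------


def test_blinding_matches_printed_candidate_strings():
    doc = helicobacter_japan_example()
    instances, _ = cand.generate_candidates(doc)
    texts = sorted(i.text for i in instances)
    assert texts == [
        "long-term entity_1 infection and the development of atrophic gastritis "
        "and entity_2 cancer in japan .",
        "long-term entity_1 infection and the development of atrophic gastritis "
        "and gastric cancer in entity_2 .",
    ]


def test_blinding_lowercases_and_substitutes_only():
    blinded = cand.blind_and_normalize(["A", "B", "C"], (0, 1), (2, 3))
    assert blinded.tokens == ["entity_1", "b", "entity_2"]
    assert (blinded.entity1_pos, blinded.entity2_pos) == (0, 2)


def test_blinded_entity_inherits_first_token_pos():
    blinded = cand.blind_and_normalize(
        ["Helicobacter", "pylori", "x", "Japan"], (0, 2), (3, 4), ["NNP", "FW", "NN", "NNP"]
    )
    assert blinded.pos_tags == ["NNP", "NN", "NNP"]


def test_overlapping_spans_rejected():
    with pytest.raises(ValueError):
        cand.blind_and_normalize(["a", "b", "c"], (0, 2), (1, 3))


# -- dependency graph --------------------------------------------------------


def test_chain_parse_yields_path_graph():
    sent = ParsedSentence(0, [Token("a", "NN", 2), Token("b", "NN", 3), Token("c", "NN", 0)])
    graph = cand.build_dependency_graph(sent)
    assert sorted(graph.edges) == [(0, 1), (1, 2)]


def test_collapsed_mention_reattaches_edges():
    # b governs a (internal to the mention) and c attaches to b externally
    sent = ParsedSentence(0, [Token("a", "NN", 2), Token("b", "NN", 0), Token("c", "NN", 2)])
    graph = cand.build_dependency_graph(sent, index_map=[0, 0, 1])
    assert sorted(graph.edges) == [(0, 1)]


@given(st.integers(0, 500))
@settings(max_examples=30, deadline=None)
def test_random_trees_keep_tree_edge_count_after_collapse(seed):
    rng = np.random.default_rng(seed)
    n = 8
    heads = [0] + [int(rng.integers(1, i + 1)) for i in range(1, n)]
    # collapse a dependency-adjacent two-token mention (start, start+1)
    start = int(rng.integers(0, n - 1))
    heads[start + 1] = start + 1  # 1-based index of `start`
    sent = ParsedSentence(0, [Token(f"t{i}", "NN", heads[i]) for i in range(n)])
    index_map = list(range(start + 1)) + [i - 1 for i in range(start + 1, n)]
    graph = cand.build_dependency_graph(sent, index_map)
    n_after = max(index_map) + 1
    assert graph.number_of_edges() == n_after - 1
    assert nx.is_connected(graph)


# -- shortest dependency path ------------------------------------------------


def test_direct_dependency_edge_gives_length_two_path():
    graph = nx.Graph([(0, 1), (1, 2)])
    assert cand.shortest_dependency_path(graph, 0, 1) == [0, 1]


def test_disconnected_entities_have_no_path():
    graph = nx.Graph()
    graph.add_nodes_from([0, 1])
    assert cand.shortest_dependency_path(graph, 0, 1) is None


def test_probe_token_absent_from_sdp():
    doc = mycobacteria_queensland_example()
    (inst,), _ = cand.generate_candidates(doc)
    assert inst.tokens.index("in") not in inst.sdp_indices


def test_sdp_matches_brute_force_on_random_graphs():
    rng = np.random.default_rng(42)
    for _ in range(200):
        n = int(rng.integers(3, 11))
        graph = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(0, 2**31)))
        if not nx.is_connected(graph):
            comp = max(nx.connected_components(graph), key=len)
            graph = graph.subgraph(comp).copy()
            graph = nx.convert_node_labels_to_integers(graph)
            if graph.number_of_nodes() < 2:
                continue
        a, b = rng.choice(graph.number_of_nodes(), size=2, replace=False)
        path = cand.shortest_dependency_path(graph, int(a), int(b))
        assert len(path) == brute_force_shortest(graph, int(a), int(b))
        assert path[0] == a and path[-1] == b


def test_sdp_tie_break_is_lexicographically_smallest():
    # two shortest paths 0-1-3 and 0-2-3; the smaller middle index wins
    graph = nx.Graph([(0, 1), (0, 2), (1, 3), (2, 3)])
    assert cand.shortest_dependency_path(graph, 0, 3) == [0, 1, 3]


# -- relative distances ------------------------------------------------------


def test_probe_token_relative_distances():
    doc = mycobacteria_queensland_example()
    (inst,), _ = cand.generate_candidates(doc)
    probe = inst.tokens.index("in")
    assert (inst.rel_dist1[probe], inst.rel_dist2[probe]) == (-4, 1)


def test_distance_is_zero_at_own_entity():
    rel1, rel2 = cand.relative_distances(["a"] * 6, 2, 5)
    assert rel1[2] == 0 and rel2[5] == 0


@given(st.integers(2, 30), st.data())
@settings(max_examples=50, deadline=None)
def test_distance_difference_is_constant(n, data):
    e1 = data.draw(st.integers(0, n - 1))
    e2 = data.draw(st.integers(0, n - 1).filter(lambda x: x != e1))
    rel1, rel2 = cand.relative_distances(["t"] * n, e1, e2)
    diffs = {a - b for a, b in zip(rel1, rel2)}
    assert diffs == {e1 - e2}


# -- candidate counts --------------------------------------------------------


def test_one_bacteria_two_locations_give_two_instances():
    doc = helicobacter_japan_example()
    instances, stats = cand.generate_candidates(doc)
    assert len(instances) == 2 and stats.n_intra_pairs == 2


def test_bacteria_only_sentence_gives_no_instances():
    text = "BactA near BactB"
    doc = _doc_with(
        text,
        [
            EntityMention("T1", EntityCategory.BACTERIA, 0, 5, "BactA"),
            EntityMention("T2", EntityCategory.BACTERIA, 11, 16, "BactB"),
        ],
    )
    instances, _ = cand.generate_candidates(doc)
    assert instances == []


def test_full_pair_enumeration_count():
    # b bacteria x h locations in one fully connected sentence -> b*h instances
    b, h = 2, 3
    surfaces = [f"B{i}" for i in range(b)] + [f"L{i}" for i in range(h)] + ["root"]
    n = len(surfaces)
    tokens = [Token(s, "NN", n if i < n - 1 else 0) for i, s in enumerate(surfaces)]
    text = " ".join(surfaces)
    mentions = []
    pos = 0
    for i, s in enumerate(surfaces[:-1]):
        category = EntityCategory.BACTERIA if i < b else EntityCategory.HABITAT
        mentions.append(EntityMention(f"T{i}", category, pos, pos + len(s), s))
        pos += len(s) + 1
    doc = attach_parses(Document("d", text, mentions), [ParsedSentence(0, tokens)])
    instances, stats = cand.generate_candidates(doc)
    assert len(instances) == b * h
    assert stats.reconciles()


def test_counters_reconcile_on_synthetic_corpus():
    for doc in generate_corpus(SynthConfig(n_docs=10, seed=17, sentences_per_doc=(2, 4))):
        _, stats = cand.generate_candidates(doc)
        assert stats.reconciles()


def test_sdp_endpoints_and_length_invariants():
    docs = generate_corpus(SynthConfig(n_docs=6, seed=23))
    for doc in docs:
        instances, _ = cand.generate_candidates(doc)
        for inst in instances:
            assert len(inst.sdp_indices) <= len(inst.tokens)
            assert inst.entity1_pos in inst.sdp_indices
            assert inst.entity2_pos in inst.sdp_indices


def test_jsonl_round_trip(tmp_path):
    docs = generate_corpus(SynthConfig(n_docs=3, seed=2))
    instances = list(
        itertools.chain.from_iterable(cand.generate_candidates(d)[0] for d in docs)
    )
    path = tmp_path / "inst.jsonl"
    with open(path, "w") as fh:
        cand.write_instances_jsonl(instances, fh)
    with open(path) as fh:
        reread = cand.read_instances_jsonl(fh)
    assert reread == instances
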
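"""Multiple Solutions Graph: construction, losslessness, accounting, export."""

import random

import pytest

from equiset import Solution, build_msg, classify_features, decode_solutions, export_dot
from equiset.msg import MSGGraph, forward_compress, or_compress
from equiset.multi_tmfbs import SolutionSet

FIG_EXAMPLE = [
    {1, 2, 3},
    {1, 2, 4, 5},
    {1, 2, 5, 6, 7},
    {1, 2, 5, 6, 8},
]


def _family(sets):
    return SolutionSet([Solution(s) for s in sets])


def random_family(rnd, max_solutions=8, max_features=12):
    k = rnd.randint(1, max_solutions)
    sets = set()
    while len(sets) < k:
        size = rnd.randint(1, max_features)
        sets.add(frozenset(rnd.sample(range(max_features), size)))
    return _family(sorted(sets, key=sorted))


class TestBuildAndDecode:
    def test_worked_four_set_example(self):
        """Building from the four-set family and decoding returns exactly
        those four sets."""
        graph = build_msg(_family(FIG_EXAMPLE), debug=True)
        decoded = decode_solutions(graph)
        assert len(decoded) == 4
        assert decoded.as_frozensets() == frozenset(frozenset(s) for s in FIG_EXAMPLE)
        # compression factored the shared prefix into an indispensable node
        inner_sets = [fs for i in graph.inner_ids() for fs in graph.nodes[i].feature_sets]
        assert frozenset({1, 2}) in inner_sets

    def test_single_solution_chain(self):
        graph = build_msg(_family([{3, 4}]))
        assert graph.inner_ids() == [2]
        assert graph.children[graph.s_id] == {2}
        assert graph.children[2] == {graph.t_id}
        assert decode_solutions(graph).as_frozensets() == frozenset({frozenset({3, 4})})

    def test_empty_sole_solution(self):
        graph = build_msg(_family([set()]))
        assert decode_solutions(graph).as_frozensets() == frozenset({frozenset()})

    def test_duplicate_and_empty_solutions_rejected(self):
        with pytest.raises(ValueError):
            SolutionSet([Solution({1}), Solution({1})])
        with pytest.raises(ValueError):
            build_msg(_family([{1}, set()]))

    def test_roundtrip_on_random_families(self):
        """decode(build(M)) == M for 200 random families, with the decoded
        family re-checked after every individual merge operation."""
        rnd = random.Random(2024)
        for _ in range(200):
            family = random_family(rnd)
            graph = build_msg(family, debug=True)
            graph.validate()
            assert decode_solutions(graph).as_frozensets() == family.as_frozensets()

    def test_decode_chain(self):
        graph = MSGGraph()
        a = graph.add_node(feature_sets=[{1}])
        b = graph.add_node(feature_sets=[{2}])
        graph.add_edge(graph.s_id, a.id)
        graph.add_edge(a.id, b.id)
        graph.add_edge(b.id, graph.t_id)
        assert decode_solutions(graph).as_frozensets() == frozenset({frozenset({1, 2})})


class TestOperationAccounting:
    def test_forward_merge_feature_accounting(self):
        """Factoring F' out of a group of n nodes removes (n-1)|F'| features
        from the graph: {1,2} and {1,3} become {1} over {2},{3}."""
        graph = MSGGraph()
        a = graph.add_node(feature_sets=[{1, 2}])
        b = graph.add_node(feature_sets=[{1, 3}])
        for node in (a, b):
            graph.add_edge(graph.s_id, node.id)
            graph.add_edge(node.id, graph.t_id)
        before = graph.total_features()
        forward_compress(graph)
        assert graph.total_features() == before - (2 - 1) * 1
        new_sets = {fs for i in graph.inner_ids() for fs in graph.nodes[i].feature_sets}
        assert new_sets == {frozenset({1}), frozenset({2}), frozenset({3})}

    def test_disjoint_children_unchanged(self):
        graph = build_msg(_family([{1, 2}, {3, 4}]))
        # nothing shared: still one node per solution (plus possible OR merge)
        assert decode_solutions(graph).as_frozensets() == frozenset(
            {frozenset({1, 2}), frozenset({3, 4})}
        )
        assert graph.total_features() == 4

    def test_or_merge_accounting(self):
        """Siblings with identical parents and children collapse into one
        multi-set node; node count drops by n-1, feature count unchanged."""
        graph = MSGGraph()
        a = graph.add_node(feature_sets=[{7}])
        b = graph.add_node(feature_sets=[{8}])
        for node in (a, b):
            graph.add_edge(graph.s_id, node.id)
            graph.add_edge(node.id, graph.t_id)
        nodes_before, feats_before = graph.n_nodes, graph.total_features()
        or_compress(graph)
        assert graph.n_nodes == nodes_before - 1
        assert graph.total_features() == feats_before
        merged = graph.nodes[graph.inner_ids()[0]]
        assert merged.feature_sets == [frozenset({7}), frozenset({8})]

    def test_or_merge_inside_worked_example(self):
        graph = build_msg(_family(FIG_EXAMPLE))
        multi = [
            graph.nodes[i] for i in graph.inner_ids()
            if len(graph.nodes[i].feature_sets) > 1
        ]
        assert any(
            set(node.feature_sets) == {frozenset({7}), frozenset({8})} for node in multi
        )


class TestClassifyFeatures:
    def test_single_solution_all_indispensable(self):
        out = classify_features(_family([{1, 2}]), universe=range(4))
        assert out == {
            0: "outside_all_solutions", 1: "indispensable",
            2: "indispensable", 3: "outside_all_solutions",
        }

    def test_replaceable_from_two_solutions(self):
        out = classify_features(_family([{1, 2}, {1, 3}]), universe=range(4))
        assert out[1] == "indispensable"
        assert out[2] == out[3] == "replaceable"


class TestExportDot:
    def test_chain_graph_dot_body(self, tmp_path):
        graph = build_msg(_family([{1, 2}]))
        path = tmp_path / "g.dot"
        export_dot(graph, path, feature_names=["z", "f1", "f2"])
        text = path.read_text()
        assert text.startswith("digraph")
        assert text.count("->") == 2
        assert "{f1,f2}" in text

    def test_deterministic_bytes(self, tmp_path):
        family = _family(FIG_EXAMPLE)
        p1, p2 = tmp_path / "a.dot", tmp_path / "b.dot"
        export_dot(build_msg(family), p1)
        export_dot(build_msg(family), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_dot_structure_well_formed(self, tmp_path):
        path = tmp_path / "g.dot"
        graph = build_msg(_family(FIG_EXAMPLE))
        export_dot(graph, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "digraph msg {"
        assert lines[-1] == "}"
        # one node statement per node, one edge statement per edge
        assert sum("[label=" in ln for ln in lines) == graph.n_nodes
        assert sum("->" in ln for ln in lines) == graph.n_edges
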
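"""Multiple Solutions Graph (MSG): compact representation of a solution family.

An MSG is a DAG with a single root ``s`` and single leaf ``t``; every other
node carries one or more feature sets. Each directed path from ``s`` to
``t``, together with a choice of one feature set per node on the path,
yields a solution (the union of the chosen sets), and the graph encodes
exactly the input family - no more, no less.

Construction is greedy: a star graph with one node per solution, followed by
a forward compression pass (factoring shared features out of sibling groups,
root-side), a backward compression pass (the mirror image, leaf-side), and
an OR pass that merges nodes with identical parents and children into one
multi-set node. Every individual merge preserves the decoded family; the
graph is lossless but not guaranteed minimal (the construction is a
heuristic, and minimality is not claimed).
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Set

from .multi_tmfbs import SolutionSet
from .single_fbs import Solution

__all__ = [
    "MSGNode",
    "MSGGraph",
    "build_msg",
    "forward_compress",
    "backward_compress",
    "or_compress",
    "decode_solutions",
    "classify_features",
    "export_dot",
    "graph_to_dict",
]

DECODE_CAP = 10_000


class DecodeCapExceeded(RuntimeError):
    """Raised when decoding would enumerate more combinations than allowed."""


@dataclass
class MSGNode:
    """A graph node carrying feature sets; the special root/leaf nodes carry
    none."""

    id: int
    feature_sets: List[frozenset] = field(default_factory=list)
    special: Optional[str] = None  # "s", "t", or None

    @property
    def var(self) -> frozenset:
        """The single feature set of a pre-OR-merge node."""
        if len(self.feature_sets) != 1:
            raise ValueError(f"node {self.id} holds {len(self.feature_sets)} sets")
        return self.feature_sets[0]


class MSGGraph:
    """Single-root, single-leaf DAG over :class:`MSGNode` objects."""

    def __init__(self):
        self.nodes: Dict[int, MSGNode] = {}
        self.parents: Dict[int, Set[int]] = {}
        self.children: Dict[int, Set[int]] = {}
        self._next_id = 0
        self.s_id = self.add_node(special="s").id
        self.t_id = self.add_node(special="t").id

    # -- structure editing -------------------------------------------------

    def add_node(self, feature_sets=(), special: Optional[str] = None) -> MSGNode:
        node = MSGNode(
            id=self._next_id,
            feature_sets=[frozenset(fs) for fs in feature_sets],
            special=special,
        )
        self.nodes[node.id] = node
        self.parents[node.id] = set()
        self.children[node.id] = set()
        self._next_id += 1
        return node

    def add_edge(self, parent: int, child: int) -> None:
        self.children[parent].add(child)
        self.parents[child].add(parent)

    def remove_edge(self, parent: int, child: int) -> None:
        self.children[parent].discard(child)
        self.parents[child].discard(parent)

    def remove_node(self, node_id: int, rewire: bool = False) -> None:
        """Delete a node; with ``rewire`` every parent is connected to every
        child first (used when a merge empties a node's feature set)."""
        ps = list(self.parents[node_id])
        cs = list(self.children[node_id])
        if rewire:
            for p in ps:
                for c in cs:
                    self.add_edge(p, c)
        for p in ps:
            self.children[p].discard(node_id)
        for c in cs:
            self.parents[c].discard(node_id)
        del self.nodes[node_id], self.parents[node_id], self.children[node_id]

    # -- inspection --------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return sum(len(cs) for cs in self.children.values())

    def total_features(self) -> int:
        """Total feature count stored across all node feature sets."""
        return sum(
            len(fs) for node in self.nodes.values() for fs in node.feature_sets
        )

    def inner_ids(self) -> list:
        return sorted(i for i in self.nodes if self.nodes[i].special is None)

    def validate(self) -> None:
        """Check the structural invariants: single root/leaf, acyclicity,
        inner in/out degrees >= 1 (hence path coverage), distinct sets."""
        roots = [i for i in self.nodes if not self.parents[i]]
        leaves = [i for i in self.nodes if not self.children[i]]
        if roots != [self.s_id]:
            raise ValueError(f"expected unique root {self.s_id}, got {roots}")
        if leaves != [self.t_id]:
            raise ValueError(f"expected unique leaf {self.t_id}, got {leaves}")
        for i in self.inner_ids():
            node = self.nodes[i]
            if not node.feature_sets or any(not fs for fs in node.feature_sets):
                raise ValueError(f"inner node {i} carries an empty feature set")
            if len(set(node.feature_sets)) != len(node.feature_sets):
                raise ValueError(f"inner node {i} carries duplicate feature sets")
            if not self.parents[i] or not self.children[i]:
                raise ValueError(f"inner node {i} is not on an s-t path")
        # Kahn's algorithm for acyclicity
        indeg = {i: len(self.parents[i]) for i in self.nodes}
        queue = [i for i, d in indeg.items() if d == 0]
        seen = 0
        while queue:
            cur = queue.pop()
            seen += 1
            for c in self.children[cur]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if seen != len(self.nodes):
            raise ValueError("graph contains a cycle")


# ---------------------------------------------------------------------------
# grouping heuristics


def _most_frequent_feature_groups(graph: MSGGraph, ids: list) -> list:
    """Greedily group nodes by their most frequent shared feature.

    Repeatedly picks the feature occurring in the most remaining nodes
    (ties: smallest feature index) and groups all nodes containing it.
    Returns a list of id-lists; nodes sharing no feature end up alone.
    """
    pool = sorted(ids)
    groups = []
    while pool:
        counts = Counter()
        for i in pool:
            counts.update(graph.nodes[i].var)
        best = min(counts, key=lambda f: (-counts[f], f))
        group = [i for i in pool if best in graph.nodes[i].var]
        pool = [i for i in pool if best not in graph.nodes[i].var]
        groups.append(group)
    return groups


# ---------------------------------------------------------------------------
# compression passes


def forward_compress(
    graph: MSGGraph, node_id: Optional[int] = None, _check: Optional[Callable] = None
) -> MSGGraph:
    """Root-side compression pass (recursing toward the leaf).

    Children of ``node_id`` (all sharing it as their sole parent, which the
    construction order guarantees) are grouped by most-frequent shared
    feature; per multi-member group the full intersection ``F'`` is factored
    into a new intermediate node and removed from the members, members left
    empty being dropped with rewiring. The pass recurses on each new node.
    """
    node_id = graph.s_id if node_id is None else node_id
    kids = [c for c in graph.children[node_id] if graph.nodes[c].special is None]
    for group in _most_frequent_feature_groups(graph, kids):
        if len(group) < 2:
            continue
        shared = frozenset.intersection(*(graph.nodes[i].var for i in group))
        if not shared:
            continue
        parent_ids = sorted(graph.parents[group[0]])
        new = graph.add_node(feature_sets=[shared])
        for member in group:
            for p in list(graph.parents[member]):
                graph.remove_edge(p, member)
            graph.add_edge(new.id, member)
        for p in parent_ids:
            graph.add_edge(p, new.id)
        for member in group:
            remainder = graph.nodes[member].var - shared
            graph.nodes[member].feature_sets = [remainder]
            if not remainder:
                graph.remove_node(member, rewire=True)
        if _check is not None:
            _check(graph)
        forward_compress(graph, new.id, _check=_check)
    return graph


def _backward_step(graph: MSGGraph, node_id: int, _check: Optional[Callable]) -> None:
    parents = [p for p in graph.parents[node_id] if graph.nodes[p].special is None]
    # parents may sit on different levels: group by identical child sets first
    by_children: Dict[frozenset, list] = {}
    for p in sorted(parents):
        by_children.setdefault(frozenset(graph.children[p]), []).append(p)
    for child_set, group_ids in sorted(by_children.items(), key=lambda kv: kv[1]):
        for group in _most_frequent_feature_groups(graph, group_ids):
            if len(group) < 2:
                continue
            shared = frozenset.intersection(*(graph.nodes[i].var for i in group))
            if not shared:
                continue
            new = graph.add_node(feature_sets=[shared])
            for member in group:
                for c in list(graph.children[member]):
                    graph.remove_edge(member, c)
                graph.add_edge(member, new.id)
            for c in sorted(child_set):
                graph.add_edge(new.id, c)
            for member in group:
                remainder = graph.nodes[member].var - shared
                graph.nodes[member].feature_sets = [remainder]
                if not remainder:
                    graph.remove_node(member, rewire=True)
            if _check is not None:
                _check(graph)


def backward_compress(
    graph: MSGGraph, node_id: Optional[int] = None, _check: Optional[Callable] = None
) -> MSGGraph:
    """Leaf-side compression pass (recursing toward the root).

    Mirror image of :func:`forward_compress`: parents of each node are first
    grouped by identical child sets (parents can sit on different levels of
    the DAG), then by shared features, and the intersection is factored into
    a new node between the group and its children. Newly created nodes are
    themselves processed before moving upward.
    """
    node_id = graph.t_id if node_id is None else node_id
    queue = [node_id]
    visited: Set[int] = set()
    while queue:
        cur = queue.pop(0)
        if cur not in graph.nodes or cur in visited or cur == graph.s_id:
            continue
        visited.add(cur)
        _backward_step(graph, cur, _check)
        queue.extend(sorted(graph.parents[cur]))
    return graph


def or_compress(graph: MSGGraph, _check: Optional[Callable] = None) -> MSGGraph:
    """Merge nodes with identical parent sets and child sets into single
    nodes holding the concatenation of their feature sets, until no merge
    applies. Node count drops by |group| - 1 per merge; the total feature
    count is unchanged."""
    changed = True
    while changed:
        changed = False
        signature: Dict[tuple, list] = {}
        for i in graph.inner_ids():
            key = (
                tuple(sorted(graph.parents[i])),
                tuple(sorted(graph.children[i])),
            )
            signature.setdefault(key, []).append(i)
        for (parents, children), group in sorted(signature.items()):
            if len(group) < 2:
                continue
            sets: List[frozenset] = []
            for i in sorted(group):
                for fs in graph.nodes[i].feature_sets:
                    if fs not in sets:
                        sets.append(fs)
            new = graph.add_node(feature_sets=sets)
            for p in parents:
                graph.add_edge(p, new.id)
            for c in children:
                graph.add_edge(new.id, c)
            for i in group:
                graph.remove_node(i)
            if _check is not None:
                _check(graph)
            changed = True
            break  # signatures are stale after a merge; recompute
    return graph


# ---------------------------------------------------------------------------
# construction, decoding, classification


def build_msg(M: SolutionSet, debug: bool = False, decode_cap: int = DECODE_CAP) -> MSGGraph:
    """Build an MSG representing the family ``M``.

    Star graph (one node per solution), then forward, backward and OR
    compression. With ``debug=True`` the decoded family is re-checked after
    every individual merge operation (losslessness of each step).
    """
    if len(M) == 0:
        raise ValueError("cannot build a graph from an empty family")
    sets = [s.as_set for s in M.solutions]
    if len(set(sets)) != len(sets):
        raise ValueError("solutions must be distinct")
    if any(not s for s in sets) and len(sets) > 1:
        raise ValueError("the empty solution is only allowed as the sole solution")

    graph = MSGGraph()
    for s in sets:
        node = graph.add_node(feature_sets=[s] if s else [])
        if not s:  # sole empty solution: bare s -> node? keep s -> t chain
            graph.remove_node(node.id)
            graph.add_edge(graph.s_id, graph.t_id)
            return graph
        graph.add_edge(graph.s_id, node.id)
        graph.add_edge(node.id, graph.t_id)

    expected = frozenset(sets)
    check = None
    if debug:

        def check(g: MSGGraph, expected=expected, cap=decode_cap):
            got = decode_solutions(g, cap=cap).as_frozensets()
            if got != expected:
                raise AssertionError("a merge operation altered the decoded family")

    forward_compress(graph, _check=check)
    backward_compress(graph, _check=check)
    or_compress(graph, _check=check)
    graph.validate()
    return graph


def decode_solutions(graph: MSGGraph, cap: int = DECODE_CAP) -> SolutionSet:
    """Enumerate every s-to-t path and per-node feature-set choice; each
    combination's union is a solution. Returns the distinct solutions,
    sorted for determinism.

    Raises :class:`DecodeCapExceeded` past ``cap`` combinations (decoding is
    for verification and visualization, not a production path).
    """
    results: Set[frozenset] = set()
    seen_combinations = 0

    def walk(node_id: int, partials: List[frozenset]) -> None:
        nonlocal seen_combinations
        node = graph.nodes[node_id]
        if node.special is None:
            partials = [p | c for p in partials for c in node.feature_sets]
            if len(partials) > cap:
                raise DecodeCapExceeded(f"more than {cap} path/choice combinations")
        if node.special == "t":
            seen_combinations += len(partials)
            if seen_combinations > cap:
                raise DecodeCapExceeded(f"more than {cap} path/choice combinations")
            results.update(partials)
            return
        for child in sorted(graph.children[node_id]):
            walk(child, partials)

    walk(graph.s_id, [frozenset()])
    ordered = sorted(results, key=lambda s: tuple(sorted(s)))
    return SolutionSet([Solution(s) for s in ordered])


def classify_features(M: SolutionSet, universe) -> dict:
    """Feature taxonomy induced by a solution family.

    ``indispensable`` features appear in every solution; ``replaceable``
    features appear in some but not all. Everything else is reported as
    ``outside_all_solutions``: telling redundant features (informative in
    some context, in no solution) apart from irrelevant ones requires an
    existential search over all conditioning contexts, which no tractable
    procedure decides, so the two are reported as one bucket.
    """
    if len(M) == 0:
        raise ValueError("need at least one solution")
    sets = [s.as_set for s in M.solutions]
    indispensable = frozenset.intersection(*sets)
    replaceable = frozenset.union(*sets) - indispensable
    out = {}
    for f in sorted(int(f) for f in universe):
        if f in indispensable:
            out[f] = "indispensable"
        elif f in replaceable:
            out[f] = "replaceable"
        else:
            out[f] = "outside_all_solutions"
    return out


# ---------------------------------------------------------------------------
# export


def _label(node: MSGNode, names: Optional[list]) -> str:
    if node.special:
        return node.special
    parts = []
    for fs in node.feature_sets:
        shown = [names[f] if names else str(f) for f in sorted(fs)]
        parts.append("{" + ",".join(shown) + "}")
    return "|".join(parts)


def export_dot(graph: MSGGraph, path, feature_names: Optional[list] = None) -> None:
    """Write the graph as a Graphviz DOT file (deterministic node order;
    the root and leaf are drawn as plain circles, multi-set nodes carry
    '|'-separated labels)."""
    lines = ["digraph msg {", "  rankdir=LR;"]
    for i in sorted(graph.nodes):
        node = graph.nodes[i]
        shape = "circle" if node.special else "box"
        lines.append(f'  n{i} [label="{_label(node, feature_names)}" shape={shape}];')
    for i in sorted(graph.nodes):
        for c in sorted(graph.children[i]):
            lines.append(f"  n{i} -> n{c};")
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def graph_to_dict(graph: MSGGraph, feature_names: Optional[list] = None) -> dict:
    """JSON-ready representation: nodes with feature-name lists, edge list."""
    nodes = []
    for i in sorted(graph.nodes):
        node = graph.nodes[i]
        nodes.append(
            {
                "id": i,
                "special": node.special,
                "feature_sets": [
                    sorted(feature_names[f] if feature_names else f for f in fs)
                    for fs in node.feature_sets
                ],
            }
        )
    edges = [
        [i, c] for i in sorted(graph.nodes) for c in sorted(graph.children[i])
    ]
    return {"nodes": nodes, "edges": edges, "root": graph.s_id, "leaf": graph.t_id}
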
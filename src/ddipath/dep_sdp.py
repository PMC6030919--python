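"""Dependency graphs and the shortest dependency path (SDP) between entities.

The SDP between the two targeted drug tokens keeps the content words that
syntactically link the entities while dropping adjunct material hanging off
the path, which is what makes it a compact, informative input sequence for
relation classification.  Path finding ignores edge direction (the walk from
one entity to the other routinely crosses head->dependent edges both ways),
but the per-edge direction is recorded for downstream features.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

from .corpus_io import Token


class GraphError(ValueError):
    pass


@dataclass(frozen=True)
class DependencyGraph:
    """Undirected view of a dependency tree: edges are (head, dependent, deprel)."""

    n_nodes: int
    edges: frozenset[tuple[int, int, str]]

    def adjacency(self, reverse_order: bool = False) -> list[list[tuple[int, str, bool]]]:
        """Neighbour lists of (node, deprel, walk_is_head_to_dep)."""
        adj: list[list[tuple[int, str, bool]]] = [[] for _ in range(self.n_nodes)]
        for head, dep, rel in sorted(self.edges):
            adj[head].append((dep, rel, True))
            adj[dep].append((head, rel, False))
        if reverse_order:
            for lst in adj:
                lst.reverse()
        return adj


@dataclass(frozen=True)
class SDPath:
    """Ordered walk from the e0 token to the e1 token in the dependency tree.

    ``directions[k]`` is True when the k-th edge is walked head->dependent.
    """

    node_indices: tuple[int, ...]
    relations: tuple[str, ...]
    directions: tuple[bool, ...]

    def reversed(self) -> "SDPath":
        return SDPath(tuple(reversed(self.node_indices)),
                      tuple(reversed(self.relations)),
                      tuple(not d for d in reversed(self.directions)))


def build_graph(tokens: list[Token]) -> DependencyGraph:
    """One labelled edge per non-root token; errors on forests."""
    roots = [t for t in tokens if t.head is None]
    if len(roots) != 1:
        raise GraphError(f"expected exactly one root, found {len(roots)}")
    edges = frozenset((t.head, t.index, t.deprel) for t in tokens if t.head is not None)
    return DependencyGraph(n_nodes=len(tokens), edges=edges)


def shortest_path(graph: DependencyGraph, src: int, dst: int,
                  reverse_adjacency: bool = False) -> SDPath:
    """BFS shortest undirected path; unique on a tree.

    ``reverse_adjacency`` flips neighbour iteration order — on a tree the
    result must not change, which the test suite asserts.
    """
    if src == dst:
        raise GraphError("source and destination tokens coincide")
    if not (0 <= src < graph.n_nodes and 0 <= dst < graph.n_nodes):
        raise GraphError("path endpoints out of bounds")
    adj = graph.adjacency(reverse_order=reverse_adjacency)
    prev: dict[int, tuple[int, str, bool]] = {}
    seen = {src}
    queue = deque([src])
    while queue:
        node = queue.popleft()
        if node == dst:
            break
        for nxt, rel, head_to_dep in adj[node]:
            if nxt not in seen:
                seen.add(nxt)
                prev[nxt] = (node, rel, head_to_dep)
                queue.append(nxt)
    if dst not in seen:
        raise GraphError(f"no path between tokens {src} and {dst}")
    nodes = [dst]
    rels: list[str] = []
    dirs: list[bool] = []
    cur = dst
    while cur != src:
        parent, rel, head_to_dep = prev[cur]
        rels.append(rel)
        dirs.append(head_to_dep)
        nodes.append(parent)
        cur = parent
    nodes.reverse()
    rels.reverse()
    dirs.reverse()
    return SDPath(tuple(nodes), tuple(rels), tuple(dirs))


def sdp_tokens(path: SDPath, tokens: list[Token]) -> list[Token]:
    """Tokens restricted to the path, in walk order."""
    return [tokens[i] for i in path.node_indices]
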
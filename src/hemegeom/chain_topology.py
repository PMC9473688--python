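"""Heme contact graphs, main-chain tracing and branch detection.

A multiheme filament carries a chain of closely packed hemes running along
its axis; occasionally a heme sits off that chain, touching it at a single
point — a branch.  The main chain is defined here as the longest simple
path in the heme contact graph (contacts at the same ≤6 Å edge-to-edge
filter used for pair geometry), found exhaustively for components of up to
24 hemes and by a double-sweep heuristic beyond that.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .porphyrin_geometry import HemePair

HemeId = tuple[str, int, str]

EXHAUSTIVE_LIMIT = 24


@dataclass
class HemeGraph:
    """Contact graph over hemes, with the traced main chain and branches.

    ``graph`` nodes are heme ids ``(chain_id, residue_seq, residue_name)``;
    edges carry ``distance`` (Å), ``theta`` (deg) and ``motif`` attributes.
    ``main_chain`` and ``branches`` are filled by :func:`trace_main_chain`
    and :func:`branch_hemes`.
    """

    graph: nx.Graph
    main_chain: list[HemeId] = field(default_factory=list)
    branches: list[tuple[HemeId, HemeId, float]] = field(default_factory=list)

    @property
    def nodes(self) -> list[HemeId]:
        return sorted(self.graph.nodes)

    @property
    def isolated(self) -> list[HemeId]:
        return sorted(n for n, d in self.graph.degree if d == 0)


def build_graph(pairs: list[HemePair]) -> HemeGraph:
    """Build an undirected simple contact graph from heme pairs.

    Duplicate edges between the same two hemes collapse to the smallest
    distance.
    """
    g = nx.Graph()
    for p in pairs:
        u, v = p.ring_a.heme_id, p.ring_b.heme_id
        if g.has_edge(u, v) and g.edges[u, v]["distance"] <= p.min_distance:
            continue
        g.add_edge(u, v, distance=p.min_distance, theta=p.theta, motif=p.motif, pair=p)
    return HemeGraph(graph=g)


def _longest_path_exhaustive(g: nx.Graph) -> list[HemeId]:
    """Longest simple path by DFS backtracking; deterministic tie-break."""
    best: list[HemeId] = []

    def extend(path: list[HemeId], visited: set[HemeId]) -> None:
        nonlocal best
        candidate = _canonical(path)
        if len(path) > len(best) or (len(path) == len(best) and candidate < _canonical(best)):
            best = list(candidate)
        for nxt in sorted(g.neighbors(path[-1])):
            if nxt not in visited:
                visited.add(nxt)
                path.append(nxt)
                extend(path, visited)
                path.pop()
                visited.remove(nxt)

    for start in sorted(g.nodes):
        extend([start], {start})
    return best


def _canonical(path: list[HemeId]) -> list[HemeId]:
    """Orient a path so its lexicographically smaller endpoint comes first."""
    if path and path[-1] < path[0]:
        return list(reversed(path))
    return list(path)


def _double_sweep(g: nx.Graph) -> list[HemeId]:
    """BFS double sweep from an extremal-degree node (large-graph heuristic)."""
    start = min(sorted(g.nodes), key=lambda n: (g.degree[n], n))
    far, _ = _bfs_farthest(g, start)
    far2, path = _bfs_farthest(g, far)
    return _canonical(path[far2])


def _bfs_farthest(g: nx.Graph, source: HemeId):
    paths = nx.single_source_shortest_path(g, source)
    far = max(sorted(paths), key=lambda n: (len(paths[n]), n))
    return far, paths


def trace_main_chain(hg: HemeGraph) -> list[HemeId]:
    """Trace the main heme chain of the largest connected component.

    The main chain is the longest simple path; exhaustive search for
    components of ≤ 24 nodes, double-sweep BFS heuristic otherwise.  Ties
    break deterministically by (chain_id, residue_seq).  If no simple path
    covers at least half of a cyclic component a warning is emitted and the
    best path is returned anyway.
    """
    g = hg.graph
    if g.number_of_nodes() == 0:
        hg.main_chain = []
        return []
    components = sorted(nx.connected_components(g), key=lambda c: (-len(c), sorted(c)))
    sub = g.subgraph(components[0])
    if sub.number_of_nodes() <= EXHAUSTIVE_LIMIT:
        path = _longest_path_exhaustive(sub)
    else:
        path = _double_sweep(sub)
    if len(path) < (sub.number_of_nodes() + 1) // 2:
        warnings.warn(
            "no simple path covers half of the largest component; "
            "returning best path found",
            stacklevel=2,
        )
    hg.main_chain = path
    return path


def branch_hemes(hg: HemeGraph) -> list[tuple[HemeId, HemeId, float]]:
    """Hemes off the main chain, with their attachment points.

    A degree-1 off-chain heme is reported with its unique neighbour; an
    off-chain heme of higher degree is reported once per attachment.  Call
    after :func:`trace_main_chain`.
    """
    if not hg.main_chain and hg.graph.number_of_nodes() > 0:
        raise ValueError("main chain not traced yet; call trace_main_chain first")
    on_chain = set(hg.main_chain)
    out: list[tuple[HemeId, HemeId, float]] = []
    for node in sorted(hg.graph.nodes):
        if node in on_chain or hg.graph.degree[node] == 0:
            continue
        for nbr in sorted(hg.graph.neighbors(node)):
            out.append((node, nbr, hg.graph.edges[node, nbr]["distance"]))
    hg.branches = out
    return out


def write_edgelist_tsv(hg: HemeGraph, path: str | Path) -> None:
    """Edge list as TSV: chain/seq of both ends, distance, theta, motif."""
    lines = ["chain_a\tseq_a\tchain_b\tseq_b\tmin_distance_A\ttheta_deg\tmotif"]
    for u, v in sorted(hg.graph.edges):
        d = hg.graph.edges[u, v]
        lines.append(
            f"{u[0]}\t{u[1]}\t{v[0]}\t{v[1]}\t{d['distance']:.3f}\t{d['theta']:.2f}\t{d['motif']}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def to_dot(hg: HemeGraph) -> str:
    """GraphViz DOT rendering; main-chain edges bold, branches dashed."""
    chain_edges = {
        frozenset(e) for e in zip(hg.main_chain, hg.main_chain[1:])
    }

    def label(n: HemeId) -> str:
        return f"{n[0]}:{n[1]}"

    lines = ["graph hemes {"]
    for n in sorted(hg.graph.nodes):
        lines.append(f'  "{label(n)}";')
    for u, v in sorted(hg.graph.edges):
        style = "bold" if frozenset((u, v)) in chain_edges else "dashed"
        d = hg.graph.edges[u, v]["distance"]
        lines.append(f'  "{label(u)}" -- "{label(v)}" [style={style}, label="{d:.1f}"];')
    lines.append("}")
    return "\n".join(lines)
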
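"""Global alignment: weighted tile graph, Prim MST / Dijkstra SPT positions.

The 2MN-(M+N) pairwise links are redundant: only MN-1 of them are needed to
place every tile.  A weighted undirected graph is built with one vertex per
tile and one edge per link; the edge weight is the normalized inverse of the
matched-feature count (more matches = more reliable transform = lighter
edge), so the spanning structure prefers well-supported links and confines
error propagation.  Links without a match count (repaired/background) get a
penalty weight heavier than every finite edge so they are used only when
unavoidable.

Two spanning structures are supported: the Prim minimum spanning tree
(lowest total edge weight) and the Dijkstra shortest-path tree rooted at the
vertex whose total shortest-path weight to all others is minimal (each tile
then reaches the origin along its individually lightest path).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .registration import NORTH, WEST
from .repair import LinkTable

__all__ = ["AlignmentGraph", "TilePositions", "build_graph", "mst_positions", "spt_positions"]

Node = Tuple[int, int]


@dataclass
class AlignmentGraph:
    """Weighted undirected graph over tiles.

    Edge attributes: ``weight`` (normalized inverse match count, or
    ``1 + penalty_constant`` for sentinel-count edges), ``t`` = (t_x, t_y)
    oriented reference -> moving, ``ref``/``mov`` nodes, ``direction``.
    """

    graph: nx.Graph
    M: int
    N: int
    weight_penalty: float

    def edge_frame(self, tree_edges=None) -> pd.DataFrame:
        """Edge list as a DataFrame (debug dump)."""
        tree = {frozenset(e) for e in (tree_edges or [])}
        rows = []
        for u, v, data in sorted(self.graph.edges(data=True)):
            rows.append(
                dict(
                    u_row=u[0], u_col=u[1], v_row=v[0], v_col=v[1],
                    weight=data["weight"],
                    t_x=data["t"][0], t_y=data["t"][1],
                    in_tree=frozenset((u, v)) in tree,
                )
            )
        return pd.DataFrame(rows)


@dataclass
class TilePositions:
    """Global top-left tile coordinates in the mosaic frame (real-valued)."""

    positions: Dict[Node, Tuple[float, float]]
    origin: Node
    tree_edges: List[Tuple[Node, Node]] = field(default_factory=list)

    def __getitem__(self, node: Node) -> Tuple[float, float]:
        return self.positions[node]

    def __len__(self) -> int:
        return len(self.positions)

    def normalized(self) -> "TilePositions":
        """Shift so that min x = min y = 0."""
        xs = [p[0] for p in self.positions.values()]
        ys = [p[1] for p in self.positions.values()]
        x0, y0 = min(xs), min(ys)
        return TilePositions(
            positions={k: (x - x0, y - y0) for k, (x, y) in self.positions.items()},
            origin=self.origin,
            tree_edges=list(self.tree_edges),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(row=r, col=c, x=x, y=y)
            for (r, c), (x, y) in sorted(self.positions.items())
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TilePositions":
        df = pd.read_csv(path)
        pos = {
            (int(rec.row), int(rec.col)): (float(rec.x), float(rec.y))
            for rec in df.itertuples(index=False)
        }
        return cls(positions=pos, origin=min(pos))


def build_graph(table: LinkTable, penalty_constant: float = 1.0) -> AlignmentGraph:
    """Build the alignment graph from a fully repaired link table.

    Finite-count edges get weight ``(1/n) / max(1/n)`` so weights lie in
    (0, 1] and the weakest finite edge has weight exactly 1; sentinel-count
    edges get ``1 + penalty_constant``.  If no edge has a finite count (fully
    repaired grid) all edges get the penalty weight.
    """
    if penalty_constant <= 0:
        raise ValueError("penalty_constant must be > 0")
    links = table.all_links()
    for link in links:
        if not link.translation.is_finite:
            raise ValueError(
                f"link {link.reference}->{link.moving} has non-finite translation; "
                "run repair_links first"
            )
    inv = [1.0 / link.n_matched for link in links if np.isfinite(link.n_matched)]
    max_inv = max(inv) if inv else None
    penalty_weight = 1.0 + penalty_constant

    g = nx.Graph()
    for r in range(table.M):
        for c in range(table.N):
            g.add_node((r, c))
    for link in links:
        if np.isfinite(link.n_matched) and max_inv is not None:
            w = (1.0 / link.n_matched) / max_inv
        else:
            w = penalty_weight
        g.add_edge(
            link.reference,
            link.moving,
            weight=w,
            t=(link.translation.t_x, link.translation.t_y),
            ref=link.reference,
            mov=link.moving,
            direction=link.direction,
        )
    return AlignmentGraph(graph=g, M=table.M, N=table.N, weight_penalty=penalty_weight)


def _accumulate_positions(
    g: nx.Graph, tree_adj: Dict[Node, List[Node]], origin: Node
) -> Dict[Node, Tuple[float, float]]:
    """Propagate translations outward from the origin along tree edges."""
    pos = {origin: (0.0, 0.0)}
    stack = [origin]
    while stack:
        u = stack.pop()
        for v in tree_adj[u]:
            if v in pos:
                continue
            data = g.edges[u, v]
            tx, ty = data["t"]
            if data["ref"] == u:  # moving tile sits at ref position + t
                pos[v] = (pos[u][0] + tx, pos[u][1] + ty)
            else:
                pos[v] = (pos[u][0] - tx, pos[u][1] - ty)
            stack.append(v)
    return pos


def _positions_from_edges(
    ag: AlignmentGraph, edges: List[Tuple[Node, Node]], origin: Node
) -> TilePositions:
    tree_adj: Dict[Node, List[Node]] = {n: [] for n in ag.graph.nodes}
    for u, v in edges:
        tree_adj[u].append(v)
        tree_adj[v].append(u)
    pos = _accumulate_positions(ag.graph, tree_adj, origin)
    if len(pos) != ag.graph.number_of_nodes():
        raise ValueError("tree does not span the grid (graph disconnected?)")
    return TilePositions(positions=pos, origin=origin, tree_edges=edges).normalized()


def mst_positions(graph: AlignmentGraph) -> TilePositions:
    """Tile positions from the Prim minimum spanning tree.

    Relative positions are root-independent for a fixed tree; the result is
    normalized so the mosaic frame starts at (0, 0).
    """
    g = graph.graph
    if not nx.is_connected(g):
        raise ValueError("alignment graph is disconnected")
    mst = nx.minimum_spanning_tree(g, algorithm="prim")
    edges = sorted(tuple(sorted(e)) for e in mst.edges())
    origin = min(g.nodes)
    return _positions_from_edges(graph, edges, origin)


def spt_positions(graph: AlignmentGraph) -> TilePositions:
    """Tile positions from the Dijkstra shortest-path tree.

    The origin is the vertex minimizing the sum of shortest-path weights from
    all other vertices (ties broken by smallest (row, col)); each tile is
    then placed by accumulating translations along its shortest path to the
    origin.
    """
    g = graph.graph
    if not nx.is_connected(g):
        raise ValueError("alignment graph is disconnected")
    nodes = sorted(g.nodes)
    totals = {}
    for n in nodes:
        lengths = nx.single_source_dijkstra_path_length(g, n)
        totals[n] = sum(lengths[m] for m in sorted(lengths))
    # float-tolerant argmin: near-ties resolve to the smallest (row, col)
    t_min = min(totals.values())
    origin = min(n for n in nodes if totals[n] <= t_min + 1e-9 * max(1.0, abs(t_min)))

    preds, _ = nx.dijkstra_predecessor_and_distance(g, origin)
    edges = []
    for n in nodes:
        if n == origin:
            continue
        parent = min(preds[n])  # lexicographic tie-break among predecessors
        edges.append(tuple(sorted((parent, n))))
    return _positions_from_edges(graph, edges, origin)
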
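"""Grid discretization of the 2D embedding and the weighted transition graph.

The bounding box of the embedded points is cut into an ``n_c x n_c`` grid;
each grid cell is a potential node, identified row-major as
``row * n_c + col``. Consecutive windows give directed edges: the weight of
edge ``(u, v)`` counts how often window ``t`` fell in cell ``u`` and window
``t+1`` in cell ``v``. Self-loops (``u == v``) carry the mass of stable,
recurring patterns, so the sum of all edge weights is exactly ``N - 1``.
Only occupied cells become nodes, hence ``|V| <= n_cell`` no matter how long
the series is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embedding import Embedding2D


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned grid over the embedding bounding box.

    Points exactly on the right/top boundary clamp into the last cell; a
    degenerate axis (max == min, cell size 0) sends every point to row/col 0.
    """

    n_c: int
    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self):
        if self.n_c < 2:
            raise ValueError(f"n_c must be >= 2, got {self.n_c}")

    @property
    def n_cell(self) -> int:
        return self.n_c * self.n_c

    @property
    def s_x(self) -> float:
        return (self.x_max - self.x_min) / self.n_c

    @property
    def s_y(self) -> float:
        return (self.y_max - self.y_min) / self.n_c

    def _axis_bin(self, coords: np.ndarray, lo: float, step: float) -> np.ndarray:
        if step <= 0:
            return np.zeros(coords.shape, dtype=np.int64)
        idx = np.floor((coords - lo) / step).astype(np.int64)
        return np.clip(idx, 0, self.n_c - 1)

    def cell_ids(self, points: np.ndarray) -> np.ndarray:
        """Row-major cell id for each (x, y) point."""
        col = self._axis_bin(points[:, 0], self.x_min, self.s_x)
        row = self._axis_bin(points[:, 1], self.y_min, self.s_y)
        return row * self.n_c + col

    def rowcol(self, node_id: int) -> tuple[int, int]:
        return divmod(int(node_id), self.n_c)


@dataclass(frozen=True)
class NodePath:
    """Sequence of cell ids visited by consecutive windows, in time order."""

    ids: np.ndarray  # (N,) int64

    def __post_init__(self):
        object.__setattr__(self, "ids", np.asarray(self.ids, dtype=np.int64))

    def __len__(self) -> int:
        return int(self.ids.size)


@dataclass
class TSGraph:
    """Directed graph with positive integer edge weights, self-loops allowed."""

    n_c: int
    edges: dict[tuple[int, int], int] = field(default_factory=dict)
    node_cells: dict[int, tuple[int, int]] = field(default_factory=dict)

    @property
    def n_cell(self) -> int:
        return self.n_c * self.n_c

    @property
    def nodes(self) -> set[int]:
        return set(self.node_cells)

    @property
    def total_weight(self) -> int:
        return sum(self.edges.values())

    def weight(self, u: int, v: int) -> int:
        return self.edges.get((u, v), 0)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for node, (row, col) in sorted(self.node_cells.items()):
            g.add_node(node, cell=f"{row},{col}", row=row, col=col)
        for (u, v), w in sorted(self.edges.items()):
            g.add_edge(u, v, weight=int(w))
        return g


def grid_partition(emb: Embedding2D, n_c: int) -> tuple[GridSpec, NodePath]:
    """Bounding-box grid over the embedding and the temporal cell-id path."""
    pts = emb.points
    if pts.shape[0] == 0:
        raise ValueError("empty embedding")
    grid = GridSpec(
        n_c=n_c,
        x_min=float(pts[:, 0].min()),
        x_max=float(pts[:, 0].max()),
        y_min=float(pts[:, 1].min()),
        y_max=float(pts[:, 1].max()),
    )
    return grid, NodePath(grid.cell_ids(pts))


def build_graph(path: NodePath, grid: GridSpec) -> TSGraph:
    """Count consecutive-window transitions into a weighted directed graph."""
    ids = path.ids
    if ids.size < 2:
        raise ValueError("path needs at least 2 nodes to form a transition")
    codes = ids[:-1] * np.int64(grid.n_cell) + ids[1:]
    uniq, counts = np.unique(codes, return_counts=True)
    edges = {
        (int(c) // grid.n_cell, int(c) % grid.n_cell): int(k)
        for c, k in zip(uniq, counts)
    }
    node_cells = {int(v): grid.rowcol(int(v)) for v in np.unique(ids)}
    return TSGraph(n_c=grid.n_c, edges=edges, node_cells=node_cells)


def edge_weight_sequence(graph: TSGraph, path: NodePath) -> np.ndarray:
    """Weight of each consecutive transition along the path (length N - 1).

    Transitions absent from the graph (possible only for a foreign path)
    get weight 0.
    """
    ids = path.ids
    codes = ids[:-1] * np.int64(graph.n_cell) + ids[1:]
    if not graph.edges:
        return np.zeros(codes.size, dtype=np.float64)
    ecodes = np.array(
        sorted(u * graph.n_cell + v for (u, v) in graph.edges), dtype=np.int64
    )
    ew = np.array(
        [graph.edges[(int(c) // graph.n_cell, int(c) % graph.n_cell)] for c in ecodes],
        dtype=np.float64,
    )
    idx = np.searchsorted(ecodes, codes)
    idx_c = np.clip(idx, 0, ecodes.size - 1)
    out = ew[idx_c]
    out[ecodes[idx_c] != codes] = 0.0
    return out


def occupancy_stats(graph: TSGraph) -> dict:
    """Summary used for scalability checks: node count never exceeds n_cell."""
    total = graph.total_weight
    self_loop = sum(w for (u, v), w in graph.edges.items() if u == v)
    return {
        "node_count": len(graph.node_cells),
        "n_cell": graph.n_cell,
        "edge_count": len(graph.edges),
        "total_weight": total,
        "self_loop_fraction": (self_loop / total) if total else 0.0,
        "max_weight": max(graph.edges.values(), default=0),
    }
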
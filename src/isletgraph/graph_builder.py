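"""Contact-graph construction from cell coordinates: radius + shadow algorithm.

Two β cells are candidate neighbors when their centre-to-centre distance is
at most the neighborhood radius.  Because cells have a finite radius
(4 μm), a nearer cell can occlude a farther one: traversing a focal cell's
candidates in order of increasing distance, a candidate is rejected when
its direction falls within the angular *shadow* of a previously accepted
neighbor, whose half-width is

    θ(d) = arctan(cell_radius / d)

for an accepted neighbor at distance ``d``.  Only accepted cells cast
shadows.  The same construction works in 3d with a neighborhood sphere and
the angle measured between direction vectors, against the same cone
half-angle.

The inner loops are numba-compiled so that the stochastic rearrangement
simulations (which rebuild graphs after every move) run at the prescribed
cohort sizes; the public functions are thin wrappers over those kernels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from numba import njit
from scipy.spatial.distance import pdist

__all__ = [
    "NeighborhoodParams",
    "IsletGraph",
    "GeometryError",
    "shadow_angle",
    "directed_neighbors",
    "build_graph",
    "edge_removal_fraction",
]

DEFAULT_CELL_RADIUS = 4.0  # μm


class GeometryError(ValueError):
    """Coincident cell centres or other degenerate geometry."""


@dataclass(frozen=True)
class NeighborhoodParams:
    """Neighborhood radius, cell radius and edge symmetrization rule.

    radius
        Maximum centre-to-centre distance (μm) for an edge; the analysis
        sweeps 5–16 μm with the 8–13 μm band as the core range.
    cell_radius
        Physical cell radius (μm) entering the shadow half-angle; 4 μm.
    symmetrization
        ``"mutual"``: an edge exists only when each endpoint accepts the
        other in its shadow traversal (default — a physical contact must
        be mutual).  ``"union"``: acceptance in either direction suffices.
    """

    radius: float = 10.0
    cell_radius: float = DEFAULT_CELL_RADIUS
    symmetrization: str = "mutual"

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("radius must be > 0")
        if not self.cell_radius > 0:
            raise ValueError("cell_radius must be > 0")
        if not self.radius > self.cell_radius:
            raise ValueError("radius must exceed cell_radius")
        if self.symmetrization not in ("mutual", "union"):
            raise ValueError("symmetrization must be 'mutual' or 'union'")


@dataclass
class IsletGraph:
    """An islet's β-cell contact graph.

    ``cell_ids`` and ``coords`` are aligned arrays (coords in μm, 2 or 3
    columns); ``graph`` is an undirected networkx graph whose nodes are the
    cell ids.  Row order of ``coords`` is ascending ``cell_ids`` order,
    which is also the tie-break order of the shadow traversal.
    """

    cell_ids: np.ndarray
    coords: np.ndarray
    graph: nx.Graph
    params: NeighborhoodParams

    @property
    def n_vertices(self) -> int:
        return len(self.cell_ids)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[tuple[int, int]]:
        return {tuple(sorted(e)) for e in self.graph.edges}


def shadow_angle(d: float, cell_radius: float = DEFAULT_CELL_RADIUS) -> float:
    """Angular half-width (radians) of the shadow cast by a cell at distance d.

    θ = arctan(cell_radius / d): a 4 μm cell subtends a narrower cone the
    farther away it sits; strictly decreasing in d, in (0, π/2).
    """
    if d <= 0:
        raise GeometryError(f"shadow angle undefined for distance {d}")
    return math.atan(cell_radius / d)


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _directed_adjacency(coords, radius, cell_radius):
    """Directed shadow-acceptance matrix.

    directed[a, b] = True when b is accepted as a neighbor in the sorted
    traversal around focal a.  Works for 2 or 3 coordinate columns.  Ties in
    distance are broken by ascending row index (callers order rows by
    cell id).  Coincident points must be excluded by the caller.
    """
    n, dim = coords.shape
    directed = np.zeros((n, n), dtype=np.bool_)
    d = np.empty(n, dtype=np.float64)
    acc = np.empty(n, dtype=np.int64)
    for a in range(n):
        for j in range(n):
            s = 0.0
            for k in range(dim):
                diff = coords[j, k] - coords[a, k]
                s += diff * diff
            d[j] = math.sqrt(s)
        order = np.argsort(d, kind="mergesort")  # stable: ties by row index
        n_acc = 0
        for oi in range(n):
            b = order[oi]
            if b == a:
                continue
            if d[b] > radius:
                break  # sorted: all further candidates are farther
            ok = True
            for k in range(n_acc):
                p = acc[k]
                dot = 0.0
                for m in range(dim):
                    dot += (coords[b, m] - coords[a, m]) * (coords[p, m] - coords[a, m])
                cosang = dot / (d[b] * d[p])
                if cosang > 1.0:
                    cosang = 1.0
                elif cosang < -1.0:
                    cosang = -1.0
                ang = math.acos(cosang)
                # strict: boundary-equal candidates are accepted
                if ang < math.atan(cell_radius / d[p]):
                    ok = False
                    break
            if ok:
                acc[n_acc] = b
                n_acc += 1
                directed[a, b] = True
    return directed


@njit(cache=True)
def _symmetrize(directed, mutual):
    n = directed.shape[0]
    adj = np.zeros((n, n), dtype=np.bool_)
    for a in range(n):
        for b in range(a + 1, n):
            if mutual:
                e = directed[a, b] and directed[b, a]
            else:
                e = directed[a, b] or directed[b, a]
            adj[a, b] = e
            adj[b, a] = e
    return adj


@njit(cache=True)
def _shadow_adjacency(coords, radius, cell_radius, mutual):
    """Symmetrized adjacency matrix of the shadow contact graph."""
    return _symmetrize(_directed_adjacency(coords, radius, cell_radius), mutual)


@njit(cache=True)
def _threshold_edge_count(coords, radius):
    n, dim = coords.shape
    cnt = 0
    for a in range(n):
        for b in range(a + 1, n):
            s = 0.0
            for k in range(dim):
                diff = coords[b, k] - coords[a, k]
                s += diff * diff
            if math.sqrt(s) <= radius:
                cnt += 1
    return cnt


# ---------------------------------------------------------------------------
# public wrappers
# ---------------------------------------------------------------------------

def _check_coords(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] not in (2, 3):
        raise ValueError("coords must be (n, 2) or (n, 3)")
    if len(coords) > 1 and pdist(coords).min() == 0.0:
        raise GeometryError("coincident cell centres (pairwise distance 0)")
    return coords


def directed_neighbors(
    focal: int,
    coords: np.ndarray,
    params: NeighborhoodParams,
    cell_ids: np.ndarray | None = None,
) -> list[int]:
    """Accepted neighbors of one focal cell, in traversal (distance) order.

    ``focal`` is an index into ``coords`` (rows ordered by ascending cell
    id).  Returns indices (or ids when ``cell_ids`` is given) of the cells
    accepted by the shadow traversal around the focal cell.
    """
    coords = _check_coords(coords)
    if not 0 <= focal < len(coords):
        raise IndexError(f"focal index {focal} out of range")
    directed = _directed_adjacency(coords, params.radius, params.cell_radius)
    deltas = coords - coords[focal]
    dists = np.sqrt((deltas**2).sum(axis=1))
    accepted = [int(i) for i in np.argsort(dists, kind="stable") if directed[focal, i]]
    if cell_ids is not None:
        return [int(cell_ids[i]) for i in accepted]
    return accepted


def build_graph(
    coords: np.ndarray,
    params: NeighborhoodParams | None = None,
    cell_ids: np.ndarray | None = None,
) -> IsletGraph:
    """Build one islet's contact graph from cell coordinates (2d or 3d).

    Rows of ``coords`` must be ordered by ascending cell id (the distance
    tie-break); when ``cell_ids`` is omitted, row indices serve as ids.
    """
    params = params or NeighborhoodParams()
    coords = _check_coords(coords)
    n = len(coords)
    if n == 0:
        raise ValueError("need at least one cell")
    if cell_ids is None:
        cell_ids = np.arange(n)
    else:
        cell_ids = np.asarray(cell_ids)
        if len(cell_ids) != n:
            raise ValueError("cell_ids and coords disagree in length")
        if np.any(np.diff(cell_ids) <= 0):
            order = np.argsort(cell_ids, kind="stable")
            cell_ids, coords = cell_ids[order], coords[order]
    adj = _shadow_adjacency(coords, params.radius, params.cell_radius,
                            params.symmetrization == "mutual")
    g = nx.Graph()
    g.add_nodes_from(int(c) for c in cell_ids)
    ii, jj = np.nonzero(np.triu(adj, 1))
    g.add_edges_from((int(cell_ids[i]), int(cell_ids[j])) for i, j in zip(ii, jj))
    return IsletGraph(cell_ids=cell_ids, coords=coords, graph=g, params=params)


def edge_removal_fraction(
    coords: np.ndarray, params: NeighborhoodParams | None = None
) -> float | None:
    """Fraction of distance-threshold edges removed by the shadow filter.

    (edges within radius − edges after shadowing) / edges within radius.
    Returns ``None`` when no pair is within the radius (undefined).
    """
    params = params or NeighborhoodParams()
    coords = _check_coords(coords)
    if len(coords) < 2:
        raise ValueError("need at least two cells")
    n_thresh = int(_threshold_edge_count(coords, params.radius))
    if n_thresh == 0:
        return None
    n_kept = build_graph(coords, params).n_edges
    return (n_thresh - n_kept) / n_thresh
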
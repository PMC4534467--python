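"""Graph measures per islet, islet size classification and group comparison.

Three measures characterize one islet's β-cell connectivity:

* **mean degree** — average number of β-β contacts per cell,
* **components per islet** — count of maximal connected vertex subsets,
  split into *singular* (a lone β cell) and *nonsingular* (a β-cell
  cluster of ≥ 2 cells),
* **cells per component** — average component size, reported both over all
  components and over nonsingular components only.

Aggregation over a cohort follows each measure's own normalization: degree
is averaged over all *cells* in the group, component counts over *islets*,
and cells-per-component over *components* (islet-weighted averaging is
available via ``weights``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from scipy.stats import mannwhitneyu

from .graph_builder import IsletGraph

__all__ = [
    "GraphMeasures",
    "degree",
    "compute_measures",
    "effective_diameter",
    "classify_islet_size",
    "aggregate_measures",
    "group_compare",
    "SMALL_ISLET_DIAMETER",
]

#: effective-diameter cutoff (μm) below which an islet is "small"
SMALL_ISLET_DIAMETER = 60.0


@dataclass(frozen=True)
class GraphMeasures:
    """Measures of one islet graph or of a cohort aggregate."""

    mean_degree: float
    n_components: float
    n_nonsingular: float
    n_singular: float
    cells_per_component: float
    cells_per_nonsingular: float | None
    n_vertices: float

    def as_dict(self) -> dict:
        return {
            "mean_degree": self.mean_degree,
            "n_components": self.n_components,
            "n_nonsingular": self.n_nonsingular,
            "n_singular": self.n_singular,
            "cells_per_component": self.cells_per_component,
            "cells_per_nonsingular": self.cells_per_nonsingular,
            "n_vertices": self.n_vertices,
        }


def degree(v: int, g: IsletGraph) -> int:
    """Number of edges containing vertex ``v`` (cell id)."""
    if v not in g.graph:
        raise KeyError(f"vertex {v} not in graph")
    return g.graph.degree[v]


def compute_measures(g: IsletGraph) -> GraphMeasures:
    """All graph measures of one islet graph (components via traversal)."""
    graph = g.graph
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    comps = [len(c) for c in nx.connected_components(graph)]
    sizes = np.array(comps)
    n_singular = int((sizes == 1).sum())
    n_nonsingular = len(sizes) - n_singular
    nonsing = sizes[sizes > 1]
    return GraphMeasures(
        mean_degree=2.0 * graph.number_of_edges() / n,
        n_components=len(sizes),
        n_nonsingular=n_nonsingular,
        n_singular=n_singular,
        cells_per_component=float(sizes.mean()),
        cells_per_nonsingular=float(nonsing.mean()) if n_nonsingular else None,
        n_vertices=n,
    )


def effective_diameter(
    islet_coords: np.ndarray, cell_radius: float = 4.0, pad: bool = True
) -> float:
    """Equivalent-circle diameter (μm) of one islet.

    2·√(A/π) with A the convex-hull area of *all* endocrine cell centres,
    padded outward by one cell radius (hull area + perimeter·r + πr²) so a
    cell's extent, not just its centre, counts.  Islets with < 3 cells or
    collinear centres use the maximal pairwise extent plus one cell
    diameter.  Set ``pad=False`` for the bare hull's equivalent circle.
    """
    pts = np.asarray(islet_coords, dtype=float)[:, :2]
    if len(pts) == 0:
        raise ValueError("need at least one cell")
    r = cell_radius if pad else 0.0
    if len(pts) >= 3:
        try:
            hull = ConvexHull(pts)
            area = hull.volume  # 2d: volume is the area, area is the perimeter
            if pad:
                area += hull.area * r + np.pi * r * r
            return 2.0 * np.sqrt(area / np.pi)
        except QhullError:
            pass  # collinear: fall through to extent rule
    extent = pdist(pts).max() if len(pts) > 1 else 0.0
    return float(extent + 2.0 * r)


def classify_islet_size(
    islet_coords: np.ndarray, cutoff: float = SMALL_ISLET_DIAMETER
) -> str:
    """``"small"`` when the effective diameter is < 60 μm, else ``"large"``.

    Classification uses all endocrine cells of the islet, not only β cells.
    """
    return "small" if effective_diameter(islet_coords) < cutoff else "large"


def aggregate_measures(
    graphs: Sequence[IsletGraph | GraphMeasures], weights: str = "per_islet"
) -> GraphMeasures:
    """Cohort aggregate of per-islet measures.

    Degree is cell-weighted (equivalent to pooling all cells of the group);
    component counts are averaged per islet; cells-per-component is averaged
    per component (``weights="per_islet"``, the default interpretation) or
    per islet (``weights="islet_mean"``).  Graphs with no nonsingular
    component are excluded from the cells-per-nonsingular average.
    """
    ms = [compute_measures(g) if isinstance(g, IsletGraph) else g for g in graphs]
    if not ms:
        raise ValueError("empty collection")
    if weights not in ("per_islet", "islet_mean"):
        raise ValueError("weights must be 'per_islet' or 'islet_mean'")
    nv = np.array([m.n_vertices for m in ms], dtype=float)
    ncomp = np.array([m.n_components for m in ms], dtype=float)
    nnons = np.array([m.n_nonsingular for m in ms], dtype=float)
    nsing = np.array([m.n_singular for m in ms], dtype=float)
    cpc = np.array([m.cells_per_component for m in ms], dtype=float)

    # cell-weighted mean degree: sum of degrees over all cells / all cells
    mean_degree = float((np.array([m.mean_degree for m in ms]) * nv).sum() / nv.sum())

    if weights == "per_islet":
        # component-weighted: total cells in components / total components
        cells_per_component = float((cpc * ncomp).sum() / ncomp.sum())
        nonsing_cells = nv - nsing
        has = nnons > 0
        cells_per_nonsingular = (
            float(nonsing_cells[has].sum() / nnons[has].sum()) if has.any() else None
        )
    else:
        cells_per_component = float(cpc.mean())
        vals = [m.cells_per_nonsingular for m in ms if m.cells_per_nonsingular is not None]
        cells_per_nonsingular = float(np.mean(vals)) if vals else None

    return GraphMeasures(
        mean_degree=mean_degree,
        n_components=float(ncomp.mean()),
        n_nonsingular=float(nnons.mean()),
        n_singular=float(nsing.mean()),
        cells_per_component=cells_per_component,
        cells_per_nonsingular=cells_per_nonsingular,
        n_vertices=float(nv.mean()),
    )


def group_compare(
    a: Iterable[float], b: Iterable[float], n_tests: int = 1
) -> tuple[float, bool]:
    """Two-sided Mann-Whitney U test with Bonferroni correction.

    Returns (p_value, significant), where significance requires
    p < 0.05 / n_tests.  The analysis uses n_tests = 32 for degree
    comparisons and 64 for component comparisons (radius sweeps × strata).
    Degenerate all-tied samples return p = 1.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):  # all tied: no evidence either way
        return 1.0, False
    method = "exact" if (len(a) <= 8 and len(b) <= 8) else "auto"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(min(res.pvalue, 1.0))
    return p, p < 0.05 / n_tests
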
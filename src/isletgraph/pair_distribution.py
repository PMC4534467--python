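"""Pair distribution functions g(r) for islet cell point patterns.

For one islet with N cells of a given type inside a bounding box of area A,
the same-type estimator is

    g(r) = A / (2π r N²) · [# ordered pairs (i, j), i ≠ j, with r_ij in the
           bin at r] / dr

and the cross-type variant normalizes by N_a·N_b with ordered pairs running
a→b.  Under complete spatial randomness g ≡ 1 (up to boundary effects: no
edge correction is applied, matching the estimator's definition; the
resulting deficit grows with r and is quantified in the tests).  ``r`` is
evaluated at bin centres; bins default to 1 μm width spanning 0–50 μm,
fine enough to resolve the 8–13 μm contact band where islet cell pairs
peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist

__all__ = [
    "PairDistribution",
    "default_bins",
    "g_same",
    "g_cross",
    "average_over_islets",
    "pdf_difference",
]


def default_bins(r_max: float = 50.0, dr: float = 1.0) -> np.ndarray:
    """Bin edges 0..r_max with width dr (default 1 μm over 0–50 μm)."""
    return np.arange(0.0, r_max + dr / 2, dr)


@dataclass
class PairDistribution:
    """A binned g(r) estimate for one islet or an islet average.

    ``g`` is NaN-free for a single-islet estimate (zero-pair bins score 0);
    in an islet average a bin may be NaN when no islet contributed there.
    """

    bin_edges: np.ndarray
    g: np.ndarray
    islet_area: float
    n_a: int
    n_b: int
    n_islets: int = 1

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.g) != len(self.bin_edges) - 1:
            raise ValueError("g must have one value per bin")
        finite = self.g[np.isfinite(self.g)]
        if np.any(finite < 0):
            raise ValueError("g values must be >= 0")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def peak_radius(self) -> float:
        """Centre of the bin with the maximal (finite) g value."""
        g = np.where(np.isfinite(self.g), self.g, -np.inf)
        return float(self.bin_centers[int(np.argmax(g))])


def _bbox_area(points: np.ndarray) -> float:
    lo, hi = points.min(axis=0), points.max(axis=0)
    return float(np.prod(hi - lo))


def _normalize(counts, bin_edges, area, norm):
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    dr = np.diff(bin_edges)
    return area * counts / (2.0 * np.pi * centers * norm * dr)


def g_same(
    cells: np.ndarray, bins: np.ndarray | None = None
) -> PairDistribution | None:
    """Same-type pair distribution of one islet.

    ``cells``: (N, 2) coordinates (μm) of the cells of one type.  The islet
    area is the axis-aligned bounding box of these points.  Returns ``None``
    (undefined) for < 2 cells or a degenerate zero-area bounding box.
    """
    bins = default_bins() if bins is None else np.asarray(bins, dtype=float)
    cells = np.asarray(cells, dtype=float)
    if len(cells) < 2:
        return None
    area = _bbox_area(cells)
    if area <= 0:
        return None
    d = pdist(cells)
    counts, _ = np.histogram(d, bins=bins)
    counts = 2.0 * counts  # ordered pairs: each unordered pair counted twice
    n = len(cells)
    return PairDistribution(bins, _normalize(counts, bins, area, n * n), area, n, n)


def g_cross(
    cells_a: np.ndarray, cells_b: np.ndarray, bins: np.ndarray | None = None
) -> PairDistribution | None:
    """Cross-type pair distribution (e.g. α-β) of one islet.

    Ordered pairs run a→b; normalization is N_a·N_b.  The islet area is the
    bounding box of the union of both point sets (the cells entering the
    estimate).  Symmetric in (a, b).
    """
    bins = default_bins() if bins is None else np.asarray(bins, dtype=float)
    cells_a = np.asarray(cells_a, dtype=float)
    cells_b = np.asarray(cells_b, dtype=float)
    if len(cells_a) < 1 or len(cells_b) < 1:
        return None
    both = np.vstack([cells_a, cells_b])
    area = _bbox_area(both)
    if area <= 0:
        return None
    d = cdist(cells_a, cells_b).ravel()
    counts, _ = np.histogram(d, bins=bins)
    na, nb = len(cells_a), len(cells_b)
    return PairDistribution(bins, _normalize(counts, bins, area, na * nb), area, na, nb)


def average_over_islets(
    distributions: list[PairDistribution | None],
) -> PairDistribution:
    """Unweighted per-bin mean of g over islets with a defined estimate.

    ``None`` entries (islets where the estimate was undefined) are dropped;
    a bin is NaN only if no islet contributed at all (cannot happen for
    single-islet inputs, whose zero-pair bins are 0, not absent).
    """
    ds = [d for d in distributions if d is not None]
    if not ds:
        raise ValueError("no islet contributed a defined pair distribution")
    edges = ds[0].bin_edges
    for d in ds[1:]:
        if not np.array_equal(d.bin_edges, edges):
            raise ValueError("islet distributions must share bin edges")
    stack = np.vstack([d.g for d in ds])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.where(np.isfinite(stack), stack, np.nan), axis=0)
    return PairDistribution(
        edges, mean, float(np.mean([d.islet_area for d in ds])),
        int(np.sum([d.n_a for d in ds])), int(np.sum([d.n_b for d in ds])),
        n_islets=len(ds),
    )


def pdf_difference(
    g1: PairDistribution,
    g2: PairDistribution,
    r_lo: float = 0.0,
    r_hi: float = 50.0,
) -> tuple[np.ndarray, float]:
    """Per-bin difference g1 − g2 and ∫|g1 − g2| dr over [r_lo, r_hi].

    The integral uses the rectangle rule over bins whose centres lie in the
    window; the analysis integrates over [0, 50] μm with the 8–13 μm
    contact band as the focus window.
    """
    if not np.array_equal(g1.bin_edges, g2.bin_edges):
        raise ValueError("distributions must share bin edges")
    diff = g1.g - g2.g
    centers = g1.bin_centers
    dr = np.diff(g1.bin_edges)
    inside = (centers >= r_lo) & (centers <= r_hi)
    sel = np.abs(diff[inside]) * dr[inside]
    integral = float(np.nansum(sel))
    return diff, integral
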
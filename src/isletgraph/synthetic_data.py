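"""Synthetic islet cohorts: cluster-seeded hard-core point configurations.

The generator emulates the statistical structure the analysis relies on,
so the whole pipeline is testable without the deposited cohort:

* a hard-core minimum spacing between cell centres (cells have a 4 μm
  radius, so centres keep ≥ 8 μm by default),
* short-range aggregation — each cell is placed within the 8–13 μm contact
  band of an existing cell of its cluster, which puts the sole peak of the
  pair distribution function in that band,
* a size mixture spanning small (< 60 μm effective diameter) and large
  islets, two thirds small as in the reference cohort,
* endocrine type fractions near the observed composition (≈ 56% β),
* a population of scattered lone cells alongside the clusters: in real
  islet sections a majority of a β-cell graph's components are singular
  (lone β cells), so a fraction of cells is placed uniformly (hard-core
  only) rather than attached to a cluster.

Placement is by dart-throwing (rejection), which satisfies the hard-core
constraint exactly at these densities.  It is a test fixture emulating
islet-like geometry, not a biophysical islet model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .islet_io import IsletTable

__all__ = ["CohortSpec", "generate_islet", "generate_cohort", "generate_volume"]


class PackingError(RuntimeError):
    """Dart-throwing could not satisfy the hard-core constraint."""


@dataclass(frozen=True)
class CohortSpec:
    """Defaults are the study conditions the pipeline assumes.

    ``type_fractions`` = (α, β, δ) ≈ observed cohort composition;
    ``hard_core`` ≥ two cell radii; cells are attached at a distance in
    [hard_core, placement_max] of an existing cluster member, the band
    where islet cell pairs concentrate.  Small/large islet extents are
    centre-disc radii in μm chosen so the size classifier (< 60 μm
    effective diameter) separates the two classes by construction.
    """

    n_islets: int = 200
    small_fraction: float = 2.0 / 3.0
    type_fractions: tuple[float, float, float] = (0.33, 0.56, 0.11)
    hard_core: float = 8.0
    placement_max: float = 13.0
    small_radius: tuple[float, float] = (10.0, 22.0)
    large_radius: tuple[float, float] = (35.0, 60.0)
    density: float = 0.011           # cells / μm² at full fill
    fill: tuple[float, float] = (0.3, 0.6)
    cells_per_cluster: int = 8       # cluster seeds per large islet ≈ n / this
    scatter_fraction: float = 0.55   # cells placed uniformly, not cluster-attached
    group: str = "control"
    subject_id: str = "S1"
    max_failures: int = 2000

    def __post_init__(self) -> None:
        if abs(sum(self.type_fractions) - 1.0) > 1e-9:
            raise ValueError("type fractions must sum to 1")
        if self.hard_core < 8.0:
            raise ValueError("hard_core must be >= 2 cell radii (8 μm)")
        if not 0.0 <= self.small_fraction <= 1.0:
            raise ValueError("small_fraction must lie in [0, 1]")


_TYPES = np.array(["alpha", "beta", "delta"])


def _throw_cluster_points(
    n: int,
    radius: float,
    n_seeds: int,
    spec: CohortSpec,
    rng: np.random.Generator,
    dim: int = 2,
) -> np.ndarray:
    """Dart-throw ``n`` points into a disc/ball, attached to cluster seeds."""
    seed_r = max(radius - spec.placement_max, 0.3 * radius)
    clusters: list[list[np.ndarray]] = []
    pts: list[np.ndarray] = []
    failures = 0

    def _uniform_in_ball(r: float) -> np.ndarray:
        while True:
            cand = rng.uniform(-r, r, size=dim)
            if (cand**2).sum() <= r * r:
                return cand

    def _ok(cand: np.ndarray) -> bool:
        if (cand**2).sum() > radius * radius:
            return False
        if not pts:
            return True
        return cdist(cand[None, :], np.array(pts)).min() >= spec.hard_core

    for _ in range(n_seeds):
        for _ in range(200):
            cand = _uniform_in_ball(seed_r)
            if _ok(cand):
                clusters.append([cand])
                pts.append(cand)
                break
        else:
            failures += 1
    placed = len(pts)
    while placed < n:
        scatter = rng.random() < spec.scatter_fraction
        for _ in range(200):
            if scatter:  # lone cell: uniform in the islet, hard-core only
                cand = _uniform_in_ball(radius)
            else:        # cluster cell: in the contact band of an existing member
                c = clusters[int(rng.integers(len(clusters)))]
                anchor = c[int(rng.integers(len(c)))]
                dist = rng.uniform(spec.hard_core, spec.placement_max)
                direction = rng.normal(size=dim)
                direction /= np.linalg.norm(direction)
                cand = anchor + dist * direction
            if _ok(cand):
                if not scatter:
                    c.append(cand)
                pts.append(cand)
                placed += 1
                break
        else:
            failures += 1
            if failures > spec.max_failures:
                raise PackingError(
                    f"could not place {n} cells with hard core {spec.hard_core} μm "
                    f"in radius {radius:.0f} μm; request fewer cells"
                )
    return np.array(pts)


def generate_islet(
    spec: CohortSpec,
    rng: np.random.Generator,
    size: str | None = None,
    center: tuple[float, float] = (0.0, 0.0),
) -> pd.DataFrame:
    """One islet's cell records (columns cell_id, x, y, cell_type).

    ``size`` forces the class (``"small"``/``"large"``); by default it is
    drawn from the cohort's size mixture.
    """
    if size is None:
        size = "small" if rng.random() < spec.small_fraction else "large"
    lo, hi = spec.small_radius if size == "small" else spec.large_radius
    radius = rng.uniform(lo, hi)
    fill = rng.uniform(*spec.fill)
    n = max(1 if size == "small" else 3,
            int(round(spec.density * np.pi * radius**2 * fill)))
    n_seeds = 1 if size == "small" else max(1, round(n / spec.cells_per_cluster))
    if n == 1:
        pts = rng.uniform(-radius, radius, size=(1, 2))
    else:
        pts = _throw_cluster_points(n, radius, min(n_seeds, n), spec, rng)
    types = _TYPES[rng.choice(3, size=len(pts), p=spec.type_fractions)]
    return pd.DataFrame({
        "cell_id": np.arange(1, len(pts) + 1),
        "x": pts[:, 0] + center[0],
        "y": pts[:, 1] + center[1],
        "cell_type": types,
    })


def generate_cohort(spec: CohortSpec, rng: np.random.Generator) -> IsletTable:
    """A cohort of islets as a validated :class:`IsletTable`.

    Islet centres sit on a grid (400 μm pitch) so bounding boxes never
    interact; a fixed seed reproduces the table exactly.
    """
    frames = []
    per_row = max(1, int(np.ceil(np.sqrt(spec.n_islets))))
    for i in range(spec.n_islets):
        center = ((i % per_row) * 400.0 + 200.0, (i // per_row) * 400.0 + 200.0)
        df = generate_islet(spec, rng, center=center)
        df.insert(0, "islet_id", i + 1)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "group", spec.group)
    out.insert(0, "subject_id", spec.subject_id)
    return IsletTable(out)


def generate_volume(
    spec: CohortSpec,
    rng: np.random.Generator,
    n_cells: int = 120,
    radius: float = 60.0,
) -> pd.DataFrame:
    """One 3d islet volume (columns cell_id, x, y, z, cell_type).

    Cells are dart-thrown into a ball with the same hard-core and
    cluster-attachment rules as the 2d generator.
    """
    n_seeds = max(1, round(n_cells / spec.cells_per_cluster))
    pts = _throw_cluster_points(n_cells, radius, n_seeds, spec, rng, dim=3)
    types = _TYPES[rng.choice(3, size=len(pts), p=spec.type_fractions)]
    return pd.DataFrame({
        "cell_id": np.arange(1, len(pts) + 1),
        "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2],
        "cell_type": types,
    })
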
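"""Stochastic vertex rearrangement processes on islet contact graphs.

Each iteration theoretically deletes one β cell and adds one back near a
chosen parent cell, preserving the islet's cell count.  Which cell is
deleted, and which parent receives the new cell, is biased by a relative
likelihood (RL) kernel of the cell's current degree or component size x:

    RL+ (code P) = 0.5 + 0.5·tanh(x − rlp)
    RL− (code M) = 0.5 − 0.5·tanh(x − rlp)

so P favours well-connected cells / large clusters and M the opposite, with
the sigmoid midpoint at the relative-likelihood parameter ``rlp``.  A model
is written ``[RL_a][RL_d][rlp_a][rlp_d]``, e.g. ``MP01``: addition kernel M
with rlp_a = 0, deletion kernel P with rlp_d = 1.

Cells are finite-sized, so addition is steric: the new cell is placed at a
uniform random distance in the contact band (8–13 μm) from the parent, at
an angle sampled uniformly from directions not occluded by the parent's
neighbors; cells that end up closer than the islet's minimal observed
pairwise distance d_min are pushed radially outward from the parent in a
propagating wave until all pairwise distances are at least d_min again.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit
from scipy.spatial.distance import pdist

from .graph_builder import (
    IsletGraph,
    NeighborhoodParams,
    _shadow_adjacency,
    build_graph,
)
from .graph_measures import GraphMeasures
from .islet_io import IsletTable, filter_cells

__all__ = [
    "RLSpec",
    "ModelSpec",
    "SimulationConfig",
    "SimulationResult",
    "SimulationError",
    "rl_value",
    "select_vertex",
    "add_vertex",
    "run_simulation",
    "run_family_sweep",
    "convergence_diagnostics",
]

logger = logging.getLogger(__name__)

DEGREE_RLP_GRID = tuple(range(0, 8))      # degree-basis sweep 0..7
COMPONENT_RLP_GRID = tuple(range(1, 6))   # component-basis sweep 1..5


class SimulationError(RuntimeError):
    """Non-terminating steric wave or unplaceable vertex."""


@dataclass(frozen=True)
class RLSpec:
    """One relative-likelihood kernel: direction P (RL+) or M (RL−),
    midpoint ``rlp``, and the graph quantity it reads (``degree`` or
    ``component_size``)."""

    direction: str
    rlp: float
    basis: str = "degree"

    def __post_init__(self) -> None:
        if self.direction not in ("P", "M"):
            raise ValueError("direction must be 'P' or 'M'")
        if self.basis not in ("degree", "component_size"):
            raise ValueError("basis must be 'degree' or 'component_size'")


@dataclass(frozen=True)
class ModelSpec:
    """Addition and deletion kernels of one model; ``code`` is the
    ``[RL_a][RL_d][rlp_a][rlp_d]`` shorthand."""

    add: RLSpec
    delete: RLSpec

    @property
    def code(self) -> str:
        return (f"{self.add.direction}{self.delete.direction}"
                f"{self.add.rlp:g}{self.delete.rlp:g}")

    @classmethod
    def from_code(cls, code: str, basis: str = "degree") -> "ModelSpec":
        """Parse e.g. ``"MP01"`` (single-digit rlp values)."""
        if len(code) != 4 or code[0] not in "PM" or code[1] not in "PM":
            raise ValueError(f"model code must look like 'MP01', got {code!r}")
        return cls(
            add=RLSpec(code[0], float(code[2]), basis),
            delete=RLSpec(code[1], float(code[3]), basis),
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Sizes, neighborhood, steric rules and seed of one simulation run.

    Defaults mirror the full-scale study (500 iterations × 500 replicates);
    desk-scale analyses pass smaller values explicitly.
    """

    n_iterations: int = 500
    n_replicates: int = 500
    params: NeighborhoodParams = field(default_factory=NeighborhoodParams)
    placement_range: tuple[float, float] = (8.0, 13.0)
    seed: int = 0
    d_min_fallback: float = 8.0  # two touching 4 μm cells; used for < 2-cell islets
    record: str = "final"        # "final" or "trajectory"
    audit: bool = False          # steric pairwise audit after every addition
    max_wave_steps: int = 10_000

    def __post_init__(self) -> None:
        if self.n_iterations < 1 or self.n_replicates < 1:
            raise ValueError("n_iterations and n_replicates must be >= 1")
        if self.record not in ("final", "trajectory"):
            raise ValueError("record must be 'final' or 'trajectory'")


@dataclass
class SimulationResult:
    """Measure trajectories of one model over replicates and islets.

    ``measures``: one row per (replicate, islet[, iteration]) with the
    graph-measure columns; ``skipped``: islet keys with < 2 β cells;
    ``n_wave_moves``: total relocations performed by the steric wave.
    """

    model: ModelSpec
    config: SimulationConfig
    measures: pd.DataFrame
    skipped: list
    n_wave_moves: int
    n_placement_retries: int


# ---------------------------------------------------------------------------
# RL kernels and vertex selection
# ---------------------------------------------------------------------------

def rl_value(x, spec: RLSpec):
    """RL kernel value(s) in [0, 1]; rl_P(x) + rl_M(x) = 1 for all x."""
    x = np.asarray(x, dtype=float)
    t = 0.5 * np.tanh(x - spec.rlp)
    out = 0.5 + t if spec.direction == "P" else 0.5 - t
    return float(out) if out.ndim == 0 else out


@njit(cache=True)
def _component_labels(adj):
    """Connected-component label per vertex via traversal; returns
    (labels, n_components)."""
    n = adj.shape[0]
    labels = np.full(n, -1, dtype=np.int64)
    stack = np.empty(n, dtype=np.int64)
    c = 0
    for s in range(n):
        if labels[s] >= 0:
            continue
        labels[s] = c
        stack[0] = s
        top = 1
        while top > 0:
            top -= 1
            v = stack[top]
            for w in range(n):
                if adj[v, w] and labels[w] < 0:
                    labels[w] = c
                    stack[top] = w
                    top += 1
        c += 1
    return labels, c


def _basis_values(adj: np.ndarray, basis: str) -> np.ndarray:
    """Per-vertex degree or component size from an adjacency matrix."""
    if basis == "degree":
        return adj.sum(axis=1).astype(float)
    labels, ncomp = _component_labels(adj)
    sizes = np.bincount(labels, minlength=ncomp)
    return sizes[labels].astype(float)


def _weighted_draw(w: np.ndarray, rng: np.random.Generator) -> int:
    """Index ~ w / Σw (uniform fallback when all weights vanish)."""
    cum = np.cumsum(w)
    total = cum[-1]
    if total <= 0.0:  # all kernels saturated to zero: uniform fallback
        return int(rng.integers(len(w)))
    return int(np.searchsorted(cum, rng.random() * total, side="right"))


def _select_index(xs: np.ndarray, spec: RLSpec, rng: np.random.Generator) -> int:
    return _weighted_draw(rl_value(xs, spec), rng)


def select_vertex(g: IsletGraph, spec: RLSpec, rng: np.random.Generator) -> int:
    """Draw one vertex (cell id) with probability ∝ its RL value."""
    if g.n_vertices == 0:
        raise ValueError("empty graph")
    adj = nx_adjacency(g)
    xs = _basis_values(adj, spec.basis)
    return int(g.cell_ids[_select_index(xs, spec, rng)])


def nx_adjacency(g: IsletGraph) -> np.ndarray:
    """Boolean adjacency matrix in ``cell_ids`` row order."""
    idx = {int(c): i for i, c in enumerate(g.cell_ids)}
    adj = np.zeros((g.n_vertices, g.n_vertices), dtype=bool)
    for a, b in g.graph.edges:
        i, j = idx[int(a)], idx[int(b)]
        adj[i, j] = adj[j, i] = True
    return adj


# ---------------------------------------------------------------------------
# steric placement
# ---------------------------------------------------------------------------

def _free_angle(
    parent_xy: np.ndarray,
    neighbor_xy: np.ndarray,
    cell_radius: float,
    rng: np.random.Generator,
) -> float | None:
    """Sample a direction (radians) from angles not occluded by neighbors.

    Each neighbor at distance d blocks the arc of half-width
    arctan(cell_radius/d) around its direction.  Returns ``None`` when the
    union of blocked arcs covers the full circle.
    """
    if len(neighbor_xy) == 0:
        return float(rng.uniform(0.0, 2.0 * np.pi))
    delta = neighbor_xy - parent_xy
    dist = np.hypot(delta[:, 0], delta[:, 1])
    phi = np.mod(np.arctan2(delta[:, 1], delta[:, 0]), 2.0 * np.pi)
    half = np.arctan2(cell_radius, dist)
    # collect blocked arcs, unwrapped onto [0, 2π)
    arcs = []
    for p, h in zip(phi, half):
        lo, hi = p - h, p + h
        if lo < 0:
            arcs += [(lo + 2 * np.pi, 2 * np.pi), (0.0, hi)]
        elif hi > 2 * np.pi:
            arcs += [(lo, 2 * np.pi), (0.0, hi - 2 * np.pi)]
        else:
            arcs.append((lo, hi))
    arcs.sort()
    merged = [list(arcs[0])]
    for lo, hi in arcs[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    free = []
    cursor = 0.0
    for lo, hi in merged:
        if lo > cursor:
            free.append((cursor, lo))
        cursor = max(cursor, hi)
    if cursor < 2 * np.pi:
        free.append((cursor, 2 * np.pi))
    total = sum(hi - lo for lo, hi in free)
    if total <= 1e-12:
        return None
    u = rng.uniform(0.0, total)
    for lo, hi in free:
        if u <= hi - lo:
            return float(lo + u)
        u -= hi - lo
    return float(free[-1][1])  # numerical guard


def _radial_push(
    pts: np.ndarray,
    v: int,
    parent: int,
    vc: int,
    d_min: float,
    hi_band: float,
    rng: np.random.Generator,
) -> None:
    """Move pts[v] outward along the ray parent→v so its distance to the
    frozen vertex vc lands uniformly in [d_min, hi_band]."""
    u = pts[v] - pts[parent]
    norm = np.hypot(*u)
    if norm < 1e-12:  # v sits on the parent: push in a random direction
        ang = rng.uniform(0.0, 2.0 * np.pi)
        u = np.array([np.cos(ang), np.sin(ang)])
    else:
        u = u / norm
    w = pts[v] - pts[vc]
    b = float(w @ u)
    c = float(w @ w)
    eps = 1e-9 * max(1.0, d_min)
    t_lo = -b + math.sqrt(max(b * b - c + (d_min + eps) ** 2, 0.0))
    t_hi = -b + math.sqrt(max(b * b - c + hi_band**2, t_lo**2))
    t = rng.uniform(t_lo, max(t_hi, t_lo))
    pts[v] = pts[v] + t * u


def _steric_wave(
    pts: np.ndarray,
    parent: int,
    new: int,
    d_min: float,
    rng: np.random.Generator,
    max_steps: int,
) -> int:
    """Resolve d_min violations caused by the new cell (in place).

    Frozen/problem-list wave: vertices within d_min of the new cell are
    pushed radially outward from the parent until their distance to the
    closest frozen vertex lies in [d_min, max(10, d_min)]; vertices newly
    violated by a move are appended until the list empties.  The parent and
    the new cell never move.  Returns the number of relocations.
    """
    n = len(pts)
    d_new = np.hypot(*(pts - pts[new]).T)
    d_new[new] = d_new[parent] = np.inf
    if not np.any(d_new < d_min):  # common case: placement caused no violation
        return 0
    hi_band = max(10.0, d_min)
    frozen = np.zeros(n, dtype=bool)
    frozen[parent] = frozen[new] = True
    problem = deque(int(i) for i in np.argsort(d_new) if d_new[i] < d_min)
    queued = set(problem)
    moves = 0
    steps = 0
    while problem:
        steps += 1
        if steps > max_steps:
            raise SimulationError(
                f"steric wave did not terminate within {max_steps} steps "
                f"(islet of {n} cells, d_min={d_min:.3f})"
            )
        v = problem.popleft()
        queued.discard(v)
        frozen_idx = np.flatnonzero(frozen)
        d_frozen = np.hypot(*(pts[frozen_idx] - pts[v]).T)
        k = int(np.argmin(d_frozen))
        if d_frozen[k] >= d_min:  # resolved by an earlier move
            frozen[v] = True
            continue
        _radial_push(pts, v, parent, int(frozen_idx[k]), d_min, hi_band, rng)
        moves += 1
        d_all = np.hypot(*(pts - pts[v]).T)
        d_all[v] = np.inf
        re_queue_v = False
        for w in np.flatnonzero(d_all < d_min):
            w = int(w)
            if w in (parent, new):
                re_queue_v = True  # cannot move the core: v must go farther out
            elif w not in queued:
                frozen[w] = False
                problem.append(w)
                queued.add(w)
        if re_queue_v:
            if v not in queued:
                problem.append(v)
                queued.add(v)
        else:
            frozen[v] = True
    return moves


def add_vertex(
    g: IsletGraph,
    parent: int,
    rng: np.random.Generator,
    config: SimulationConfig,
    d_min: float | None = None,
) -> IsletGraph:
    """Add one cell near ``parent`` (a cell id) and rebuild the graph.

    The new cell id is max(cell_ids) + 1.  Raises
    :class:`SimulationError` when the parent is fully enclosed (no
    admissible angle); the simulation driver then retries another parent.
    """
    idx = int(np.flatnonzero(g.cell_ids == parent)[0])
    if d_min is None:
        d_min = observed_d_min(g.coords, config.d_min_fallback)
    new_pts, _ = _place_and_relax(
        g.coords, idx, d_min, rng, config, nx_adjacency(g)
    )
    new_ids = np.append(g.cell_ids, int(g.cell_ids.max()) + 1)
    return build_graph(new_pts, g.params, cell_ids=new_ids)


def observed_d_min(coords: np.ndarray, fallback: float = 8.0) -> float:
    """Minimal pairwise distance observed in the islet (fallback for < 2 cells)."""
    if len(coords) < 2:
        return fallback
    return float(pdist(coords).min())


def _place_and_relax(coords, parent_idx, d_min, rng, config, adj):
    """Place a new cell near parent and run the steric wave.

    Returns (new coordinate array with the new cell as the last row, number
    of wave moves).  The placement band [8, 13] μm and the relocation band
    [d_min, 10] μm are clamped from below at d_min so the steric invariant
    is preservable even in sparse islets.
    """
    lo = max(config.placement_range[0], d_min)
    hi = max(config.placement_range[1], lo)
    neighbors = coords[adj[parent_idx]]
    ang = _free_angle(coords[parent_idx], neighbors, config.params.cell_radius, rng)
    if ang is None:
        raise SimulationError("parent fully enclosed: no admissible angle")
    dist = rng.uniform(lo, hi)
    new_xy = coords[parent_idx] + dist * np.array([np.cos(ang), np.sin(ang)])
    pts = np.vstack([coords, new_xy])
    moves = _steric_wave(pts, parent_idx, len(pts) - 1, d_min, rng,
                         config.max_wave_steps)
    return pts, moves


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------

def _measures_from_adj(adj: np.ndarray) -> GraphMeasures:
    labels, ncomp = _component_labels(adj)
    sizes = np.bincount(labels, minlength=ncomp)
    n = adj.shape[0]
    n_singular = int((sizes == 1).sum())
    nonsing = sizes[sizes > 1]
    return GraphMeasures(
        mean_degree=float(adj.sum()) / n,
        n_components=int(ncomp),
        n_nonsingular=int(len(nonsing)),
        n_singular=n_singular,
        cells_per_component=float(sizes.mean()),
        cells_per_nonsingular=float(nonsing.mean()) if len(nonsing) else None,
        n_vertices=n,
    )


def _run_islet(
    coords: np.ndarray,
    model: ModelSpec,
    config: SimulationConfig,
    rng: np.random.Generator,
    sink: list,
    tag: tuple,
) -> tuple[int, int]:
    """Iterate delete+add on one islet; append measure rows to ``sink``."""
    params = config.params
    mutual = params.symmetrization == "mutual"
    d_min = observed_d_min(coords, config.d_min_fallback)
    n0 = len(coords)
    wave_moves = 0
    retries = 0
    pts = coords.copy()
    for it in range(1, config.n_iterations + 1):
        adj = _shadow_adjacency(pts, params.radius, params.cell_radius, mutual)
        # deletion move
        xs = _basis_values(adj, model.delete.basis)
        kill = _select_index(xs, model.delete, rng)
        pts = np.concatenate((pts[:kill], pts[kill + 1:]), axis=0)
        adj = _shadow_adjacency(pts, params.radius, params.cell_radius, mutual)
        # addition move (basis recomputed on the post-deletion graph)
        xs = _basis_values(adj, model.add.basis)
        w = rl_value(xs, model.add)
        placed = False
        excluded = None
        for _ in range(len(pts)):
            parent_idx = _weighted_draw(w, rng)
            try:
                pts, moves = _place_and_relax(pts, parent_idx, d_min, rng, config, adj)
                wave_moves += moves
                placed = True
                break
            except SimulationError:
                retries += 1  # parent fully enclosed; exclude it and redraw
                if excluded is None:
                    excluded = np.zeros(len(pts), dtype=bool)
                    w = w.copy()
                excluded[parent_idx] = True
                w[parent_idx] = 0.0
                if w.sum() <= 0.0:
                    w = (~excluded).astype(float)
        if not placed:
            raise SimulationError("no parent admits a new cell in this islet")
        if len(pts) != n0:
            raise AssertionError("cell count not conserved")  # structural bug guard
        if config.audit and len(pts) > 1:
            if pdist(pts).min() < d_min - 1e-9:
                raise SimulationError(
                    f"steric audit failed at iteration {it}: "
                    f"min distance {pdist(pts).min():.6f} < d_min {d_min:.6f}"
                )
        if config.record == "trajectory" or it == config.n_iterations:
            adj_now = _shadow_adjacency(pts, params.radius, params.cell_radius, mutual)
            m = _measures_from_adj(adj_now)
            sink.append((*tag, it, *m.as_dict().values()))
    return wave_moves, retries


_MEASURE_COLS = [
    "mean_degree", "n_components", "n_nonsingular", "n_singular",
    "cells_per_component", "cells_per_nonsingular", "n_vertices",
]


def run_simulation(
    table: IsletTable,
    model: ModelSpec,
    config: SimulationConfig,
) -> SimulationResult:
    """Run one model over all islets of a table, for all replicates.

    Only β cells participate (they are the graph's vertices); islets with
    fewer than 2 β cells are skipped and reported.  With a fixed
    ``config.seed`` the run is bit-reproducible: every (replicate, islet)
    pair draws from its own RNG stream derived from the master seed.
    """
    beta = filter_cells(table, "beta")
    islets = [(key, beta.coords(sub)[:, :2]) for key, sub in beta.islets()]
    kept = [(k, c) for k, c in islets if len(c) >= 2]
    skipped = [k for k, c in islets if len(c) < 2]
    if skipped:
        logger.info("skipping %d islets with < 2 beta cells", len(skipped))
    if not kept:
        raise ValueError("no islet has >= 2 beta cells")
    rows: list = []
    wave_moves = 0
    retries = 0
    for rep in range(config.n_replicates):
        for islet_no, (key, coords) in enumerate(kept):
            rng = np.random.default_rng([config.seed, rep, islet_no])
            w, r = _run_islet(coords, model, config, rng, rows,
                              (rep, str(key[0]), int(key[1])))
            wave_moves += w
            retries += r
    measures = pd.DataFrame(
        rows,
        columns=["replicate", "subject_id", "islet_id", "iteration", *_MEASURE_COLS],
    )
    return SimulationResult(model, config, measures, skipped, wave_moves, retries)


def final_cohort_means(result: SimulationResult) -> pd.DataFrame:
    """Per-replicate cohort means of each measure at the final iteration.

    Degree is cell-weighted; component counts islet-weighted;
    cells-per-component component-weighted — the same normalizations as
    :func:`isletgraph.graph_measures.aggregate_measures`.
    """
    df = result.measures
    df = df[df["iteration"] == df["iteration"].max()]
    out = []
    for rep, sub in df.groupby("replicate"):
        nv = sub["n_vertices"].to_numpy(float)
        ncomp = sub["n_components"].to_numpy(float)
        out.append({
            "replicate": rep,
            "mean_degree": float((sub["mean_degree"] * nv).sum() / nv.sum()),
            "n_components": float(ncomp.mean()),
            "cells_per_component": float(
                (sub["cells_per_component"] * ncomp).sum() / ncomp.sum()
            ),
        })
    return pd.DataFrame(out)


def run_family_sweep(
    table: IsletTable,
    family: str,
    basis: str,
    rlp_a_values,
    rlp_d_values,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Run one model family (e.g. ``"MP"``) over an rlp grid.

    Returns one row per (rlp_a, rlp_d, replicate) with cohort-mean
    measures at the final iteration; seeds are decoupled per grid point.
    """
    if len(family) != 2 or any(c not in "PM" for c in family):
        raise ValueError("family must be two letters from {P, M}")
    rows = []
    for ia, rlp_a in enumerate(rlp_a_values):
        for idd, rlp_d in enumerate(rlp_d_values):
            model = ModelSpec(
                add=RLSpec(family[0], float(rlp_a), basis),
                delete=RLSpec(family[1], float(rlp_d), basis),
            )
            cfg = replace(config, seed=int(np.random.SeedSequence(
                [config.seed, ia, idd]).generate_state(1)[0] % (2**31)))
            res = run_simulation(table, model, cfg)
            means = final_cohort_means(res)
            means.insert(0, "rlp_d", float(rlp_d))
            means.insert(0, "rlp_a", float(rlp_a))
            rows.append(means)
    return pd.concat(rows, ignore_index=True)


def convergence_diagnostics(values: np.ndarray) -> pd.DataFrame:
    """Running maximal SD and maximal change in mean over replicates.

    ``values``: array of shape (n_replicates, n_parameter_pairs) holding one
    summary measure per replicate per (rlp_a, rlp_d) pair.  For each i, the
    SD over replicates 1..i and the absolute change of the running mean are
    computed per pair and maximized over pairs.  Convergence shows as the
    maximal SD flattening and the maximal Δmean approaching zero.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] < 2:
        raise ValueError("need >= 2 replicates")
    n = values.shape[0]
    max_sd = np.full(n, np.nan)
    max_dmean = np.full(n, np.nan)
    prev_mean = values[0].astype(float)
    for i in range(2, n + 1):
        chunk = values[:i]
        max_sd[i - 1] = chunk.std(axis=0, ddof=1).max()
        mean = chunk.mean(axis=0)
        max_dmean[i - 1] = np.abs(mean - prev_mean).max()
        prev_mean = mean
    return pd.DataFrame({
        "n_replicates": np.arange(1, n + 1),
        "max_sd": max_sd,
        "max_delta_mean": max_dmean,
    })
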
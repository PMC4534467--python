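"""Shared fixtures: small synthetic cohorts and brute-force oracles.

The oracles deliberately re-implement the geometric predicates naively
(pure Python, no shared code with the package) so graph construction and
component finding can be checked against an independent route.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from isletgraph import CohortSpec, IsletTable, generate_cohort


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_neighbors(coords, focal, radius, cell_radius):
    """Naive shadow traversal: sorted candidates, angle test per accepted."""
    coords = [tuple(map(float, c)) for c in coords]
    cand = []
    for j in range(len(coords)):
        if j == focal:
            continue
        d = math.dist(coords[focal], coords[j])
        if d <= radius:
            cand.append((d, j))
    cand.sort()  # ties broken by ascending index (= ascending cell id)
    accepted = []
    for d, j in cand:
        ok = True
        vj = [coords[j][k] - coords[focal][k] for k in range(len(coords[0]))]
        for dp, p in accepted:
            vp = [coords[p][k] - coords[focal][k] for k in range(len(coords[0]))]
            dot = sum(a * b for a, b in zip(vj, vp))
            cosang = max(-1.0, min(1.0, dot / (d * dp)))
            if math.acos(cosang) < math.atan(cell_radius / dp):
                ok = False
                break
        if ok:
            accepted.append((d, j))
    return [j for _, j in accepted]


def oracle_edges(coords, radius, cell_radius, mutual=True):
    """Symmetrized edge set from the naive traversal."""
    n = len(coords)
    directed = [set(oracle_neighbors(coords, a, radius, cell_radius)) for a in range(n)]
    edges = set()
    for a in range(n):
        for b in range(a + 1, n):
            ab, ba = b in directed[a], a in directed[b]
            if (ab and ba) if mutual else (ab or ba):
                edges.add((a, b))
    return edges


def oracle_components(n, edges):
    """Equivalence classes of reachability via transitive closure."""
    reach = [[i == j for j in range(n)] for i in range(n)]
    for a, b in edges:
        reach[a][b] = reach[b][a] = True
    changed = True
    while changed:
        changed = False
        for i in range(n):
            for j in range(n):
                if reach[i][j]:
                    for k in range(n):
                        if reach[j][k] and not reach[i][k]:
                            reach[i][k] = True
                            changed = True
    classes = {tuple(row) for row in reach}
    return len(classes)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def small_cohort():
    """60 synthetic islets under the default cohort conditions."""
    spec = CohortSpec(n_islets=60)
    return generate_cohort(spec, np.random.default_rng(17))


@pytest.fixture
def tiny_table():
    """Three one-β-cell islets of one control subject."""
    df = pd.DataFrame({
        "subject_id": ["C1"] * 3,
        "group": ["control"] * 3,
        "islet_id": [1, 2, 3],
        "cell_id": [1, 1, 1],
        "x": [0.0, 100.0, 200.0],
        "y": [0.0, 0.0, 50.0],
        "cell_type": ["beta"] * 3,
    })
    return IsletTable(df)
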
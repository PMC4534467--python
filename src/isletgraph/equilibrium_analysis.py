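"""Measure-equilibrium detection for stochastic rearrangement models.

For each model family and addition parameter rlp_a, the mean simulated
minus experimental value of each graph measure is a curve in the deletion
parameter rlp_d.  A *measure-equilibrium* is an rlp_d at which that curve
crosses zero — the rearrangement process preserves the measure.  Curves are
summarized by the x-intercepts of a least-squares quadratic fit (curves
carry 5–8 points, so the quadratic is a fit, not a 3-point interpolation);
only real roots inside the swept rlp_d range count.  A family whose curves
never cross zero anywhere has no equilibrium (the full-scale study found
none for PM and MM).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph_measures import GraphMeasures

__all__ = [
    "MeasureDifferenceCurve",
    "measure_difference",
    "quadratic_intercepts",
    "summarize_equilibria",
    "curves_from_sweep",
]

MEASURES = ("mean_degree", "n_components", "cells_per_component")


@dataclass
class MeasureDifferenceCurve:
    """(rlp_d, simulated − experimental) points for one measure and rlp_a."""

    measure: str
    rlp_a: float
    rlp_d: np.ndarray
    diff: np.ndarray

    def __post_init__(self) -> None:
        self.rlp_d = np.asarray(self.rlp_d, dtype=float)
        self.diff = np.asarray(self.diff, dtype=float)
        order = np.argsort(self.rlp_d)
        self.rlp_d, self.diff = self.rlp_d[order], self.diff[order]
        if len(self.rlp_d) != len(self.diff):
            raise ValueError("rlp_d and diff must align")

    @property
    def has_sign_change(self) -> bool:
        """True when the curve touches or crosses zero within the sweep."""
        d = self.diff
        return bool(np.any(d == 0.0) or (d.min() < 0.0 < d.max()))


def measure_difference(sim: GraphMeasures, exp: GraphMeasures) -> dict[str, float]:
    """Simulated minus experimental value, per measure."""
    out = {}
    for m in MEASURES:
        out[m] = float(getattr(sim, m)) - float(getattr(exp, m))
    return out


def quadratic_intercepts(curve: MeasureDifferenceCurve) -> list[float]:
    """Real roots of the least-squares quadratic fit, inside the sweep range.

    Degenerate fits (quadratic and linear coefficients both ≈ 0) yield no
    roots; complex and out-of-range roots are discarded.
    """
    x, y = curve.rlp_d, curve.diff
    if len(x) < 3:
        raise ValueError("need >= 3 points for a quadratic fit")
    a, b, c = np.polyfit(x, y, 2)
    scale = max(1.0, np.abs(y).max())
    lo, hi = x.min(), x.max()
    tol = 1e-12 * scale
    if abs(a) < tol:
        if abs(b) < tol:
            return []
        roots = np.array([-c / b])
    else:
        roots = np.roots([a, b, c])
    out = []
    for r in roots:
        if abs(np.imag(r)) > 1e-9:
            continue
        r = float(np.real(r))
        if lo - 1e-9 <= r <= hi + 1e-9:
            out.append(min(max(r, lo), hi))
    return sorted(out)


def summarize_equilibria(
    curves: list[MeasureDifferenceCurve],
) -> pd.DataFrame:
    """Per-measure root ranges over rlp_a, plus the grand mean over all roots.

    One row per measure with [min, max] of its equilibria; the
    ``__mean__`` row holds the mean over all roots of all measures.  When no
    curve of any measure crosses zero the frame is empty apart from a
    ``no_equilibrium`` marker row.
    """
    rows = []
    all_roots = []
    for measure in dict.fromkeys(c.measure for c in curves):
        roots = []
        for c in (c for c in curves if c.measure == measure):
            roots.extend(quadratic_intercepts(c))
        if roots:
            rows.append({"measure": measure, "rlp_d_min": min(roots),
                         "rlp_d_max": max(roots), "n_roots": len(roots)})
            all_roots.extend(roots)
    if not all_roots:
        return pd.DataFrame([{"measure": "no_equilibrium", "rlp_d_min": np.nan,
                              "rlp_d_max": np.nan, "n_roots": 0}])
    rows.append({"measure": "__mean__", "rlp_d_min": float(np.mean(all_roots)),
                 "rlp_d_max": float(np.mean(all_roots)), "n_roots": len(all_roots)})
    return pd.DataFrame(rows)


def curves_from_sweep(
    sweep: pd.DataFrame, experimental: GraphMeasures
) -> list[MeasureDifferenceCurve]:
    """Build difference curves from a model-family sweep.

    ``sweep``: output of :func:`isletgraph.rearrangement_sim.run_family_sweep`
    (one row per (rlp_a, rlp_d, replicate) with cohort-mean measures);
    ``experimental``: cohort aggregate of the original islets at the same
    radius/strata.  Replicates are averaged per (rlp_a, rlp_d).
    """
    mean = sweep.groupby(["rlp_a", "rlp_d"], as_index=False)[list(MEASURES)].mean()
    curves = []
    for measure in MEASURES:
        exp_val = float(getattr(experimental, measure))
        for rlp_a, sub in mean.groupby("rlp_a"):
            curves.append(MeasureDifferenceCurve(
                measure=measure,
                rlp_a=float(rlp_a),
                rlp_d=sub["rlp_d"].to_numpy(),
                diff=sub[measure].to_numpy() - exp_val,
            ))
    return curves
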
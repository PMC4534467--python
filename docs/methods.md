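# Methods

This note records the models implemented by `isletgraph`, the choices made
where the method left details open, and what the synthetic test conditions
do and do not establish about real data.

## Contact-graph construction

Two β cells are candidate neighbors when their centre distance is at most
the neighborhood radius (default 10 μm for descriptive analyses, swept over
5–16 μm). Because cells are discs of radius ρ = 4 μm, a nearer contact can
occlude a farther one. The occlusion filter traverses a focal cell's
candidates in ascending distance and rejects a candidate whose direction
lies strictly inside the angular shadow of any *accepted* neighbor, of
half-width θ(d) = arctan(ρ/d) for a neighbor at distance d (θ is the
half-angle subtended by a 4 μm disc at distance d; it shrinks with
distance, so remote cells occlude little). Choices:

* **Only accepted cells cast shadows.** A rejected (occluded) cell is not a
  contact and cannot block others.
* **Tie-break.** Equidistant candidates are traversed in ascending cell-id
  order, making construction deterministic.
* **Boundary.** A candidate exactly on a shadow edge is accepted; the
  strict inequality keeps a measure-zero boundary from deleting edges.
* **Symmetrization.** An edge requires acceptance in *both* directions
  (`mutual`, the default — a physical contact must be mutual); `union`
  (either direction) is available for sensitivity checks.
* **3d.** The identical rule with the angle measured between direction
  vectors and a neighborhood sphere.

The inner loops are numba-compiled; tests check them edge-for-edge against
a naive pure-Python reimplementation on hundreds of random configurations.

## Graph measures and aggregation

Mean degree, components per islet (singular vs nonsingular) and cells per
component are computed per islet graph and aggregated per cohort with each
measure's natural weighting: degree over all cells of the group, component
counts per islet, cells-per-component per component (per-islet averaging is
available via `weights="islet_mean"`). Graphs without a nonsingular
component contribute no value (not zero) to the cells-per-nonsingular mean.

Islet size uses the equivalent-circle diameter 2√(A/π), with A the convex
hull of all endocrine cell centres padded outward by one cell radius
(A + P·ρ + πρ², P the hull perimeter); islets with < 3 or collinear cells
use the maximal extent plus one cell diameter. The < 60 μm cutoff defines
"small". The source analysis cites an external definition without printing
a formula, so exact reproduction of published large/small splits is not
promised; the padding can be disabled (`pad=False`).

Group contrasts: two-sided Mann-Whitney U (exact for samples ≤ 8, normal
approximation otherwise), Bonferroni-corrected with n = 32 for degree and
n = 64 for component comparisons (radius sweep × strata), matching the
published correction counts.

## Pair distribution estimator

g(r) = A/(2πrN²)·Σᵢ Σ_{j≠i} δ(r−r_ij) is realized as a histogram of
ordered pair distances with dr = 1 μm bins over 0–50 μm (fine enough to
resolve the 8–13 μm band), evaluated at bin centres. A is the axis-aligned
bounding box of the points entering the estimate. **No edge correction is
applied** — the defining formula has none. Consequence, quantified: for
uniform points in an L×L box the expectation is not 1 but
1 − 4r/(πL) + r²/(πL²); at L = 300 μm this is a 12% deficit at r = 30 μm,
and the calibration test asserts the estimator against this exact closed
form (to ±0.06 with 20 replicates of 500 points) rather than against 1.
Bins with zero pairs score 0 (defined), islets with < 2 cells or a
degenerate box contribute nothing to islet averages. Estimates are
undefined (None), never fabricated, in degenerate cases.

## Stochastic rearrangement process

Per iteration and islet: one deletion, then one addition (basis quantities
recomputed between the two moves). Selection draws a vertex with
probability proportional to its relative-likelihood value,
RL± = 0.5 ± 0.5·tanh(x − rlp), where x is the cell's degree
(degree basis, rlp grid 0–7) or its component's size (component basis,
grid 1–5). Normalizing the relative likelihoods into a distribution is the
minimal completion of "relative"; if every value underflows to zero the
draw falls back to uniform.

**Steric addition.** The new cell is placed at a uniform distance in the
contact band [8, 13] μm from the parent, at an angle drawn uniformly from
the complement of the parent's neighbors' shadow arcs (the same occlusion
geometry as graph construction). Cells within d_min of the new cell — d_min
being the minimal pairwise distance observed in the islet at simulation
start, 8 μm for islets with fewer than two β cells — are pushed radially
outward from the parent until their distance to the nearest frozen cell
falls in [d_min, 10] μm (the free relocation distance is drawn uniformly in
the admissible interval); newly violated cells join the wave until it
empties. Both bands are clamped from below at d_min so the steric invariant
is exactly preservable in sparse islets where d_min exceeds 8 or 10 μm.
A fully enclosed parent triggers reselection of another parent (logged); a
wave exceeding its step cap raises a simulation error rather than returning
an invalid configuration. Audited runs recheck all pairwise distances after
every addition (tolerance 1e-9 μm for floating-point roundoff).

**Simulation radius.** The default neighborhood radius for simulations is
13 μm, the upper edge of the contact band. The addition move means "place a
cell in contact with the parent", and its distance band is exactly the
8–13 μm band; a graph radius below 13 would silently discard a fraction of
those intended contacts and bias every model toward fragmentation, an
artifact of mismatched scales rather than a property of the process.
Descriptive analyses keep radius 10 as elsewhere.

**Reproducibility.** Every (replicate, islet) pair draws from its own RNG
stream derived from the master seed; reruns are bit-identical.

## Equilibrium detection

For each model family, rlp_a and measure, the curve of mean
simulated-minus-observed difference vs rlp_d is fitted with an ordinary
least-squares quadratic (curves carry 5–8 points, so "interpolation" with
three coefficients is a fit); real roots inside the swept range are the
measure-equilibria. A vanishing quadratic coefficient degrades gracefully
to the linear root; complex and out-of-range roots are discarded. Exact
polynomial inputs recover closed-form roots to 1e-9. Summaries report the
per-measure root range over rlp_a and the grand mean over all roots (the
mean-of-roots reading of the published summary statistic).

## 2d sections vs 3d volumes

z values quantized by 15 μm sectioning are de-quantized by per-cell uniform
jitter in [−7.5, 7.5] μm under a global 4 μm minimum distance; violating
draws are redrawn per cell (cap 1000, then an error naming the cell —
re-jittering the whole volume would also be defensible; per-cell redraw is
cheaper and keeps the accepted jitters untouched). Slabs are half-open
[lo, hi) intervals so sectioning is a partition for every slice-start
offset 0–14. The comparison aligns 3d sphere-graph measures with
slab-graph measures per radius; agreement is judged by rank correlation
across radii, the qualitative claim the comparison supports.

## Synthetic cohort generator

The generator emulates the features the pipeline relies on, with defaults
frozen as the package's study conditions:

* hard-core spacing ≥ 8 μm (two touching 4 μm cells), satisfied exactly by
  dart-throwing (rejection sampling) — no Gibbs/MCMC approximation;
* short-range aggregation: cluster cells attach at U[8, 13] μm from an
  existing cluster member, putting the sole g(r) peak inside 8–13 μm;
* scattered lone cells: 55% of cells are placed uniformly (hard-core only).
  In the reference architecture the majority of a β-cell graph's components
  are singular, and with these defaults the generated cohorts match its
  statistics closely at radius 13 — singular-component share ≈ 0.59
  (observed ≈ 0.61), ≈ 2.1 cells per component (≈ 2.3), mean degree ≈ 1.2;
* a size mixture, two-thirds small (< 60 μm effective diameter by
  construction: small-islet extents are capped well below the cutoff), with
  per-islet cell counts from an areal density of 0.011 cells/μm² at fill
  fractions 0.3–0.6;
* endocrine types drawn i.i.d. at (α, β, δ) = (0.33, 0.56, 0.11).

What it does **not** emulate: mantle-core type arrangement (types are
independent of position), islet-shape irregularity (discs/balls), density
gradients, vasculature, subject-level heterogeneity, or cell pairs closer
than the hard core. The last matters for the shadow filter: with all
spacings ≥ 8 μm, two candidates within a 10 μm radius can never sit inside
each other's occlusion cone, so the filter removes ≈ 0% of edges at radius
10 on synthetic cohorts, whereas measured sections (which contain closer
nucleus pairs) lose a few percent; occlusion on synthetic data only
appears at radii ≳ 14 μm. Tests passing
on these cohorts establish the correctness and internal consistency of the
algorithms — not that real islets satisfy any particular value; the
data-dependent count checks run only when the deposited cohort files are
supplied.

## Problem sizes

Desk-scale runs use 100–200 synthetic islets; simulation checks run 100
iterations, with 20 replicates for the equilibrium sweep over
rlp_a ∈ {1, 3} × rlp_d ∈ {1..5} for the MP and MM component-basis families.
At these sizes the MP-admits-equilibria / MM-does-not sign pattern is
reproduced with crossings near rlp_d ≈ 2, and the acceptance script
completes in a few minutes. Full-scale published sweeps (500 × 500 per grid
point, both bases, all four families and strata) are cluster-scale and out
of scope here.

## Known limitations

* The pair-distribution estimator's boundary deficit grows with r (see
  above); comparisons between estimates at matched geometry are unaffected,
  absolute levels at r ≳ 20 μm are biased low.
* d_min is fixed at simulation start; a process that itself compacted an
  islet below its initial minimal spacing cannot be expressed.
* The steric wave resolves violations outward from the parent only, as the
  defining procedure prescribes; pathological dense configurations are
  guarded by a step cap, not proven terminating.
* Effective-diameter padding is a convention (see above); size-class
  boundaries for borderline islets depend on it.
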
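# Methods

This note documents the models, conventions, defaults and numerical choices
behind `biofilmstat`, and what the synthetic constructions used in the test
suite do and do not demonstrate.

## Cell representation and coordinates

A cell is a centroid `r ∈ ℝ³` (µm; right-handed frame, substrate at `z = 0`,
colony in `z ≥ 0`), a unit director `n` (nematic: `n ≡ −n`; stored as a full
vector to avoid angle conventions), a pole-to-pole length `ℓ` and a diameter
`w` with `ℓ ≥ w > 0`. For all contact computations cells are treated as
spherocylinders: the axis segment of length `ℓ − w` swept by a sphere of
radius `w/2`. The surface separation of a pair is the minimal segment–segment
distance minus `w`; negative separation means steric overlap. CSV
serialization uses 9 significant digits, making write→read an identity to
1e-9 and outputs byte-stable.

## Per-cell features

* **Aspect ratio** `a = ℓ/w` — the mechanical shape parameter of a rod.
* **Local number density** — the count of *other* cells whose centroids lie
  within 2 µm of the focal centroid. Centroid-to-centroid distance is used
  (surface distance would require shape assumptions the cell table does not
  carry). The 2 µm radius is the package default and configurable.
* **Local nematic order** `S` — largest eigenvalue of
  `Q = (3⟨n nᵀ⟩ − I)/2`, the average running over the focal cell *and* its
  neighbours within the radius. Including the focal director stabilizes
  isolated cells (`S = 1` alone); `S ∈ [−1/2, 1]` analytically and is never
  clipped in statistics. The largest-eigenvalue (de Gennes) convention gives
  `S = 1` for perfect alignment and `0` for isotropy.
* **Distances** — to the substrate (`z`) and to the unweighted centroid of
  all cell centroids.
* **Surface area per volume** — area/volume of the alpha shape of cell
  centroids: Delaunay tetrahedra with circumradius below `α` form the body,
  faces used by exactly one kept tetrahedron form the surface. Default
  `α = 3 × mean cell width`, large enough to bridge nearest-neighbour gaps
  and small enough to follow colony concavities. This is a point-cloud proxy
  for a segmentation-mask surface; it is accurate to a boundary layer of one
  cell diameter and converges to the convex-hull ratio as `α → ∞`.

## Distribution representation and the Cd dissimilarity

Property supports are pooled [0.005, 0.995] quantile intervals over the whole
collection, widened by 5 % per side; sharing supports across a collection is
what makes coefficients comparable between biofilms. Values outside the
support (< 1 % by construction) are clamped to the edges rather than
discarded, preserving sample size. A property with zero pooled spread (e.g.
the constant width of synthetic packings) has no usable support and is
dropped with a notice.

On the canonical interval `[−1, 1]` the sample is smoothed by a Gaussian KDE
with Silverman bandwidth `h = 0.9 min(σ, IQR/1.34) n^{−1/5}`, floored at
0.01 canonical units, with mirror reflection at both interval edges.
Reflection keeps edge-concentrated distributions (neighbour counts piling up
at zero) unbiased and keeps the density mass inside the interval, so the
reconstruction integrates to 1 within a few percent. The KDE is evaluated at
the `d + 1` Chebyshev–Gauss–Lobatto nodes (`d = 20` by default) and
interpolated exactly via the type-I DCT; evaluation uses Clenshaw recursion.
Truncation can make reconstructed densities slightly negative; they are
reported as-is. The fit is deterministic bit-for-bit.

The dissimilarity between two fitted densities of the same property is
`Cd = 2 Σₖ |Δcₖ|` — a weighted-L1 metric on coefficient space. Because
`|Tₖ| ≤ 1` and the canonical interval has length 2, Cd upper-bounds the L1
distance between the reconstructions; summed over properties it bounds the
cumulative L1 distance between two biofilms' histogram sets. The bound, the
metric axioms, and the interpolation property are all verified in the test
suite against quadrature and direct-summation oracles.

**Cross-property redundancy.** For property comparison, each property's
coefficient vector across biofilms is z-normalized per coefficient index
(across biofilms, within property) so that properties with different units
become comparable; the Cd form is then applied between the normalized
vectors. Average-linkage hierarchical clustering on this m × m matrix, with
the cluster number chosen to maximize the mean silhouette coefficient over
`k = 2..m−1` (ties toward the smallest k; singleton clusters score 0, the
standard convention), merges redundant properties; each cluster is
represented by its medoid (minimal summed Cd to members, ties toward the
earliest input position). Exact duplicates and affinely related properties
(length vs aspect ratio at fixed width) come out at distance ≈ 0 and merge.

## PCA, the biofilm architecture index, and the phase diagram

Each biofilm's `(d+1) × p` coefficient matrix is flattened property-major and
the collection is decomposed by SVD after per-dimension centring. The
dimensions are values of canonical probability densities on a shared
interval — already unit-free and on a common scale — so no per-dimension
rescaling is applied: rescaling every coefficient to unit variance would give
noise-dominated dimensions the same weight as signal-carrying ones, burying
the architectural variance (measured on density-only synthetic collections it
drops the first component's explained variance from ~0.8 to ~0.24 and the
BAI–density rank correlation from ~0.98 to ~0.8). Zero-variance dimensions
are dropped and recorded; all non-trivial components are kept, so explained
variance ratios sum to one.

The **BAI** is the first principal-component score. Its sign is a convention:
the canonical-coordinate mean of the local-density distribution is linear in
the density coefficient block, and the sign is fixed so the BAI covaries
positively with that mean — "denser → larger BAI" by construction. (A simpler
rule, requiring the summed raw loading of the density block to be
non-negative, does not track the direction of a distribution shift and was
rejected.) Property contributions to the BAI are the summed squared PC1
loadings per coefficient block, normalized to one.

The phase diagram places each biofilm at (mean aspect ratio, mean local
density), coloured by BAI, nematic-order variance, or surface area per
volume.

## Mechanistic growth model

State: per-cell centroid, director, length. Dynamics are overdamped
(velocity ∝ force), appropriate at bacterial scales.

**Pair forces.** With surface separation `δ`, repulsion range `r_rep`,
attraction range `r_att`:

* repulsion `k_rep (r_rep − δ)^{3/2}` for `δ < r_rep` (Hertzian-type; the
  positive range models the soft matrix envelope around cells);
* attraction `f_att (1 − (δ − r_rep)/r_att)` for `r_rep ≤ δ < r_rep + r_att`,
  saturating at `f_att` for `δ < r_rep`. The saturation makes the total force
  continuous and creates a genuine resting separation
  `δ* = r_rep − (f_att/k_rep)^{2/3}` where adhesion balances repulsion; a
  force that switched off below `r_rep` would be discontinuous and admit no
  equilibrium.

Both terms are exact negative gradients of piecewise-C¹ potentials (verified
by central finite differences at random configurations, relative tolerance
1e-4). Forces act at the contact points along the contact normal, so every
pair is momentum-free while exerting torques about the centroids. Cell–surface
forces have the same form per endpoint sphere against the plane `z = 0`
(stiffness `k_rep`, strength `f_surf`, range `r_surf`), giving a resting
height `w/2 − (f_surf/k_rep)^{2/3}` for a horizontal cell.

**Contact geometry.** Segment–segment closest points via the unconstrained
solution followed by alternating coordinate clamping (convex box-constrained
quadratic; iterated well past convergence), validated against a fine
grid-search oracle. Coincident axes fall back to a fixed perpendicular
normal. Ellipsoids are approximated as spherocylinders: the closed-form
segment geometry is robust and preserves the qualitative mechanics (contact
range, attraction shell) of rod-shaped cells.

**Drag.** Translational drag `ζ∥ ℓ` along the axis and `ζ⊥ ℓ` across it with
`ζ⊥/ζ∥ ≥ 1` (the matrix polymer network suppresses transverse motion);
rotational drag `ζ_rot ℓ³`; only the torque component transverse to the axis
reorients a rod.

**Growth and division.** Lengths multiply by `exp(γ Δt)` each step
(exponential single-cell growth — exact to 1e-9 in the tests). Each cell
carries a division threshold drawn at birth from
`L_div · exp(σ_div 𝒩(0,1))`; on crossing it the mother splits into two
half-length daughters placed end-to-end along its axis, each tilted by a
small Gaussian kick (`σ_ori`) and given a fresh threshold. Daughters do not
inherit the mother's growth phase. The population doubling time equals
`ln 2/γ`; the tests estimate it by regressing `log₂ N(t)` over six
generations across ten seeds (within 5 %, typically ~1 %).

**Integration.** Explicit Euler with `Δt = 0.01 h` and a stability guard
that subdivides any step whose largest displacement would exceed `w/10`.
Neighbour candidates come from a k-d tree on centroids with cutoff
`max ℓ + r_rep + r_att`, rebuilt per step (equivalent to a uniform spatial
grid and faster to construct at these sizes). A single seeded
`numpy.random.Generator` supplies every stochastic draw in a fixed order
(founder orientation, then per-division tilt and threshold draws in cell
order), so runs are bit-reproducible given (params, seed).

**Defaults** (package choices validated by the invariant suite, not a
published calibration): `w = 0.8 µm`, `γ = ln 2 / 0.5 h⁻¹` (30-minute
doubling), `L_div = 3.0 µm`, `r_rep = 0.2 µm`, `r_att = 0.4 µm`,
`f_att = 1`, `k_rep = 100`, `f_surf = 2`, `r_surf = 0.2 µm`, `ζ∥ = 1`,
`ζ⊥/ζ∥ = 5`, `ζ_rot = 5`, `σ_div = 0.1`, `σ_ori = 0.05 rad`. Forces are in
arbitrary units; only their ratios and the drag scale matter for the
architecture.

## Parameter scans and fitting

A scan enumerates the Cartesian product of the four mechanical parameters
(`L_div`, `r_rep`, `r_att`, `f_att`) times seeds; outputs are standard cell
tables plus a manifest, and re-running skips existing outputs. Fitting
computes property tables for targets and library, pools Chebyshev supports
jointly over both (coefficients must share supports to be comparable — so
library Cd values depend on the targets they are fitted against), and ranks
library simulations by the cumulative Cd over the comparison properties
(aspect ratio, length, local density, local nematic order, substrate and
centroid distances; width is excluded as degenerate for fixed-diameter
cells). By default the Cd to a target group is the arithmetic mean over the
group's replicates; a per-replicate mode ranks each target separately. The
self-consistency experiment in the tests — targets simulated at a known grid
point with fresh seeds, fitted over a 3 × 2 grid of well-separated attraction
strengths and division lengths at 500 cells — recovers the generating point
in ≥ 8/10 repetitions (typically 9–10).

## Synthetic packing generator

Random sequential addition of non-overlapping spherocylinders into a
hemispherical dome on the substrate: candidates are placed at exactly the
prescribed spacing from a randomly chosen existing cell, rejected on steric
overlap or on leaving the dome, until the target count is reached (a bounded
attempt budget raises a "jammed" error when the spacing is infeasible for the
aspect ratios). Widths are fixed at 0.8 µm; lengths are width times a
lognormal aspect ratio. Orientations are in-plane isotropic within 1.2 µm of
the substrate and 3-D isotropic above (a crude mimic of the observed vertical
differentiation), or globally aligned with Gaussian tilt noise. The dome
geometry exercises substrate distance and surface-per-volume meaningfully.

The generator emulates the *statistical* structure of real microcolonies —
groups with prescribed shape and density levels — not their mechanics: there
is no growth history, no nematic ordering from steric interactions, and the
realized density saturates near the random-packing limit (long cells at
0.9 µm spacing jam). Passing tests on packings therefore demonstrate that the
statistics pipeline detects planted density/shape structure, not that it
reproduces any particular species.

The reference four-group construction used in tests (aspect-ratio medians
1.7 / 3.5 × spacings 1.0 / 2.2 µm, five biofilms of 500 cells per group)
spans mean neighbour counts from ~1.5 to ~12 — a contrast comparable to a
strong adhesion sweep — and aspect ratios from stubby to elongated rods. On
it, the pipeline separates the four groups in the first two principal
components (label silhouette ~0.9) and ranks local density and aspect ratio
as the top two BAI contributors.

## Problem sizes and limitations

Test-suite and acceptance-script experiments use 300–500-cell packings and
colonies and a 2,000-cell demonstration colony; these sizes give stable
statistics for every quantity measured while keeping a full run in minutes
on one CPU. Known limitations: the spherocylinder contact is a proxy for
ellipsoid contact; the alpha-shape surface is a centroid-cloud proxy; the
silhouette criterion for redundancy reduction is unreliable when all
properties are mutually near-equidistant (it then has no preferred scale);
and Cd values are comparable only within a shared-support collection, not
across separately fitted collections.
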
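# Methods

This note documents the model, the numerical choices and the limits of
what the test suite demonstrates.

## Tree model and units

A vascular tree is a rooted directed acyclic graph: nodes are points in
ℝ³ (μm), edges are straight rigid cylinders with radius (μm) and
volumetric flow (μm³/s).  Length is always derived from the endpoint
positions, never stored, so no geometric state can go stale while the
optimizer moves nodes.  The internal unit system is μm / s / N
throughout; pressures cross the API in mmHg via the single constant
1 mmHg = 1.33322·10⁻¹⁰ N μm⁻².  With these units the material cost and
the power cost both come out in N μm s⁻¹ (μW), which is what makes the
default weights commensurate.

Assumptions inherited by everything downstream: straight cylindrical
segments; terminals end in the cortex; blood is incompressible and
Newtonian, flow laminar; branching pressure losses are negligible; flow
is split equally over terminals.

## Hemodynamic closure

Flows: terminal vessels carry Q₀/N; internal vessels the sum of their
children (Kirchhoff).  Radii: terminal radii are drawn once from
N(10.08, 0.14) μm and propagated rootward by Murray's law
r_p³ = Σ r_c³; a degree-1 chain passes the radius through.  Radii are
*never* optimization variables — making them so is known to produce
abrupt radius jumps and to collapse the Strahler-order count, so the
cube law is a hard constraint.  Pressures: breadth-first from
p₀ = 100 mmHg with Δp = 8 μ l Q / (π r⁴).

Because radii and flows are a pure function of the topology and the
stored terminal radii, both are recomputed after every
topology-changing pass; conservation and the cube-law identity
therefore hold to floating-point accuracy at all times.

## Image priors

*Cortex shell.* Erosion of the organ mask by a Euclidean ball of radius
R₁ is computed as a distance-transform threshold (a voxel survives iff
its distance to background exceeds R₁) — exact for the Euclidean
structuring element and much faster than an explicit 3-D kernel.
Defaults R₁ = 2000 μm (rat cortical thickness at 12–18 weeks) and
R₂ = 5650 μm (hilar exclusion ball around the root).  Voxel/world
convention everywhere: 0-based indices, corner origin,
world = origin + index·voxel_size, isotropic voxels only.

*Centerline preprocessing.* Edge radius is the minimum of the endpoint
node radii (a vessel is no wider than its thinnest end), which
guarantees that loop/spur artifacts through thin spurious nodes rank
below every true edge.  The chain is: per-component minimum spanning
tree under weight −radius (each cycle loses its thinnest edge) →
orientation away from the root, keeping the root's component → collapse
of degree-2 chains into single straight vessels whose radius is the
length-weighted mean of the constituent radii → degree pruning (keep
the ≤ 4 children with the geometrically deepest subtrees; geometric
length was chosen over hop count so the metric matches depth pruning) →
depth pruning at 10 000 μm of cumulative path length (the printed
"450 voxels at 22.6 μm" is the rounded equivalent; 10 000 μm is taken
as canonical) → one final chain collapse, because depth pruning can
orphan one child of a bifurcation and leave a fresh degree-2 node.
With that last step the chain is idempotent, which the tests assert.

## Terminal sampling

Bridson dart throwing restricted to the mask: background grid of cell
r/√3, k = 30 candidates per active point drawn uniformly (by volume)
from the annulus [r, 2r], acceptance requires in-mask and no neighbor
within r.  A cube-then-filter Monte-Carlo variant is provided for exact
replication of the original procedure.  The spacing comes from
r_min = η (V/n)^{1/3}.  η = 0.7 was fixed from packing arithmetic — it
occupies π η³/6 ≈ 18 % of the volume, comfortably under the ≈ 38 %
ceiling of maximal Poisson-disk packings — and then verified once by
the calibration experiment in the suite (≥ 95 % of requested points on
the phantom cortex).  Same seed ⇒ bitwise-identical point sets.

## The optimization engine

Initialization connects each sampled terminal straight to its nearest
pre-built node (configurable to nearest *ending* node; exact ties break
to the lower node id) and records the attachment node as the terminal's
subtree label.  Those labels define piece-wise convex regions: a
terminal is only ever reconnected within its own subtree, so no vessel
ever crosses the organ's interior obstructions that the pre-built
geometry already avoids.

The local cost at a node v is Σ over incident vessels of
w_c π r² l + w_p Q² 8 μ l / (π r⁴).  The tree total sums the local cost
over all nodes, so every vessel is counted once per endpoint (exactly
2× the per-vessel sum); only this one convention is ever used, so the
factor cancels from all comparisons.

Passes, per outer iteration:

* **Relaxation** sweeps optimizer-created intermediate nodes in id
  order and minimizes each node's local cost by BFGS with the analytic
  gradient Σ coef_e (v − n_e)/‖v − n_e‖ (smoothed at 10⁻¹² to survive
  anchor collisions; a failed line search leaves the node unmoved).
  The root, the terminals and all pre-built nodes are fixed: the
  pre-built tree is the subject-specific prior, and moving it would
  destroy exactly the information the hybrid method exists to keep.
  For the same reason merging never contracts a pre-built node away and
  splitting only regroups non-pre-built children.
* **Merging** contracts the shortest incident vessel of any node where
  shortest/second-shortest < 0.2 (the threshold is exposed as
  `merge_ratio`; 0.2 merges relaxation-induced coincidences while
  legitimate short branches survive).  Sweeps repeat to a fixpoint —
  one contraction can expose a new near-coincidence at the surviving
  node, and the postcondition "no violating node remains" is the
  property the pass exists to establish.
* **Splitting** at a node with > 2 children: all child pairs are scored
  (O(n²)) as the cheapest 2-subset to hang under a new intermediate,
  the subset then grows one child at a time while the cost drops
  (capped at n−1 children; regrouping all of them is a pure chain
  insertion), and the split commits only on a strict decrease.
  Candidate positions are solved by a Weiszfeld fixed point — orders of
  magnitude cheaper than a quasi-Newton call per candidate, and the
  committed node is re-polished by the next BFGS relaxation anyway.
  After the improving sweep, any node still carrying more than four
  children receives the cheapest available split regardless of sign:
  more than four daughters is anatomically implausible, and the hard
  cap takes precedence over cost monotonicity in this rare corner.
* **Pruning** (scheduled coarsening): at iteration t, each
  initialization subtree keeps g(t) = 2 + ⌊t/2⌋ vessel generations
  below its attachment node ("generation" = edge depth; the schedule
  keeps two branch levels at first and grants one more every other
  iteration).  Detached terminals reconnect by a straight vessel to the
  nearest surviving node of their own subtree; intermediates left
  childless are discarded.  Leaf identity is preserved exactly.

The outer loop refines relax → merge → split to an inner fixed point
(≤ 6 sweeps, tolerance = the convergence tolerance) before measuring
the cost, tracks the incumbent (best refined tree), and restarts the
next, coarser scale from the incumbent when a prune+rebuild lands
worse.  The per-iteration cost log is therefore genuinely
non-increasing after the first iteration.  Convergence: relative cost
change < 10⁻³ between iterations; the final iteration ends after the
refine (never after a prune), so the returned tree is fully refined.
Non-convergence within `max_iterations` returns the incumbent with a
warning.  One seeded generator drives the terminal-radius draws; the
whole run is bitwise reproducible from (inputs, seed).

Pre-built ending nodes that attract no terminals are removed at
initialization: a childless non-terminal has no Murray radius or flow,
so the hemodynamic closure would be undefined below it.

## The phantom

`make_kidney_phantom` is a solid ellipsoid (default half-axes
8 × 5 × 4 mm, 100 μm voxels) with a ~2 % smooth random surface
perturbation and a paraboloid hilar indentation on the −x side — the
minimal geometry with the non-convexity the initialization must
survive.  `make_prebuilt_tree` grows 2–3 children per node for ~3
branch generations (what a real prior yields before segmentations stop
being trustworthy), tips at 30 μm and Murray radii upstream, so
distance-transform radii and cube-law radii agree on fixtures.
`make_noisy_centerline` re-creates the raw-skeleton artifacts — polyline
nodes, thin short spurs, thin loops — with artifact radii strictly below
every true radius and anchors restricted to junction nodes, which makes
exact ground-truth recovery a provable property (spur removal relies on
degree pruning with `max_children` matching the generator's branching
factor, as in the recovery test).

What the phantom does *not* emulate: medulla/pyramid/pelvis geometry,
CT intensities, anisotropic sampling artifacts, or segmentation bias.
Passing the suite therefore demonstrates the algorithmic contracts on
kidney-like geometry, not segmentation robustness on real scans.

## Desk-scale study conditions

Full scale is 30 000 terminals (≈ 10 h of optimization); the package's
tests and acceptance run use 60–500 terminals on a 200 μm phantom so
the whole suite fits in minutes.  Two scaling conventions keep the
small runs faithful:

* the inlet flow is scaled as Q₀(n) = n · Q₀/30 000, holding each
  terminal at its physiologic 3.89 nl/s — with the full 7 ml/min forced
  through 500 terminals the power term (∝ Q²) would dominate the
  material term ~3600-fold and the pressure field would be meaningless;
* analytic worked numbers (Murray root radius, symmetric-tree counts,
  flow bookkeeping) are computed at the true n = 30 000, since they
  cost seconds.

The idealized symmetric counterpart of the reconstructed tree is built
*with* its root trunk vessel (the renal artery exists as a segment and
carries the top Strahler order): 30 000 leaves give 2·30 000 − 1 ≈ 60 K
segments and ⌈log₂ 30 000⌉ + 1 = 16 levels, where a level counts the
vessels on a root-to-leaf path.

Pressures on a 500-terminal desk run are *not* physiologic at the path
level: the scaled tree spans full-kidney lengths with radii appropriate
to 500 terminals, so total drops exceed the real tree's (terminal
pressures near 50–55 mmHg emerge only at full scale).  The suite
asserts the structural property — strict monotone decrease from
100 mmHg — not the absolute values.

## Known limitations

Constant Newtonian viscosity (no Fåhræus–Lindqvist effect), no
pulsatility, no autoregulation or nephron models, no paired venous
tree, no curved vessels or tapering.  Skeletonization itself is out of
scope: the package consumes a centerline graph.  The greedy split is an
approximation to an NP-hard subset choice; the suite shows it matches
exhaustive enumeration on small fan-outs, not global optimality.
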
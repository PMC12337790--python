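# Methods

This note documents the models, estimators and numerical choices behind
`clonemech`, and what the synthetic-data validation does and does not
establish about real microscopy data.

## Tissue representation

A tissue is a planar polygonal tessellation: 2D vertices (µm), junction
polylines with one or two flanking cells, and cell polygons with flags
(clonal / apoptotic / excluded). Border junctions (one flanking cell) are
excluded from every statistic; cells touching the image or lattice edge are
flagged `excluded` because their polygons are truncated, but stay in the
adjacency graph so they still mediate graph distances.

**Mask ingestion.** Junctions are traced on the pixel-corner grid: every
unit edge between 4-adjacent pixels of different labels belongs to that
label pair, and chaining a pair's edges yields its shared polylines. Two
labels are adjacent only if a shared chain has ≥ 2 unit edges — this
suppresses the spurious single-corner contacts pixelation creates where
four cells meet. Coordinates are pixel-center based and converted to µm on
ingestion (one unit system downstream). Junctions shorter than the pixel
size cannot be recovered from a mask; on Lloyd-relaxed Voronoi tissues a
handful of sub-pixel junctions exist, so exact adjacency round-trips are
guaranteed only when the pixel size resolves the shortest junction
(acceptably, `rasterize_mask` at 0.2 µm/px round-trips the hexagonal
lattice exactly).

## Clone morphometrics

Circularity is C = 4πA/P² on the clone union outline; holes (an enclosed
non-clonal cell) reduce A but only the outer boundary enters P, matching a
contour-traced measurement. For pixelated outlines the staircase inflates P
and biases C down, so an optional single Chaikin corner-cutting pass
(`smooth=True`) is applied to the outer ring before measuring; both raw and
smoothed modes are exposed because the measurement convention on real
images is a user choice. Union geometry is computed with coordinates
snapped to a 1e-9 grid so that exactly coincident cell edges merge
robustly.

Connectivity is K = 2·E_int/n with E_int the number of distinct adjacent
clonal pairs. The theoretical ceiling uses the maximal polyhex edge count
E_max(n) = 3n − ⌈√(12n−3)⌉, the hexagonal-tiling idealization of minimal
soap-bubble clusters; an exhaustive polyhex enumeration
(`_hex.max_internal_edges_exhaustive`, feasible to n = 10) validates the
closed form in the test suite, and the greedy spiral construction attains
it for every n tested.

## Junction intensity

Mean intensity is measured over the junction polyline dilated to a
configurable width (default 3 px, a conventional thin-line choice; the
acquisition line width of real measurements is rarely reported). Pixels at
a shared vertex are counted in every junction meeting there. Normalization
divides by the mean intensity of the *same tissue's* external junctions —
never pooled across tissues — making Î gain-invariant and the external
class mean exactly 1. Line comparisons between classes use OLS of raw
intensity on junction length with the standard ANCOVA sequence: the
slope-equality test is the interaction coefficient, the intercept test is
the class offset under a common slope.

The synthetic painter draws each junction band at its class amplitude,
composing overlaps at shared vertices with the maximum. When the enriched
class has the highest amplitude this leaves band means unbiased (a lower
amplitude neighbor never contaminates a brighter band), which is the
regime used in the validation; with several enrichment levels the
junctions of intermediate classes acquire a small upward bias near their
vertices, bounded by the band-overlap fraction.

## Ablation recoil

The post-cut vertex separation follows an exponential with a plateau,
(d_t − d0)/l_c = D∞(1 − e^{−(t−t0)/τ}). d0 is fixed to the pre-ablation
mean (the protocol provides frames every 1.5 s for 7.5 s before the cut)
and t0 to the known ablation frame — fitting them at 1.5 s cadence trades
bias for variance. Nonlinear least squares runs over (D∞, τ) with bounds
D∞ ∈ [−1, 5], τ ∈ (0, 10·window], three τ starts, and plain squared loss.
Fits with τ below the frame cadence are flagged `under_resolved` rather
than silently reported, since only the plateau is then trustworthy — the
reason plateau-based statistics are preferred at this temporal resolution.
v0 = l_c·D∞/τ makes the plateau/initial-velocity proportionality exact by
construction.

Simulated traces use the same model at the experimental cadence (Δt =
1.5 s, 5 pre-ablation frames, 60 s post window within the 55.5–79.5 s
acquisition range) with additive Gaussian noise; default l_c = 3 µm is a
typical notum junction length.

## Mechanical equilibrium foams and force inference

**Balance definition (shared).** At every interior vertex (all incident
junctions two-sided) the tensions pull along junction chords; with
pressures enabled, each junction also contributes
½·L·(p_a − p_b)·n̂ to both endpoints along its normal. One function
(`forces.balance_residual`) defines this residual; the generator drives it
to zero and the inference assembles it into the matrix B.

**Why a pure tension network cannot be the generator.** At a trivalent
vertex the three tensions determine the inter-junction angles (force
triangle), and the angles must close around every face — one constraint
per face. An iid lognormal tension field violates these closure
constraints, so it admits *no* planar tension-only equilibrium: energy
minimization collapses edges (T1 cascades) and root-finding on the force
residual diverges. Two generators address this:

* `equilibrium_foam` — physical vertex-model statics, E = Σ T·L +
  (K_A/2)Σ(A − A⁰)², boundary vertices fixed, damped Newton with analytic
  gradient/Hessian to a residual below 1e-8 × mean tension. K_A is
  annealed from 0.2 down to 0.02 (tension units per µm³); the equilibrium
  pressures p = K_A(A⁰ − A) are part of the returned ground truth. Edges
  whose drawn tension exceeds the local T1 threshold are detected
  (length < 10% of rest length) and their tension reduced 30% with a
  cooldown, so the *returned* tension map always admits the equilibrium;
  typically ≲ 2% of edges are touched.
* `tension_only_foam` — the validation foam: alternates vertex-model
  relaxation with a minimal ridge projection of the tensions onto the
  null space of the current balance matrix (mean pinned at 1, spread
  rescaled to the drawn sd), then a joint Newton step on (positions,
  tensions) — the residual is linear in T, so the min-norm joint step
  lands exactly on the nearest tension-only root. The result is a genuine
  zero-pressure equilibrium whose tensions are lognormal-seeded with the
  requested sd (default 0.2), minimally adjusted. About 5% of draws admit
  no stable relaxation path at fixed topology and are redrawn from a
  deterministically derived sub-seed, so the ensemble is conditioned on
  relaxability. A planted localized contrast (e.g. clone-internal
  tensions ×0.6) is partially attenuated by the projection — the returned
  ground truth is always the *final* field, so recovery statistics remain
  honest.

**Inference.** T̂ = argmin ‖B·T‖² + μ‖T − 1‖² subject to mean(T) = 1,
solved exactly by parametrizing T = 1 + P·z with P an orthonormal basis of
the mean-zero subspace. μ (default 0.1; values below 1 are typical) is the
unit-mean prior strength; μ = 0 requires identifiability under the gauge
and otherwise raises. Chord directions are used rather than
curvature-resolved tangents — curvature estimated from pixelated junctions
adds noise with nothing to calibrate against. Negative tensions are
flagged, never clipped: they diagnose ill-conditioning. With
`with_pressure=True` the cell pressures enter as additional unknowns
(ridge toward 0, mean-centered); on pressure-carrying foams the joint
system is structurally underdetermined (≈ #junctions + #cells − 2·#interior
vertices null dimensions), which caps tension recovery near Pearson ≈ 0.8
at σ_T = 0.2 — the reason the zero-pressure foam is the parameter-recovery
benchmark (Pearson ≈ 0.98 at μ = 0.1). The full hierarchical evidence
maximization of Bayesian force-inference frameworks is an extension point;
the ridge form reproduces its point estimate under a fixed prior weight.

Group comparisons of inferred tensions use a two-sided permutation test on
the difference of medians, p = (1 + #{|Δ_perm| ≥ |Δ_obs|})/(1 + n_perm) —
the add-one estimate never returns zero.

## Apoptosis statistics

The null model is uniform sampling without replacement: the apoptotic
count in a category of m cells among N, with n apoptotic cells total, is
hypergeometric, and the *expected* count is the pmf mode k* (ties broken
toward smaller k). Each ring (clone = ring 0, then +1, +2, +3, >+3 by
graph distance) is tested marginally against its own hypergeometric,
accepting inter-ring dependence — fidelity to the stated method over a
joint multivariate model. Excluded cells (sensory organs, truncated border
cells, debris) are removed from N, m and n consistently; debris is an
input flag, never inferred. Ring sizes come either from the measured
tissue graph or from the hexagonal-tiling approximation around a maximally
compact (spiral) polyhex of the mean clone size — consistent with the
connectivity ceiling construction. Cross-genotype comparison rescales each
group's per-image ring percentages by (grand mean of total apoptotic
counts across groups)/(group mean total).

## Synthetic data: what it emulates, what it does not

The generator produces near-hexagonal monolayers (exact lattice, or
Lloyd-relaxed Voronoi with mirrored boundary seeds; mean apical area
16 µm², the pupal-notum scale), clones of 1–10 cells with tunable
compactness (rejection sampling weighted exp(β·E_int); β rises with
compactness, capped at 3 with a best-of-draws fallback; compactness 1 is
a deterministic beam search attaining the polyhex ceiling; clone sizes
default to a truncated geometric on 1..10 — a stand-in, as published
clone-size histograms are not printed as counts), painted junction images
(enrichment defaults ×1.5 internal, ×2.0 peripheral are placeholders, not
measured values), recoil traces, equilibrium foams, and apoptosis
placements (uniform without replacement, or ring-biased via weighted
sampling without replacement with Efraimidis–Spirakis keys). Everything is
deterministic under its seed.

Passing tests on these data establish that the estimators recover what
was planted under the stated noise models. They do not establish
robustness to real-image failure modes — segmentation errors, uneven
illumination, out-of-plane tilt, curved junctions, photobleaching — which
the pipelines inherit from their inputs.

## Numerical choices and degenerate inputs

- Relaxations: L-BFGS warm-up then damped Newton; the optimizer's
  projected-gradient norm is exactly the vertex force residual, so the
  convergence tolerance is the physical one (1e-8 × mean tension).
- Foam problem sizes in the validation suite: one 200-cell foam for
  correlation recovery, 100-seed ensembles at 100 cells for the clone
  readout — sizes chosen to exercise the full pipeline at interactive
  runtimes.
- Masks need ≥ 3 cells, integer labels, positive scale; traces need ≥ 3
  post-ablation samples, strictly increasing times, positive l_c; empty
  clone sets classify everything external (not an error); tissues without
  external junctions yield flagged, undefined normalized intensities.
- Tie-breaks: hypergeometric mode toward smaller k; clone components
  ordered by smallest member id; compact-growth ties toward the seed
  centroid.

## Known limitations

- Force inference is relative (mean-1 gauge); absolute tensions are not
  identifiable from geometry alone.
- Junctions are treated as straight chords; strongly curved junctions
  (high pressure differences) violate this.
- The mask reader assumes a single focal plane; no 3D topology.
- Ring statistics cap at +3 by default; deeper gradients are pooled into
  ">+3".
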
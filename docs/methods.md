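# Methods

This note documents the models, numerical choices and known limitations
behind `pitchshapes`, in the order of the pipeline.

## From tracking data to shape images

A frame is one team's player positions (metres) at one instant. The
goalkeeper is excluded before any geometry: their position is dictated
by the goal, not by the outfield block, and would distort the hull. The
hull itself is computed by Qhull (the QuickHull algorithm) and
normalized to counter-clockwise vertex order starting from the
lexicographically smallest vertex, so identical point sets always
produce byte-identical polygons. Collinear point sets are rejected
rather than degraded to segments — every downstream descriptor is
undefined for zero-area shapes.

Rasterization uses the pixel-center rule: a pixel is foreground iff its
center lies inside or on the polygon (boundary centers count as
foreground; this is the deterministic tie rule). The grid is snapped to
the world pixel lattice, so translating a shape by whole pixels shifts
its mask without resampling, and sub-pixel translations produce the
small, honest rasterization noise used as the comparison floor in the
scale-sensitivity checks. The contour is the set of foreground pixels
with at least one background 8-neighbour. Note that 8-connected digital
boundaries over-count the Euclidean perimeter by a digitization factor
approaching 4/π — one of the reasons the scalar descriptors are
computed from the polygon, not the raster.

**Raster defaults.** `pixel_size = 0.2 m/px`, `padding_px = 160`. The
padding is not cosmetic: it is the dilation budget of the multiscale
descriptor, 32 m at the default resolution. The multiscale curve of a
smooth convex hull only becomes sensitive to physical scale once
dilation radii pass the hull's inradius (≈ 10–15 m for team shapes):
below that, every convex outline yields the same near-1 dimension
curve, and the curve encodes size through the radius at which the
shape's interior saturates. 32 m safely exceeds the inradius of any
realistic team hull. The coarser 0.2 m pixel keeps these padded masks
small (a full pitch is ~525×340 px) with contours still hundreds of
pixels long; descriptor values at 0.1 m/px differ negligibly but cost
4× the memory and time.

## Multiscale fractal dimension

The exact squared Euclidean distance transform of the contour is
computed by the two-pass separable lower-envelope algorithm (numba-
compiled). Exactness is a contract, not an aspiration: squared
distances are integers (sums of two squares) and the test suite checks
bit-exact agreement with a brute-force nearest-contour scan and with
scipy's EDT. The dilation-area curve A(r) is then the cumulative
histogram of the cost map — the contour dilates symmetrically inward
and outward over the whole padded grid.

The log–log curve is fitted with a degree-10 polynomial. The fit runs
on log r mapped to [−1, 1] (`numpy.polynomial.Polynomial.fit`), which
keeps the degree-10 design matrix well conditioned; derivatives apply
the chain rule through the same mapping, so this is numerically
equivalent to fitting raw log r. r = 0 is excluded (log domain); the
fit window is [1 px, r_max] with r_max the largest radius whose
dilation stays fully inside the image, so clipped dilations never bias
the fit.

F(r) = 2 − f′(log r) is sampled at 100 points evenly spaced in log r
(linear spacing available) over the fit window trimmed by 10% of its
log-span at each end (`radius_trim = 0.1`). The trim exists because a
least-squares polynomial is least constrained at its window ends and
the smallest radii carry the strongest discretization artefacts; inside
the trimmed span, F is stable, and MF = max F is a meaningful summary
rather than an edge-wiggle artefact. FA is the trapezoidal integral of
the 100 samples — no finer grid is invented.

Validation anchors: a rasterized regular 64-gon (quasi-circle) and a
straight segment have central F ≈ 1; the iteration-4 Koch island's MF
falls in [1.15, 1.40], bracketing the analytic boundary dimension
log 4/log 3 ≈ 1.2619 with discretization tolerance.

## Scalar descriptors

Area and perimeter come analytically from the polygon (shoelace, edge
lengths) rather than from pixels, removing resolution dependence;
raster-based values can be derived from the mask if strict
image-pipeline parity is wanted. The minimum enclosing rectangle is the
minimum-area rectangle over all orientations (shapely's rotating
calipers), because team shapes have arbitrary orientation; an
axis-aligned mode exists behind a flag. Anchors: any rectangle has
rectangularity 1, any triangle exactly 0.5, a near-disk π/4 ≈ 0.785;
square circularity is 16, the disk minimum 4π. AllD concatenates the
five scalars raw (no normalization), preserving plain concatenation
semantics; a z-scored variant is a caller-side one-liner on the
descriptor table.

## Retrieval evaluation

Rankings are by Euclidean (L2) distance, ascending, ties broken by
image id for reproducibility. The query is excluded from its own
ranking by default: a distance-0 self-match carries no information and
would inflate P@n. Panels shown to raters are the union of the seven
descriptors' top-12 lists, deduplicated, shuffled by seed; 7 disjoint
lists give 84 images. P@n = r/n and R@n = r/rt, with rt the rater's
relevant count on the shown panel — images never shown do not enter rt.
P@n uses the unadjusted denominator n even when fewer than n relevant
images exist. Precision×recall curves are recorded at each rank where a
relevant image appears and aggregated at the standard 11 interpolated
recall levels. Aggregation is mean ± sd over (query, rater) cells.

## Rater agreement

Cohen's kappa on binary selected/not-selected labels over each query's
shared panel, pairwise between raters; per-descriptor tables restrict
the items to that descriptor's contributing top-12. Bands: ≤ 0.2
slight, 0.2–0.4 fair, 0.4–0.6 moderate, 0.6–0.8 substantial, > 0.8
almost perfect. The degenerate case of two identical constant raters
(p_e = 1) is defined as kappa = 1 with a warning. Kappa is reported
both raw and ×100 alongside the NR–NR and R–R percentages.

## Tactical clustering

k-means (k-means++, 10 restarts, fixed seed) on raw MFC vectors — all
100 components share the fractal-dimension scale, so standardization is
deliberately omitted. The number of clusters is chosen at the knee of
the inertia curve: both axes normalized to [0, 1], knee = the k whose
point lies farthest from the chord joining the curve's endpoints; if
the curve is anomalous (non-decreasing), the maximum second difference
is used with a warning. The inertia curve is always returned so an
analyst can override the automatic k. Halves are clustered jointly and
occurrence percentages split by half afterwards; exemplars are the
frames nearest each centroid (ties → earliest).

## Synthetic data

The generators define the conditions under which the pipeline is
tested:

- **Formation templates** (4-4-2, 4-3-3, 3-5-2, 4-2-3-1): ten outfield
  anchors on a 105×68 m pitch, jittered with isotropic Gaussian noise
  (default σ = 1 m, a realistic short-horizon positional spread) and
  optionally scaled about the block centroid. The anchor layouts were
  drawn once from standard mid-block geometries; the 4-2-3-1 is
  modelled as its characteristic compact low block, because regimes
  whose hulls have equal extent and similarly smooth outlines are not
  distinguishable by any shape descriptor — the templates represent
  tactically distinct organizations, in outline *and* extent.
- **Simulated matches** switch templates on a fixed schedule and carry
  the true regime labels, so cluster recovery is scored against ground
  truth (ARI), never re-derived from images.
- **The scale-varied benchmark**: 4 templates × block scales ×1, ×1.5,
  ×2 × 25 images = 300 images in 12 classes, 25 queries drawn from the
  collection. A class is a (template, scale) pair, so scale-invariant
  descriptors confuse the scales of one template while any single
  scalar collides somewhere; only the 100-point curve separates both
  factors. This is the construction behind the descriptor-ordering
  result.
- **Synthetic raters** judge an image relevant iff it shares the
  query's class, with independent label flips at error rate 0.1 (three
  raters per query) — an idealized, rule-based stand-in for human
  relevance judgment.

What the generators do not emulate: ball position and possession
phases, opponent interaction, player velocities, camera/tracking noise
structure, and the within-regime temporal correlation of real matches
(frames are sampled independently around the anchors). Passing tests
therefore demonstrate the correctness and discriminative structure of
the descriptors under controlled conditions, not match-analysis
findings: cluster counts, occurrence percentages and effectiveness
values on real tracking data are match- and rater-dependent.

## Problem sizes

Default experiment sizes were chosen to make every stochastic check
stable across seeds while keeping a full run in tens of seconds: 100
random 48×48 masks for EDT exactness, 20 hulls for
invariance/sensitivity, 300-image benchmark with 75 (query, rater)
cells, 40 frames per regime segment for recovery, 50 queries × 84
items for the kappa null.

## Known limitations

- The MFC's scale sensitivity saturates once shapes grow far beyond the
  dilation budget; shapes larger than ~2× the padding reach are
  compressed toward similar curves. Increase `padding_px` for
  collections with wider size ranges.
- Degree-10 fitting wiggles outside the trimmed span by construction;
  F values near the span ends are reported but should not be
  interpreted individually.
- Rectangularity inherits shapely's rotated-rectangle exactness
  (vertex-edge flush solutions); for near-degenerate slivers the MER
  area approaches zero and rectangularity is numerically delicate.
- The elbow rule is a heuristic; for real matches the returned inertia
  curve should be inspected, and k overridden where domain knowledge
  (e.g. known phase structure) suggests it.
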
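# pitchshapes

Shape descriptors for the spatial organization of football teams.

At any instant, a team's outfield players span a convex hull on the
pitch — the "surface area" of tactical analysis. Surface area alone
cannot say *how* a team is organized: different player arrangements can
produce equal areas, and similar arrangements can differ only in how
stretched they are. `pitchshapes` describes the hull's *shape* from its
binary image, with the multiscale fractal curve as the central
descriptor, and provides the full evaluation and application pipeline
around it: content-based image retrieval with precision/recall scoring,
inter-rater agreement, and k-means clustering of the shapes a team
adopts over a match.

It is aimed at sports scientists and performance analysts working with
2D player-tracking data, but the descriptor core operates on arbitrary
binary shape images and transfers directly to other shape-analysis
settings (e.g. biological image analysis).

## The descriptors

For a binary shape with contour dilation area `A(r)` at radius `r`, the
Minkowski–Bouligand dimension is `2 − lim_{r→0} log A(r) / log r`. The
multiscale variant keeps the whole scale dependence instead of the
limit: fit a degree-`n` polynomial (`n = 10`) to `log A` versus `log r`
and evaluate

    F(r) = 2 − d(log A)/d(log r)

from its analytic derivative at 100 sampled radii. The sampled curve is
the **MFC** feature vector; **MF** = max F and **FA** = ∫F d(log r) are
its scalar summaries. `A(r)` comes exactly from the cumulative histogram
of the contour's exact squared Euclidean distance transform.

Polygon scalars complete the set: **AP** = A/P (m), **Circularity** =
P²/A (dimensionless, ≥ 4π), **Rectangularity** = A/A(MER) ∈ (0, 1] with
the minimum-area enclosing rectangle over all orientations, and
**AllD** = [AP, FA, Circularity, MF, Rectangularity]. Circularity and
rectangularity are scale-invariant; the MFC is deliberately not — the
same outline at a different physical size yields a different curve,
which is what lets it separate team shapes that differ only in extent.

## Worked example

```python
import numpy as np
import pitchshapes as ps

# a simulated match: 4-4-2 out of possession, switching to 3-5-2
frames, true_regimes = ps.simulate_match(
    ["4-4-2", "3-5-2"], segment_lengths=30, jitter_sd=1.0, seed=7
)

# hull -> binary image -> multiscale fractal curve per frame
curves = []
for frame in frames:
    hull = ps.convex_hull(ps.exclude_goalkeeper(frame).positions)
    image = ps.rasterize(hull)
    curves.append(ps.mfc(image))

d0 = curves[0]
print(f"frame 0: hull area {ps.convex_hull(frames[0].positions).area:.1f} m^2, "
      f"MF {d0.MF:.3f}, FA {d0.FA:.3f}")

X = np.array([d.F for d in curves])
k, inertias = ps.elbow_k(X, k_max=8, seed=0)
result = ps.kmeans_mfc(X, k, seed=0)
result = ps.occurrence_stats(result, [f.half for f in frames], [f.t for f in frames])
print(f"elbow k = {k}")
print(result.occurrence.round(1))
```

prints

```
frame 0: hull area 931.4 m^2, MF 1.155, FA 4.293
elbow k = 2
         C1     C2
half
1       0.0  100.0
2     100.0    0.0
```

The first frame's hull covers 931 m²; its curve peaks at a fractal
dimension of 1.155 (a smooth convex outline stays near 1) with area
4.293 under the curve. The elbow of the inertia curve finds the two
planted organization regimes, and the occurrence table shows each half
spent entirely in its own shape cluster — the simulated tactical switch
at half-time, recovered from shape descriptors alone.

The same pipeline is scriptable from the shell (`pitchshapes shapes
build`, `descriptors all`, `cbir rank/panel/eval`, `agreement`,
`tactics cluster`, `fixtures make`); see `pitchshapes --help`.

Descriptor evaluation follows a retrieval protocol: queries are drawn
from the collection, the collection is ranked by L2 distance per
descriptor, raters judge relevance on shuffled panels built from each
descriptor's top 12 (7 disjoint lists → 84 images per query), and
effectiveness is summarized as P@5/P@10/R@5/R@10 and precision×recall
curves, with pairwise Cohen's kappa quantifying rater agreement.

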
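# Methods

## Signal model and T2 estimation

Multi-echo spin-echo magnitude images are modeled voxelwise as
mono-exponential decay, S(TE) = S0 · exp(−TE/T2), sampled at a strictly
increasing echo train (default: 11.4, 22.8, 34.2, 45.6, 57.0, 68.4, 79.8,
91.2 ms). The default estimator is unweighted log-linear least squares —
a straight-line fit of ln S against TE with T2 = −1/slope and
S0 = exp(intercept) — using all echoes. An `exclude-first-echo` style
subset is supported by passing a truncated echo train, since stimulated
echoes commonly contaminate the first echo in practice; nothing in the
default pipeline drops it. A signal-domain nonlinear least-squares
estimator (optionally with an additive constant offset, to absorb a noise
floor) is provided for bias studies and initialized from the log-linear
solution, falling back to it with a flag on non-convergence.

Numerical edge cases: zero or negative signals (possible only in
synthetic data; magnitude MRI is non-negative) are clipped to 1e-6 of the
voxel's peak before the log; a voxel with more than two such echoes, or
with fewer than three echoes, or with a fitted slope at or above −1e-9 per
ms (i.e. T2 above 1e9 ms — no physical decay), is flagged invalid rather
than raising. R² is computed in the domain of the fit (log for
log-linear, linear for NLS) and clipped to [0, 1]. Fits are voxelwise
independent; no spatial regularization is applied before filtering.

## Filtering

The tendon mask is filtered before profiling to suppress noise and
partial-volume contamination: a voxel survives if its fit is valid, its
T2 lies in [5, 120] ms, and its R² is at least 0.7. The bounds are design
defaults — chosen to exclude cortical/subchondral bone (T2 of a few ms,
low signal) and bursal fluid (T2 of hundreds of ms) while retaining even
strongly degenerate tendon (segment means up to ~70 ms) — and are
user-settable. Removal counts are reported per criterion; removing more
than half the mask logs a warning but does not abort.

## Length parameterization and profiling

Every mask voxel receives a normalized along-tendon coordinate: the
geodesic distance from the lateral (footprint) seed, computed by Dijkstra
on the 8-connected voxel adjacency graph with edges weighted by the
physical step length in mm, divided by the distance at the medial
(musculotendinous) seed and scaled to percent. This reduces to the axis
coordinate on straight bands and follows arc length on curved ones; mask
voxels geodesically slightly beyond the medial seed are clipped to 100 %
(they sit within one bin of the end). The choice of arc-length
parameterization over image-column averaging was deliberate: it is the
only option robust to tendon curvature and it makes the normalization
property (profiles invariant under geometric scaling) exact by
construction.

The T2 distribution profile is the mean T2 of surviving voxels in 100
equal-width bins (1 % each) on [0, 100] — half-open bins, last bin closed.
Empty bins are flagged and excluded from regression rather than
interpolated. Segment boundaries sit at exact thirds of normalized length
(lateral [0, 33.3), middle [33.3, 66.7), medial [66.7, 100]); the
anatomical alternative (anchoring the boundaries to the humeral head) is
not computable from a mask alone. Per-segment mean and SD use all
surviving voxels (SD with n−1 denominator). Pre/post "alignment" is
comparison in the shared normalized coordinate — no deformable
registration.

## Statistics

Per-segment straight-line regressions are fitted to the nonempty bin
means (unweighted; a count-weighted option would be a one-line change but
profile-level lines are the intended analog of the published analysis).
The x coordinate stays global — the intercept is always the extrapolation
to the footprint (x = 0) — so intercepts of different segments share one
scale; this is also why medial intercepts around 70 ms coexist with
segment means around 40 ms. Bins straddling a segment boundary mix
voxels of two segments (the piecewise profile is discontinuous at the
boundaries) and are excluded from both segments' fits.

Two visits are compared per segment with the Chow test at k = 2 (slope
and intercept both free): F = [(RSS_pooled − RSS₁ − RSS₂)/2] /
[(RSS₁ + RSS₂)/(n₁ + n₂ − 4)], p from the upper tail of F(2, n₁+n₂−4).
Perfect separate fits (RSS₁ + RSS₂ = 0, within a roundoff tolerance
scaled to the data) are degenerate: p = 1 if the pooled fit is also
perfect (identical lines), else p = 0. Heteroscedasticity-robust
variants are out of scope.

Paired segment means are compared with the two-sided Wilcoxon
signed-rank test: zero differences dropped (classic treatment, not
Pratt's), tied absolute differences mid-ranked, W = min(W+, W−). For
n ≤ 25 the p-value is exact — the null distribution of W+ over all 2ⁿ
sign assignments is built by convolution on the doubled-rank lattice,
which remains valid under ties — otherwise a tie- and
continuity-corrected normal approximation is used. Clinical scores use
the paired t-test (identical to a one-sample t on the differences);
normality is checked with Shapiro–Wilk at alpha = 0.05. No
multiple-testing correction is applied across segments, mirroring
per-segment reporting. LOESS smoothing (tricube local linear, via
statsmodels lowess) is available for plots only and never feeds the
regressions or the Chow test.

## Digital phantoms

The phantom is a 2-D coronal slice: a band of half-thickness 4 voxels
(default) around a quadratic-arc centerline (two control points give a
straight band for oracle tests), on a 96 × 192 grid at 0.55 mm spacing
(roughly the 140 mm / 256 field of view of a clinical T2-mapping
protocol). Tendon voxels take T2 from a piecewise-linear profile over
the band's normalized arc-length position; presets bundle the
characteristic regression parameters of tendinotic, partial-tear and
asymptomatic supraspinatus tendons before/after PRP treatment, and the
default is the tendinotic pre-treatment shape. A long-T2 fluid
compartment (200 ms, full proton density) flanks the concave side of the
band and a short-T2, low-signal bone compartment (2 ms, 5 % proton
density) the other side, so the partial-volume filter has realistic work;
those two compartment values are design choices, not published numbers.
Signals follow the mono-exponential forward model; Rician noise
(magnitude of a complex Gaussian perturbation) is applied per echo with
echo-indexed substreams of the config seed, default sigma 2 % of the
tendon S0. Everything is deterministic given the config.

A synthetic cohort draws per-subject geometry (centerline jitter, band
thickness) and noise substreams from one seed while sharing the group's
profile preset. Group profiles average subject bin means with equal
subject weight — not voxel pooling — so large tendons do not dominate.

What the phantom does *not* emulate: 3-D shoulder anatomy, B1
inhomogeneity and stimulated-echo contamination, chemical-shift
artifacts, intra-tendon heterogeneity beyond the 1-D profile, or
segmentation error (masks are exact). Passing tests therefore
demonstrate correctness of the computational chain under the stated
model, not robustness to every acquisition artifact of real shoulder MRI.

## Problem sizes and numerical choices

The default phantom has ~1500 tendon voxels; a full single-subject run
takes well under a second, a 9-vs-9 paired cohort a few seconds, and the
2000-replicate Chow null calibration about a second — sizes chosen so the
whole validation suite runs comfortably on a laptop while keeping every
Monte-Carlo band (e.g. null rejection in [0.04, 0.06]) statistically
meaningful. Ties in bin assignment are resolved by half-open bins; the
position exactly at a third boundary belongs to the upper segment.

## Known limitations

- The geodesic coordinate on thick curved bands deviates from true arc
  length near the band ends by up to roughly the half-thickness times
  (√2 − 1), i.e. under one bin for default geometry; tests quantify this.
- Bin means at the two profile-discontinuity bins are not comparable to
  the generating lines and are excluded from segment fits.
- The exact Wilcoxon enumeration is limited to n ≤ 25 pairs (beyond
  that the normal approximation is used automatically).
- Mono-exponential decay is assumed throughout; multi-component T2 and
  ultrashort-TE behavior are out of scope.
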
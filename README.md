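# tendont2

Quantitative T2 mapping and length-normalized T2 distribution profiling of
the supraspinatus tendon.

Transverse relaxation time (T2) of tendon tissue rises with free water,
matrix disorganization and inflammation, which makes voxelwise T2 maps a
quantitative marker of tendinopathy and of its response to treatment
(e.g. platelet-rich plasma injection). This package implements the full
analysis chain for such studies:

1. **Relaxometry** — voxelwise mono-exponential fits
   S(TE) = S0 · exp(−TE/T2) to multi-echo spin-echo magnitude images
   (default: 8 echoes, TE = 11.4 … 91.2 ms), by log-linear or nonlinear
   least squares.
2. **Profiling** — a manually drawn tendon mask running from the lateral
   footprint to the medial musculotendinous junction is filtered against
   noise and partial-volume voxels (bone: very short T2; bursal fluid:
   very long T2), every voxel is assigned a normalized along-tendon
   coordinate x ∈ [0, 100] % via geodesic distance inside the mask, and
   mean T2 is binned against x — the *T2 distribution profile*. The tendon
   splits into lateral / middle / medial thirds with mean ± SD per segment.
3. **Statistics** — per-segment straight-line regressions T2(x) = a + b·x
   of the profiles; the Chow F-test
   F = [(RSS_p − RSS_1 − RSS_2)/2] / [(RSS_1 + RSS_2)/(n_1 + n_2 − 4)]
   for structural change between two visits' regressions; Wilcoxon
   signed-rank (exact, by enumeration, for n ≤ 25) on paired segment
   means; paired t-tests for clinical scores; Shapiro–Wilk normality
   checks; LOESS smoothing for plots.
4. **Phantoms** — digital tendon phantoms with a curved band, adjacent
   fluid/bone compartments, a piecewise-linear ground-truth T2(x) and
   Rician noise, so the whole chain is testable without patient data.

Because profiles live on the normalized length coordinate, tendons of
different size — or the same tendon at two visits — are compared without
image registration.

## Worked example

Simulate a tendinotic phantom at the default 2 % Rician noise level and run
the full pipeline:

```python
from tendont2 import PhantomConfig
from tendont2.pipeline import run_phantom_subject, segment_regressions

res, truth = run_phantom_subject(PhantomConfig(seed=1))
print(f"tendon length: {res.length.tendon_length_mm:.1f} mm, "
      f"kept {res.filter_report.n_kept}/{res.filter_report.n_mask} voxels")
for s in res.segments:
    print(f"{s.segment:8s} mean T2 = {s.mean_t2:5.1f} +/- {s.sd_t2:4.1f} ms  (n={s.n_voxels})")
for name, fit in segment_regressions(res.profile).items():
    print(f"{name:8s} slope = {fit.slope:+.3f} ms/%  intercept = {fit.intercept:.1f} ms")
```

prints

```
tendon length: 102.0 mm, kept 1465/1465 voxels
lateral  mean T2 =  35.6 +/-  3.8 ms  (n=484)
middle   mean T2 =  36.4 +/-  3.6 ms  (n=491)
medial   mean T2 =  40.9 +/-  4.3 ms  (n=490)
lateral  slope = -0.250 ms/%  intercept = 39.6 ms
middle   slope = +0.152 ms/%  intercept = 28.7 ms
medial   slope = -0.337 ms/%  intercept = 69.2 ms
```

The phantom's generating profile was the tendinotic pre-treatment preset
(lateral slope −0.268 / intercept 39.5, middle +0.151 / 28.4, medial
−0.347 / 70.1): the recovered per-segment regressions land on the
generating lines up to binning discretization and the 2 % image noise, and
the segment means show the characteristic biphasic shape (T2 falling over
the lateral third, rising through the middle, falling again medially).

A command-line interface mirrors the library:

```
tendont2 simulate --config cfg.yaml --out phantom/
tendont2 fit --echoes phantom/ --mask phantom/mask.nii.gz --out fit/
tendont2 profile --t2map fit/ --mask phantom/mask.nii.gz \
    --seeds phantom/seeds.json --out profile.csv
tendont2 compare --before pre.csv --after post.csv --out report.json
tendont2 cohort --n-subjects 9 --seed 0 --out cohort/
```

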
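# pipmorph

Outline geometric morphometrics and discriminant classification of grape-pip
(seed) silhouettes, for archaeobotanists and morphometricians who want to
ask: *do these seeds look wild or domesticated, and which modern cultivars
do they resemble?*

Grape domestication changed pip shape — domestic pips are elongated with a
long beak, wild pips smaller and roundish with a short one — so the outline
of a waterlogged archaeological pip carries a classifiable signal. The
package implements the standard analysis chain:

1. **Outline extraction** — a binary silhouette is traced to the closed
   outer boundary of its largest component and resampled to 360 points at
   equal arc-length spacing.
2. **Elliptic Fourier descriptors** — the outline (x(t), y(t)), t the arc
   length, is expanded as truncated Fourier series with per-harmonic
   coefficients (a_n, b_n, c_n, d_n), computed with the exact closed-form
   polyline sums. After normalising for position, scale (centroid size) and
   the start point relative to the centroid, the first six harmonics give a
   24-feature shape vector; harmonic power P_n = (a_n²+b_n²+c_n²+d_n²)/2
   checks that six harmonics carry over 95% of shape information.
3. **Stepwise linear discriminant analysis** — variables enter by the
   largest Wilks'-lambda partial F exceeding F > 3.84 (removal below 2.71,
   tolerance floor 0.001), classification uses Fisher's linear functions
   C_j(x) = μ_j′W⁻¹x − ½μ_j′W⁻¹μ_j + ln π_j with pooled within-class
   covariance W, and accuracy is estimated by leave-one-out
   cross-validation.
4. **Two-stage assignment and reporting** — unknowns are classified wild vs
   domestic against a balanced reference (equal pips per class); the
   domestic ones are then assigned to individual modern cultivars, and
   results are aggregated into per-site integer percentages and breakdowns
   by berry colour and cultivar origin region.

Because the original pip images and germplasm reference are not publicly
deposited, the package ships a **synthetic silhouette generator**: shape
classes are Gaussians in the normalized descriptor space, rendered to
binary rasters at realistic resolution (142 px ≈ 6 mm at 600 dpi), so every
analysis stage can be validated as a parameter-recovery problem — including
populations constructed at an exact Mahalanobis separation Δ, for which
balanced LOOCV accuracy must recover the Bayes rate Φ(Δ/2).

## Worked example

```python
import pipmorph as pm

result = pm.run_pipeline(pm.demo_config(), seed=11)
print("stage-1 LOOCV accuracy:", round(result.stage1.loocv.accuracy, 3))
print(result.report.status_counts)
print(result.report.status_percent)
```

prints

```
stage-1 LOOCV accuracy: 1.0
status   domestic  wild
site
well_N         54     6
well_KK        21     9
status   domestic  wild
site
well_N         90    10
well_KK        70    30
```

The demo generates a small reference (40 wild + 40 domestic pips after
balancing, 8 cultivars) and two sites of unknowns (60 and 30 pips, mixed
10% and 30% wild). Stage 1 separates the default wild and domestic shape
classes perfectly (LOOCV accuracy 1.0 — the default templates are far
apart relative to their within-class variation), the per-site counts are
the stage-1 assignments of each unknown pip, and the percentages are the
counts rounded half away from zero — here recovering the generating wild
fractions exactly. `result.report` also holds the per-cultivar count table
(with the ≥10-pip headline filter) and the colour and origin-region
percentage breakdowns of the assigned pips.

The same flow runs from the shell:

```bash
pipmorph run --demo --seed 11 --out-dir out/
pipmorph simulate --seed 0 --n-per-class 50 --out-dir data/   # PNGs + truth
pipmorph extract data/images/*.png --out outlines.csv --features-out feats.csv
```

At full scale (1319 + 1319 balanced reference, 2228 unknowns across three
sites, 330 cultivars) `pm.run_pipeline(seed=1)` completes in about 2.5
minutes on one CPU.

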
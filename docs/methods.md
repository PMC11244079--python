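# Methods

## Problem and overall design

`pipmorph` implements outline-based geometric morphometrics for grape pips
(seeds): a closed silhouette outline is summarised by elliptic Fourier
descriptors (EFDs), reference material of known status trains a stepwise
linear discriminant classifier, and unknown pips are assigned in two stages —
first to the wild or domestic morphotype, then (for domestic-classified pips
only) to an individual modern cultivar — with the results aggregated into
percentage-allocation reports by site, berry colour and geographic origin of
the assigned cultivar. Because no archaeological pip images or germplasm
reference scans are publicly deposited, a synthetic silhouette generator
with known descriptor-space structure stands in for both, which turns every
stage of the analysis into a parameter-recovery problem with a computable
ground truth.

## Elliptic Fourier descriptors

An outline is a closed polygon of 360 points sampled at equal arc-length
spacing. With segment increments (dx_p, dy_p), lengths dt_p, cumulative arc
length t_p and perimeter T, the coefficients of harmonic n are the exact
closed-form polyline sums

    a_n = T/(2 n^2 pi^2) * sum_p (dx_p/dt_p) [cos(2 pi n t_p/T) - cos(2 pi n t_{p-1}/T)]

(b_n with sines; c_n, d_n with dy_p). No FFT approximation is involved; a
periodic trapezoidal quadrature oracle agrees to 1e-6 on dense polylines.
Six harmonics are retained, giving 24 features per pip; harmonic power
P_n = (a_n^2 + b_n^2 + c_n^2 + d_n^2)/2 is reported against a 30-harmonic
reference total (configurable), and on the default synthetic population the
first six harmonics carry more than 95% of that total.

Before coefficient extraction the outline is normalised: centroid to the
origin; coordinates divided by the centroid size (RMS radius); the point
farthest from the centroid re-indexed first (ties to the lowest original
index) and rotated onto the positive x axis. The 24 features are therefore
invariant to translation, scale, rotation and trace start, but deliberately
not to reflection: dorsal-view scans have a fixed handedness. Full
Kuhl–Giardina first-ellipse normalisation is not used, since it would pin
a_1, b_1, c_1 to constants and waste three of the 24 retained features.

A parametrization subtlety: a truncated Fourier series is not arc-length
parameterized, so "compute coefficients of the reconstructed curve" is only
an approximate inverse. The map that is exactly idempotent is the full
extraction path — reconstruct densely, resample to 360 equal-arc points,
normalise, extract — and its fixed points (found by iteration, residual
~1e-4, limited by the 360-point phase granularity) are used as class
templates so that generated coefficients are recoverable end to end.

## Outline extraction

Silhouettes are thresholded (fixed level or Otsu), the largest 8-connected
component is kept (components under 32 px are rejected as specks), its outer
boundary is extracted by marching squares at level 0.5 (holes ignored),
converted to y-up mathematical axes and oriented counter-clockwise. The
boundary is then smoothed with a periodic Gaussian of 2 px standard
deviation (configurable; 0 disables). The smoothing exists because the
half-pixel staircase of a digitised contour makes the farthest-point start
anchor unstable on locally flat tips: unsmoothed, the anchor can jump
several degrees between repeat rasterisations of the same shape, injecting
spurious start/rotation variation of ~0.04 per coefficient. At seed scale
(perimeter ~350 px) the filter attenuates harmonics 1–6 by under 0.1%,
which is far below the class variation being measured.

## Synthetic pip populations

Each shape class is a Gaussian in the 24-dimensional normalized feature
space. Defaults (all in `pipmorph.config`, overridable by YAML):

- wild template: oval with a short beak (d1 = 0.80, a2 = 0.03, a3 = 0.005,
  refined to an extraction-map fixed point);
- domestic template: elongated with a pronounced beak (d1 = 0.55, a2 = 0.10,
  a3 = 0.025). Both are illustrative — no quantitative shape parameters for
  wild vs domestic pips are published, so only relative behaviour
  (separability, recoverability) is testable;
- per-harmonic coefficient standard deviation 0.030/0.015/0.010/0.0075/
  0.006/0.005 (harmonics 1–6, all four coefficients), reflecting that gross
  shape varies more between seeds than fine detail;
- canvas 512 x 512 px, seed length 142 px (~6 mm at 600 dpi) so
  discretisation error matches flatbed-scan acquisition;
- self-intersecting draws are rejected and redrawn (budget 100 per sample);
  all randomness flows from one seed through a single generator stream.

Silhouettes are produced by inverse Fourier reconstruction, scaling so the
larger side of the outline's bounding box equals the nominal seed length
(generated pips lie along x after normalisation, so this is the major-axis
extent), centring and polygon-filling.

Two-class populations at a prescribed Mahalanobis separation Δ are built by
`calibrated_two_class_specs`: isotropic class Gaussians (sd 0.03 per
coefficient) around means placed symmetrically along the wild-to-domestic
template axis. Normalisation projects out position/scale/start-point gauge
directions — and rasterisation adds its own small distortion — so a
separation prescribed in raw coefficient space is not the separation the
classifier sees. The constructor therefore calibrates in two steps: an
analytic pilot (300 probes through reconstruct/resample/features, no
rasterisation) gives a provisional separation from the local covariance and
mean response; then 250 paired pilot draws per class run through the full
image round trip with common random numbers — the same coefficient noise
added to both provisional means, so the realized mean-difference estimate
is nearly noise-free — and the separation is rescaled so the realized,
inverse-Wishart-debiased Mahalanobis distance equals Δ. Residual
calibration error is a few percent (dominated by pooled-covariance
estimation in 24 dimensions). Balanced LOOCV accuracy then recovers the
Bayes rate Φ(Δ/2) within Monte-Carlo error, which is the package's central
calibration check.

What the generator does not emulate: scanner texture, lighting, charring or
mineralisation deformation, touching seeds, or the heavier high-harmonic
content of real pip outlines (real populations will sit closer to the 95%
power bound than the synthetic ones do). Passing tests demonstrate that the
machinery recovers known structure through rasterisation at realistic
resolution, not that real wild/domestic pips are separated by any
particular margin.

## Stepwise discriminant analysis

Wilks' lambda on a feature subset is det(W)/det(T) (within-group over total
SSCP). The partial F for growing a p-variable model is
F = ((n − g − p)/(g − 1)) (Λ_p/Λ_{p+1} − 1). Each step first removes the
in-model variable with the smallest F-to-remove if it is below 2.71, else
enters the candidate with the largest F-to-enter if it exceeds 3.84
(both strict comparisons; thresholds configurable — 3.84 is the documented
entry criterion, 2.71 and the 0.001 tolerance floor are the conventional
companion defaults of the originating statistics package). Candidate
tolerance is 1 − R² of its within-group regression on the in-model
variables, computed from the pooled within SSCP. Selection stops when
neither action applies, when residual degrees of freedom run out, or on a
repeated model state (cycling guard).

Classification functions are C_j(x) = μ_j' W⁻¹ x − ½ μ_j' W⁻¹ μ_j + ln π_j
with W the pooled within-class covariance (divisor n − g). Priors are equal
by default (the reference is deliberately balanced); ties break toward the
lowest group index. A pooled-covariance condition number above 1e12 is
reported as an error, never silently regularised.

LOOCV holds the selected subset fixed and re-estimates only group means and
pooled covariance without each case (rank-one SSCP downdate), matching a
naive per-case refit exactly; per-fold reselection would answer a different
question (selection stability) and is left to explicit sensitivity runs.
Both LOOCV and resubstitution accuracy are reported, since published
"overall correct classification" figures often do not say which they are.

## Two-stage pipeline and reporting

Stage 1 balances the reference to an identical count per status class
(default 1319, drawn without replacement from larger generated pools),
runs stepwise selection + LDA + LOOCV, and assigns every unknown. Stage 2
takes only domestic-classified unknowns and assigns each to one of the
cultivars (default 330) by a multi-class LDA with equal priors — no prior
abundance information exists for archaeological material — trained on the
full domestic pool (default 5 pips per cultivar; cultivars under 3
reference pips are dropped with a warning). The same stepwise selection is
applied before the stage-2 fit (configurable off). Sites share the trained
models and are aggregated independently.

Reports give per-site integer percentages (rounded half away from zero —
the rule that reproduces the published well N and well KK splits; no
integer rule reproduces the published Nora pair, which is internally
inconsistent), per-cultivar count tables (full, plus a headline table
filtered to cultivars with at least 10 assigned pips), and colour/region
percentages weighted by assigned pips rather than by distinct cultivars
(the pip-level convention is the one consistent with published usage).

## Problem sizes and determinism

The default configuration runs the full study scale — 1450 wild + 1650
domestic generated reference pips (balanced to 1319 + 1319), 2228 unknowns
across three sites, 330 cultivars — in roughly 2.5 minutes on one CPU;
`demo_config()` is a seconds-scale miniature with identical structure.
Acceptance-style checks use 200-outline populations for harmonic power and
500 pips per class for Bayes-accuracy recovery. Every stochastic step takes
an explicit seed; identical seed and configuration reproduce byte-identical
output tables.

## Known limitations

- Default templates and mixing fractions are plausible but unvalidated
  against real material; only relative and structural claims are tested.
- The farthest-point start anchor, though smoothed, remains the least
  stable part of the normalisation for nearly round outlines; shapes
  without any beak will show inflated start/rotation variance.
- Stage 2 fits one joint multi-class LDA; with hundreds of overlapping
  cultivar classes, per-cultivar assignment is intrinsically noisy (the
  synthetic default recovers the true cultivar for ~63% of pips, against a
  chance rate of 0.3%), so reports should be read at the aggregate
  (colour/region/count-table) level.
- Reflection is not normalised; inputs must share a consistent dorsal-view
  orientation.
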
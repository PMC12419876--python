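# Methods

## Mechanical model

The seed unit (achene + beak, length *L*) is treated as a rigid lever on a
short elastic pedicle (length ℓ, radius *c*) emerging from the raised
attachment site. The pedicle's vascular bundle is modelled as a uniformly
porous disc: its solid fraction *k* scales both the load-bearing area
(A = kπc²) and the disc's own second moment (kπc⁴/4).

When the seed is pulled at angle θ₁ and abscises at axis angle θ₂, the
pedicle carries a tension component Ft = Fa·cos(|θ₁|−|θ₂|) and a bending
moment M = Fa·p with moment arm p = (L+ℓ)·sin(|θ₁|−|θ₂|). Abscission
occurs when σt + σb = Ft/A + M·y_max/I reaches the pedicle's breaking
stress. The breaking stress cancels in every ratio against the straight
pull (Fas = σ_break·A), so it is never needed numerically and absolute
force prediction is out of scope.

### Engaged section and the compression rule

The attachment site backs the pedicle asymmetrically: two rectangles of
size 2c×w flank it, and a semi-ellipse with semi-axes r (toward the scape)
and c+w (lateral) closes the horseshoe on the scape side; the apex side is
open. Base tissue joins the bending unit only where the bend puts it into
compression — the resting achene–base contact cannot transmit tension.
Concretely:

* straight pull: pedicle disc only;
* positive pull (toward apex): pedicle + the apex-side *halves* of the two
  rectangles (each c×w, centroid +c/2);
* negative pull (toward scape): pedicle + the scape-side half-rectangles
  (centroid −c/2) + the semi-ellipse (flat edge at −c, centroid
  −c − 4r/(3π)).

The half-rectangle rule is this package's reading of "compression side":
a sideways bend compresses only the half of each flanking rectangle lying
on the bend side of the pedicle axis. Exact published section composition
is not available; this reconstruction reproduces the qualitative
directional ordering and the order of magnitude of the measured ratios
(see Limitations).

The two materials are combined with the transformed-section method: base
regions enter the area, centroid and second-moment sums with weight 1/β,
β = Ep/Eb ≥ 1. The neutral axis is the weighted centroid δ; I follows
from the parallel-axis theorem about δ; y_max = c + |δ| is measured to the
pedicle edge opposite the pull (the tension edge, cantilever convention).
The model is flagged invalid when y_max leaves the pedicle
(y_max ∉ [c, 2c]) — flags are reported, never raised, so sweeps can show
where the model breaks down.

### The cos(Δθ) term

One rendering of the exact ratio is ambiguous between cos(|θ₁|−|θ₂|) and
cos((|θ₁|−|θ₂|)/2). The full-angle form is the default here: it is the
projection of the applied force on the pedicle axis, and it is the form
whose bending-dominated limit matches the printed approximation. The
half-angle variant is kept behind `force_ratio_full(..., eq32_halfangle=True)`
for comparison; nothing else uses it.

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| L | seed length | 12 400 | µm |
| w | base width | 64 | µm |
| r | base (attachment-site) radius | 39 | µm |
| c | pedicle radius | 18.6 | µm |
| k | pedicle solid fraction | 0.33 | — |
| ℓ | pedicle length | 200 | µm |
| β | stiffness ratio Ep/Eb | 25.9 | — |
| θ₁ | applied-force angle | 90 | ° |
| θ₂ | abscission angle | 15 (pos) / 35 (neg) / 0 (straight) | ° |

L, w, r, c, k are measured population means; their SDs (1000, 16, 10, 5,
0.10) drive `sample_morphology` and their bootstrapped standard errors
(100, 2, 2, 0.95, 0.05 — the pedicle-radius error symmetrised) drive error
propagation. ℓ is not reported; 200 µm keeps L/ℓ = 62, comfortably inside
the slender-lever validity condition L/ℓ ≥ 20, and is configurable. θ₂
defaults are the video-derived abscission angles.

## Fitting β

`fit_beta` minimises Σ (log₁₀ predicted − log₁₀ target)² over the two
measured ratios Fap/Fas and Fan/Fas, with β ∈ [1, 1000] (β > 1 is the
physical assumption — stiff brittle pedicle, deformable base; 1000 is a
generous ceiling). Log-space least squares balances ratios an order of
magnitude apart. The optimiser is a 400-point log-spaced grid followed by
bounded golden-section refinement in log₁₀ β to 10⁻⁴ relative — fully
deterministic. A grid optimum at either end is flagged `at_boundary`.

With the measured targets (0.005, 0.03) and this package's section
reconstruction, the objective is minimised at the lower bound β = 1:
the reconstructed section's ratios remain below the experimental values
for all admissible β (closest at β = 1, where predictions agree with the
targets within a factor of ~2.5–4.5, i.e. within the order-of-magnitude
agreement the data support). On model-generated targets the fit recovers
the generating β to better than 0.1%, so the boundary result reflects the
section reconstruction, not the optimiser.

## Statistics

* **Summaries** — median and quartiles per angle bin; quartiles use linear
  interpolation between order statistics (the most common convention;
  stated because published IQR comparisons depend on it).
* **Bootstrap** — B = 1000 resamples with replacement; the CI is the 25th
  and 975th order statistics of the sorted replicate medians (≈95%
  percentile interval). Input is sorted before resampling so the interval
  depends only on the sample multiset and the seed (default 0). B < 40 is
  rejected — the prescribed order statistics are undefined below that.
* **Tests** — two-sided Wilcoxon rank-sum: exact null distribution when
  min(n_x, n_y) ≤ 10 and the pooled data are tie-free, otherwise the
  normal approximation with tie and continuity corrections. All nine
  pairwise direction comparisons are reported unadjusted (matching the
  raw p-value reporting convention of the source analysis).

## Synthetic data

The generator emulates direction-binned pull-off force measurements. Per
bin, forces are i.i.d. log-normal with µ = ln(median) and
σ = ln(Q3/Q1)/(2·z₀.₇₅) from the published bin summaries — the calibrated
distribution's median and quartile *ratio* equal the printed values
exactly. A two-parameter log-normal pinned at the printed median cannot
also match both printed quartiles individually unless the median is the
geometric mean of Q1 and Q3; the published bins are close to but not
exactly log-symmetric, so individual quartiles are matched approximately
(within ~16% at worst). The log-normal choice itself is a modelling
decision: the data are only known to be non-normal and right-skewed, and
the asymmetric CIs and order-of-magnitude spreads support a multiplicative
noise model.

Default bin sample sizes are an even split of the published experiment
totals (sideways 128, azimuth 75, elevation 90 → 40/25/30 per bin;
per-bin counts are unpublished). Bins receive independent seeded streams
(spawned from one root seed), so a bin's draws do not depend on which
other bins are configured. Morphology draws are independent truncated
normals (positive; k ≤ 1) at the published mean/SD.

What the generator does **not** emulate: seed-head random effects or any
between-head correlation, angle measurement error, load-cell time traces
and residual post-abscission contact, and any true (deposited) raw-data
distribution shape. Tests passing on synthetic data therefore show the
pipeline is correct under the stated statistical model, not that the model
captures every feature of real force data.

## Numerical choices

* Internal units µm / mN; angles degrees at interfaces, radians inside.
* `force_ratio_approx` raises on sin(|θ₁|−|θ₂|) = 0 (no bending — the
  approximation has no meaning there); the exact form returns 1 smoothly.
* Validity failures are flags/warnings, not exceptions, everywhere ratios
  are computed; sweep output keeps invalid points with `valid=False`.
* Experimental ratios default to ratios of bin medians; a bootstrap-ratio
  estimator (median over replicate ratios of resampled medians) is
  available via `ratio_method="bootstrap"` in `run_pipeline`.
* The pipeline report is deterministic for a fixed seed (per-bin bootstrap
  seeds derive from the root seed and the bin's canonical position).
* Problem sizes used by the test suite and acceptance script: 2000 draws
  per bin for median-recovery checks, 600–1000 replicates for bootstrap
  coverage, 10⁶ draws for Monte-Carlo calibration checks — chosen to make
  sampling error a small fraction of each asserted tolerance.

## Known limitations

* The engaged-section composition (half-rectangle rule, semi-ellipse
  placement) is a reconstruction; consequently the fitted β and the
  absolute predicted ratios should be read as order-of-magnitude
  quantities. The directional ordering Fap < Fan < Fas, the sensitivity
  trends in c and r, and the scale invariance of the approximate ratio are
  robust to this choice.
* No 3-D receptacle geometry, contact mechanics, crack propagation,
  viscoelasticity or dynamic loading; θ₂ is an input, not predicted.
* No uncertainty on β itself (a point fit); no joint fitting of β with
  geometry; no multiple-testing correction (deliberate, to mirror the raw
  reporting convention).
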
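# abscission

Directional seed abscission in the dandelion (*Taraxacum officinale*):
a composite-beam model of the seed–receptacle attachment, the robust
statistics used to analyse pull-off force measurements, and a calibrated
synthetic force generator so the whole analysis runs with no external data.

## The problem

Dandelion seeds detach (abscise) when wind bends them far enough to break
the pedicle — the thin porous vascular bundle connecting the achene to the
receptacle. The force needed depends strongly on direction: pulling a seed
toward the capitulum apex (*positive*) takes roughly an order of magnitude
less force than pulling it toward the scape (*negative*), and two orders
less than pulling it straight out. The cause is morphological: the raised,
horseshoe-shaped attachment site backs the pedicle on the scape side only,
so the cross-section that resists bending differs by pull direction.

## The model

The pedicle (radius *c*, solid fraction *k*) and the compression-side part
of the attachment site bend as one composite unit, handled by the
transformed-section method with stiffness ratio β = Ep/Eb ≥ 1 (base
material enters area and second-moment integrals with weight 1/β). A force
*F*ₐ applied at angle θ₁ to the seed axis (length *L*) abscises the seed at
axis angle θ₂, loading the pedicle with tension σt = Ft/A and bending
σb = M·y_max/I, where A = kπc², I is the second moment of the engaged
section and y_max the neutral-axis-to-tension-edge distance. Setting
σt + σb equal to the (direction-independent) breaking stress and dividing
by the straight pull gives

    Fa/Fas = 1 / ( cos(|θ1|−|θ2|) + A·y_max·p / I ),      p = (L+ℓ)·sin(|θ1|−|θ2|),

which in the bending-dominated regime (L/ℓ ≥ 20, θ1/θ2 ≥ 3/2,
|θ1|−|θ2| ≥ 45°, c ≤ y_max ≤ 2c) reduces to

    Fa/Fas ≈ I / ( kπc² · y_max · L · sin(|θ1|−|θ2|) ).

Because the engaged section is larger for negative pulls (it includes the
semi-elliptical back of the horseshoe), Fap < Fan < Fas follows from the
geometry alone. The one free parameter β is fitted to measured force
ratios by deterministic log-space least squares.

Measurement statistics follow the skewed nature of force data: medians and
interquartile ranges per angle bin, a 1000-replicate percentile bootstrap
(25th/975th order statistics) for the median CI, and two-sided Wilcoxon
rank-sum tests for all pairwise direction comparisons. The synthetic
generator draws per-bin log-normal forces calibrated so the distribution's
median and quartile ratio match the published summaries exactly.

## Worked example

```python
from abscission import MorphParams, PullScenario, force_ratio_full, run_pipeline

params = MorphParams(beta=25.9)   # measured means: L=12.4 mm, w=64, r=39, c=18.6 µm, k=0.33
neg = force_ratio_full(params, PullScenario("negative"))   # θ1=90°, θ2=35°
pos = force_ratio_full(params, PullScenario("positive"))   # θ1=90°, θ2=15°
print(f"Fan/Fas = {neg.ratio:.3g}  (y_max = {neg.y_max:.1f} µm, I = {neg.I:.3g} µm⁴)")
print(f"Fap/Fas = {pos.ratio:.3g}  (y_max = {pos.y_max:.1f} µm, I = {pos.I:.3g} µm⁴)")

report = run_pipeline(seed=1)     # synthetic forces -> stats -> fit -> sweeps
r = report.experimental_ratios
print(f"observed ratios: Fap/Fas = {r['fap_fas']:.3g}, Fan/Fas = {r['fan_fas']:.3g}")
print(f"negative/positive force factor = {report.derived['neg_pos_force_factor']:.3g}")
print(f"wind-speed factor = {report.derived['wind_speed_factor']:.3g}")
```

prints

```
Fan/Fas = 0.00187  (y_max = 30.6 µm, I = 2.11e+05 µm⁴)
Fap/Fas = 0.000447  (y_max = 20.5 µm, I = 4e+04 µm⁴)
observed ratios: Fap/Fas = 0.00739, Fan/Fas = 0.0319
negative/positive force factor = 4.32
wind-speed factor = 2.08
```

The first two lines are the model's directional force ratios at β = 25.9:
a negative pull needs ~0.2% of the straight-out force, a positive pull ~4×
less again. The last three come from a seeded synthetic experiment:
the ratio of the −90° and +90° bin medians says a seed pushed toward the
scape needs ~4.3× the force of one pushed toward the apex — and, since
aerodynamic drag scales as F ∼ U², a wind ~2.1× as fast.

The same pipeline is available from the shell:

```sh
abscission --seed 1 --out-dir out report     # summary.tsv, tests.tsv, sweep_{c,r}.tsv, report.json
abscission simulate                          # synthetic force CSV only
abscission fit --fap-fas 0.005 --fan-fas 0.03
abscission sweep --which r --beta 25.9
```

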
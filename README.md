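# canopyage

Post-fire canopy-structure trajectories and stand-age prediction from canopy
height models.

In fire-killed (obligate-seeder) woodlands, a stand-replacing fire resets the
whole tree cohort, and the canopy then rebuilds over decades to centuries.
`canopyage` is for ecologists and remote-sensing scientists who study that
recovery with airborne laser scanning: it turns 1 m canopy height models
(CHMs) into structural metrics, models how those metrics change along a
stand-age chronosequence, and inverts the relationship to estimate stand age
from structure alone.

The pipeline has four stages:

1. **Metrics** — from each CHM: top height *H*<sub>max</sub> (98th-percentile
   pixel height), canopy cover *Cover*<sub>5m</sub> (% pixels > 5 m), height
   heterogeneity *H*<sub>cv</sub> (CV of canopy pixel heights), and a
   normalized rumple index *Rumple*<sub>norm</sub> (canopy surface area /
   ground area / *H*<sub>max</sub>).
2. **Trajectories** — additive smooth models
   *Y* = *f*₁(age) + *f*₂(rainfall) + *f*₃(plot size), fitted by penalized
   cubic regression splines with data-driven smoothness (GCV), from which
   fitted curves, per-decade rates of change, peak locations and
   wet-vs-dry rainfall contrasts (302 vs 260 mm yr⁻¹) are extracted.
3. **Age inversion** — age = Σ *f*(metric) + *f*(rainfall) + *f*(area) for
   11 metric subsets, validated by stratified repeated hold-out (11 age
   classes, 90/10 split, repeated), with per-age-class bias and residual
   semivariogram diagnostics.
4. **Synthetic data** — a two-tier generator: Tier A draws plot tables from
   calibrated truth trajectories (cover peaking at 48 % around 120 yr,
   ~15 m top-height plateau, self-thinning from >4000 to ~20 trees ha⁻¹,
   …); Tier B builds explicit tree-level stands (Poisson/Boolean canopy
   placement, snag spikes after fire) and rasterizes them to 1 m CHMs, so
   the whole pipeline runs without any field data.

## Worked example

```python
import numpy as np
from canopyage import GeneratorConfig, build_truth, simulate_plot_table
from canopyage.trajectories import (fit_trajectory, predict_curve,
                                    find_extremum, rainfall_contrast)
from canopyage.age_model import AgeModelSpec, ALL_METRICS, repeated_validation

truth = build_truth()
table = simulate_plot_table(truth, GeneratorConfig(seed=1))   # 250 plots

fit = fit_trajectory(table, "cover_5m_pct")
grid = np.arange(4.0, 450.0)
curve = predict_curve(fit, grid, reference_rainfall=290.0, reference_area=4.4)
peak = find_extremum(curve, "maximum")
_, contrast = rainfall_contrast(fit, grid)
print(f"adjusted R2      : {fit.r2_adjusted:.2f}")
print(f"cover peak       : {peak.peak_value:.1f}% at {peak.peak_age:.0f} yr")
print(f"decline to 450 yr: {-peak.mean_rate_after:.2f} pp per decade")
print(f"wet-dry contrast : +{contrast:.1f} pp (302 vs 260 mm/yr)")

res = repeated_validation(table, AgeModelSpec(ALL_METRICS),
                          n_repetitions=50, seed=1)
print(f"age model (4 metrics): RMSE {res.rmse_mean:.0f} ± {res.rmse_sd:.0f} yr, "
      f"R² {res.r2_mean:.2f}")
```

prints

```
adjusted R2      : 0.66
cover peak       : 49.7% at 133 yr
decline to 450 yr: 0.79 pp per decade
wet-dry contrast : +5.9 pp (302 vs 260 mm/yr)
age model (4 metrics): RMSE 45 ± 6 yr, R² 0.87
```

The fitted cover trajectory peaks near 50 % in the second century after fire
and declines by ~0.8 percentage points per decade towards old-growth
openness; wetter stands hold ~6 pp more cover.  Inverting the relationship,
the four-metric model recovers stand age with ~45 yr hold-out RMSE across a
1–450 yr chronosequence — good skill, though per-class bias shows the
familiar failure mode of recently burned stands (low cover, snag-driven
heterogeneity) occasionally being mistaken for old growth.

A command-line interface covers the same stages — `canopyage simulate`,
`canopyage metrics`, `canopyage fit-trajectories`, `canopyage validate`, and
`canopyage run` for the full pipeline with a JSON report; see
`canopyage --help`.

## Layout

```
src/canopyage/
  truth.py         calibrated truth trajectories (anchor solving)
  synthetic.py     Tier A plot tables, Tier B stand scenes and rasterization
  chm_io.py        GeoTIFF / ESRI ASCII CHM I/O, cropping, plot tables
  metrics.py       the four structural metrics
  gam.py           penalized additive smooth models (P-splines + GCV)
  trajectories.py  trajectory fitting, curves, rates, extrema, contrasts
  age_model.py     age inversion, stratified hold-out, bias, semivariogram
  pipeline.py      end-to-end runner and reports
  cli.py           command-line interface
docs/methods.md    full model and design documentation
```
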
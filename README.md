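# soilgeo

Geostatistical analysis of soil CO₂ efflux (FCO₂) and related soil
attributes on point-survey grids, built for studies of spatial
variability in managed tropical soils (the reference design is an Oxisol
sugarcane field after reform tillage: a 90 m × 90 m grid of 100 points
at 10 m spacing, plus a two-region microbiological comparison with nine
composite samples per region).

The package covers the full chain such a study runs:

* **Variography** — the Matheron semivariogram estimator under the
  intrinsic hypothesis,

  γ̂(h) = 1/(2N(h)) · Σᵢ [z(xᵢ+h) − z(xᵢ)]²,

  with weighted least-squares fits of permissible models (spherical,
  exponential, gaussian; nugget C₀, partial sill C₁, range *a*), model
  selection by SSR / R² / cross-validation RMSE, and a configurable
  **spatial dependence index** SDI% = MF·[C₁/(C₀+C₁)]·[min(a, MD/2)/(MD/2)]·100
  classified weak (≤ 7), moderate (≤ 15) or strong (> 15).
* **Ordinary kriging** — ẑ(x₀) = Σ λᵢ z(xᵢ) with unit-sum weights via a
  Lagrange multiplier, kriging variances, raster maps (ESRI ASCII grid),
  and leave-one-out cross-validation.
* **Derived soil-carbon quantities** — TOC = SOM/1.724, carbon stock
  Cstock = OC·Ds·E/10 (Mg ha⁻¹), daily emitted carbon C–CO₂ from FCO₂,
  decay constant k = C–CO₂/Cstock, macroporosity and air-filled pore
  space, plus descriptive statistics with Warrick–Nielsen CV classes.
* **Region analysis** — delineation of contrasting-emission regions
  (R1/R2) from the kriged FCO₂ map by value bands, pooled Student's t
  per variable, Hotelling's T², Ward hierarchical clustering, and
  correlation-matrix PCA with Kaiser retention and a |loading| ≥ 0.70
  interpretation rule.
* **Synthetic data** — exact (Cholesky) Gaussian random-field simulation
  on the survey grid from any admissible variogram, and a two-group
  assay generator, both parameterised by built-in reference tables so
  every stage is testable against known structure.

## Worked example

```python
import numpy as np
import soilgeo as sg
from soilgeo.reference import compose_survey, default_survey_config

# a survey with the reference field's spatial structure (100 points)
ds = compose_survey(sg.simulate_survey(default_survey_config(seed=42)))

s = sg.describe(ds.values("FCO2"))
print(f"FCO2 mean={s.mean:.2f} sd={s.sd:.2f} CV={s.cv_percent:.1f}% ({s.cv_class})")

emp = sg.empirical_variogram(ds, "FCO2")          # 10 m bins, half max distance
var = float(np.var(ds.values("FCO2"), ddof=1))
best, diag = sg.select_model(
    [sg.fit_variogram(emp, k, sample_variance=var) for k in ("spherical", "exponential")]
)[0]
print(f"best: {best.kind}(C0={best.nugget:.3f}, sill={best.sill:.3f}, a={best.range_:.1f} m)")

sdi = sg.spatial_dependence_index(best, ds.max_pairwise_distance())
print(f"SDI = {sdi.sdi_percent:.1f}% -> {sdi.dependence_class}")
print(f"LOO RMSE = {sg.loo_rmse(ds, 'FCO2', best):.3f}")

vmap, _ = sg.krige_map(ds, "FCO2", best, cell_size=2.0)
print(sg.delineate_regions(vmap).counts())
```

prints

```
FCO2 mean=2.88 sd=0.40 CV=14.0% (moderate)
best: exponential(C0=0.088, sill=0.177, a=70.2 m)
SDI = 15.9% -> strong
LOO RMSE = 0.366
{'R1': 1187, 'R2': 373, 'unassigned': 556}
```

The simulated efflux averages 2.88 µmol m⁻² s⁻¹ with moderate
variability; the fitted variogram for this realisation keeps a small
nugget share, so its spatial dependence classifies as strong; kriging
predicts held-out points to ±0.37 µmol m⁻² s⁻¹; and the map splits into
a high-emission region R1 (2.9–4.2 µmol m⁻² s⁻¹), a low-emission region
R2 (1.9–2.7), and cells between the bands.

The same chain is available from the shell:

```bash
soilgeo run --seed 7 --outdir run7           # full pipeline
soilgeo simulate --seed 1 --out points.csv   # survey only
soilgeo variogram points.csv FCO2 --spacing 10
soilgeo krige points.csv FCO2 --spacing 10 --out fco2.asc
soilgeo compare --seed 1                     # two-region battery
```

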
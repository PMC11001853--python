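# pelagichab

Habitat-suitability modelling for pelagic fishes from longline catch
records. The package turns a table of longline sets (date, position,
hooks, catch count) and gridded environmental fields (sea-surface height,
SST, chlorophyll, bathymetry) into:

* **environmental covariates** — per-layer *spatial anomalies* (the
  mesoscale signal left after subtracting each layer's study-area mean) and
  *interannual anomalies* (residuals of a seasonal + linear-trend
  decomposition of monthly domain means);
* **a hierarchical Bayesian count model** — negative-binomial or Poisson
  catches with a log link, an effort offset
  `E_i = (Σy/ΣH)·H_i`, polynomial covariate effects, a Matérn spatial
  random field (SPDE/finite elements on a Delaunay mesh) and a cyclic
  monthly random effect, fitted by a nested Laplace approximation;
* **WAIC model competition** over enumerated structures that respect
  collinearity screening (|r| > 0.6, GVIF > 3 forbidden pairs);
* **habitat-suitability maps** — posterior expected catch at unit effort
  on a 0.25° grid, scaled to 1, with the high-quality-habitat share
  (HQH, % of cells ≥ 0.6) per monthly climatology and per year.

It ships a synthetic-study generator with known ground truth (eddy-bearing
sea-surface-height fields, shelf/basin bathymetry, seasonally structured
catches), so the whole pipeline is testable end to end without any data
download. It is aimed at quantitative fisheries ecologists who want the
model mechanics — anomaly construction, SPDE spatial effects, offset
handling, WAIC ranking — as reusable, tested parts.

## Worked example

```python
import numpy as np, pandas as pd
from pelagichab.workflow import simulate_study
from pelagichab import ModelStructure, FitSettings, fit
from pelagichab.prediction import climatology_predict

study = simulate_study(seed=5, n_sets=600, n_months=240,
                       mesh_kwargs=dict(max_edge_inner=2.5, max_edge_outer=4.0,
                                        cutoff=0.8, extension=2.0))
print(f"trend {study.decomposition.trend_slope_per_decade:.2f} cm/decade, "
      f"zero fraction {study.report['zero_fraction']:.3f}")

structure = ModelStructure(terms=(("adt_sa", 2), ("bottom_depth", 2), ("adt_ia", 1)))
result = fit(structure, study.paired, mesh=study.mesh,
             settings=FitSettings(hyper_method="eb", seed=0))
print(result.summary())

times = pd.to_datetime(study.adt_sa["time"].to_numpy())
stack = study.adt_sa.isel(time=np.where((times.year >= 2012) & (times.year <= 2019))[0])
maps = climatology_predict(result, {"adt_sa": stack}, study.depth,
                           study.grid, study.polygon)
print("HQH % by month:", [round(m.hqh_percent, 1) for m in maps])
```

prints (seed 5):

```
trend 4.34 cm/decade, zero fraction 0.040
structure: nb~adt_sa^2+bottom_depth^2+adt_ia+W+gamma(M)
WAIC 4581.50  (p_waic 24.21, n 600)
  intercept          -0.2081 (0.1514)
  adt_sa             +0.1641 (0.0479)
  adt_sa^2           -0.0919 (0.0243)
  bottom_depth       +0.5571 (0.1179)
  bottom_depth^2     -0.0447 (0.0739)
  adt_ia             +0.2390 (0.0442)
  [spatial_range] 2.882 (nan)
  [spatial_sd] 0.43 (nan)
  ...
HQH % by month: [7.0, 7.1, 6.8, 7.0, 7.0, 7.0, 6.7, 6.8, 6.9, 6.9, 6.6, 6.9]
```

The recovered trend is the generator's injected long-term sea-level rise
(4.8 cm/decade, attenuated slightly by the finite interannual cycle count);
the fitted intercept equals the generating intercept plus the documented
offset-convention shift; the HQH row is the share of the study area at or
above suitability 0.6 in each monthly climatology.

A command line covers the same stages:

```bash
pelagichab simulate --out study/ --seed 1 --n-sets 2000
pelagichab anomalies --var study/adt.nc --polygon study/polygon.geojson --out anom/
pelagichab screen --paired study/paired.csv --covariates adt_sa,adt_ia,bottom_depth --out report.json
pelagichab select --paired study/paired.csv --covariates adt_sa,adt_ia --out board.csv
pelagichab predict --paired study/paired.csv --env anom/adt_sa.nc \
    --depth study/depth.nc --polygon study/polygon.geojson --out maps/
```

## Layout

| module | contents |
|---|---|
| `pelagichab.synthetic` | environmental/bathymetry/fishery generators with ground truth |
| `pelagichab.anomalies` | spatial anomalies, monthly means, interannual decomposition |
| `pelagichab.pairing` | validation, regridding, window averaging, cell matching, offset |
| `pelagichab.screening` | correlations, GVIF, forbidden pairs, structure enumeration |
| `pelagichab.mesh` / `spde` | Delaunay meshing, FEM matrices, Matérn precision, cyclic RW1 |
| `pelagichab.model` | the latent Gaussian count model, Laplace inference, WAIC |
| `pelagichab.selection` | WAIC leaderboard and best-structure selection |
| `pelagichab.prediction` | gridded suitability, scaling, HQH, climatology, year scenarios |

See `docs/methods.md` for the model, priors, numerical choices, and known
limitations.
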
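# efit

Light-use-efficiency estimation of a forest site's theoretical maximum
potential total net primary productivity (`tNpp_tmax`, Mg ha⁻¹ yr⁻¹) from
monthly climate normals and atmospheric CO₂, and of its **Ecosystem Fit**
(`eFit = 100 × tNpp_obs / tNpp_tmax`) — the percent of that maximum a site
actually realizes.

The chain per site:

1. **Growing season** — months with mean temperature ≥ 0 °C (threshold and
   strictness configurable) give the season length `G_d` (sum of non-leap
   calendar days), mean temperature `G_t`, and mean daily solar radiation
   `G_srad`.
2. **CO₂ compensation point** `Γ* = exp(19.02 − 37.83 / (R·(G_t + 273.15)))`
   with `R = 0.008314 kJ mol⁻¹ K⁻¹`.
3. **Uptake** — intercellular CO₂ `c_i = 0.7·c_a`, rubisco-limited term
   `W_i = c_i / (4.5·c_i + 10.5·Γ*)`, net uptake `A = (1 − Γ*/c_i)·W_i`.
4. **Conversion efficiency** `ε_c = A·β·α` with `β = 0.45`, `α = 0.90`.
5. **Maximum productivity**
   `tNpp_tmax = G_srad·G_d·0.45·ε_i·ε_c / 1000 / 18.2 × 10`
   (kJ→MJ, divide by the 18.2 MJ kg⁻¹ specific energy of dry biomass,
   kg m⁻² → Mg ha⁻¹).
6. **Ecosystem Fit** from observed productivity, percent by default.

Also included: annual Mauna Loa CO₂ means (1959–2022) as packaged data,
monthly-climate extraction from WorldClim-style GeoTIFF stacks (point or
circular-buffer mean), PAM (k-medoids) clustering with silhouette-based
selection of k, per-group squared Pearson correlation of eFit vs observed
NPP, and a synthetic-data generator with analytic truth tables.

## CLI

```sh
# generate a synthetic 3-zone dataset (CSV tables + optional GeoTIFFs)
efit synth --n-sites 30 --seed 1 --rasters --out-dir demo

# compute per-site results from the climate table ...
efit compute --sites demo/sites.csv --climate-table demo/climate.csv \
             --co2-table demo/co2.csv --out demo/results.csv

# ... or from monthly raster stacks, with an optional buffer mean
efit compute --sites demo/sites.csv --raster-dir demo/rasters \
             --buffer-m 5000 --out demo/results.csv

# PAM clustering with silhouette-based k selection
efit cluster --results demo/results.csv --features g_temp,g_srad,g_days \
             --k 2:8 --seed 17

# per-group r² of eFit against observed NPP
efit groupwise-r2 --results demo/results.csv --sites demo/sites.csv \
                  --group-by climate_zone

# show every effective parameter and its source (default|config|flag)
efit params
efit params --config overrides.toml --beta 0.5
```

`compute` writes one row per site
(`site_id, g_days, g_temp, g_srad, c_a, c_i, gamma_star, w_i, a_net,
eps_c, tnpp_tmax, efit, flags`) plus a JSON manifest with parameter
values, input hashes, and per-site flags. Undefined eFit (empty growing
season) is serialized as an empty field with an `efit_undefined` flag.
`--ratio` emits eFit as a ratio instead of percent. Exit codes: 0 success,
2 configuration error, 3 data error.

CO₂ is resolved by exact-year lookup (no interpolation) from the packaged
Mauna Loa table, a user table (`--co2-table`), or a constant fallback
(`--co2-constant`).

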
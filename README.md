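# fireflux

Burned-area mapping and fire-driven aboveground-carbon emission accounting
for tropical landscapes.

During drought years, fires in Amazonia spread far beyond deforestation
frontiers into standing forest, savanna (cerrado) and managed land, and the
resulting carbon flux rivals that of deforestation itself. Attributing that
flux to the land covers that produced it requires joining several data
streams: multi-date satellite reflectance for burn-scar mapping, a
land-cover map, an aboveground-biomass (AGB) map with its error map, and
active-fire point detections. `fireflux` implements that chain as a tested,
reusable pipeline for researchers working on fire carbon budgets, driven
either by real rasters or by its own synthetic-landscape generator with
known ground truth.

## The model

**Burn-scar mapping.** Each 3-band (RED/NIR/SWIR) image is decomposed per
pixel by a linear spectral mixing model into vegetation, soil and shade
endmember fractions (non-negative, summing to one). Fresh burn scars are
dark, so the shade-fraction image is segmented by region growing (difference
threshold 8 on the 0–255 rescaled image, minimum region 4 pixels) and region
mean shade is clustered into burned/unburned, with the high-shade cluster
called burned above a shade floor of 0.5. Per-date masks accumulate into a
cumulative map with each pixel's first-burn month; components under the
25 ha minimum mapping unit (4 pixels at 250 m) are removed.

**Biomass loss.** Remaining live biomass after a single fire is proportional
to pre-fire biomass,

    B_after = α · B_initial,      α = 0.7084 ± 0.034 (Mg Mg⁻¹),

with α fit by York errors-in-variables regression (both axes of the
before/after plot compilation carry measurement error). Burned pixels lose
`(1 − α) · B_initial`.

**Emission bookkeeping.** With a carbon fraction of 0.48 Mg C per Mg dry
biomass, the per-class carbon loss splits into the in-year *gross* flux and
the later-years *committed* flux by land-cover pathway: COMBUST (cerrado,
productive lands, cerrado regrowth — all loss combusted, committed 0),
DEFOR_SPLIT (fresh deforestation — 50 % combusted / 50 % to the decay pool)
and DECAY (standing forest and forest regrowth — no combustion; first-year
release `1 − e^(−k)` with decay rate k = 0.17 yr⁻¹).

**Uncertainty.** A Monte Carlo scheme perturbs the slope and the per-pixel
biomass with Gaussian draws at their stated errors and the categorical
inputs (class label, burn flag) by uniform-threshold rules at the map
accuracies (land cover 0.80; burn map 0.992 forest / 0.9693 non-forest).

**Regional scaling.** High-confidence (> 80) active-fire detections inside
burn scars, aggregated per burned-forest polygon, drive a weighted least
squares regression of burned area on fire count (weights from an OLS
pre-fit, inverse group residual variance) used to extrapolate forest burned
area — and hence emissions — beyond the mapped region.

## Worked example

```python
import fireflux as ff

# a synthetic 200 x 200 pixel fire-season scene (defaults reproduce the
# published study conditions) and its burn map recovered from reflectance
cfg = ff.LandscapeConfig(grid_rows=200, grid_cols=200, seed=42)
scene = ff.generate_scene(cfg)
burn = ff.map_burn_scars(scene.reflectance_by_month)

# biomass-retention slope from synthetic before/after plot pairs
pairs = ff.generate_plot_pairs(500, seed=42)
model = ff.fit_york(pairs)
print(f"retention slope alpha = {model.alpha:.4f} +- {model.alpha_sd:.4f}")

# per-class carbon bookkeeping
_, loss = ff.apply_loss(scene.biomass, model, burn)
records = ff.compute_class_emissions(loss, scene.landcover, burn,
                                     biomass=scene.biomass)
summary = ff.summarize(records, class_areas_km2=scene.class_areas_km2())
print(f"burned area          = {sum(r.burned_area_km2 for r in records):.1f} km2")
print(f"total carbon loss    = {summary.total_c_tg:.3f} Tg C")
print(f"gross emission 2010  = {summary.gross_c_tg:.3f} Tg C")
print(f"committed emission   = {summary.committed_c_tg:.3f} Tg C")
print(f"forest percent burnt = {summary.percent_burned_by_class[1]:.2f} %")
```

prints

```
retention slope alpha = 0.7059 +- 0.0039
burned area          = 270.9 km2
total carbon loss    = 0.255 Tg C
gross emission 2010  = 0.175 Tg C
committed emission   = 0.080 Tg C
forest percent burnt = 4.48 %
```

The fitted slope recovers the generating value 0.7084 within its standard
error; 4.48 % of the synthetic old-growth forest burns because the scene is
generated at the published burned fractions; and the gross/committed split
reflects the pathway mix of the classes that burned. At this desk scale
(2 500 km² instead of ~900 000 km²) the absolute carbon numbers are
proportionally small.

The same chain runs from the shell:

```sh
fireflux run-all --out run1 --seed 42          # or stage by stage:
fireflux simulate --out run1 --seed 42
fireflux map-burns --out run1
fireflux emissions --out run1
```

writing TIFF rasters, CSV tables (per-class emissions and burned areas), a
Monte Carlo summary and a plain-text report into `run1/`.

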
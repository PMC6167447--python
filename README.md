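# wavetrait

Continuous-wavelet-transform (CWT) screening of canopy reflectance
spectra for trait estimation.

Hyperspectral canopy reflectance (350–2500 nm at 1 nm) carries
information about canopy leaf biomass (CLB, kg dry leaf mass per m²
ground), but two-band vegetation indices extract only a sliver of it and
transfer poorly across varieties, sites and growth stages.  `wavetrait`
implements the alternative: decompose every spectrum against a large bank
of mother wavelets, and search the whole (wavelength, scale) plane for
the single wavelet coefficient that best predicts the trait.  It is aimed
at crop-phenotyping and imaging-spectroscopy researchers who want a
tested, reproducible implementation of that screening procedure —
including a synthetic-spectra generator with a planted, exactly known
best feature, so every stage can be validated without field data.

## Method

For a reflectance spectrum *f*(*t*) (t = wavelength in nm), the wavelet
coefficient at scale *a* and shift *b* is

    C(a, b) = ∫ f(t) · a^(−1/2) · ψ*((t − b) / a) dt,

with dyadic scales a = 2³ … 2⁸ (in 1-nm samples) and ψ one of 108 mother
wavelets from 15 families (Haar, db2–db20, sym2–sym17, coif1–5, 15
biorthogonal + 15 reverse-biorthogonal pairs, Meyer, Mexican hat, Morlet,
discrete Meyer, gaus1–8, cgau1–8, and the complex Shannon / frequency
B-spline / Morlet families).  The screening procedure is, per function:

1. transform every calibration spectrum (water-absorption windows
   1350–1410, 1790–1950 and 2471–2500 nm zeroed beforehand);
2. regress the trait on the coefficient at every (W, S) cell and record
   the calibration R² — the correlation scalogram;
3. keep the top 1% of eligible cells as the function's candidate features.

Across functions, the top sets are pooled into an occurrence map, each
function is summarised by its best eligible R², and the box-plot outlier
rule (above Q3 + 1.5 IQR) singles out the optimal mother wavelets.  The
winning function's best features are calibrated as single-feature linear
models Y = slope·x + intercept, validated on held-out experiments
(Rv², RRMSE = 100·RMSE/mean(O)), compared against the NDVI(R2160, R1540)
and ratio(R708, R565) vegetation-index baselines on the identical split,
and characterised by their per-band influence profile and their position
on the mean coefficient curve (peak / valley / zero-crossing).

## Worked example

```python
from wavetrait import RunConfig, SimulationConfig, run_screen

config = RunConfig(
    simulation=SimulationConfig(n_samples=300, target_cell_r2=0.8),
    functions=("db7", "mexh", "haar", "sym3", "gaus3", "bior3.5"),
    seed=7,
)
result = run_screen(config)
model, report = result.models[0]
feat = model.feature
print(f"winner: {result.winner} (W{feat.wavelength}, S{feat.scale_exponent})")
print(f"model:  {model.equation}   Rc2 = {model.rc2:.2f}  SE = {model.se:.3f} kg/m2")
print(f"valid:  Rv2 = {report.rv2:.2f}  RRMSE = {report.rrmse:.2f}%")
```

prints

```
winner: db7 (W1100, S5)
model:  Y = 22.180x+0.142   Rc2 = 0.79  SE = 0.029 kg/m2
valid:  Rv2 = 0.80  RRMSE = 21.74%
```

The simulated dataset plants a known relationship between CLB and the
db7 coefficient at (1100 nm, S=5) with cell-R² = 0.8; the screen
recovers exactly that function and cell.  The validation block of the
comparison table shows the wavelet feature beating both index baselines
(Rv² 0.80 vs 0.59 and 0.42; RRMSE 21.7% vs 33.6% and 39.4%) — the
pattern the method is designed to expose.

The same run is available from the shell:

```
wavetrait simulate --n 300 --seed 7 --out data/
wavetrait run-all --config run.yaml
```

with `simulate`, `decompose`, `screen`, `select`, `fit`, `validate`,
`compare`, `report` and `run-all` verbs for the individual stages
(`wavetrait --help`).

## Data formats

Spectra are wide CSV: first column `sample_id`, then one column per
integer wavelength, reflectance as a fraction:

```
sample_id,350,351,...,2500
s00000,0.1402,0.1405,...,0.1621
s00001,0.2210,0.2214,...,0.1843
```

Traits are CSV with columns `sample_id, clb_kg_m2, experiment_id, site,
variety, sampling_date, growth_stage`:

```
sample_id,clb_kg_m2,experiment_id,site,variety,sampling_date,growth_stage
s00000,0.1485,exp1,JAAS,Ningmai 9,2004-04-18,after
s00001,0.0761,exp1,JAAS,Xumai 26,2004-03-25,before
```

The calibration/validation split is assigned per experiment (never
within one), at an approximate 2:1 ratio.

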
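# Methods

## The screening model

The package treats trait estimation from canopy reflectance as a feature
search over the continuous wavelet transform.  A spectrum *f*(*t*) on the
fixed 1-nm grid (350–2500 nm, 2151 bands) is decomposed against a mother
wavelet ψ at dyadic scales a = 2^S, S = 3…8 (a in units of 1-nm
samples, so S = 8 analyses a ≈ 256-nm neighbourhood) and every shift *b*
on the grid.  At each (wavelength, scale) cell the calibration trait
values are regressed on the coefficient with a simple linear model; the
cell's R² fills the correlation scalogram, the top 1% of eligible cells
form the function's candidate features, and functions are compared by
their best eligible R².  The underlying assumptions are those of the
simple regression: a single coefficient carries the predictive signal,
the coefficient–trait relation is approximately linear, and calibration
and validation samples are exchangeable apart from the experiment-level
split.

## Transform quadrature

The spectrum is taken as piecewise constant on 1-nm cells centred on the
integer wavelengths.  The defining integral then reduces exactly to a
discrete convolution of the band values with a kernel of per-cell
integrals of the scaled wavelet — the classic integrate-then-difference
scheme (the kernel entries are differences of the running integral of ψ
at consecutive cell edges).  The cell integrals are evaluated:

- for closed-form wavelets (mexh, morl, gaus, cgau, shan, fbsp, cmor) by
  12-point Gauss–Legendre quadrature per cell, which is machine-precise
  on these smooth forms for cells at most 1/8 wavelet-unit wide;
- for cascade wavelets (haar, db, sym, coif, dmey, bior, rbio) as the
  exact integral of the piecewise-linear interpolant of the ψ samples;
- the continuous Meyer wavelet is first synthesised on a fine grid from
  its analytic Fourier spectrum (band-limited quadrature), then handled
  like a sampled wavelet.

Evaluating the cell edges exactly (rather than snapping them to the ψ
sample grid) keeps the engine within 1e-8 of a brute-force Riemann
evaluation of the integral for closed forms; the test suite verifies
this against an independent per-shift midpoint-sum oracle.

Kernels are centred on the midpoint of the wavelet's support grid.  The
spectrum is zero-padded — consistent with the zeroed interior water
windows — and a shift is flagged *boundary-dependent* when more than 1%
of the kernel's absolute mass falls outside the measured range.  Flagged
cells and the 252 masked water-window bands (closed intervals
[1350,1410], [1790,1950], [2471,2500]) are computed and exported but
ineligible for feature ranking.  A fixed-fraction-of-support exclusion
was rejected: at S = 7–8 every wavelet's scaled support exceeds the
2151-band record, which would leave no eligible cell at exactly the
scales where broad absorption features live; the mass criterion measures
actual padding dependence instead.

Complex wavelets enter the regressions through the modulus of their
coefficient — a real regressor is required and the modulus is the
standard envelope choice; nothing else in the pipeline distinguishes
them.

## Wavelet bank conventions

The registry enumerates 108 functions in 15 families.  Parameterised
complex families follow their listed parameter combinations (shan Fb–Fc:
1–0.1, 1–0.5, 1–1, 1–1.5, 2–3; fbsp M–Fb–Fc: 1–1–0.5, 1–1–1, 1–1–1.5,
2–1–0.1, 2–1–0.5, 2–1–1; cmor Fb–Fc: 1–0.4, 1–0.5, 1–1, 1–1.5, 2–0.1,
2–0.5).  Cascade wavelets are sampled by successive refinement from the
family filter banks (PyWavelets) at resolution 2^−J, default J = 10;
both biorthogonal families use the decomposition wavelet of their pair,
which for the reverse-biorthogonal names (swapped filter banks) is the
plain family's reconstruction counterpart.  Normalisation is unit L²
norm for cascade output and textbook constants for the closed forms; any
consistent rescaling of ψ rescales coefficients linearly and provably
changes no R² (a property the tests assert to 1e-12).  Both the
continuous Meyer ψ (`meyr`) and its FIR approximation (`dmey`) are in
the registry as separate functions.

## Screening rules

- Top-q cardinality is ⌈q·E⌉ over the E eligible cells; ties at the
  cutoff break towards higher scale, then lower wavelength, making the
  selection deterministic.
- The per-function summary for the box plot is the maximum eligible
  calibration R².
- Box-plot fences use linear-interpolation quartiles; optimal functions
  exceed Q3 + 1.5·IQR, poor ones fall below Q1 − 1.5·IQR.
- Zero-variance regressors at a cell yield R² = 0 (logged) rather than
  an error, so full-plane sweeps always complete.

## Models and metrics

Single-feature models are ordinary least squares; `rc2` is the squared
Pearson correlation, `se` the standard error of estimate
√(SSE/(n−2)) in trait units.  Validation applies the calibrated model
unchanged: `rv2` is the squared correlation of predictions with
observations (1:1-plot convention; the 1 − SSE/SST variant is exported
alongside), and RRMSE = 100·√(mean((Pᵢ−Oᵢ)²))/mean(O) percent.
Validating a simple linear model on its own calibration data reproduces
rc2 exactly, which the suite uses as an identity check.  Subgroup
reports evaluate the single global model inside validation subgroups
(growth stage relative to anthesis, site, variety, year) without
refitting; subgroups under 3 samples are flagged with metrics
suppressed, and the mean row is the unweighted mean of subgroup metrics.
Vegetation-index baselines (normalized difference on 2160/1540 nm;
simple ratio on 708/565 nm — the ratio form is our reading of an index
whose printed definition names only its bands) are fitted and validated
on the identical split as the wavelet features.

Because the coefficient is linear in the spectrum, the influence profile
of a feature is exactly the transform's kernel weight per band (modulus
for complex ψ); its local extrema are reported as the influential
wavelengths.  Feature positions on the mean calibration coefficient
curve are classified zero-crossing (sign change within ±2 nm), else
peak/valley by local extremality, with curvature as the fallback for
monotone neighbourhoods; precedence is zero-crossing > peak > valley.

## Synthetic data generator

The generator is phenomenological, not a radiative-transfer model: the
screening pipeline needs controllable statistical structure — a known
best cell — more than physical fidelity.  Each spectrum is a mixture
(1−c)·soil + c·leaf of a linear soil line (0.12→0.32) and a fixed
green-leaf signature (green bump at 550 nm, chlorophyll trough at
680 nm, red-edge sigmoid at ~715 nm, NIR plateau ≈ 0.5 declining through
the SWIR, liquid-water dips at 970/1200/1450/1940 nm).  Canopy cover
follows a Beer–Lambert response c = 1 − exp(−k·CLB) with extinction
k = 12 m²/kg — saturating near the top of the biomass range, as real
canopies do — with 8% multiplicative scatter standing in for
canopy-structure variation.  CLB is drawn from a right-skewed
Beta(2, 3) scaled to [0.0096, 0.330] kg/m², with per-experiment level
factors in [0.75, 1.25] emulating between-experiment spread.  Smooth
correlated noise (Gaussian-filtered white noise, ~30 nm correlation
length, sd 0.01) and white sensor noise (sd 0.002) are added, and the
water windows are zeroed.

The planted feature is exact by construction.  A perturbation shaped
like the planted wavelet (db7 at W\*=1100 nm, S\*=5 by default — chosen
so its scaled support clears both the water windows and the spectrum
edges) is added per sample with an amplitude solving, via the linearity
of the transform, for a planted-cell coefficient equal to an affine
function of CLB plus orthogonalised noise; the noise amplitude is tuned
by bisection until the sample squared correlation equals
`target_cell_r2` (contract ±0.02, achieved to ~1e-6; at target 1.0 the
correlation is exact regardless of the other noise sources).  Matching
the injected amplitude to the natural coefficient spread at that cell
keeps the spectra plausible while leaving every other function to see
the perturbation only through its (imperfect) kernel overlap plus its
own uncancelled noise — which is what makes the planted cell the
dataset's genuinely best feature.

Default layout: 1502 samples in eight pseudo-experiments sized
(127, 219, 136, 126, 285, 203, 240, 166), experiments 2/4/5/7/8
calibration (1036 samples) and the rest validation (466); other sample
sizes scale the layout proportionally (largest remainder).

What the generator does *not* emulate: radiative-transfer coupling
between pigments, water and structure; view/illumination geometry;
growth-stage dependence of biomass (sampling dates are assigned at
random); instrument-specific noise spectra.  Passing recovery tests
therefore demonstrate that the pipeline finds a planted linear
coefficient–trait relation under realistic spectral shape, noise and
saturation — not that any particular feature is optimal for real
canopies.

## Numerical and design choices

- Resolution J = 10 (step 2^−10) balances the zero-mean tolerance
  (|∫ψ| ≤ 1e-3 for the zero-mean families) against evaluation cost;
  kernels are cached per (function, scale).
- Degenerate correlations (zero variance on either side) are defined as
  0 and logged.
- Artifacts contain no timestamps; a manifest records the seed and a
  hash of the scientific configuration (output location excluded), so
  reruns from one manifest are byte-identical.
- Per-function failures during a screen are logged and skipped; a run
  aborts only when more than 10% of functions fail.
- The acceptance script uses 20 seeded replicates at n = 300 for
  recovery rates and one full-registry run at n = 1502 for the flagship
  comparison; these sizes are the package's reference configuration for
  reproducible summary numbers.

## Known limitations

- The screening fits single-feature models only; multi-feature or
  nonlinear models are out of scope.
- Per-cell R² values are used for ranking, not inference — no
  multiple-testing correction is applied or implied.
- The boundary mass criterion is a pragmatic stand-in for a formal
  treatment of edge effects in a redundant transform.
- Complex families are handled through the coefficient modulus; if a
  different realization (e.g. real part) mattered for a use case it
  would need the switch extended at the engine level.
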
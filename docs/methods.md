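# Methods

## Forward model

The synthetic study conditions are generated by a closed-form steady-state
diffusion-approximation reflectance model for a semi-infinite homogeneous
medium with an extrapolated boundary (the classical two-dipole / Farrell-type
solution), evaluated at the probe's source–detector separation (SDS):
750 μm for probe 1, 650 μm for probe 2. For an isotropic point source buried
at depth z₀ = 1/μt′ (μt′ = μa + μs′) and its image dipole above the
extrapolated boundary at z₀ + 2z_b (z_b = 2AD, D = 1/3μt′, A from the
Groenhuis internal-reflection polynomial at relative refractive index 1.4),

R(ρ) = a′/4π · [ z₀(μ_eff + 1/r₁) e^{−μ_eff r₁}/r₁² +
                 (z₀+2z_b)(μ_eff + 1/r₂) e^{−μ_eff r₂}/r₂² ],

with μ_eff = √(3 μa μt′), a′ = μs′/μt′, r₁ = √(z₀²+ρ²),
r₂ = √((z₀+2z_b)²+ρ²).

Wavelength dependence enters through two spectral shapes, both normalised to
band mean 1 over 450–630 nm so that the scalar labels are exactly the
band-average optical properties:

* **absorption**: a monotone piecewise-cubic interpolation of tabulated
  relative oxyhemoglobin extinction values (Soret tail falling through the
  blue, Q-bands at 540/577 nm, near-transparent red), reflecting the
  hemoglobin used as phantom absorber;
* **scattering**: the Mie-like power law (λ/540 nm)^(−0.37), the typical
  visible-band slope of ~1 μm polystyrene microspheres used as phantom
  scatterer.

Each simulated grayscale spectrum is multiplied column-by-column by a
reflectance-standard curve — a white-LED-like source × detector response:
broad phosphor lobe peaking near 565 nm, blue shoulder, logistic roll-off at
the blue band edge from the grating/camera response, moderate red-edge
sensitivity. This gives spectra the peaked, tailed morphology of
grating-dispersed camera spectra. The grayscale spectrum is then split into
R/G/B channel spectra in proportion to a piecewise-linear wavelength→RGB map
(band-edge intensity falloff disabled so the channel fractions are defined on
the whole working band; pure red above 620 nm). The split conserves intensity
exactly: gray = R + G + B at every column.

### Known limitations of the stand-in

The diffusion approximation requires the observation distance to exceed the
transport mean free path 1/μt′ (~1.1–1.4 mm here); at an SDS of 0.75 mm it is
evaluated *outside* its validity domain, where it systematically
underestimates absorption contrast relative to photon-transport Monte Carlo:
|∂lnR/∂μa| ≈ 0.11 cm here versus several times that for a Monte-Carlo
forward model of the same geometry. Two measurable consequences, both
documented by the test suite rather than hidden:

* the hemoglobin-band dips deepen only from ~10% to ~45% of the local
  continuum as μa sweeps 0.44→2.45 cm⁻¹, so the 35 whole-spectrum features
  constrain μa more weakly than they would on Monte-Carlo spectra. The
  fivefold-CV RMSE% of the WIR model consequently reaches ~3.5–4.6% for μa in
  the noisy and all-errors-compounded conditions (the spectral-matching
  inversion on the *same* spectra achieves ~1% under noise, showing the
  information loss is in the feature summary, not the spectra);
* the qualitative robustness ordering is nevertheless preserved, and strongly:
  on the all-errors condition the inversion degrades to ~59% RMSE% for μa and
  ~11% for μs′, an order of magnitude above the regressor.

Passing tests on this synthetic data therefore demonstrate the mechanics and
the qualitative robustness ordering (features degrade far more gracefully
than wavelength-by-wavelength matching under miscalibration), not the
absolute error levels attainable on Monte-Carlo-generated or measured
spectra.

## Study conditions (generator defaults)

* 1520 spectra per condition: a 40 × 38 Cartesian label grid, μa equally
  spaced over [0.44, 2.45] cm⁻¹ and μs′ over [6.53, 9.58] cm⁻¹, endpoints
  included exactly. Records sharing a μa level share a synthetic "titration"
  group id used by leave-one-group-out validation.
* Wavelength grid: 585 pixel columns spanning 450–630 nm (≈0.308 nm/px,
  matching a device dispersion of ~12 px per 3.7 nm).
* Corruptions (defaults; all seeded): Gaussian noise at linear RMS SNR 35:1
  (45:1 when all errors are compounded, mirroring the harder convergence
  regime of the compounded condition); wavelength shift −4.8 nm (leftward,
  grid labels unchanged — the miscalibration is silent); compression of
  1 nm at each tail (affine squeeze, margins hold edge values); tail rotation
  by a mean-1 linear ramp with slope drawn uniformly in ±5%; systematic
  scaling by one factor per spectrum drawn uniformly in ±5%.
  "35:1" is interpreted as a linear RMS-amplitude ratio; the interpretation
  is configurable (`ErrorConfig.snr_linear`).
* Compounding order is fixed: scale → rotate → shift → compress → noise
  (detection noise enters after the optical/calibration distortions).
* The augmentation suite applies 14 fixed corruption combinations to the
  base dataset: 14 × 1520 = 21,280 training records.
* Deterministic distortions are applied identically to R, G and B; noise is
  drawn at the gray level and distributed to the channels by the column RGB
  fractions, so the gray-level SNR contract and gray = R+G+B both hold
  exactly.

## Models

* **WIRRegressor** — one `sklearn` `GradientBoostingRegressor` per target
  (200 estimators, max depth 5, min 3 samples/leaf, random_state 0, squared
  error, learning rate 0.1). The probe id is one-hot encoded internally;
  predictions are clipped to the training label range per target (tree
  ensembles do not extrapolate; the clip makes the invariant exact).
* **DenseNNRegressor** — baseline: per-target MLP with two hidden layers of
  25 units, standardised inputs, MSE loss, adam, early stopping on a 10%
  validation split, ≤500 epochs, fixed seed. Input is either the 35-feature
  vector or the concatenated raw gray+R+G+B spectra (4N values). Baseline
  plumbing only; no accuracy contract.
* **SpectralMatchingInverter** — the classical inversion: coarse 200 × 200
  grid over μa ∈ [0.3, 3.0], μs′ ∈ [5.5, 10.5] (slightly wider than the
  generation ranges), scored by summed squared wavelength-by-wavelength
  differences against a precomputed forward library (float32, ~90 MB),
  followed by bounded trust-region least-squares refinement to relative
  tolerance 1e-6. Non-converged records keep best-found values and are
  flagged.

## Error metric and validation

RMSE% = √(mean(((pred − truth)/truth)²)) × 100 — the root-mean-square of
relative errors, comparable across the two targets' different scales. An
alternative normalisation (RMSE / mean truth × 100) is available via
`rmse_percent(mode="mean_normalized")`.

Fivefold cross-validation uses random shuffled folds (seeded); pooled
held-out predictions give one RMSE% per target. Leave-one-group-out
validation holds out one titration (or experiment) group at a time; optional
augmentation records join every training set and never a test set; the mean
row is the arithmetic mean of per-group RMSE%.

## Preprocessing chain (measured-image path)

threshold (per-channel values < 10 DN → 0, strict inequality) →
exposure normalisation I/(Ti·ISO) → column collapse (sum over the M pixel
rows) → centred moving average, window 6 (3 left / 2 right of each index,
reflected edges) → reflectance-standard calibration (divide for measured
spectra; the simulated path multiplies instead, imprinting the response).
The chain is deterministic; metadata travels in a sidecar JSON record.

Numerical notes: the even smoothing window turns symmetric peaks into exact
two-sample plateaus, so the second-maximum feature counts a plateau once, at
its leftmost sample; the moving average conserves the mean exactly for
spectra with zero window-wide margins. Wavelength shift and compression use
linear interpolation — exact for integer-pixel shifts and for content linear
in wavelength, curvature-limited (~1e-3 relative for smooth band-limited
spectra) otherwise. Fractional quantities tied to an 8-bit rendering stay
within 2/peak_DN of the ideal value per column.

## Seeds and reproducibility

Every stochastic stage consumes a child seed derived from one master seed and
the stage name (SeedSequence over (seed, crc32(stage)), reduced below 2³¹);
no global random state is used anywhere. Two pipeline runs from one master
seed produce bit-identical artifacts; each run writes a manifest with the
effective config, a config hash, and per-file SHA-256 checksums.

## Problem sizes used by tests and the acceptance script

Unit tests use a 5 × 5 label mini-grid; the acceptance-level checks use the
canonical 1520-spectrum grid for dataset conformity, inversion
self-consistency (1520 inversions), and the per-condition fivefold CV sweep.
The full robustness experiment (`robustness_experiment`) accepts reduced grid
sizes and model subsets; its defaults run all four models on all seven
conditions at the canonical size.
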
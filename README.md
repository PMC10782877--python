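# wirdrs

Use-error-robust estimation of tissue optical properties from visible diffuse
reflectance spectroscopy (DRS).

## The problem

Visible DRS probes tissue by measuring how much illumination light is
diffusely reflected back into a collection fiber as a function of wavelength.
Two scalar optical properties summarise the tissue over the working band
(450–630 nm): the absorption coefficient μa (cm⁻¹, elevated by tumour
angiogenesis) and the reduced scattering coefficient μs′ (cm⁻¹, lowered by
extracellular-matrix breakdown). The classical way to recover (μa, μs′) from
a spectrum is inverse spectral matching ("MCI"): search for the property pair
whose forward-model spectrum best matches the measurement wavelength by
wavelength. That approach is accurate on ideal data but brittle against the
artefacts real devices accumulate in the field — wavelength miscalibration,
sensor misalignment, light sources that were never warmed up, plain noise —
collectively *use-errors*.

`wirdrs` implements the alternative: a **wavelength-independent regressor
(WIR)** — gradient-boosted regression trees (200 estimators, depth 5, ≥3
samples per leaf) trained on 35 whole-spectrum features that never reference
a specific wavelength:

* max / mean / standard deviation of intensity for the R, G, B and gray
  spectra (12),
* max / min / mean / std of the per-pixel-column slope series (16),
* two spectrum-length features: columns above quarter-maximum, and the pixel
  distance between the two highest local maxima of the smoothed gray
  spectrum (2),
* skewness of each channel (4), and the probe id (1).

Because these features are statistics of the whole spectrum, a shifted,
compressed, tilted or rescaled spectrum changes them far less than it changes
a wavelength-by-wavelength match.

The package contains everything needed to re-run the robustness experiment at
desk scale on synthetic data: a closed-form diffusion forward model standing
in for photon-transport Monte Carlo, the grayscale→RGB channel split, the
image→spectrum preprocessing chain, the six use-error corruptions and their
14-row training-augmentation suite, the WIR model, a dense neural-network
baseline, and the spectral-matching inversion baseline.

## Worked example

```python
import wirdrs as w

# 1520 synthetic spectra on a 40 x 38 label grid:
# mu_a 0.44-2.45 cm^-1, mu_s' 6.53-9.58 cm^-1
base = w.generate_grid_dataset()

# corrupt with every use-error compounded (noise SNR 45:1, -4.8 nm shift,
# 1 nm/tail compression, +/-5% tilt, +/-5% systematic scale)
corrupted = w.make_condition_dataset(base, "all", seed=42)

# fivefold cross-validation of the WIR model on the corrupted spectra
report = w.kfold_cv(corrupted, k=5, seed=0)
print(report.rmse)
```

prints (RMSE% = root-mean-square relative error × 100):

```
  condition model      target   group  rmse_percent
0       all   wir        mu_a  pooled      4.439702
1       all   wir  mu_s_prime  pooled      2.516708
```

i.e. with every use-error compounded the regressor still recovers μa to ~4.6%
and μs′ to ~2.5%, while the spectral-matching baseline on the same spectra
(`SpectralMatchingInverter`) degrades to ~59% for μa and ~11% for μs′ — an
order of magnitude worse. On noiseless data the inversion baseline is
essentially exact (RMSE% below 0.01) — a self-consistency check of the
forward/inverse pair.

A command-line interface mirrors the library
(`wirdrs simulate|corrupt|augment|preprocess|extract|train|evaluate|
robustness|make-fixtures`); see `wirdrs --help`.

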
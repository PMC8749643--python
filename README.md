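# oxispec

Multi-wavelength spectral SpO₂ measurement as a tested, reproducible
pipeline: a physics-grounded simulator of finger-transmission spectra, the
normalization/noise-augmentation preprocessing, a 1-D convolutional
classifier with expectation decoding, grid and Bayesian hyperparameter
search, the classical dual-wavelength ratio-of-ratios baseline, and a
region × noise evaluation harness with time-series filtering.

## The problem

Conventional pulse oximetry estimates arterial oxygen saturation from two
wavelengths (red ≈ 660 nm, NIR ≈ 940 nm) via the ratio of ratios

    Q = ln(1 − AC₁/DC₁) / ln(1 − AC₂/DC₂)  ≈  (AC₁/DC₁) / (AC₂/DC₂),

where DC is the quasi-static transmitted intensity and AC the pulsatile
component, followed by an empirical calibration SpO₂ = b − a·Q. Two
wavelengths limit the extractable information and the approximation itself
introduces error. A 12-channel spectral sensor bank (centers 450–860 nm)
offers more features — but no closed formula maps many wavelengths to SpO₂,
which motivates learning the map instead.

`oxispec` implements that approach end to end for anyone studying
multi-wavelength oximetry algorithms without access to a hardware rig:

1. **Simulate** labeled transmission spectra with the Beer–Lambert law,
   I(λ) = I₀·10^(−A(λ)), A(λ) = d·c_Hb·[s·ε_HbO₂(λ) + (1−s)·ε_Hb(λ)] +
   A_tissue(λ), band-integrated over each sensor channel's Gaussian FWHM,
   quantized to a 16-bit ADC.
2. **Preprocess**: per-curve min–max normalization to [0, 1], spectral
   region selection (the visible "first region" 450–610 nm, the NIR
   "second region" 650–860 nm, the full bank, and their 3-channel
   sub-regions), and expansion of each concentration's curve to 1000 rows
   by multiplicative uniform noise at {0, 1, 2, 5, 10} %.
3. **Classify** with a 1-D CNN (conv–conv–pool twice, dense ReLU stack with
   dropout, 10-way softmax over labels 81, 83, …, 99 %) and decode the
   softmax output to a scalar: **SpO₂ = Σᵢ Lᵢ·Wᵢ**, the expectation of the
   labels under the predicted class weights.
4. **Optimize** hyperparameters by exhaustive grid with stratified k-fold
   cross-validation or by Gaussian-process Bayesian optimization with
   expected improvement, optionally coarse-then-fine.
5. **Evaluate**: argmax and ±1 %-tolerance accuracy, per-concentration
   deviation tables, calibration regression (slope, R²), and the
   region × noise ablation grid; plus median/moving-average filtering for
   dynamic (streaming) estimation.

The network is implemented directly on numpy (im2col convolutions, explicit
backpropagation, Adam) — sizes are tiny, so training is seconds-fast and
bit-reproducible under a seed.

## Worked example

```python
import numpy as np
from oxispec import simulator as sim, preprocess as pp, model as M, evaluate as ev

# independent training and verification sessions, NIR region, 2 % noise
train_ds, test_ds = ev.train_test_datasets(pp.REGIONS["SECOND"], 0.02, 0.02, seed=42)

mcfg = M.best_reported_config(epochs=300, seed=42)   # filters 10/16, kernel 6, ...
tm = M.train(M.build_model(mcfg, 6, 10), train_ds, mcfg)

print("argmax accuracy:", round(ev.accuracy(tm, test_ds), 3))
decoded = M.decode_batch(tm, test_ds.X)
rep = ev.deviation_report(decoded, test_ds.y)
print("total relative error: %.2f%%" % rep.total_relative_error)
w = M.predict_weights(tm, test_ds.X[0])
print("true %.0f -> decoded %.2f" % (test_ds.y[0], M.decode_spo2(w)))
```

prints

```
argmax accuracy: 0.998
total relative error: 0.05%
true 91 -> decoded 91.00
```

The accuracy is the fraction of verification rows whose argmax class equals
the true concentration; the total relative error is the mean of
|decoded − truth|/truth over all rows, in percent; the last line shows one
spectrum's softmax distribution collapsed to a scalar estimate by
expectation decoding.

A command-line surface wraps the same pipeline:

```bash
oxispec simulate --labels 81:99:2 --n 1 --seed 7 -o frames.csv
oxispec build-dataset --frames frames.csv --region SECOND --noise 0.02 --rows 1000 -o ds.csv
oxispec train --dataset ds.csv --epochs 100 -o model_dir
oxispec evaluate --model model_dir --dataset ds.csv
oxispec baseline fit --frames frames.csv -o cal.json
```

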
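# Methods

## The measurement model

`oxispec` treats transmission pulse oximetry as a forward optical model
plus a learned inverse. The forward model (module `simulator`) composes:

* **Beer–Lambert attenuation.** For arterial saturation s = SpO₂/100, the
  blood optical density at wavelength λ is
  d · c_Hb · [s·ε_HbO₂(λ) + (1−s)·ε_Hb(λ)], with d the effective optical
  path through blood (cm), c_Hb total hemoglobin (mmol/L), and ε the molar
  extinction coefficients (L·mmol⁻¹·cm⁻¹). The ε values at the 12 channel
  centers are transcribed from the standard published compilation of
  hemoglobin extinction spectra into `data/chromophores.csv`; the simulator
  treats them as input data and interpolates linearly across each channel
  band. The arterial and venous compartments are not distinguished: one
  saturation parameterizes the whole blood path.
* **A bloodless-tissue baseline.** A single decaying exponential in
  wavelength, A_tissue(λ) = 3.0·exp(−(λ−450)/100 nm). This stands in for
  scattering plus non-heme absorption; its magnitude is set so that the
  per-curve-normalized visible-region (450–610 nm) spectra nearly coincide
  across saturations while the NIR region (650–860 nm) separates — the
  qualitative structure of measured finger spectra, where blue/green light
  is strongly attenuated before reaching the detector.
* **Band integration.** Each sensor channel is a Gaussian band (σ =
  FWHM/2.355, truncated at ±2·FWHM, weights normalized to 1). The visible
  sensor's channels (450–600 nm and 650 nm) carry FWHM 40 nm; the NIR
  sensor's (610 nm and 680–860 nm) carry 20 nm. The wide visible bands
  genuinely flatten the saturation contrast there because they integrate
  across the steep 570–600 nm extinction edge.
* **AC/DC decomposition.** DC is the diastolic transmitted intensity; AC is
  the intensity drop when the arterial path lengthens by
  `pulsatile_fraction` of the baseline blood path at systole. With the
  default fraction 0.02 the red/NIR channels sit in the small-signal regime
  (AC/DC ≈ 0.01–0.03) where the first-order ratio-of-ratios formula
  applies. Strongly absorbed blue/green channels are *not* small-signal —
  as in real tissue — and often quantize to zero counts (flagged per
  channel).
* **Quantization and noise.** Intensities are quantized round-half-even to
  the 16-bit ADC range after adding Gaussian sensor read noise
  (`read_noise_counts`, default 80 counts RMS ≈ 0.3–3 % of the NIR signal),
  which models session-to-session lamp/sensor variation. Underflow and
  saturation are flagged rather than raised.

Default physical parameters, with rationale:

| parameter | default | meaning / why |
|---|---|---|
| `path_length_cm` | 0.2 | effective optical path through blood (geometric path × vascular volume fraction of transilluminated pulp); chosen so normalized NIR curves separate by saturation with the spread seen in measured finger spectra |
| `hb_total` | 2.3 mmol/L | ≈150 g/L hemoglobin, normal adult |
| `pulsatile_fraction` | 0.02 | systolic arterial path increase; gives perfusion-index-scale AC/DC |
| `tissue_od` | 3.0·e^(−(λ−450)/100) | see above |
| `source_intensity` | 60 000 counts | mid-range of the 16-bit ADC |
| `read_noise_counts` | 80 | session-level sensor/illumination variation |

**What the generator emulates and what it does not.** It reproduces the
spectral *structure* that makes the region comparison meaningful:
label-indistinguishable visible curves, label-separated NIR curves, ADC
quantization, and independent measurement sessions. It does not model
photon transport, skin layering, motion artifacts, perfusion changes,
subject-to-subject anatomy, or additional chromophores. Passing tests
therefore demonstrate that the pipeline recovers saturation under the
stated optical model — not clinical performance on human data.

## Preprocessing

Each curve is min–max normalized over its own channels (after region
selection), so every curve spans [0, 1]; a constant curve maps to zeros
with a warning rather than an error so batch runs survive degenerate
frames. Augmentation multiplies each normalized entry by (1 + u), u ~
Uniform(−r, +r) independently per entry, then clips to [0, 1]; r ∈
[0, 0.10] is the studied range. Noise is injected after normalization,
multiplicatively: this keeps the zero-intensity anchor fixed and the
normalized range intact. The training table holds one representative curve
per concentration (81, 83, …, 99 %), each expanded to `n_rows_per_label`
rows (1000 at full scale) and shuffled under a named seed. The DC
intensities feed the classifier; the AC/DC decomposition is consumed only
by the ratio-of-ratios baseline.

## The classifier

Two blocks of (conv–conv–maxpool) with ReLU, a flatten, `n_dense_layers`
fully connected ReLU layers with inverted dropout, and a softmax over the
10 labels, trained with categorical cross-entropy and Adam. Choices the
architecture description leaves open were resolved as follows:

* **Padding**: length-preserving ("same") convolutions — valid padding
  would annihilate a 6-sample input under kernel ≥ 4 plus two pools.
* **Pooling**: max, window 2 — the smallest standard choice compatible
  with 6- and 12-sample inputs. A 3-channel sub-region survives only one
  pool, so `n_blocks=1` must be requested there; building a two-block net
  on 3 inputs raises with that advice.
* **Kernel clamp**: kernels longer than the input (the search space allows
  32 against 6 channels) are clamped to the input length with a warning.
* **Optimizer**: Adam at the configured learning rate; the best-found
  configuration (`best_reported_config()`: filters 10/16, 3 dense layers of
  40 nodes, kernel 6, dropout 0.37, batch 85) uses learning rate 9×10⁻⁴,
  the value the one-axis-at-a-time sensitivity analysis identifies as best;
  rates ≳10⁻² destabilize cross-entropy training of this net.
* **"Accuracy"** means argmax classification accuracy against the 10-label
  grid. The scalar estimate SpO₂ = Σ Lᵢ·Wᵢ (expectation decoding) feeds the
  deviation and calibration metrics, and a ±1 %-tolerance accuracy of the
  decoded value is reported alongside. Decoded output is always inside
  [81, 99] because it is a convex combination of the labels.
* **Determinism**: pure-numpy arithmetic; parameter init, dropout masks and
  batch shuffling all derive from the config seed, so runs are
  bit-reproducible.

## Hyperparameter search

Grid mode reproduces the published value lists; interval mode the
published bounds (learning rate on a log scale). Cross-validation is
stratified k-fold with k = 5 by default (the fold count is not otherwise
specified). The full grid product space exceeds 10⁶ points and is refused
above a configurable cap (default 256): callers pin all but a few axes,
mirroring one-axis-at-a-time practice. Bayesian optimization uses a
Matern(5/2) Gaussian process with a small white-noise term on the
unit-scaled space and expected improvement (ξ = 10⁻³) over 512 random
candidates per step, with 5 space-filling initial trials; integers are
proposed by rounding. Any improvement-based surrogate satisfies the search
contract; this one is chosen for determinism under seed and zero extra
dependencies. Coarse-then-fine shrinks each interval to `stage2_shrink`
of its width around the stage-1 best and pools the trials, so the final
best can only improve on stage 1.

## Evaluation harness

Training and verification datasets come from *independent simulated
sessions* (separate read-noise realizations of the per-label frames), the
analogue of building separate training and verification measurement sets;
a stratified 80/20 split of a single dataset is also provided
(`split_dataset`) for within-dataset checks. Deviation tables use the
population standard deviation by default (a `std="sample"` flag switches);
the total relative error is the mean absolute relative error in percent
over all rows. The ablation grid derives each cell's seed deterministically
from the base seed and cell index and records per-cell failures without
aborting the grid.

## Streaming

Per-frame normalize → predict → decode, then a median filter and a trailing
moving average, in that order (median first, to remove isolated spikes
before averaging). Windows default to 5 and 5; edges are handled by window
truncation (the median window shrinks symmetrically so it stays odd), which
keeps the filter causal enough for a live display and never produces values
outside the raw range. The sampling interval defaults to 0.7 s, the
sensor's integration-plus-compute cadence.

## Study sizes

The test suite and the acceptance script run a scaled-down version of the
full study: 200 training and 50 verification rows per concentration
(vs. 1000 at full scale), 30-epoch training for the five-noise-ratio region
sweep, and 300-epoch training (within the searched 10–500 range) where a
converged model is the object under study — the augmentation-benefit
comparison and the deviation/calibration summaries, which are properties of
converged models. These sizes are the package's own defaults for a
desk-scale study; the full-scale values remain available through the same
interfaces.

## Known limitations

* The simulator's saturation contrast is set by `path_length_cm`; very
  different values change class separability and hence absolute accuracies
  (directional findings — NIR ≥ visible, augmentation helps under session
  noise — are robust across seeds).
* The 0 %-noise condition produces 1000 identical rows per class by
  construction; models trained on it converge trivially and their
  verification accuracy depends entirely on session-to-session variation.
* The chromophore fixture carries values only at the 12 channel centers;
  band integration interpolates linearly between them, which smooths the
  true extinction fine structure.
* No attempt is made to reproduce absolute accuracies measured on human
  breath-hold data; the harness reproduces structural and directional
  findings on synthetic spectra only.
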
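# Methods

## Measurement model

An AChE-coated ISFET reports a differential gate–source response
ΔV<sub>gs</sub> (mV): the difference between a baseline read in PBS buffer
and a read in acetylcholine-chloride substrate. Without inhibitor this
*reference* response is Normal(μ(T), σ²) with μ(25 °C) = 45.35 mV and
σ = 1.6 mV. Carbaryl inhibits the enzyme; the inhibited response is

  ΔV<sub>gs</sub><sup>carbaryl</sup> = ΔV<sub>gs</sub><sup>w/o</sup> · (1 − I/100),

where the percent inhibition follows the empirical log-linear law
I = 6.6098 ln(c) + 134.62 at 25 °C (c in molar), clamped to [0, 100].
Inverting the inhibition equation gives the 0.45 mV-per-percent
equivalence used by the matrix correction (45.35/100 = 0.4535 ≈ 0.45,
consistent within 2 %).

## Simulator (`enzisfet.simulate`)

The generator reproduces the printed empirical relations only; it contains
no device physics (no site-binding model, no drain-current curves). All
constants live in `SimParams`; the defaults are:

| parameter | default | unit | provenance |
|---|---|---|---|
| ph_slope / ph_intercept | 49.86 / 418.98 | mV/pH, mV | measured pH line |
| ref_mean_25c / ref_sd | 45.35 / 1.6 | mV | measured reference |
| inhib_slope / inhib_intercept | 6.6098 / 134.62 | %/ln(M), % | measured inhibition line |
| matrix_offset_range | (2.68, 3.24) | % | extract-vs-buffer gap |
| mv_per_percent | 0.45 | mV/% | inhibition-equation inverse |
| ref_temp_coeff | 0.3 | mV/°C | stand-in (effect shown, value unpublished) |
| inhib_temp_coeff | 0.4 | %/°C | stand-in (same) |
| signal_noise_sd / temp_noise_sd | 0.2 / 0.1 | mV / °C | stand-in noise scale |

The two temperature coefficients and the noise SDs are documented
stand-ins: the underlying experiments demonstrate the effects but publish
no numbers. The pipeline works for any values, including 0. The inhibition
line is extrapolated (then clamped) outside its calibrated 10⁻⁶–10⁻⁴ M
range so the 10⁻⁷ and 10⁻³ M campaign levels can be generated. The extract
matrix offset is drawn uniformly per reading from its range and subtracted
from inhibition *before* the [0, 100] clamp. A campaign row's recorded
temperature is the nominal set point plus `temp_noise_sd` jitter, and the
signal responds to that actual temperature (the thermistor is treated as
exact). Everything stochastic flows through one `numpy.random.Generator`,
so datasets are bit-reproducible from `(SimParams, seed)`.

What the simulator deliberately does *not* emulate: sensor ageing and
day-scale drift, interfering compounds (chlorpyrifos also inhibits AChE),
pH/ionic-strength effects of real matrices, and autocorrelated drift noise
(all noise is i.i.d. Gaussian). Passing tests therefore demonstrate that
the algorithms recover what this noise model can hide — not field
performance on real produce.

## Preprocessing (`enzisfet.preprocess`)

Min–max normalization maps every feature and target column to [0, 1];
parameters are fitted on the training split and applied unchanged to the
test split (the split-local variant is retained behind
`refit_norm_on_test` purely for protocol reproduction, since it leaks
split information). The regression target is log₁₀(c): the assay spans
four decades and raw molarity would collapse four of the five calibration
levels into the bottom 0.1 % of the unit interval; a `raw` mode exists for
comparison. AWGN augmentation replicates each row `factor` times with
independent zero-mean Gaussian noise on the signal and temperature
features, leaving targets untouched. Augmentation happens *before* the
stratified 80/20 split, matching the protocol's ordering; note that noisy
siblings of a training row can land in the test split, which flatters test
metrics relative to a row-group-disjoint split.

## Networks and training (`enzisfet.nn`)

Plain feed-forward networks: affine layers, tanh on hidden layers, ReLU on
the scalar output (the normalized target is non-negative). Loss is the MSE;
optimization is full-batch gradient descent with exact backpropagated
gradients (d tanh/dz = 1 − tanh² z; the ReLU subgradient at exactly 0 is
taken as 0). No momentum, adaptivity, regularization or mini-batching —
the training procedure itself is deliberately the plain algorithm. The two
deployed presets are 2–20–16–1 (α = 0.01, ≤ 5000 epochs) and 1–10–5–1
(α = 0.01, ≤ 3000 epochs, stop at training MSE 0.01).

Numerical choices:

* **Initialization** is uniform(−0.5, 0.5) · `init_scale`, seeded. A ReLU
  output unit whose pre-activation is negative on *every* row has an
  exactly-zero gradient and can never recover under full-batch descent;
  about 29 % of raw draws start in that state. `train()` therefore redraws
  the initialization from the same seeded stream until the output unit
  fires on at least one training row — deterministic given the seed.
* **Stopping**: "divergence" between train and test loss is
  operationalized as `patience` (default 20) consecutive epochs of rising
  test MSE; an optional training-MSE threshold stops early; otherwise the
  epoch cap. The parameters with the lowest recorded test MSE are
  returned, not the last epoch's.
* A non-finite loss aborts with an error advising a smaller learning rate.
* Model files are JSON (layer sizes, row-major weight/bias arrays, the
  min–max parameters and target-transform tag, training metadata), so a
  saved model reproduces forward outputs bit-identically and prediction
  needs no training-time state.

## Signal compensation (`enzisfet.compensation`)

Enzyme loading varies sensor-to-sensor, shifting the whole response curve.
The reference model (1–10–5–1) learns μ(T) from population blank reads;
a fresh sensor's *calibration voltage* is the mean of
(measured blank − predicted reference) over its blank reads (default 3,
the triplicate protocol), interpreted as an additive offset — all
compensations in this scheme are expressed in mV, so a difference rather
than a ratio. Compensation subtracts it from every reading. For
vegetable-extract samples the inhibition deficit (2.68–3.24 % lower than
buffer) makes the signal read *high*; the matrix correction
(gap × 0.45 mV/%, i.e. 1.206–1.458 mV; range midpoint 1.332 mV when the
gap is unknown) is stored as a non-negative magnitude and likewise
subtracted, so a corrected extract reading matches the buffer reading that
encodes the same inhibition. Temperature is always a measured input, never
inferred from the signal.

When blank reads are exactly constant (no drift, no noise) the target
column of the reference fit is degenerate under min–max normalization;
`fit_reference_model` pads that one column's range by ±1 mV so the
constant-reference case trains cleanly.

The reference-model training set defaults to 4 temperatures × 50 blank
replicates = 200 base reads, augmented ×10 to 2000 rows — the same dataset
size as the concentration model, which is the one constraint the protocol
states for it.

## Evaluation metrics (`enzisfet.metrics`)

MSE and MAE are computed on the normalized target scale and additionally
reported ×100 as percentages (the convention the headline figures use);
the results object also reports them in log₁₀-molar units (decades), which
is the physically interpretable scale. R² is the literal variance-ratio
form (Var(y) − MSE)/Var(y) with population variance; it can be negative
and is reported unclamped with a warning. The 3σ LOD criterion is the
exact arithmetic 3·SD + min-carbaryl-signal < reference; with the printed
inputs (1.6, 28.78, 45.35 mV) this gives 33.58 mV, whereas 33.50 mV has
also circulated for the same inputs — the package reports the exact
arithmetic. Conversion of the 10⁻⁷ M LOD to ~0.02 ppm uses carbaryl's
molar mass 201.22 g/mol, an external physical constant.

## Problem sizes and known limitations

The default campaign (200 → 2000 rows, 5000 epochs full-batch) trains in
roughly 10 s on one CPU; the test suite's convergence fixtures use a
smaller 60-row noiseless campaign trained longer (α = 0.05, 20 000
epochs), which recovers all five calibration concentrations within 10 %
and is the basis of the compensation-invariance checks.

On the default noisy campaign the held-out metrics are R² ≈ 0.994,
normalized MSE ≈ 0.06 % and MAE ≈ 1.7–2 %. The per-reading reference draw
(σ = 1.6 mV) and the 0.2 mV noise floor put an irreducible conditional
spread of roughly 0.03–0.17 decades on any regressor's predictions, which
is what those MSE/MAE values reflect; note also that an R² of 0.992 on
this five-level design already corresponds to a normalized MSE of about
0.1 %, so headline triples quoting far smaller MSE/MAE alongside R² ≈ 0.99
are not mutually consistent on any single scale. The package reports all
three metrics as computed, on both scales, and leaves the interpretation
explicit rather than tuning the noise model to meet any one of them.
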
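# Methods

This note documents the models, the synthetic-data design, the numerical
conventions, and the open design choices made in this package, in enough
detail to reproduce or challenge any of them.

## The measurement model

An intact fruit excited by a short air pulse behaves, to first order, as a
set of damped harmonic oscillators.  The simulator writes the post-onset
surface velocity as

    v(t) = r(t) · Σ_k A_k · exp(−2π f_k ζ_k t) · sin(2π f_k √(1−ζ_k²) t)
           + b(t) + n(t)

where `f_k` are modal frequencies, `ζ_k` damping ratios (default 0.012),
`A_k` modal amplitudes, `r(t) = 1 − exp(−t/τ)` a rise envelope (τ = 4 ms)
standing in for the finite excitation pulse, `b(t)` a stationary
band-limited stochastic component, and `n(t)` white sensor noise
(sd 0.05, arbitrary velocity units — the LDV's absolute scale is irrelevant
because spectra are later standardized per bin).

Modal frequencies are affine in firmness F within a cultivar:
`f_k(F) = f_k(mean) + slope_k · (F − mean)`.  The three default profiles
anchor (f1, f2) at (841.7, 1293.2), (900.3, 1401.9) and (665.7, 1403.8) Hz
at cultivar mean firmness 2.01, 4.63 and 6.07 N/mm, with slopes
(+5, +6), (+5, +6) and (−4, +5) Hz/(N/mm).  The negative f1 slope of the
firmest profile makes the pooled f1–firmness relation non-monotonic — the
firmest cultivar has the *lowest* first resonance — while within-cultivar
relations stay positive.  This is the structure that defeats
resonance-only prediction across cultivars and motivates full-spectrum
calibration.

The band-limited component is white noise shaped by a Butterworth band-pass
(order-2 design, 2900–3100 Hz) and scaled so its variance is
`highband_slope · F` (an increasing affine function of firmness; slope
5·10⁻³).  A steep band-pass is used rather than a single resonator biquad
because a resonator's shallow skirts smear the injected power — and with it
the firmness information — across the whole upper spectrum and the AR noise
floor, making "where the information lives" ill-defined.

### Biological scatter (what the generator does and does not emulate)

Real fruit of equal firmness differ in size, shape, density and internal
structure.  The dataset simulator therefore draws, per fruit (shared by its
three replicate excitations):

| source of scatter              | distribution            | default |
|--------------------------------|-------------------------|---------|
| firmness                       | truncated normal, sd = range/4, clipped to the cultivar range | per profile |
| mass                           | uniform                 | 0.15–0.30 kg |
| resonance-frequency offsets    | normal, per mode        | sd 30 Hz |
| modal-amplitude factors        | lognormal, per mode     | σ 0.25 |
| high-band power factor         | lognormal               | σ 0.25 |
| sensor-noise level factor      | lognormal               | σ 0.3 |
| replicate amplitude jitter     | normal around 1, clipped| sd 0.05 |

The consequences, measured on the default 471-fruit dataset (seed 7):
peak *position* is an informative but imperfect firmness proxy (30 Hz
scatter against a ±10–25 Hz slope effect), peak *amplitude* is essentially
uninformative, and the high band is the strongest single cue — the per-bin
PSD–firmness correlation is ≈ +0.84 near 3 kHz versus ≈ +0.08 around
1 kHz, reproducing the characteristic correlation profile of this kind of
data.  Under these conditions PLSR reaches test R² ≈ 0.63 and the CNN
≈ 0.81, i.e. the linear-vs-nonlinear separation the method exists to
demonstrate.  Ablating the 2.8–3.2 kHz input region collapses the CNN to
R² ≈ 0.4, confirming the band, not the resonances, carries most of the
within-cultivar information.

What the generator does **not** emulate: real spectra contain more than two
modes, mode coupling, shape-dependent mode splitting, drift between
replicate excitations, and day/storage effects; the firmness–band-power
link is a modelling device (tissue elasticity raising high-frequency
transmissibility), not a measured law.  Passing tests on this generator
therefore demonstrate that the *pipeline* recovers the structure it was
told to expect — not that the same accuracies would hold on orchard fruit.

Reference firmness comes from toy puncture curves: exactly linear at slope
F (N/mm) up to a 4 mm yield depth, then a smooth exponential approach to a
plateau; the reference value is the mean least-squares slope over the first
2 mm of three curves (the fit depth is configurable; the choice only
matters once noise is added, since the region is linear by construction).

## Spectral stage

Burg's recursion estimates AR coefficients in the convention
`x[n] + Σ a_k x[n−k] = e[n]`; reflection coefficients are clipped to
[−1, 1], so the model is minimum-phase by construction, and the innovation
variance is the final forward/backward prediction-error power.  The PSD is
evaluated one-sided, `P(f) = (2σ²/fs)/|A(e^{−i2πf/fs})|²`, on the inclusive
uniform grid `linspace(0, 5000, 2623)` — the only uniform convention with
exactly 2623 points on 0–5000 Hz (step ≈ 1.907 Hz).  At the full 312.5 kHz
rate the order is 400; all desk-scale runs here use a reduced-rate mode
(12.5 kHz, order 50) that preserves the entire 0–5 kHz analysis band while
cutting the Burg cost by three orders of magnitude.  Resonance recovery at
the reduced rate is within ~1 Hz of the profile anchors, far inside the
10 Hz acceptance window.

Onset detection (first index where |x| exceeds k·sd of the leading noise
window for m consecutive samples; k = 5, m = 10, window 0.5 s) is defined
in samples: at 312.5 kHz the m-run spans 32 µs, at 12.5 kHz it spans
0.8 ms — longer than a half-period of the first mode — so reduced-rate
users should scale m or rely on the simulator's stored ground-truth onset,
which the dataset builder does.

Degenerate-variance rules: a PSD bin whose training variance (or a
correlation bin whose power variance) is zero up to floating-point residue
(relative tolerance 10⁻¹²/10⁻¹⁰) is flagged; standardization maps it to
exactly 0 and correlation reports r = 0.

## Dataset assembly

Replicates are aggregated by pointwise mean PSD (a median mode exists
behind a flag).  Splits are stratified by cultivar; partition sizes follow
largest-remainder rounding of the ratios over the full sample count
(471 at 7:1:2 → 330/47/94; 120 at 4:1 → 96/24), and per-stratum allocations
are reconciled to those totals by a deterministic greedy pass.
Standardization (per-bin mean/sd) is fitted on the training partition only.
The linear and kernel baselines consume the standardized raw PSD; the CNN
consumes standardized log10 PSD (PSD dynamic range spans orders of
magnitude; a raw mode exists behind a flag).

## Baselines

PLSR is single-response NIPALS; the latent-variable count minimizes
validation RMSE over 1…60 (ties to the smaller count).  The kernel baseline
projects onto the smallest PCA basis exceeding 95% cumulative explained
variance (training mean centring) and fits ε-insensitive SVR; kernel
(linear/polynomial/gaussian/sigmoid), box constraint C (log-uniform
10⁻³…10³) and ε (log-uniform 10⁻³…1) are tuned by expected improvement
under a Matern-5/2 Gaussian-process surrogate with seeded initialization
(a plain seeded random search is available).  libsvm iterations are capped
at 2·10⁵ per fit: on nearly separable data at large C the solver otherwise
stalls for minutes inside the search; the cap only affects configurations
the search is about to discard.

## ISNet-1D

Architecture (input length 2623): conv(16, k3, same) → batch norm → ReLU →
max-pool(2,2) → Inception with four branches (1×1; 1×1→k3; 1×1→k5;
max-pool(3, stride 1, same)→1×1; 16 filters each, ReLU after every
convolution, depth-concatenated to 64 channels) → squeeze-and-excitation
gate (global average pool, two 1×1 convolutions with reduction 4, ReLU then
sigmoid) → conv(32, k5, same) → ReLU → max-pool(2,2) → dense(64) → ReLU →
dropout 0.3 → dense(1).  1 357 233 trainable parameters under the default
configuration (verified against an independent per-layer hand count).

Training: Adam, batch 16, initial rate 10⁻⁴ decayed ×0.1 every 50 epochs,
loss `MSE + (λ/2)‖ω‖²` with λ = 10⁻⁴ applied to convolution and dense
weights only (not biases or batch-norm parameters), early stopping on
validation loss (patience 30 by default), weights restored from the
best-validation epoch.  The output bias is initialized to the training-set
mean firmness — a standard regression-net choice; at a 10⁻⁴ Adam step the
bias would otherwise consume most of the epoch budget just reaching the
response's scale.  Desk-scale runs train for up to 60–80 epochs with
patience 15; on the default synthetic dataset validation loss typically
bottoms out between epochs 5 and 35.

Everything is implemented in NumPy with explicit backward passes (verified
against central-difference gradients to ~10⁻⁶ relative error on a float64
configuration).  Parameters are float32 for training throughput;
`predict` evaluates in float64, making a sample's prediction identical
alone or in any batch to well below 10⁻⁶.  Batch norm uses batch statistics
in training and running statistics (momentum 0.1, eps 10⁻⁵) in evaluation;
a layer's statistics can be pinned, which the transfer stage uses.
Training is bit-reproducible for a fixed seed: seeded He initialization,
seeded shuffling and dropout, deterministic kernels.

## Grad-CAM for 1-D regression

Saliency is computed at the final convolutional layer (conv 32, k5),
upsampled linearly to the 2623-bin input grid and min-max normalized per
map (an all-constant map returns zeros with a degenerate flag).  Two
choices deliberately differ from the classification-style recipe:

* **Position-wise weighting.**  The classic form averages each channel's
  gradient over position into a single weight.  On this shallow 1-D network
  that projection produces a near-uniform pedestal (channels respond
  everywhere, and one global weight per channel cannot localize evidence).
  The default instead multiplies gradients and activations
  position-by-position and sums over channels — each position's first-order
  contribution to the prediction, as in HiResCAM.  The spatially-averaged
  convention is available as `weighting='average'`.
* **Absolute value instead of rectification.**  Classification Grad-CAM
  keeps only evidence *for* the class.  For a signed regression output,
  evidence that pulls the prediction down (a soft fruit's weak high band)
  is exactly as relevant as evidence that pushes it up, so the default maps
  the magnitude of the contribution; `mode='relu'` restores the one-sided
  convention.

A known limitation, measured on the default dataset: the mean saliency in
the injected 3 kHz band exceeds the spectrum-wide mean for about 65–75% of
test fruit, not more.  The misses are systematic, not noise — for fruit
whose band power sits near the training mean, or whose cultivar identity
(read from the resonance region) already pins the prediction, the band's
first-order contribution is genuinely small, and the saliency map honestly
says so.  Per-sample saliency reflects per-sample reliance, not the
population-level importance of a region.

## Transfer learning

`fine_tune` freezes the stem convolution + batch norm, the Inception
branches and the SE gate (bit-identical before/after, enforced); the final
convolution trains at 0.1× the base rate; the two dense layers train at the
full rate.  The new-cultivar data are standardized with the *original*
training standardizer (the network's input convention must not change) and
split 4:1 train/validation (largest remainder, seeded shuffle).  Fine-tuning
runs up to 100 epochs with the inherited schedule and early stopping.  The
bundled "new cultivar" profile models a soft early-season white peach
(mean 1.79 N/mm, range 0.45–4.47) with resonance anchors and slopes unlike
any training cultivar; the pretrained network extrapolates poorly to it
(validation R² strongly negative), and fine-tuning recovers R² ≈ 0.7–0.8.

## Evaluation conventions

RMSE divides by n; R² uses the measured-value mean; RPD = SD/RMSE with the
*sample* SD (n−1).  With the population SD the identity
`RPD = 1/√(1−R²)` holds exactly on a common partition, which the tests
assert; reported RPDs use the sample convention.  Relative model changes
are `(candidate − baseline)/baseline × 100`, rounded to two decimals;
metric tables round half-even to four decimals.  All pipeline randomness
descends from a single root seed via spawned seed sequences.

## Known limitations

* The generator's high-band correlation with firmness (~0.85) is stronger
  than the ~0.55 a real correlation profile peaks at; with a weaker band no
  model can rely on it, and the package's saliency and ablation analyses
  would be vacuous.  Absolute accuracies on synthetic data are therefore
  not comparable to accuracies on real fruit.
* The CNN is trained at desk scale (reduced-rate spectra, ≤ 80 epochs);
  the published-scale schedule (order-400 AR at 312.5 kHz, 300 epochs) is
  supported but not exercised by the test suite.
* Grad-CAM band-saliency coverage is ~65–75% of test samples, for the
  structural reason above.
* The Bayesian search optimizes validation RMSE only; no nested
  cross-validation.
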
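# Methods

## The model

`alloego` implements a physiologically constrained feed-forward network
that learns to aim gaze at a remembered target in the presence of a
visual landmark that may shift between target presentation and movement.
The pipeline is

    stimulus images ──> Gabor-energy CNN ──┐
                                           ├──> sigmoid MLP ──> cosine-tuned
    initial gaze ──> eye-position code ────┘      motor population
                                                       │
                                        fixed OLE decoder ──> saccade vector

Each trial supplies two binary raster images: an *encoding* image
(crossing-lines landmark plus a 6×6 px target square) and a *decoding*
image (landmark only, possibly displaced by a shift vector **s**).  Both
are translated into retinal coordinates by subtracting the initial gaze.
The network is trained end-to-end by minimising the mean squared error
between the decoded saccade vector and the true gaze displacement; only
the convolutional feature-pooling weights (16 scalars) and the MLP
weights are learned — the Gabor filters, the eye-position code and the
read-out decoder are fixed analytically.

### Visual front-end

Two repeated-filtering layers, each convolution → rectification →
normalization → pooling:

* **Convolution.** A quadrature pair (cosine/sine phase) of 7×7 Gabor
  filters at 4 orientations {0°, 45°, 90°, 135°}, σ = 1 px, aspect ratio
  γ = 2, phase ψ = 0, zero-padded "same" convolution.  The carrier
  wavelength is 2 px (0.5 cycles/px, the Nyquist band).  A sub-pixel
  carrier wavelength would alias to DC on the integer raster, turning the
  axis-aligned filters into pure low-pass Gaussians; at 2 px the filters
  are oriented band-pass units, which gives the two properties the
  architecture is built around: separation of the horizontal and vertical
  lines across orientation channels, and decay of total energy from
  layer to layer.
* **Rectification.** Complex-cell energy E = √(C_cos² + C_sin²).
* **Normalization.** Divisive across the 4 orientations at each pixel
  (a partition of unity where defined).  Pixels whose summed energy falls
  below ε = 10⁻⁴ output zero; the floor sits above the float32 FFT noise
  floor (~10⁻⁶) so empty image regions stay genuinely silent.
* **Pooling.** Separable binomial low-pass [1, 2, 1]/4 (edge-replicated,
  so constants survive) followed by stride-2 decimation.

Layer 2 treats each of the four layer-1 channels as a new input image,
yielding 16 doubly filtered channels (VV, VH, …).  A **feature-pooling**
stage collapses these to one map per image, F = Σᵢ wᵢ Sᵢ, with the 16
weights fit by least squares against the pixel-wise product of all 16
channels (normalized to max 1 per image) — the product is large only
where every orientation is active, i.e. at the line crossing and the
target.  The pooled map is flattened row-major; encoding and decoding
features are concatenated.

### Input and output codes

* **Eye position** (44 units): Gaussian receptive fields (σ = 10°),
  centres uniform in ±15°, with amplitude gain-modulated by gaze
  eccentricity: aᵢ = (bᵢ + αᵢ‖g‖)·exp(−‖g − cᵢ‖²/2σ²), bᵢ ~ U(0, 1),
  αᵢ ~ U(0, 0.05/deg).  A pure-linear variant (no Gaussian) is exposed.
  Under the noisy training condition the rates are Poisson-sampled
  (50 counts per rate unit).
* **Motor population** (250 units): preferred directions evenly spaced
  over 360°; quarter-cosine tuning a = 0.5 + (0.5‖M‖/M_max)·cos θ for
  θ ≤ 90°, clamped at the 0.5 baseline beyond, M_max = 150.  Activities
  therefore live in [0.5, 1].
* **Read-out**: an optimal linear estimator W = Q⁻¹C with
  Q = σ_n²I + ∫ a aᵀ dM and C = ∫ M a(M) dM integrated on a 64 × 128
  polar grid over the movement disk (σ_n² = 0.01).  The round-trip error
  of encode→decode is below 0.01% of M_max on a 21×21 grid.  The weights
  are computed once, in closed form, and never updated by training.

### Sensorimotor MLP and training

One sigmoid hidden layer (100 units full scale, 50 reduced) and a
sigmoid motor layer, with bias terms (initialised at zero).  Inputs are
standardized by training-set mean/SD before entering the MLP: the pooled
feature maps have magnitudes around 10⁻², and sigmoid layers train
poorly on unscaled inputs.  Hidden weights use scaled-uniform fan-in
initialisation; the motor-layer weights start at 0.4 × that scale so
that each motor unit's tuning is inherited primarily through the fixed
decoder (see "Unit heterogeneity" below).

Training: Adam, learning rate 10⁻³, batch size 32, at most 50 epochs,
90/5/5 train/validation/test split (80/10/10 at the reduced scale so the
test split holds 1,000 trials).  Early stopping tracks the validation
RMSE: when no epoch has improved the best value by more than 10⁻³ for 12
consecutive epochs, training stops and the best-epoch weights are
restored.  The restoration matters under the noisy condition, where the
validation error turns upward well before epoch 50.

### Unit heterogeneity and the motor init scale

Because the decoder is fixed, each motor unit's weight gradient is
proportional to its 2-D decoder vector times a shared error signal, so
with near-zero initialisation every unit converges to the same function
of the decoded gaze — perfectly gaze-coded but with zero across-unit
variability, unlike recorded motor populations.  With full-scale random
initialisation the opposite happens: each unit inherits a random
projection of the landmark-dominated hidden layer and the population
looks landmark-coded.  The default (0.4 × fan-in scale) sits in the
physiological regime: the majority of units code future gaze with a
minority carrying landmark-centred idiosyncrasies, and the continuum
positions disperse across units.  The scale is exposed as
`motor_init_scale`.

## Synthetic data

The generator emulates a cue-conflict saccade protocol: landmark at one
of 4 oblique positions 11° from the target, shifts of 8° in one of 8
directions (or none), initial gaze jittered in a 7–12° annulus, reward
window 8–12°.

* **Scenario datasets** (idealised): target uniform in ±50°, landmark in
  ±40°, shift components uniform in ±10°, initial gaze in ±10°; final
  gaze = T + w·s for allocentric weight w ∈ {0, 0.3, 1}.
* **Neuro dataset** (for unit analysis): targets on a 7×7 grid at 10°
  spacing, protocol landmark/shift geometry with zero-shift trials at
  the protocol rate (1/9), final gaze drawn around the weighted cue
  combination (w = 0.33) with the combined-cue SD derived from
  σ_ego = 3°, σ_allo = 6° (≈2.7°).  The 0.33 weight is set explicitly;
  the cue SDs are exposed as config.
* **"High" noise**: Gaussian image blur of 10° SD, Poisson sampling of
  the eye-position code, and 2° isotropic Gaussian noise on the gaze
  endpoint.  Pixel-wise Poisson corruption of the images (blur first,
  then p → Poisson(50p)/50) is available behind a config flag but off by
  default; with it enabled the Nyquist-band front-end becomes
  noise-dominated and held-out performance drops far below the noiseless
  ceiling.

Reduced-scale profile (used throughout the tests and the acceptance
script): the canvas is 64×64 px covering the same ±100° field
(3.125°/px), 10,000 trials (8,000 train / 1,000 validation / 1,000
test), 50 hidden units.  The full-scale profile (200×200 at 1°/px,
100 hidden) is a config choice.  Pixel-denominated stimulus sizes (1 px
lines, 6×6 px target block) keep their raster structure at both scales.

What the generator does *not* emulate: real oculomotor dynamics
(saccade kinematics, torsion, 3-D geometry), temporal structure (delays,
masks, memory), session/neuron-specific target grids, and any
visual-epoch responses — so passing tests demonstrate that the analysis
pipeline and learning dynamics behave as designed under the model's own
assumptions, not that the model fits any particular recorded dataset.

## Behavioral analysis

Gaze endpoints can be normalized by subtracting, per target location
(nearest-grid-cell binning for jittered data), the mean error of the
zero-shift trials.  The allocentric weight of a shifted trial is the
projection AW = ((G − T)·(T′ − T))/‖T′ − T‖², i.e. 0 when gaze lands on
the target and 1 when it follows the shift fully; AW distributions are
compared with the Wilcoxon signed-rank test.  Error distributions report
the fraction of trials inside the 8° and 12° reward bounds.

## Reference-frame (unit) analysis

Response fields are mapped on grid-target probe datasets drawn from the
same distribution as the training set (one zero-shift, one shifted;
400 trials each by default, comparable to per-neuron trial counts in
recordings).  The "final gaze" entered into the spatial models is the
network's **own decoded saccade** on each probe trial — the model's
produced behaviour, the analogue of the recorded endpoint.

Candidate spatial models: target, landmark, shifted target/landmark,
target-relative-to-landmark and future gaze, each in screen or eye
coordinates (eye = screen − initial gaze), plus two 30-step continua of
intermediate eye-frame models, T–G and T–T′ (10 steps between the
reference points, 10 beyond each end; positions reported as a percentage
of the T→X distance).  Each candidate is fit by leave-one-out Gaussian
kernel regression, A_fit(xᵢ) = Σ_{j≠i} Aⱼ e^{−|xᵢ−xⱼ|²/kw} /
Σ_{j≠i} e^{−|xᵢ−xⱼ|²/kw}, scored by PRESS (mean squared LOO residual)
over the bandwidth grid kw ∈ {2², 4², …, 20²} deg²; the lowest-PRESS
(model, kw) wins, with exact ties broken toward the target end of a
continuum.

**Spatial tuning** is decided per condition on the canonical fits by a
selection-aware shuffle test: activities are permuted over positions 200
times and every shuffled field is refit with the same model × bandwidth
selection as the data; a unit is tuned when its rank-based p-value
(1 + #{null ≤ best})/201 is ≤ 0.05.  Because the null undergoes the same
selection, the test is exactly calibrated (measured type-I 4.9% on 1,000
pure-noise units); re-using a single-candidate null instead inflates the
false-positive rate to ~17% through the minimum over 60 candidates.
Continua are fit only on the units tuned in the shift condition, and
units with fewer than 16 probe responses above their own floor are
excluded before any fitting.

Population statistics: best-model histograms; per-model paired t-tests
of PRESS against each unit's best model; Wilcoxon signed-rank of the
T–T′ positions against zero; ordinary least squares of the T–T′
(allocentric) on the T–G (egocentric) continuum position across tuned
units (slope, SE, R², p).

## Numerical choices

* Front-end convolutions run in float32 via batched real FFTs (the
  downstream use is statistical; agreement with direct convolution is at
  the 10⁻⁴ level, below any decision threshold in the pipeline).
* The smoother matrices of the tuning null are stacked into one matrix
  so the 200 shuffles reduce to 200 BLAS multiplications.
* Degenerate inputs: zero-denominator kernel rows fall back to the
  leave-one-out mean; an all-identical AW comparison returns p = 1; a
  constant egocentric-fraction regressor makes the ego–allo slope
  unidentifiable and is reported as NaN with p = 1.
* All randomness flows through explicitly seeded NumPy generators;
  training, rendering with noise, and the analysis are bit-reproducible
  given the seeds.

## Known limitations

* The network reads the landmark (full-extent lines) far more reliably
  than the target block, so under heavy image noise its performance is
  limited by target localisation; enabling pixel-level Poisson noise on
  top of the blur drives held-out R² well below the noiseless values.
* In this model the landmark-shift condition makes the motor units look
  *more* purely gaze-coded than the no-shift condition (shifted trials
  decorrelate the decoded gaze from the landmark), so the fraction of
  gaze-frame units does not drop between conditions.
* The recovered allocentric weight saturates slightly below 1 for fully
  allocentric training data: the network applies MSE-optimal shrinkage
  to its noisy estimate of the shift.
* Motor units are analysed at their final trained state; there is no
  visual/delay epoch, so visuomotor response classes and their bimodal
  egocentric distributions are outside the model's reach.
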
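# Methods

## Hologram formation model

Each frame is a scalar-diffraction simulation of an in-line holographic
microscope. A unit-amplitude plane wave (λ = 532 nm) enters the far side
of the imaged column and propagates toward the recording plane through
the suspended particles. Every particle is modeled as an opaque disk
(binary amplitude transmittance) at its (x, y, z); particles are sorted
by depth, grouped into at most `n_slices` planes (default 16), and the
field is propagated plane-to-plane with the angular-spectrum transfer
function `exp(i·2π·Δz·sqrt(1/λ² − fx² − fy²))` (evanescent components
dropped). Because one slice's diffracted field illuminates the next,
adjacent-particle multiple scattering is approximated at first order.
The recorded intensity |U|² (1 for an empty volume) is mapped to the
unit interval by `I → clip(I/2, 0, 1)`, placing the flat reference at
mid-scale.

Deliberately out of scope: Mie/T-matrix scattering (particles are not
phase objects here), partial coherence, and camera ISP effects. The
periodic FFT boundary means diffraction that leaves the frame re-enters
on the opposite side; for a speckle-statistics study this wraparound is
indistinguishable from scatterers just outside the field of view.
Against a direct Rayleigh–Sommerfeld disk integral, the propagator
reproduces the single-particle radial intensity profile to within a few
percent and places the first diffraction minimum on the same pixel
(see the test suite).

## Suspension model

Particle counts per class are Poisson with mean `C·V / E[m]`, where `C`
is the requested mass concentration (µg/ml), `V` the imaged volume
(field of view × `sample_depth`) and `E[m]` the mean single-particle
mass under the class's truncated-normal diameter law (fine:
1.256 ± 1.309 µm on [0.2, 3] µm; coarse: 7.657 ± 1.286 µm on [5, 10] µm;
density 2.65 g/cm³, silica-dominated mineral dust). Positions are
uniform in the volume; the realized concentration (total drawn mass / V)
is recorded with each field and is an unbiased estimator of `C`.

`sample_depth` defaults to 25 mm — the illuminated path through a small
sample bottle — with the recording plane 5 mm outside the volume
(`focal_offset`). The depth controls how many particles contribute per
frame and therefore how developed the speckle is; it is the one geometry
parameter with no single obvious value, and it is configurable.

Acquisition noise has two parts: a smooth, stack-shared background
pattern (Gaussian-filtered noise, RMS amplitude 0.05 on the unit scale —
dust and fixed-pattern artifacts that background subtraction should
remove) and per-frame i.i.d. Gaussian sensor noise (σ = 0.02).

## Preprocessing chain

Per frame, in order: subtract the stack's ensemble-average background
(re-centered at mid-scale so negative residuals survive), filter with
the branch's Gaussian mask built on the centered integer frequency grid,
shift by `S` counts, stretch contrast by `out = mean + C·(in − mean)` on
the 8-bit scale, and cut into disjoint 70-px tiles normalized to the
unit interval. Filtering happens on the full frame, before tiling.
Clipping (not renormalization) follows each 8-bit stage.

Branch defaults are (HPF, S = 50, C = 7) for fine and (LPF, S = 0,
C = 5) for coarse, both with R = 20. S, C and R are dataset-dependent
knobs: the method's own tuning procedure sweeps them and keeps the
validation-RMSE minimizer. On the synthetic holograms the fine-branch
sweep favors a mild gain, and the shipped desk-scale profile uses C = 1
there: a ×7 gain about the mean saturates the high-pass residual into a
quasi-binary texture whose above-mean pixel fraction is nearly
concentration-independent, which erases exactly the mean-level signal a
64-dimensional autoencoder latent can represent. The coarse branch keeps
its printed values, which preserve both its class response and the
fine-leakage response the correction relies on.

## Networks

Both stages are dense numpy networks with seeded fan-in-scaled uniform
initialization; a fixed seed reproduces training bitwise on one CPU.

* Autoencoder: widths 4900–512–256–128–64–…–4900, sigmoid everywhere
  (inputs live on [0, 1]); Adam (β = 0.9/0.999), per-batch RMSE loss,
  batch 4096, 5000 epochs, lr 1e−3 at full scale.
* Regression head: 64–256–256–1, ReLU hidden, linear output, plain SGD
  (no momentum), per-batch MAE loss, batch 8192, 10000 epochs, lr 1e−7
  at full scale. Features are standardized inside the regressor (the
  statistics ship with the model) and the output bias starts at the
  label mean, so SGD refines rather than bootstraps.

The desk-scale profile shrinks this to a 4900–256–64 encoder and a
64–64–64–1 head, 150 autoencoder epochs (batch 256) and 4000 regressor
epochs at lr 1e−2 — enough for the reconstruction loss to plateau on the
synthetic segments while the whole study stays around four minutes.
An optional denoising-style input corruption is available on the
autoencoder (off by default).

Training data in the desk profile are three independent stacks of eight
frames per class rather than one long stack: each stack carries its own
background realization, and with a single stack per class a
sufficiently flexible encoder learns the stack's background-residual
fingerprint as a proxy for the class label and fails on new stacks.
Evaluation, leakage measurement and mixtures always use fresh stacks.

## Coarse-PM correction

The misprediction line is ordinary least squares through the per-class
means (true fine concentration, coarse-branch prediction) of low-pass
filtered fine-only stacks; blank classes are kept, since they pin the
intercept. `k` is grid-searched on [0, 1.5] in steps of 0.01 against
validation mixtures (ties go to the smallest k), and the corrected
prediction `P_c = P − k(A·X̂ + B)` uses the fine branch's prediction X̂,
not the unknown truth. Negative corrected concentrations are clipped to
zero and logged. Reported results come from a disjoint set of test
mixtures, so the improvement is measured out of sample.

## Desk-scale study design

The shipped test profile uses 280-px frames (70 µm field of view,
16 tiles per frame). Coarse particles are the constraint: at 8 µg/ml a
7.7-µm silica sphere weighs ~0.6 ng, so even a 70 µm × 70 µm × 25 mm
column averages under two coarse particles per frame, and smaller frames
would leave the coarse classes with essentially empty images. Fine
classes average roughly 15–120 particles per frame at 1–8 µg/ml. The
concentration grids are the study conditions: monodisperse fine
{1, 3, 6, 8} µg/ml, monodisperse coarse {1, 3, 8} µg/ml, and five
(ρ_f, ρ_c) mixtures spanning the same range.

What passing at desk scale shows — and does not. The synthetic study
demonstrates that the pipeline's machinery works end to end: speckle
statistics increase with concentration, the autoencoder features order
held-out fine classes strictly with mean error well under 25%, injected
leakage coefficients are recovered to the grid resolution, and the
correction lowers the coarse error on unseen mixtures. It does not
certify accuracy on real recordings: real dust is non-spherical and
absorbing, real backgrounds drift, and the coarse branch here operates
in a few-particles-per-frame regime where its standalone accuracy is
modest (the correction's benefit is correspondingly small but
consistent).

## Numerical choices and edge cases

* Autocovariance uses the Wiener–Khinchin relation with the variance
  normalizer (mean of I² minus squared mean), giving f(0,0) = 1 exactly;
  zero-variance images are rejected with a relative tolerance rather
  than an exact-zero test.
* Speckle FWHM takes the first half-max crossing moving outward from
  zero lag on the central horizontal/vertical profiles, linearly
  interpolated, doubled, and averaged over the two axes; a profile that
  never crosses signals "undefined" distinctly.
* PSD centroids exclude the DC bin per axis; an axis whose off-DC power
  is numerically zero (below 1e−12 of total) contributes 0.
* Speckle counting uses 8-connectivity, so diagonal grains merge.
* Connected-component, thresholding (mean + sd) and statistic
  definitions operate on the unit intensity scale.
* All randomness flows from one `SeedSequence` per entry point; spawned
  children keep simulation, noise and training streams independent.
* Sub-resolution particles (< 2 px) render as ≤ 1-px disks with a
  warning — the entire fine class is sub-resolution by design, which is
  precisely why its signal is speckle statistics rather than resolved
  images.

## Known limitations

* Opaque-disk scattering overestimates extinction for weakly refracting
  fine particles; concentration-to-speckle-contrast scaling is therefore
  qualitative, and learned models transfer only within the simulator.
* The coarse branch's standalone accuracy at desk scale is limited by
  counting statistics, not by the method; a full-scale (700-px, 100
  frames/class) run improves it at proportional cost.
* The correction is linear in the leakage line; nonlinear coupling
  between the two speckle signals is acknowledged but not modeled.
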
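# Methods

This note documents the models, the synthetic-data generator, and every
numerical choice a user may want to audit or change. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Event model and vocabulary

Events are single-particle records from one of two airflow-cytometer
designs. A holography-type event holds two orthogonal grayscale images
(0.595 µm/pixel; either may be absent), the particle's signed offset from
the measurement-channel centre in µm, and a 3×5 matrix of fluorescence
intensities (excitation sources 280/365/405 nm × five emission wavebands
over 333–694 nm). A scattering-type event holds a 2×14×T scattering array
(polarization plane × angle × time), a 32-point fluorescence spectrum
(350–530 nm, 12 nm resolution), 3×T lifetime traces (bands 375–397,
415–450, 467–487 nm) and a 16×T array from a flattened 4×4 675 nm detector.

The label vocabulary is the closed set of 17 reference species. The genus
grouping is derived mechanically from the first token of each label and
yields 10 genera; source material sometimes counts 11 genera for this panel
under current nomenclature (*Pithomyces chartarum* is now placed in
*Pseudopithomyces*), but the study labels themselves are the ground truth
for this artifact, so the label-derived 10 are used throughout. The pooled
7-class grouping for the scattering instrument merges the five *Alternaria*
and three *Cladosporium* species into "*Alternaria* spp." and
"*Cladosporium* spp."; the five remaining measured species keep their names.
Species not measured on that instrument (*Chaetomium globosum*, both
*Fusarium*, *Stemphylium vesicarium*) have no pooled class and raise an
error when mapped.

Schema defaults that the instruments do not pin down: image side 200 px
(the ~120 µm field of view at 0.595 µm/px implies ≈202 px; a round, even
200 is used and the pitch is a constant consumers can rescale with), and
time-sample counts T_s = 64 (scattering), T_l = 64 (lifetime), T_ir = 16
(infrared). All are configurable and serialized with the data. Channel
position is a single signed scalar because the position filter is
one-dimensional.

## Synthetic-data generator

The generator's purpose is statistical, not optical: it produces labelled
event streams whose structure exercises every downstream stage — species
separability where profiles are separated, and realistic corruption where
they are not. What it emulates, and how:

* **Morphology.** A spore is an ellipsoid with semi-axes (L/2, W/2, W/2);
  L, W are drawn per event from per-species means ± sd. Defaults come from
  standard mycological descriptions of typical conidium dimensions (e.g.
  *Alternaria alternata* 30×11 µm with a 25% beak and 4 septa;
  *Cladosporium sphaerospermum* 4×3.5 µm; *Exserohilum rostratum* 60×15 µm
  with 7 septa). The two views are projections of the same randomly
  oriented 3-D axes onto two orthogonal camera planes; the projected
  ellipse uses the exact in-plane angle and an axis-length interpolation
  a_proj = sqrt(L²·|u_proj|² + W²·(1−|u_proj|²))/2, which is exact for
  in-plane and axial orientations and a close approximation between.
  Optional features: a beak protrusion along the major axis, darker
  transverse septa bands, chains of 2–4 conidia placed along the shared
  axis with slight overlap (probability `chain_prob`), and hyphal fragments
  (3× length, ⅓ width, probability `hypha_prob`). Chains and hyphae keep
  the parent species' label, as cleaned reference datasets retain such
  particles. A damped-cosine ring texture around the silhouette
  (amplitude 0.07, period 6 px, decay 8 px on the background distance
  transform) plus additive Gaussian pixel noise (σ = 0.02) emulate the look
  of reconstructed holograms. True diffraction physics (Fresnel
  propagation) is deliberately out of scope: the classifiers consume
  grayscale morphology, and no optical forward model is specified for
  these instruments.

* **Fluorescence.** Each excitation source has a species-specific simplex
  of mean relative band intensities; per event a relative profile is drawn
  from a Dirichlet around that mean (concentration 80 by default) and
  scaled by a lognormal total intensity (σ = 0.3) around a species mean.
  The per-species simplex means are synthetic stand-ins constructed to be
  mutually distinct (peak waveband varies by species and source); only
  qualitative diversity of published average profiles is emulated, since
  no per-particle distributions are published. Species with notably weak
  intrinsic fluorescence (the three *Cladosporium*, *Curvularia
  caricae-papayae*, *Pithomyces chartarum*) get a lower intensity scale.

* **Corruption modes and calibration.** Four independent Bernoulli draws
  per event: one image dropped (`missing_image_prob`), both images replaced
  by near-constant frames with grayscale range < 0.1 (`empty_image_prob`),
  off-centre position (`offcentre_prob`, positions drawn from a mixture of
  uniform on [0, 500] µm and uniform on (500, 1500] µm so the position
  filter exercises both branches), and sub-threshold spectrum
  (`subthreshold_prob`). Because the draws are independent, the expected
  fully-recorded fraction equals exactly 1 − `missing_image_prob`, and the
  default profiles set that parameter per species from the panel's
  published fully-recorded percentages (e.g. 88% for *Alternaria
  chartarum* → 0.12). Likewise `subthreshold_prob` = 1 − (above-threshold
  %)/100 per pooled class (e.g. 63% above threshold for *Botrytis
  cinerea* → 0.37); the spectrum's maximum is an exact draw from a mixture
  with mass `subthreshold_prob` below 4000 units, so calibration is exact
  by construction and the empirical check is purely binomial. Default
  nuisance rates with no published value: `empty_image_prob` = 0.02 and
  `offcentre_prob` = 0.05, chosen once as plausible minor-corruption rates.

* **Scattering-instrument signals.** Spectra are smooth curves obtained by
  interpolating the species' five-band profile to 32 detectors; lifetime
  traces are exponential decays (τ uniform in 4–10 samples) whose onset is
  delayed by 0–10 samples so alignment is non-trivial, with small additive
  noise; scattering is a forward-dominant angular envelope × Gaussian
  temporal pulse with amplitude ∝ L·W and perpendicular-plane amplitude
  scaled by W/L; the 675 nm array is a spatial Gaussian blob × temporal
  pulse. These are size- and shape-correlated caricatures, not instrument
  physics.

* **Determinism.** A master seed spawns one child stream per class and one
  grandchild per event (`numpy` `SeedSequence`), so datasets are
  bit-stable across runs and any per-class subset is reproducible
  independently of generation order. Provenance records the seed and a
  SHA-256 hash of the full configuration.

What passing tests on this generator do **not** show: robustness to real
holography speckle and defocus, to fluorescence variation with culture age
and humidity, to debris and non-fungal particles, or to class imbalance in
ambient air. The end-to-end accuracies reported by the acceptance script
are upper bounds produced by deliberately well-separated synthetic classes;
they validate the pipeline's mechanics, not field performance.

## Cleaning rules

Four rules, applied without any species-specific logic. Holography events:
(1) missing image — either view absent; (2) empty images — grayscale range
(max − min) of a view strictly below 0.1 on [0, 1]-normalized pixels
("grayscale intensity difference" is not defined more precisely anywhere;
max − min is adopted and documented); (3) off-centre — |position| > 500 µm
(the boundary itself is retained). Rules apply in that fixed order and each
event is counted under the first rule it violates, so an event with one
absent and one empty image counts as missing. Scattering events: removed
iff max(spectrum) < 4000 units, i.e. a maximum of exactly 4000 is retained,
matching the wording that values *below* the threshold are excluded. The
other two boundary conventions (inclusive position window, strict empty
comparison) are unstated in the source material and fixed here for
testability. No fluorescence threshold is applied to holography data — that
path deliberately has no such knob.

## Preprocessing

Holography: images pass through unchanged (already [0, 1]); the 3×5
fluorescence matrix is divided row-wise by each source's summed intensity
(all-zero rows are returned as zeros and flagged, never divided). The
models consume the normalized matrix flattened to 15 values.

Scattering instrument, in order:

1. **Detector removal** — 1-based indices 7 and 8 (~450 and ~462 nm,
   susceptible to scattering-laser interference) are dropped from the
   32-point spectrum, leaving 30; indices are 1-based in configuration to
   mirror the instruments' detector numbering.
2. **Savitzky–Golay smoothing** of the spectrum and of every scattering
   trace in all three scattering images (two polarization planes and the
   675 nm array), along the time/detector axis. Window 7, order 2 by
   default — no values are published; this is mild smoothing that
   preserves structure in a 30-point spectrum, and both are configurable.
   Smoothing may produce small negative excursions; arrays are clipped at
   zero afterwards.
3. **Lifetime alignment** — each band is shifted so the trace starts at the
   first occurrence of its global maximum, with the tail zero-padded.
   Zero-padding (rather than wrapping) avoids fabricating decay signal;
   first-occurrence-of-global-maximum makes the operation unambiguous and
   idempotent.
4. **Image-like rasterization** of spectrum and lifetime to a configurable
   2-D shape (default 30×30): vectors are resampled along the width and
   broadcast down the rows; matrices are resampled per row and row-repeated
   block-wise. Then min–max scaling to [0, 1] per event; constant inputs
   map to all zeros.
5. **[0, 1] scaling** of the scattering and infrared arrays, also per
   event. Whether these arrays should be normalized per event or
   dataset-globally is not specified anywhere; per-event min–max is applied
   uniformly, flagged here as an assumption.

Stage idempotence: alignment and min–max scaling are idempotent;
Savitzky–Golay smoothing and rasterization resampling are not, so running
the chain on already-preprocessed arrays changes the smoothed modalities —
the pipeline therefore operates on raw events only.

## Models

All three families share one pattern: per-modality encoders, feature
concatenation, and a feedforward classification head. They are implemented
on a small numpy engine (`sporoclass.nn`) with manual backpropagation —
conv2d via im2col, ReLU, dense, layer normalization, 2×2 max pooling,
global average pooling, identity-shortcut residual blocks, softmax
cross-entropy and Adam. The engine is deterministic given a seed on a
single thread, which makes training runs exactly reproducible — a property
the test suite asserts.

* **Holography-only** (`poleno_holo`): one convolutional encoder applied to
  each of the two views — weight-shared by default, since the two views are
  statistically exchangeable projections (a no-sharing flag exists) — the
  two feature vectors concatenated, layer-normalized, passed through a
  feedforward stack (two hidden layers by default; widths are free) into
  the softmax classifier.
* **Holography + fluorescence** (`poleno_holo_fluor`): adds a feedforward
  encoder of the 15 normalized fluorescence values whose embedding is
  concatenated with the combined image embedding before the classifier.
* **Four-branch residual network** (`rapide_multibranch`): one residual
  convolutional branch per modality with 4 (lifetime), 3 (scattering),
  5 (spectrum) and 2 (infrared) block-layers; each block-layer wraps 3
  convolutions (4 in the first block-layer) in an identity shortcut
  x + F(x); the first convolution of each branch is 5×5 with 2×2 padding
  and stride 1 so monochrome inputs keep their spatial dimensions. Branch
  embeddings are concatenated into the same layer-norm + feedforward head
  (the fusion method for this family is not specified anywhere; plain
  concatenation mirrors the holography design).

`backbone_scale` selects widths/depths, never topology. `tiny` (default,
used by all training tests) uses an 8→16→32-channel stride-2 image encoder
on images resampled to 24×24 and 4-channel residual branches; it trains in
seconds to minutes on one CPU. `paper` builds a deeper plain-conv residual
encoder following the EfficientNet-B0 stage widths
(32, 16, 24, 40, 80, 112, 192, 320) and 32-channel branches; it is a
geometry-faithful stand-in, not a literal EfficientNet-B0 — depthwise
convolutions, squeeze-excitation and batch normalization are not
implemented in the numpy engine. The classifiers' scientific content (the
fusion topology, the branch/block structure, the shared split protocol)
is independent of this scale knob.

**Split protocol.** 80% train / 10% validation / 10% test, stratified per
class by largest-remainder allocation (every class within one event of the
exact fractions; classes need ≥ 10 events). The permutation is seeded by
(SHA-256 of the dataset content, seed) only, so the partition is a pure
function of the data and the seed — every model family trains, validates
and tests on identical events, which a test asserts by comparing
partitions.

**Training.** Cross-entropy, Adam (lr 10⁻³), batch size 32, a fixed epoch
budget with the best-validation-epoch weights restored afterwards
(selection metric: validation macro F1 by default, validation loss
optionally). Optimizer, learning rate, batch size, epochs, augmentation and
class weighting have no published values for this analysis; these defaults
are ordinary choices for small CNNs and all are exposed in `TrainConfig`.
No augmentation; no pretrained weights anywhere.

## Evaluation

Per-taxon accuracy is implemented as recall (diagonal over row sum), which
is what row-normalized confusion heat maps display; the alternative
reading of "accuracy" as a global proportion is exposed separately as
`overall_accuracy`. Macro F1 uses the 0-when-degenerate convention
(F1 = 0 if precision + recall = 0), so absent classes penalize the average
rather than silently dropping out. Genus aggregation sums counts within
genera and is proven (by property test) to commute with mapping the label
vectors before building the matrix. Heat maps are rendered row-normalized
to percentages.

## Problem sizes used in tests and the acceptance script

Unit and property tests run on events with 16–48 px images and tiny
datasets (tens to hundreds of events). Calibration recovery uses the
reference panel's own event counts (10,737 and 14,108 events) at 48 px —
the corrupted fractions do not depend on image size. End-to-end runs use 5
classes × 200 events at the full 200 px with 12 training epochs, and a
4-class fluorescence-only-signal contrast at 120 events per class; the
four-branch model runs at 3 classes × 80 events. These sizes were chosen
as the smallest at which the statistical checks (3-binomial-SE calibration
bands, macro-F1 thresholds) are meaningful.

## Known limitations

* The renderer is a silhouette-plus-texture caricature of inline
  holography; no interference physics, defocus or reconstruction
  artefacts.
* Fluorescence profile means are synthetic constructions, not measured
  spectra; only their mutual distinctness and the per-source simplex
  structure are meaningful.
* The `paper` backbone scale approximates encoder geometry but not the
  MBConv/SE internals of EfficientNet-B0.
* Native instrument file formats are not parsed; data enters through the
  package's own HDF5/NPZ schema.
* Class-balanced generation only; ambient-air prevalence, debris classes
  and concept drift are out of scope.
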
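# Methods

`mcftwin` models imaging through a multi-core fiber (MCF) endoscope as a
three-stage chain — per-core sampling of the object, per-core transmission,
and re-imaging of the core array onto a camera — and builds everything else
(single-reference calibration, honeycomb-free reconstruction, network
training) on top of that forward model.  This note records the model, its
assumptions, the parameters that matter, and the choices made where the
design was genuinely open.

## Fiber model

A fiber instance is a `FiberLayout`: floating-point core centers (row, col
pixels; origin at the top-left pixel center), a core radius, the nominal
pitch (core-to-core spacing), and a bundle disk that contains every center.
Synthetic instances are a hexagonal lattice clipped to the bundle disk with
isotropic Gaussian jitter applied per core; jittered cores that leave the
disk or violate the non-overlap constraint (pairwise distance ≥ 2 × core
radius) are removed deterministically in (row, col) order.  Defaults:

| parameter | default | rationale |
|---|---|---|
| core radius | 0.35 × pitch | keeps visible cladding gaps between cores |
| jitter std | 0.1 × pitch (experiments) | mild manufacturing disorder; configurable |
| transmissivity | clipped normal N(0.8, 0.15²) on [0, 1] | inhomogeneous gains with realistic spread; std 0 = homogeneous |

The model deliberately excludes core-diameter variation, elliptical cores,
inter-core coupling, coherent propagation and speckle: each core carries one
intensity sample, independently.

## Forward model (the digital twin)

For a scene `S` in [0, 1] (bilinearly resampled to the layout canvas when
shapes differ):

1. **Sampling** — core *i* receives `v_i = Σ w(r) S(r) / Σ w(r)` with a
   Gaussian weight of std `sampling_sigma` centered on the core.  The default
   is `sampling_sigma = core_radius`: a collection aperture comparable to the
   core size.  This default is what enforces the physically expected
   pitch-limited resolution — with a much narrower aperture, sub-pitch
   patterns alias into the core samples instead of vanishing.
2. **Transmission** — `v_i ← g_i · v_i` with the per-core gain vector.
3. **Rendering** — the camera frame is a sum of isotropic Gaussian spots of
   std `spot_sigma = 0.4 × core_radius` with peak amplitude `v_i`, clipped to
   [0, 1] (clipping mimics camera saturation and is applied after the sum, so
   linearity holds pre-clip), then masked to zero outside the bundle disk
   (rim-core spots are truncated by at most their outer tail).

The reference frame — the fiber under uniform illumination — is the same
rendering with amplitudes equal to the gains themselves.  Optional additive
Gaussian camera noise is applied last.  All spot windows extend to 6σ so
truncation error per spot is below 1e-8 of its mass.

## Single-reference calibration (`FiberTwinModel`)

`FiberTwinModel(reference, expected_pitch).fit()` estimates the layout and
gains from one reference frame:

- **Detection** — Gaussian smoothing (σ = 1 px), local maxima above
  `rel_threshold` (default 0.1) of the global maximum with a small candidate
  footprint (≈ 0.5 × pitch diameter), then iterated Gaussian-windowed
  centroid refinement (window σ = 0.15 × pitch, 4 iterations).  The soft
  window suppresses neighbor tails and the iteration converges geometrically
  onto the spot center; on clean renders the residual is below 0.1 px.
  Finally, refined centers closer than 0.65 × pitch are merged (the higher
  refined peak wins, ties broken by (row, col) order) — physical cores can
  never be that close, so such pairs are duplicate detections.  The small
  candidate footprint matters: a footprint as large as the pitch lets a
  bright neighbor's flank suppress a weak core's peak entirely.
- **Pitch estimate** — median nearest-neighbor distance.  Note this is a
  minimum statistic: under jitter it sits a few percent below the nominal
  lattice pitch; it is used only to scale radii, where that bias is harmless.
- **Gain estimate** — mean intensity in a disk aperture (default radius =
  core radius) around each center, normalized by the maximum over cores (the
  brightest core defines gain 1).  The disk integral is evaluated on a 3×
  supersampled grid with bilinear interpolation and a soft disk edge;
  a naive hard pixel mask varies by a few percent with the sub-pixel
  position of the center, which is larger than the accuracy target.

On a ~300-core fiber with jitter 0.1 × pitch and noise σ = 0.01 this
pipeline reaches full recall at 0.5 px with no false positives and gain
correlation above 0.99 (see `tests/test_acceptance.py` and
`scripts/acceptance.py` for the measured values).

## Classical reconstruction

Per-core values are re-extracted from a honeycomb frame with the same
supersampled disk mean, divided by `max(gain, floor)` (floor 0.05 bounds
noise amplification at dark cores; affected cores are flagged), and
interpolated from the scattered core centers onto the output grid by
barycentric interpolation over the Delaunay triangulation (exact for affine
intensity fields; nearest-core fill outside the convex hull).  A C1
Clough–Tocher interpolant is available as `method="cubic"`; fewer than three
or collinear cores fall back to nearest-core with a warning.

## Learned reconstruction

The cascade is implemented as a compact float32 CNN stack written on numpy
(im2col 3×3 convolutions, explicit backpropagation, Adam).  Hidden
activations are leaky rectifiers (negative slope 0.1): with hard
rectification, some seeds of this narrow cascade die into a constant
predictor within the first epoch and never recover.

- **Stage 1 (depixelation)** — a small U-Net: two 3×3 conv + leaky-ReLU
  blocks,
  one 2× average-pool down/nearest-neighbor up pair at double width, skip
  concatenation, and a linear 1-channel output.  When the reference channel
  is enabled the input has two aligned planes (MCF frame, reference frame);
  the reference feeds this stage only.
- **Stage 2 (super-resolution)** — residual blocks at base resolution, a
  global skip, and a sub-pixel convolution tail: the last convolution emits
  `upscale²` channels that a pixel shuffle rearranges into the magnified
  frame, so no convolution runs at output resolution.
- **Output bound** — an exact clip to [0, 1] with a straight-through leaky
  gradient (slope 0.05 outside the range).  A sigmoid bound was measurably
  slower to fit in this regime because most scene values sit near the
  saturating tails.

Training minimizes mean absolute error (L2 selectable) with Adam under a
cosine learning-rate schedule; the best-validation-PSNR weights are
checkpointed and returned.  Initialization, shuffling and all data flow from
explicit seeds, so runs are bit-reproducible on a fixed BLAS (the stated
determinism contract).  Gradients were verified against finite differences
(directional derivative converging to the analytic gradient norm as the step
shrinks).

Transfer learning (`fine_tune`) continues optimization from the pre-trained
weights at a lower learning rate and compares the small-domain validation
PSNR before and after; if fine-tuning did not improve it, the returned model
keeps the stronger starting weights and carries a `no_improvement` flag.

## Synthetic scenes and datasets

- **Textures** — Gaussian-filtered white noise, min–max rescaled; the
  correlation-length parameter is the half-width at half-maximum of the
  autocorrelation (filter σ = L / (√2·√(2 ln 2))).  These stand in for a
  natural-image pre-training corpus.
- **Blobs** — soft-edged elliptical blobs (`exp(−q²)` of an anisotropic
  quadratic form, flat-topped) on a dim background: a deliberately different
  statistics family standing in for tissue autofluorescence frames in the
  transfer experiments.
- **Bar targets** — binary three-bar groups (bar width = period/2, length
  2.5 periods) with a JSON-serializable `BarSpec` locating each group for
  contrast measurement.  For resolution-limit measurements the group is
  embedded in a mid-gray surround: on a black surround the finite group's
  own envelope leaves ~0.14 Michelson contrast even when the bar modulation
  is completely destroyed.

`build_dataset` writes scenes (at `scene_scale` × the canvas, the
reconstruction target resolution), simulated frames, the fiber reference and
a JSON manifest with split labels, per-sample transmissivity seeds/hashes
and the reference SHA-256.  Under the `redraw-per-sample` policy every
sample gets its own drawn transmissivity *and its own rendered reference
frame* — the reference channel must reflect the sample's gains, otherwise a
network cannot learn correction from it.  Split sizes default to the
5000/100/400 pre-training design; the desk preset is 200/20/40.

What the generator does **not** emulate: natural-image statistics (textures
are stationary Gaussian fields), real cladding background, autofluorescence
spectra, coherent artifacts, or measurement noise beyond additive Gaussian.
Passing tests therefore demonstrate the mechanics and the relative orderings
(correction beats no correction; reference conditioning closes the
hallucination gap; transfer learning helps on a new family) — not absolute
performance on clinical data.

## Evaluation

PSNR is `10 log10(range²/MSE)` (+∞ sentinel at MSE 0).  SSIM uses a 7×7
uniform window, k1 = 0.01, k2 = 0.03, data range 1 (scikit-image's
implementation behind the module surface).  Both accept an optional circular
bundle mask; simulated frames are zero outside the bundle, which inflates
full-frame similarity, so masked values are worth reporting alongside.
Michelson contrast of a bar triplet is taken from the mean profile across
the bars restricted to the span between the outer bar centers; ≥ 0.1 is the
documented "resolved" threshold.

## Desk-scale experiment design

The two headline experiments (in `mcftwin.experiments`) run on a 64×64
canvas, ~150-core fiber (pitch 4.5 px), 200/20/40 splits, width-4 cascade,
12 training epochs — sizes chosen once so a full run takes minutes on one
CPU core:

- **Hallucination ordering** — a no-reference cascade trained on
  homogeneous simulations, tested on the fiber's true inhomogeneous gains,
  drops ~1.4 dB versus matched homogeneous testing; a reference-conditioned
  cascade trained with redrawn per-sample gains recovers most of the gap.
  The inhomogeneous test set reuses the same scenes and the same gain vector
  that produced the reference, exactly as a physical fiber would.
- **Transfer learning** — pre-train on textures, fine-tune on exactly 50
  blob pairs, test on 40 held-out blob scenes.  The families differ enough
  that the gain is large (≈ +9 dB at these sizes).

## Known limitations

- The forward model is incoherent and linear; no speckle, crosstalk or
  wavelength dependence.
- The pitch estimator's small negative bias under jitter (minimum
  statistic) is accepted rather than corrected.
- The numpy cascade is sized for CPU desk runs; it demonstrates the
  training-strategy orderings, not state-of-the-art restoration quality.
- Bundle masking truncates rim-core spots at the disk of core centers;
  rim-core photometry is accordingly slightly less accurate than interior
  cores (visible as the last ~1% in gain-estimation accuracy).
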
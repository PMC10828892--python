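# mcftwin

Digital-twin simulation and resolution-enhanced reconstruction for
**multi-core fiber (MCF) endoscopy**.

Ultrathin fiber-bundle endoscopes relay an image through thousands of
independent light-guiding cores.  Each core transmits a single intensity
sample, so raw frames carry a honeycomb pattern that limits resolution to
the core-to-core spacing (the *pitch*), and manufacturing disorder gives
every fiber its own arbitrary core arrangement and inhomogeneous per-core
transmissivity.  A reconstructor trained without knowing those per-fiber
properties *hallucinates*: it produces plausible but wrong detail whenever
the real fiber's transmission deviates from the training assumption.

`mcftwin` is for researchers building or evaluating MCF image-restoration
pipelines.  From a **single reference frame** (the fiber under uniform
incoherent illumination) it:

1. recovers the fiber's core positions and per-core gains
   (sub-pixel detection + photometry — the fiber's *digital twin*);
2. simulates honeycomb endoscopic frames of arbitrary scenes through that
   specific fiber (unlimited paired training data, no acquisition);
3. reconstructs artifact-free images via
   - a classical baseline: per-core extraction, gain correction
     `v_i / max(g_i, floor)`, and barycentric interpolation over the
     Delaunay triangulation of the core centers, and
   - a learned cascade: a depixelation U-Net followed by a residual
     super-resolution stage with a sub-pixel convolution tail, optionally
     conditioned on the reference frame as a second input channel, with
     pre-training and transfer-learning (fine-tuning on ~50 pairs) modes.

## Model

With scene \(S \in [0,1]\), core centers \(\mathbf{r}_i\), gains
\(g_i \in [0,1]\):

- sampling: \(v_i = \dfrac{\sum_r w_\sigma(r-\mathbf{r}_i)\,S(r)}{\sum_r w_\sigma(r-\mathbf{r}_i)}\),
  with Gaussian aperture \(\sigma = \) core radius;
- transmission: \(v_i \leftarrow g_i v_i\);
- rendering: \(I(r) = \mathrm{clip}\big(\sum_i v_i\, e^{-\|r-\mathbf{r}_i\|^2/2\sigma_s^2}\big)\)
  with spot width \(\sigma_s = 0.4\,\times\) core radius, masked to the
  bundle disk.

Quality is scored by PSNR \(= 10\log_{10}(R^2/\mathrm{MSE})\) and SSIM
(7×7 uniform window), and bar-target resolvability by Michelson contrast
\((I_{max}-I_{min})/(I_{max}+I_{min}) \ge 0.1\).

## Worked example

```python
import numpy as np
import mcftwin as m

# a synthetic fiber: ~300 cores, pitch 8 px, jittered hexagonal packing
layout = m.generate_fiber_layout((168, 168), pitch_px=8.0,
                                 jitter_std_px=0.8, bundle_radius_px=74.0, seed=0)
gains = m.sample_transmissivity(layout, mean=0.8, std=0.15, seed=1)

# the fiber's reference frame, with camera noise
ref = m.render_reference(layout, gains)
noisy = np.clip(ref + np.random.default_rng(2).normal(0, 0.01, ref.shape), 0, 1)

# fit the digital twin from that single frame
res = m.FiberTwinModel(noisy, expected_pitch_px=8.0).fit()
print(res.summary())
```

```
Fiber digital twin — reference fit
============================================
cores detected               301
pitch (px)                 6.822
core radius (px)           2.388
bundle radius (px)         74.09
gain mean / std        0.773 / 0.126
gain min / max         0.391 / 1.000
reference refit corr      0.9883
```

All 301 cores are recovered (mean sub-pixel error ≈ 0.02 px against the
generating layout; estimated-vs-true gain correlation 0.999).  The fitted
pitch reads low because it is a median *nearest-neighbor* distance — a
minimum statistic under jitter.  `res.simulate(scene)` then produces
honeycomb frames of any scene through this fiber, and
`m.classical_reconstruct(mcf, res.layout, res.transmissivity)` or a trained
cascade (`m.train`, `m.fine_tune`, `m.reconstruct`) inverts them.

The same pipeline is scriptable from the shell:

```bash
mcftwin generate-layout fiber.csv --reference-out ref.tiff
mcftwin simulate scene.png fiber.csv mcf.tiff
mcftwin reconstruct-classical mcf.tiff fiber.csv out.png
mcftwin run config.json        # multi-stage workflow with provenance
```

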
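# Methods

## Model and guarantee

The denoiser f maps an H×W grayscale image (intensities nominally in
[0,1]) to an image of the same shape. It is J-invariant: for every pixel
j, f(x)ⱼ is functionally independent of xⱼ. The guarantee is purely
architectural and holds at initialization, after every optimizer step,
and through the 8-fold test-time averaging wrapper.

Layer graph:

    x ─ donut K×K conv ─ lrelu ─┬─ [3×3 dil-2 conv + lrelu] × m₂ ─┐
                                │                                  concat ─ 1×1 merge ─ lrelu ─(+ skip)─ head(1×1) ─ out
                                └─ [3×3 dil-3 conv + lrelu] × m₃ ─┘

Offset bookkeeping: the donut layer reaches the ring
{−⌊K/2⌋..⌊K/2⌋}²∖{0}; a d-dilated 3×3 layer adds offsets from
{−d, 0, +d}²; 1×1 layers and the skip addition add nothing. The center
offset 0 is representable as r + Σ sᵢ (r in the ring, sᵢ dilation steps)
iff some ring offset has both coordinates divisible by d — impossible
exactly when **d > ⌊K/2⌋** in every path. The condition is enforced
strictly at build time; d = ⌊K/2⌋ (e.g. d = 2 at K = 5) fails, which
`receptive_field` and the brute-force dependency map both confirm.

Design choices where the design was genuinely open:

* **Padding is zero, not reflective.** Reflection maps a border pixel's
  own value into its neighborhood and breaks the guarantee exactly at
  the boundary; the invariance verifier therefore always probes the four
  corners.
* **Skip connection placement.** The two paths concatenate to 2C
  channels while the donut features have C, so a direct sum is
  shape-impossible; the skip is added after the 1×1 merge brings the
  concatenation back to C channels. The merge is pointwise, so the
  invariance argument is unaffected.
* **Donut constraint by multiplicative masking** on every forward pass,
  not by parameter deletion, so any standard optimizer works unmodified.
* **Depths/widths.** The reference description of this architecture
  does not pin down channel counts or per-path depths; defaults are
  channels = 64, m₂ = m₃ = 2, head depth 2, leaky-ReLU slope 0.1.
  J-invariance holds for any setting; the defaults affect quality only.
  Desk-scale experiments in the tests and the acceptance script use
  channels = 8 (4 for the receptive-field batteries) to keep full runs
  in minutes on one CPU.

## Losses

* Plain self-supervision: mean over all batch pixels of (f(x)ⱼ − xⱼ)².
* ADSS: weights wⱼ = 1/(1 + λ|rⱼ|), λ ≥ 0, default 10. `detach_weights`
  defaults to true — w is a constant during differentiation, so the ADSS
  gradient is exactly the L2 gradient scaled by wⱼ < 1 (suppressed
  backpropagation). Differentiating through w (flag off) adds a term
  that pulls predictions toward the noise; both readings are
  implemented and tested.
* TV: anisotropic ℓ1 forward differences, summed over pixels, averaged
  over the batch axis only; weight α (default 0, 1e−7 when enabled, on
  squared-[0,1]-intensity scale). Isotropic TV was considered and not
  implemented.
* Clipped: per-pixel squared residual capped at ε (sweep values 0.2,
  0.4, 0.6 on [0,1] images); equals L2 once ε ≥ max r².

`check_loss_decomposition` estimates both sides of
E‖f(x)−x‖² = E‖f(x)−y‖² + E‖x−y‖² by paired Monte-Carlo over
independent noise draws and reports the standard error of the paired
difference; zero-mean families must agree within 3 SE, salt-and-pepper
on a non-mid-gray image must not.

## Noise simulators

σ_g and σ_s are quoted on the 0–255 scale and divided by 255 at
application; d is a probability. Speckle noise is uniform with mean 0
and standard deviation σ_s (support ±√3·σ_s/255), multiplied by the
signal. The salt/pepper split within d is equiprobable. AWGN/speckle
outputs are not clipped before training — clipping would destroy the
zero-mean property the decomposition relies on — and clipping to [0,1]
happens only at metric/export time. Each seed expands into four named
substreams (gaussian, uniform, mask, value), so disabling a fusion
component leaves the other components' draws bit-identical; fusion
composes salt_pepper(speckle(awgn(x))) in that fixed order.

## Synthetic clean images

`make_synthetic_clean` produces flat, gradient, checker, band-limited
texture, and piecewise-constant "shapes" images (dark background, mean
≈ 0.3, sharp-edged rectangles and disks). These emulate the
piecewise-smooth structure of natural grayscale photographs well enough
to exercise denoising, brightness preservation and TV behavior. They do
**not** contain fine-scale natural texture, long-range self-similarity,
or camera-pipeline artifacts, so passing tests demonstrate the
mechanism (invariance, bias control, self-supervised convergence), not
benchmark-grade restoration quality on photographs.

## Training protocol

RAdam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8), initial learning rate 0.03,
continuous exponential decay lr·0.9^(step/2000) (decay constants are
engineering defaults recorded in every checkpoint), λ = 10, rotation and
mirror augmentation applied per patch at sample time (statistically
equivalent to pre-expanding the dataset 8-fold, and cheaper). Default
batch 64 / patch 64 / 20k steps; the desk-scale experiments use batch 8,
patch 32, and 800–2000 steps, which is enough for the mechanism under
test to be visible (the brightness experiment separates L2 from ADSS by
a factor of ~5; self-supervised AWGN training gains >10 dB over the
noisy input). The supervised baseline mode shares all plumbing, swaps
the donut for a full kernel, and targets clean patches; at equal steps
it upper-bounds the self-supervised result.

Training is bit-reproducible per seed on one device: all randomness
flows through named, seed-derived generators, and the training loop and
report writers introduce no timestamps or unordered iteration.

## Numerical choices

* Network arithmetic is float32; losses, metrics and simulators are
  float64.
* The brute-force dependency probe compares perturbed batch elements
  against an unperturbed element *inside the same batched forward pass*;
  comparing against a separately computed forward is wrong because BLAS
  rounding may differ between batch shapes and produce false positives.
  The probe unions a finite-difference pass and an analytic-derivative
  pass (the leaky-ReLU slope never vanishes, so a dependency path
  cannot hide behind a dead unit).
* PSNR returns +inf on identical images. SSIM uses the de-facto
  standard 11×11 Gaussian window (σ = 1.5, no sample-covariance
  correction; cross-checked against scikit-image to 1e−10); a
  whole-image "global" mode exposes the single-statistic form directly
  for closed-form checks. Inputs are clipped to [0, max] before either
  metric.
* TV subgradient uses sign(0) = 0 at ties.
* 8-bit image round trips are exact to 1/510 (half a quantization
  step); float TIFF round trips are bit-exact; no clipping inside TTA
  averaging, only at export.

## Known limitations

* Single-channel 2-D only; no volumetric or color support.
* The numpy engine targets small networks on CPU; it has no GPU path
  and no general autodiff.
* Quality defaults (depths, widths, decay constants) are not tuned
  reproductions of any published configuration.
* Salt-and-pepper's salt fraction is fixed at 1/2; asymmetric impulse
  noise would need a one-line extension of the simulator.
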
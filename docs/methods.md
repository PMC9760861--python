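# Methods

## Overview

`dermseg` segments pigmented skin lesions in dermoscopy images.  The
pipeline runs in a fixed order:

    read → denoise → hair detect → inpaint → luminance → equalize →
    sigmoid → level set → postprocess

Every stage can be disabled in the configuration; a disabled stage
passes its input through.  All stages operate on floating-point images
in [0, 1]; source bit depth is erased on read.

## Hair and bubble artifact removal

Hairs are dark curvilinear occlusions 1–5 px wide.  Detection convolves
the inverted luminance with a bank of even-symmetric (cosine) Gabor
kernels — 12 orientations at wavelengths 4 and 8 px, envelope std half
the wavelength, chosen to bracket typical dermoscopic hair widths — and
takes the pixelwise maximum response, clipped at zero and normalized to
[0, 1] by its own maximum.  Kernels are DC-free under the envelope
weighting, so structure-free images give an exactly zero response.

The response is hysteresis-thresholded at its 0.93/0.75 quantiles
(floored at 0.15/0.05 of the normalized scale so that images with
almost no structure do not threshold at numerical noise).  Quantile
thresholds make detection invariant to affine luminance changes; the
fairly generous quantiles reflect that hairy images carry 10–25% hair
pixels, and that the component filter, not the threshold, carries the
specificity.

The component filter accepts a candidate component when it is at least
`min_length` (15 px, echoing the local-window scale of the segmenter)
long and either

* elongated — eccentricity ≥ 0.9, the isolated-hair case — or
* a *thin dark web* — 99th-percentile distance-transform half-width
  ≤ 7 px and mean darkness relative to a σ=10 px Gaussian background
  estimate ≥ 0.05.  Crossing hairs fuse into a single connected network
  whose overall eccentricity is low; thin-and-dark identifies such
  networks while rejecting compact blobs (bubbles, gel spots, dark
  cores), which are either thick or not dark.

Two rim guards deal with the lesion boundary, which otherwise
masquerades as curvilinear structure: a ±3 px band around lesion-scale
dark regions (Otsu dark class opened with a 3-px disc, components ≥ 1%
of the frame) is excluded before labelling, then re-admitted where it
adjoins a kept hair so strokes stay contiguous across the boundary; and
components ≥ 95% inside a dark region whose distance-to-rim standard
deviation is < 2.5 px are rejected as rim-parallel side-lobe ridges (a
genuine hair crossing the lesion spans a wide range of rim distances).

Bright compact artifacts (bubbles, gel glints) are detected separately:
pixels exceeding the σ=10 px local background by 0.08 *and* in the
brightest 1.5% of the frame, grouped into components of ≤ 200 px with
disc-like solidity ≥ 0.5.  Working on local contrast makes the detector
independent of smooth illumination.  Their mask joins the hair mask for
inpainting; a bubble sitting on the lesion boundary otherwise notches
the final contour.

**Inpainting (NBRF).**  Neighbourhood-based region filling is an
onion-peel fill: each cycle, every masked pixel with at least one
unmasked 8-neighbour takes the mean of those neighbours' values from
the previous cycle, then becomes unmasked.  The update is
order-independent within a cycle, terminates in at most max(H, W)
cycles, leaves unmasked pixels bit-identical, and each filled value is
a convex combination of original values.  Across a linear intensity
ramp the fill is exact up to one column step at the stroke edges.

**Denoise.**  A 3×3 mean filter (centre included, reflective borders),
applied per channel before detection.  It preserves affine intensity
ramps exactly and leaves 2–3 px hairs detectable.

## Enhancement

Luminance is CIELAB L* (D65), rescaled to [0, 1].  Illumination is
modelled as multiplicative and smooth: the field estimate B is a
Gaussian blur of the luminance with std = 0.25·min(H, W)/2, and the
output is `clip(lum · mean(B)/max(B, 1e-6), 0, 1)`, which preserves the
global mean.  The lesion must be smaller than the kernel scale or part
of it is treated as shading — hence the 0.25 fraction against lesions
up to roughly half the frame.

The adaptive sigmoid is a per-image logistic stretch
`s(x) = 1/(1 + exp(-gain·(x - c)))` with gain 10 and cutoff c the Otsu
threshold of the (equalized) luminance — the natural bimodal estimator;
a `midpoint` mode (mean of the two class means) is available.  The
stretch is strictly monotone, maps the cutoff to exactly 0.5, and for
large gain approaches the hard threshold rule.  It feeds the level set
with a near-binary image in which lesion/skin histograms overlap by
under 5% even at illumination amplitude 0.3.

## The hybrid level set

The segmenter evolves φ (positive inside the lesion) under a
multiscale binary-fitting force with reaction–diffusion regularization;
no reinitialization of φ as a signed distance function exists anywhere
in the module.

**Local fitting means.**  With K_s a normalized Gaussian window of size
s×s (std s/4) and H_ε(z) = ½(1 + (2/π)·arctan(z/ε)),

    f1 = K_s*(H I)/K_s*H,    f2 = K_s*((1-H) I)/K_s*(1-H)

are the local inside/outside means; the residual terms are

    e_i(x) = I(x)² − 2 I(x)(K_s*f_i) + K_s*(f_i²).

**Force composition.**  A purely local fitting force vanishes
identically inside homogeneous regions (H constant ⇒ f1 = f2 = local
mean), so it cannot expel the skin captured by the box initialization —
the locality that makes binary fitting robust to inhomogeneity also
blinds it at long range.  The data force therefore blends the local
multiscale term with its own coarsest member, the global (Chan–Vese)
fitting force E_i = (I − c_i)²:

    F = (1−g)·Σ_s w_s (λ1 e1_s − λ2 e2_s) + g·(λ1 E1 − λ2 E2),  g = 0.5.

Scales default to {15, 31} px with equal weights; with a window at
least the image size the local term reduces to the global one and the
model coincides with Chan–Vese (a tested property).

**Scaling, step, regularization.**  Residual products are evaluated on
the 0–255 gray-level scale (`force_scale` = 255): binary-fitting
parameter values (λ = 1, dt = 0.1) are conventionally stated for 8-bit
intensities, and on [0, 1] images the unscaled force moves the front by
under 10⁻³ px per iteration.  The update is

    φ ← φ + dt·δ_ε(φ)·(−F + μ·κ(φ)),   δ_ε(z) = ε/(π(z²+ε²)),

with curvature κ by central differences (gradient floored at 1e-8),
followed by `rd_steps` = 2 explicit heat-equation sub-steps
φ ← φ + rd_dt·Δφ (5-point Laplacian, reflective borders, rd_dt = 0.1,
stable below 0.25), and a clip of φ to the binary-step range [−2, 2].
The clip keeps the two amplitudes symmetric; an asymmetric profile
would let the diffusion drift the zero level toward the
larger-amplitude side.  Under this regime φ is a diffuse step: the mean
|∇φ| in the 5-px band around the contour settles around 0.25–0.6 and
the evolution needs no reinitialization.

**Initialization and stopping.**  φ starts as +2 inside the 10%-expanded
bounding box of the largest connected component of the Otsu-dark class
(opened with a 2-px disc so residual thin artifacts cannot tether the
component to the frame), −2 outside.  Convergence is declared when the
fraction of sign flips per iteration stays below 1e-4 for 10
consecutive iterations; on synthetic scenes the model converges in
roughly 30 iterations.  max_iter = 500 caps the loop.

**Post-processing.**  Morphological closing with a 5-px disc, hole
filling, largest connected component, dilation by 1 px.  The final
1-px dilation puts a geometric ceiling on achievable Jaccard of
A/(A+P) for a region of area A and perimeter P; lesions under ~30 px
radius cannot reach 0.95 against truth for that reason alone.

## Baselines

All baselines share the hybrid's initialization, flip-based stopping
and post-processing so comparisons isolate the data term; all take the
plain (unenhanced) luminance.

* **Chan–Vese** — two-constant model; c1, c2 are the means of the hard
  sign regions (with the bounded step profile of φ, smooth-Heaviside
  weighting at ε = 1 would mix ~15% of each region into the other mean
  and bias the recovered constants far beyond usefulness), force scaled
  and φ clipped as in the hybrid.
* **Geodesic active contour** — edge map g = 1/(1 + |∇(G_σ*I)|²) with
  σ = 2; the gradient is rescaled to maximum magnitude 4 before
  entering g, since on [0, 1] images the raw |∇I|² ≈ 0.01 at a strong
  edge would barely slow the front.  Evolution
  φ_t = g|∇φ|(κ + balloon) + ∇g·∇φ; balloon defaults to −1 (inward)
  because the shared initialization is a box around the lesion.
* **Otsu** — 256-bin between-class-variance threshold, lesion = the
  darker class (melanoma lesions are darker; the generator's gray
  bands 41–64 vs 157–181 reflect that).  An independent exhaustive
  256-level scan is kept as a test oracle; when the histogram gap is
  empty the maximizer is a plateau and only the attained variance (not
  the tie-broken threshold value) is comparable.
* **EM** — a hand-written two-component univariate Gaussian-mixture EM
  (5 restarts, variance floored, best log-likelihood kept) exposing the
  per-iteration log-likelihood trace, which is asserted non-decreasing;
  scikit-learn's `GaussianMixture` serves as an independent
  cross-check in the tests, never as the implementation.  Pixels go to
  the higher-posterior component; lesion = lower mean.  With unequal
  class variances the posterior crossing sits far from the Otsu
  threshold, so the two rules genuinely split boundary-ramp pixels
  differently.

## Synthetic scenes

The generator emulates the artifact types the pipeline is built for and
exports exact ground truth.  One `numpy.random.Generator` seeded from
`SceneParams.seed` drives every sub-step, so scenes are bit-reproducible
at the stored 8-bit level.

* **Lesion** — an ellipse (default axes 70×55 px in a 256×256 frame)
  radially perturbed by a ≤ 5-harmonic random Fourier series scaled to
  `boundary_wobble` (0.15), blended over a 3-px ramp; truth is the 0.5
  coverage level.  Optional multitone mode darkens a half-axes core by
  20–40 gray levels.
* **Luminance** — smooth random textures filling the lesion band
  (41–64) and skin band (157–181) exactly; the bands are the two
  gray-level distributions a dermoscopic lesion/skin pair exhibits and
  are disjoint before noise.
* **Illumination** — multiplicative 1 + a·g with a = `illumination_amp`
  and g a unit-peak plane plus Gaussian bump; multiplicative matches
  real vignetting.
* **Hairs** — anti-aliased cubic Bézier strokes spanning the frame,
  luminance 0.03–0.12, thickness 1.5–3 px; truth is coverage > 0.
  Drawn after illumination so hair luminance stays < 0.15.
* **Bubbles** — bright (0.92–0.98) anti-aliased discs of radius 2–6 px.
* **Noise** — additive Gaussian, shared between the artifacted and
  clean copies, so the two images agree bit-exactly off-artifact.

Defaults (6 hairs, 3 bubbles, illumination 0.15, noise 0.01) are a
moderately artifacted dermoscopy frame; the robustness studies use
illumination 0.3 with noise 0.02, and the hair studies 15 hairs.

What the generator does **not** emulate: skin texture (pores, pigment
network), ruler and ink markings, specular highlight geometry, vessel
trees, colour variegation (scenes are gray in RGB), or lesions touching
the frame.  Passing tests therefore demonstrate correctness of the
algorithms under controlled conditions, not clinical performance.
Known limitation: in multitone mode the core rim can resemble a thin
dark curve and be flagged as hair; inpainting it is mildly smoothing
but harmless to the final mask.

## Problem sizes and verification scope

The shipped studies use 256×256 scenes: one noise-free two-phase scene,
20 illumination/noise scenes (amp 0.3, σ 0.02), and 10 fifteen-hair
scenes with paired clean runs; metric code is checked against a
brute-force per-pixel oracle on 100 random 64×64 mask pairs, and the
confusion-matrix utilities against hand arithmetic on a printed
three-class recognition table.  `scripts/acceptance.py` regenerates all
of these from a single seed and reports medians; typical values are
Jaccard ≈ 0.97 on the clean scene, ≈ 0.95 median under illumination
(Otsu baseline ≈ 0.55–0.61), hair recall ≈ 0.92 / precision ≈ 0.82,
inpainting MAE ≈ 0.02, and a clean-vs-hairy Jaccard gap ≈ 0.02.
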
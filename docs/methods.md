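# Methods

## Measurement model

The measured object is a photograph of a laser spot transmitted through a
fibrous sample. Light spreads preferentially along the fibre axis, so the
spot's iso-intensity contours are (to good approximation) concentric
ellipses sharing one axis ratio, tilted at the fibre angle. The statistic
reported is the squared ratio of the fitted ellipse's long to short axis,
`(L_L/L_S)^2 = (a/b)^2`, which is 1 for isotropic structure and grows with
fibre alignment. Only the ratio matters: the statistic is invariant to
uniform scaling, rotation of the frame, and (for a concentric-elliptical
profile) to the choice of which iso-contour is traced — the property the
pipeline's robustness rests on.

## Processing chain and the role of each stage

1. **Gaussian denoising.** Laser speckle is high-frequency multiplicative
   noise; a small normalised Gaussian template (default 7 × 7) suppresses it
   while preserving the spot's decay profile. The template width defaults to
   `sigma = 0.3*((size-1)/2 - 1) + 0.8` px, the conventional size-tied
   kernel-width heuristic; both size and sigma are configurable. Borders are
   replicated so the correlation is defined everywhere.
2. **Sobel edge detection with border replication.** The 3 × 3 Sobel
   gradient magnitude is thresholded at `threshold_factor` (default 4.0)
   times its mean to delineate where the spot's structure lies. A 5 × 5
   Sobel variant exists for comparison but is non-default: its wide, noisy
   response blurs the boundary. Before filtering, the outermost rows and
   columns are replicated outward by half the template size and the result
   cropped back, so gradient responses at the frame border are not
   attenuated.
3. **Morphological closing.** Dilation then erosion with a disc of radius 3
   (a disc, for rotational fairness on elliptical contours) joins
   discontinuous edge pixels. The implementation pads by the element radius
   before dilating, so closing follows infinite-plane set semantics exactly:
   it is extensive, idempotent, and increasing, including at the frame
   border.
4. **Binarisation and component selection.** The final spot mask comes from
   thresholding the *denoised intensity* (Otsu's 256-bin between-class
   criterion by default, or a fixed threshold), keeping the connected
   component that overlaps the filled, closed edge map. This division of
   labour is deliberate: an intensity threshold cuts the boundary on an
   iso-intensity contour, whose shape carries the true axis ratio for any
   threshold level, while the edge map only localises which component is
   the spot. Thresholding the gradient ring itself was rejected: the outer
   rim of a gradient-magnitude ring is not a similar ellipse of the
   intensity contours (its iso-lines mix `1/sigma` factors per axis), and
   under strong speckle the gradient response is dominated by noise texture,
   inflating the variance of the statistic several-fold. Otsu plateaus
   (empty histogram bins between the background and spot populations)
   resolve to the plateau midpoint.
5. **Inward shift, tracing and fitting.** The spot component is hole-filled,
   eroded inward by `inward_offset` px (default 20) — realised as a
   Euclidean distance-transform threshold, i.e. erosion by the exact
   Euclidean disc — and the eroded region's outer boundary is traced with
   Moore-neighbour tracing (ordered, closed, 8-connected). Offset 0 reproduces fitting the outermost
   coordinate points. The traced points are fitted with the direct algebraic
   least-squares ellipse (Halir–Flusser's numerically stable block
   formulation of the ellipse-specific conic fit), with coordinates centred
   and uniformly scaled before solving; the eigenvector satisfying the
   ellipse discriminant constraint with positive leading coefficient is
   taken. Axes are sorted `a >= b`; the tilt of the major axis is normalised
   to [0, pi).

Errors at any stage surface as `PipelineStageError` carrying the stage
name; an all-dark or featureless image fails at binarisation.

### The inward shift and its bias

Eroding by a disc of radius `d` shortens both semi-axes by about `d`, so
the shifted contour's ratio `(A-d)/(B-d)` slightly exceeds the true ratio
`A/B`; the relative error of the squared statistic is approximately
`2 d (r-1) / (r (B-d))` for true ratio `r` and boundary radius `B`. The
shift is nonetheless the default because on real photographs the outermost
points are the noisiest; the bias is the price of moving to a cleaner
contour, and it vanishes as the spot grows relative to the offset. With the
default simulated geometry (boundary radius ≈ 300 px at the Otsu level) the
bias stays under ~3% at the strongest anisotropy studied (ratio² = 1.56).

## Channel choice

The source is a red He-Ne laser (632.8 nm), so the red channel carries
essentially all of the signal and is the default. Luminance (BT.601) and
per-pixel max conversions are available for other light sources; the choice
is configurable because nothing in the measurement depends on it once the
spot is well exposed in the chosen channel.

## Synthetic spots: what they emulate and what they do not

The simulator renders `amplitude * exp(-(u²/2σ_maj² + v²/2σ_min²))` in
rotated coordinates, multiplies by unit-mean gamma noise with standard
deviation `speckle_contrast` (the standard surrogate for fully developed
speckle), adds zero-mean Gaussian sensor noise, clips to [0, 1] and
quantises to the red channel of an 8-bit image (green/blue at 4% of red,
emulating sensor bleed). Ground truth is exact: every iso-contour has ratio
`σ_maj/σ_min`, so the true statistic is `(σ_maj/σ_min)²`.

Defaults: 1536 × 1536 frame, `σ_min = 200` px, amplitude 0.9, speckle
contrast 0.3, background SD 0.01, tilt 25°. The geometry mirrors the
close-up camera photographs the method is used on, where the spot fills
most of the frame; as noted above, a frame-filling spot is also what keeps
the 20-px inward shift benign. Cohort generation derives one seed per
replicate from a single base seed, so cohorts are bit-reproducible.

Features of real photographs *not* emulated: spatially correlated speckle
grain (simulated speckle is per-pixel), the 45° incidence geometry (its
distortion is treated as already absorbed into the observed ellipse),
vignetting, saturation, and background gradients. Passing the synthetic
recovery tests therefore demonstrates correctness of the measurement chain
on the stated noise model, not calibration on any particular camera.

## Validation statistics

The destructive benchmark index is the degree of organisation, the
transverse/longitudinal shear-force ratio; ratios are computed per sample
and only then summarised, matching how the published group averages are
defined. Coefficients of variation use the n−1 sample standard deviation
over the mean (in percent). "Mean normalisation" is `(x - mean)/(max -
min)` — the standard definition, adopted here since the source material
names the method without a formula. Spearman correlation is the Pearson
correlation of mid-ranks (ties averaged; delegated to scipy). Both a
group-means correlation and, when sample identifiers pair up, a pooled
per-sample correlation are reported, since published per-sample data for
the original four-product study are not available and the two modes answer
slightly different questions.

## Numerical choices and degenerate inputs

- Otsu requires a non-constant grid; the error advises a fixed threshold.
- The ellipse fit requires ≥ 5 non-collinear points; rank deficiency and
  non-elliptical conic solutions raise validation errors rather than
  returning garbage.
- Over-erosion (offset larger than the spot's inradius) reports the maximal
  feasible offset.
- 16-bit images are rescaled to 8 bits by integer division by 257 rather
  than rejected; the chain is scale-invariant after normalisation.
- All randomness flows through `numpy.random.default_rng(seed)`; the
  measurement path itself contains no randomness, and re-running `measure`
  on identical inputs yields byte-identical CSV output.

## Problem sizes used in the test suite

Unit and property tests run on compact spots (512-px frames, σ ≈ 60 px,
and 16–32 px operator fixtures), where every qualitative property of the
chain already holds. The ground-truth recovery study runs at the
simulator's default full-scale geometry (1536-px frame, five anisotropy
levels spanning the published 1.20–1.56 range plus a 1.05 control, ten
seeded replicates each), which is the scale at which the 5% recovery
tolerance is meaningful given the inward-shift bias analysis above.

## Known limitations

- The statistic saturates toward 1 for nearly isotropic samples; the sign
  of tiny anisotropies below the pixel-quantisation floor is not resolved.
- Single-spot images only; multiple spots or strong background structure
  would require the component-selection stage to be revisited.
- No uncertainty propagation from pixel noise to the statistic beyond
  simulation-based spread; the fit RMS distance is a diagnostic, not a
  standard error.
- The inward-shift bias analysis assumes a convex, roughly elliptical spot;
  strongly non-convex spots (defects, occlusions) will bias the fit in ways
  the pipeline does not detect.
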
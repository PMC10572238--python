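# fibrespot

Non-destructive quantification of fibre orientation in fibrous foods
(extruded jerky, meat analogues, and similar products) from
laser-transmission spot photographs.

## The method

When a coherent red laser beam enters a fibrous sample, light propagates
preferentially along the fibre axis, so the transmitted spot photographed on
the sample elongates in the fibre direction. The **degree of orientation**
is defined from the ellipse fitted to the spot boundary:

```
degree of orientation = (L_L / L_S)^2
```

where `L_L` and `L_S` are the lengths of the fitted ellipse's long and short
axes. An isotropic (non-oriented) sample gives a circular spot and a value
of 1; well-aligned fibres give larger values.

Raw spot photographs are dominated by laser speckle, so the measurement runs
a five-stage processing chain before any geometry is read off:

1. **Gaussian denoising** — correlation with a 7 × 7 normalised Gaussian
   template (width tied to template size; replicated borders).
2. **Sobel edge detection** — 3 × 3 gradient-magnitude response with the
   image border replicated outward so edge strength is not attenuated at the
   frame; thresholded at a multiple of the mean gradient.
3. **Morphological closing** — disc of radius 3, joining discontinuous
   boundary pixels.
4. **Binarisation** — Otsu's 256-bin between-class-variance threshold on the
   denoised intensity; the connected component overlapping the closed edge
   map is kept as the spot.
5. **Boundary fit** — the spot region is filled, its boundary shifted
   inward by 20 px (erosion by a Euclidean disc), traced, and fitted with a
   direct least-squares ellipse (algebraic conic fit constrained to an
   ellipse); the statistic is `(a/b)^2` of that ellipse.

A seeded simulator generates spot images with known ground-truth anisotropy
(elliptical-decay profile, unit-mean gamma speckle, additive sensor noise),
and a validation layer reproduces the statistics used to benchmark the
optical index against destructive texture analysis: per-group summaries,
coefficients of variation, mean normalisation, and Spearman rank
correlation with the **degree of organisation** (transverse / longitudinal
shear force).

## Worked example

```python
from fibrespot import LaserSpotModel, spec_for_orientation

# a simulated spot whose true degree of orientation is 1.40 (pork-jerky-like)
model = LaserSpotModel.from_synthetic(spec_for_orientation(1.40, seed=3))
fit = model.fit()
print(fit.summary())
```

```
Laser-spot orientation fit
==========================
source:                 synthetic(seed=3)
config digest:          bbe83f9ca784
boundary points:        1917
fit RMS distance (px):  3.714
centre (row, col):      (768.59, 768.09)
long axis L_L (px):     683.10
short axis L_S (px):    569.02
tilt (deg):             25.27
degree of orientation:  1.4412
```

The fitted ellipse is centred on the spot, tilted at the simulated fibre
angle (25°), and the measured statistic 1.4412 recovers the true value 1.40
to within 3% despite speckle at contrast 0.3. `fit.plot()` overlays the
traced boundary and fitted ellipse on the photograph.

The same measurement from the shell, over whole cohorts:

```
fibrespot simulate --out spots/           # 4 groups x 10 seeded replicates + truth.csv
fibrespot measure  --out results/ spots/*.png
fibrespot validate --results results_grouped.csv --shear shear.csv --out validation/
```

`measure` writes a CSV/JSON results table plus a run manifest (config
digest, per-file status); re-running on identical inputs produces
byte-identical CSVs. `validate` writes group summaries with coefficients of
variation, mean-normalised trend series, and the Spearman correlation
between the destructive and optical indices.

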
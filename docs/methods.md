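# Methods

This note describes the models and procedures implemented in `sarcotex`, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not establish.

## Problem setting

Cardiomyocytes — whether endogenous or reprogrammed from fibroblasts —
express their contractile maturity in the spatial regularity of their
sarcomeres: α-actinin immunostains show periodic Z-line striations with a
spacing of roughly 1.8–2.2 μm in healthy cells.  The package quantifies, per
segmented cell, (i) which cardiomyocyte markers the cell expresses
(α-actinin, Hcn4, perinuclear Nppa), (ii) its size and shape, and (iii) the
strength, spacing and direction of its striation pattern.  All distances are
converted with a pixel size of 0.15625 μm/px by default, the scale at which
the pipeline's pixel-denominated thresholds (25 px ≡ 3.91 μm binucleate
join, 8 px ≡ 1.25 μm perinuclear ring) were defined.

## Segmentation and classification

Nuclei are detected on the DAPI channel by grayscale morphological closing
(disk radius 3 px), Gaussian smoothing (kernel radius 4 px, σ = radius/2),
Otsu thresholding, and removal of objects under 60 px.  Marker channels are
smoothed and Otsu-binarized the same way; a nucleus is marker-positive only
when **every** nucleus pixel lies inside the marker foreground (a relaxation
fraction is exposed as `enclosure_fraction` but defaults to strict).  Nppa,
being perinuclear, is scored on an annulus extending 8 px from the nucleus
edge and excluding all nucleus pixels: positive when the ring's
90th-percentile intensity (linear interpolation between order statistics)
exceeds 0.1.  Same-class nuclei whose pixel sets come within 25 px
(shortest boundary-to-boundary distance, closed transitively) are merged
into binucleate groups.

Cell territories are found by a marker-controlled watershed on the Sobel
gradient magnitude, run in three sequential passes so neighbouring cells of
different classes cannot capture one another's territory: α-actinin-only
cells on the actinin image with the Hcn4 foreground zeroed; Hcn4-only cells
on the Hcn4 image with the actinin foreground zeroed; dual-positive cells on
the pixelwise-maximum image restricted to the intersection of both
foregrounds.  Each pass is seeded by that pass's nucleus groups plus a
background marker (pixels below the pass image's Otsu threshold, eroded by
a 5-px disk, clear of the seeds); pixels claimed by an earlier pass are
never reassigned, which guarantees disjoint masks.

A DAPI bleed-through correction is provided
(`correct_dapi_bleedthrough`): DAPI pixels whose intensity exceeds 1.5× the
pixelwise maximum of the Nppa and Hcn4 channels are zeroed (a zero
reference with positive DAPI counts as exceeding).  Note that this rule
removes DAPI precisely where it *dominates* the marker channels, so on data
without marker signal over the nuclei it deletes true nuclei — including
every marker-negative cell.  The batch pipeline therefore leaves it off by
default (`apply_bleed_correction=False`); enable it only for acquisitions
with strong marker bleed into the DAPI channel.

## Morphology

Per cell: area (pixel count × pixel size²), elongation (major/minor axis of
the same-second-moments ellipse), eccentricity (focal distance over major
axis of that ellipse), and circularity 4π·Area/Perimeter².  The perimeter
estimator is the one genuinely convention-dependent piece on a raster; the
Crofton 4-direction estimator is used because it is nearly unbiased on
discs (raster circularity 1.001–1.01 for radii 20–80 px, against ~0.93 for
chain-length counting), and its name is recorded in the run metadata.
Orientations are reported in degrees in [0, 180), 0° along +x,
counterclockwise on screen — the same axial convention used for striation
directions, so the misalignment angle is a plain fold of their difference
into [0, 90].

## Sarcomere texture analysis

The core statistic is a gray-level co-occurrence matrix (GLCM) computed
**inside the cell mask only**: for an integer displacement v, all pixel
pairs (p, p+v) with both members in the mask are accumulated into a g×g
matrix over g = 8 equal-width intensity bins spanning the in-mask min–max
range (2 bins for binary images), symmetrically (each pair counted both
ways) and normalized to probabilities.  Because pairing needs no bounding
box, irregular cell outlines contribute no edge artifacts — the decisive
advantage over window-based spectral methods.

Four Haralick features are read off each matrix:

* correlation  Σᵢⱼ (i−μᵢ)(j−μⱼ) p(i,j) / (σᵢσⱼ)
* contrast   Σᵢⱼ |i−j|² p(i,j)
* uniformity  Σᵢⱼ p(i,j)²
* homogeneity Σᵢⱼ p(i,j)/(1+|i−j|)

with μ, σ the marginal means and standard deviations.  A *variance* summary
(sum of contrast over the distinct unit displacements of the angle grid) is
close to zero for homogeneous regions.  A constant region has zero marginal
variance; its correlation is reported as undefined rather than coerced.

The **feature surface** samples a feature over 45 angles (0°–176°, 4°
steps; values repeat with period 180°) × 40 integer offset distances
(1–40 px).  At angle θ and distance d the displacement is
round(d·(−sin θ, cos θ)); each per-angle trace is then interpolated with a
cubic spline at 8× sub-pixel resolution — against the *exact projection* of
each rounded displacement onto the angle's axis, not the nominal d.  (The
rounding makes the true sample position differ from d by up to ~0.7 px
off-axis; plotting against d aliases off-axis traces into sawtooths whose
spurious spline peaks can out-prominence the true direction by two grid
steps.  The GLCM itself always uses exact integer displacements.)

On striated texture the correlation trace along the myofibril axis is a
decaying oscillation with peaks at multiples of the sarcomere spacing.  The
package reports:

* **sarcomere organization** — the maximum topographic peak prominence over
  all traces.  Prominence is used rather than raw peak height because it is
  baseline-free on a decaying trace; `mode="height"` implements the
  alternative reading.
* **primary sarcomere direction** — the angle of the winning trace, i.e. the
  periodicity axis (perpendicular to the Z-line stripes).
* **sarcomere length** — the offset of the winning peak × pixel size.
  Harmonics at k×period have numerically near-tied prominences; the
  earliest peak within 2% of the trace maximum is reported so the length
  names the fundamental, and `length_from_harmonic` flags the rare case
  where that peak is not the global maximum.
* **cell–sarcomere misalignment** — min(|Δ|, 180−|Δ|) between the striation
  direction and the cell's major axis, in [0, 90].

Length, direction and misalignment are suppressed when organization is at
or below 0.1 (configurable): below that level the winning peak reflects
incidental intensity structure and the derived length is meaningless.  For
the same reason the batch pipeline computes texture metrics only for
α-actinin⁺ cells — per-region min–max binning stretches the near-flat
background of a marker-negative cell into spurious smoothing-scale texture.

## Comparator metrics

*Gabor score*: filters at 10 log-spaced wavelengths (4–32 px) × 16
orientations (11.25° steps) are applied by FFT convolution to the
mean-subtracted image (low-frequency Gabor kernels have nonzero DC gain
that would otherwise score flat images); the in-mask mean response
magnitude versus wavelength is fitted per orientation to quadratic +
Gaussian (nonnegative amplitude, trust-region least squares, three starts
over the center), and the score is the maximum Gaussian height over
orientations.

*Fourier score*: the centered FFT magnitude spectrum of the cell's bounding
box is sampled along 360 one-degree rays and accumulated per radial
frequency bin (one sample wide).  Constant angular multiplicity keeps the
profile of a decaying spectrum decaying — a per-pixel bincount would grow
∝ r even for white noise, which the aperiodic model could not represent.
The profile is fitted to two exponentials + Gaussian (σ bounded at 0.06
cycles/px: a striation peak is narrow) and the score is the area under the
Gaussian.  When bound-pinned parameters leave no covariance estimate, a
linearized single-parameter standard error for the area is supplied so
"indistinguishable from zero" remains testable.

Because the Fourier score sees the bounding box, changing only the mask
outline changes it substantially while the mask-respecting correlation
score barely moves; the test suite demonstrates a >5× ratio of relative
changes on identical texture.

## Synthetic data

`make_stripes` renders rectangular bands (duty 0.5, levels 0.2/0.8,
1-px Gaussian edge softening; a sinusoidal profile is optional) at a given
period and periodicity direction, with optional additive clipped Gaussian
noise, partial coverage (stripes confined to a contiguous fraction of the
image along the periodicity axis), and per-band phase jitter over lateral
bands.  With no noise, jitter, or partial coverage the image is exactly
periodic, and regeneration at a rotated orientation matches rotating the
image (both are tested).

`make_sarcomere_phantom` is the canonical striation phantom: period 12.8 px
(2.0 μm at the default scale), lateral phase jitter of sd 2.5 px over bands
one period wide.  The jitter is not cosmetic: neighbouring myofibrils in
real cells register only approximately, and that lateral incoherence is
what makes the primary direction identifiable at all.  For a perfectly
coherent infinite stripe field, *every* sampling direction sees a periodic
correlation trace (of the projected period), so the direction of maximum
peak prominence is mathematically ill-posed; transverse decorrelation
breaks the tie in favour of the true axis.

`make_cell_field` lays out non-overlapping perturbed-ellipse cells
(semi-axes ~30–44 × 17–28 px) with 1 or 2 nuclei (binucleate centers 20 px
apart; nuclei of different cells kept ≥48 px apart so the 25-px join rule
cannot bridge cells), renders DAPI nucleus blobs (Gaussian, σ 4 px),
striped α-actinin texture along the cell's major axis (levels 0.55/0.9 —
Z-line striation rides a bright cytoplasmic baseline, and the watershed
needs the cell/background edge to dominate internal stripe ridges), filled
Hcn4, and perinuclear Nppa rings, then smooths (σ 1 px) and adds mild noise
(σ 0.01).  Marker flags per cell fully determine which channels carry
signal.

What the phantoms do **not** emulate: point-spread blur beyond Gaussian
smoothing, shot noise, uneven illumination, touching/overlapping cells,
out-of-focus debris, and partial marker expression within a cell.  Passing
the suite therefore shows the algorithms are implemented correctly and
behave as designed on controlled texture; it does not certify performance
on real micrographs with those artifacts.

## Numerical choices and degenerate inputs

* Otsu on a single-valued histogram → empty foreground (not an error).
* GLCMs with fewer than two valid pairs raise; in surfaces the entry
  becomes NaN without poisoning neighbours, and traces interpolate over the
  valid range only.
* Percentiles use linear interpolation between order statistics.
* Angle grid ties in the misalignment fold and near-tied harmonics resolve
  as described above; all tie-breaks are deterministic, and reruns with the
  same seed are byte-identical.
* Problem sizes used by the validation suite and the acceptance script —
  160² phantoms, a 512² ten-cell field, 20+20 discrimination phantoms —
  were chosen as the smallest at which the measured quantities are stable
  against the raster.

## Known limitations

* The organization score of highly periodic texture is bounded by the
  correlation range (prominence ≤ 2) and saturates near ~1.9 on clean
  phantoms; it is a ranking score, not a calibrated physical quantity.
* Sub-pixel length recovery degrades off the angle grid by the projection
  factor cos Δθ ≤ 1 (at most ~0.06% within a 4° grid — negligible against
  the ±0.5 px raster error).
* The strict "fully within" marker rule makes classification sensitive to
  single-pixel foreground erosion on very noisy data; `enclosure_fraction`
  exists for that case.
* Border-touching cells are flagged (`touches_border`), not dropped: their
  morphology is unreliable but their texture metrics remain valid.
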
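# Methods

This note documents the models, parameter choices and numerical details
behind the package, and what the synthetic phantoms do and do not
establish about real data.

## Depth geometry

The axial dimension is discretised into `n_pixels = 50` single-pixel
slabs of `Δ = 3.87 µm` (the instrument's maximum digital axial
resolution), spanning the ILM to 193.5 µm.  Depth-pixel indices are
1-based and inclusive; pixel `k` covers `((k−1)Δ, kΔ]`.  Printed
micrometre boundaries are `kΔ` rounded to 0.1 µm; pixel indices are
authoritative wherever a rounded value is ambiguous.

SMAS band `m` (1…12) covers pixels `4(m−1)+3 … 4(m−1)+6`: four-pixel
(≈15.5 µm) bands tiling pixels 3–50 with no gaps or overlaps.  Pixels 1–2
are excluded because the shallowest ~8 µm contain vitreous-interface and
glial artefact rather than bundles.  Detection uses the first
`analyzed_slabs = 7` bands (down to 116.1 µm); deeper bands are still
constructed for visualisation.  The five comparator schemes are fixed
catalogs of per-region bands (see `smas.depth.scheme_catalog`);
region-dependent composites are stitched along hard region-mask
boundaries with no feathering.

## Preprocessing

*Attenuation.* The depth-resolved single-scattering estimator
`μ_i = I_i / (2Δ Σ_{j>i} I_j)` converts intensities to an optical
property invariant to global signal scaling.  The last pixel, whose tail
sum is undefined, copies its anterior neighbour; a pixel with positive
intensity over an all-zero tail receives a configurable cap (default 1)
with a warning.

*Gamma and montage.* Each acquisition field is matched to the central
reference field with `out = in^γ`, `γ` = ratio of median intensities in
the overlapping region (per depth slice by default; a single whole-stack
γ is available).  Overlaps fuse by per-pixel maximum.  Registration
offsets are inputs; the package does not register images.

*Background and normalisation.* The background level is the mean
intensity of an 11 px window at the central raphe landmark, sampled at
the depth pixel containing 35 µm (`⌈35/Δ⌉` = pixel 10); values below the
level are set to zero (a threshold transformation, not a subtraction).
The window must sit inside the bundle-free raphe gap — a wider or more
fovea-proximal window overlaps temporal-macula bundles and contaminates
the level.  The stack is then divided by the mean of the per-depth 99th
percentiles (linear-interpolation sample quantile) and clipped to 1.

## Anatomic standardisation

Coordinates are (row, col), row increasing downward; right-eye format
places the ONH nasal (larger column) of the fovea.  The fovea–disc angle
is the signed angle of the fovea→ONH vector; the fovea–raphe angle is
the arithmetic mean of the five fovea→raphe-point slope angles.  Each
side of the fovea is sheared vertically by the negative of its angle
(`row' = row − tanθ·(col−col_f)`), identically at every depth; columns
never move, so horizontal distances (and hence the superpixel size rule)
are unaffected.  Interpolation is bilinear along rows; rows sheared in
from outside the canvas are zero-filled and excluded via a validity mask
that propagates to the superpixel stage (a padded superpixel is never
tested).  Angles of 45° or more are refused as degenerate.  Interpolation
and padding behaviour are configuration points; the defaults were chosen
so that zero-fill can never masquerade as a reflectance defect.

## Superpixel lattice and regions

`s = round(d/20)` (ties away from zero) with `d` the aligned fovea–ONH
column distance; the grid is anchored with the fovea at a cell centre
and the fovea–ONH axis along a lattice row.  Superpixel values are plain
means of constituent pixels; partial or partially-invalid cells are
flagged and excluded (`min_coverage = 0.999`).  Per-eye lattices are
re-indexed onto a fovea-centred window (rows ±10, columns −13…+27 in
superpixel units) so normative statistics pool cell-by-cell across eyes.

Named regions are defined in superpixel units relative to fovea and ONH
cells: ONH region = radius 6 around the ONH cell; temporal macula =
temporal cells within radius 10 of the fovea; raphe = temporal cells
beyond the macula within ±4 rows of the horizontal; central = remaining
cells within ±4 rows; the rest split by row into superior/inferior
nasal.  These radii are declared defaults (configurable), chosen to
resemble the published region sketches; they affect only the
region-dependent schemes, not SMAS, Hood or Deep.

## Normative model and deviation maps

Control distributions of superpixel intensity are frequently multimodal
or skewed at modest n, so limits of normality come from a Gaussian-KDE
fit rather than empirical order statistics.  Bandwidth is Silverman's
rule (`sd·(3n/4)^(−1/5)`, matching `scipy.stats.gaussian_kde`); the
density is evaluated on a 512-point grid over the data range padded by
three bandwidths, truncated to [0, 1] by renormalisation (intensities
are bounded); percentiles are read from the estimated CDF and are
monotone in level by construction.  Constant samples return the constant
at every level.

ROI censoring is two-stage, per slab: (1) candidate cells must reach a
*visibility floor* — 50% of the scheme-wide 95th-percentile control cell
mean — an automated stand-in for manually identifying regions with
visible bundles; (2) within candidates, cells below
`grand mean − 2.5·SD` of the per-cell control means are excluded for all
eyes.  The one-stage variant (candidates = all cells) fails structurally
on slabs whose cells are bimodal: the dark no-bundle mode inflates the
SD until nothing is excluded, and background-thresholded cells with
values hugging zero then enter the ROI, where the [0, 1] truncation
lifts the estimated 1st percentile above zero and misclassifies exact
zeros.  The scheme-wide (not per-slab) brightness reference matters for
multi-slab schemes: a slab containing no bundles at all must end with an
(almost) empty ROI rather than a dark-mode-relative one.  Cells with
fewer than `min_controls = 5` control observations are never tested.

Classification is strict: `below1` if value < p1, else `below5` if
< p5, else `below10` if < p10, else within normal limits; NaN or
out-of-ROI ⇒ untested.  The SMAS combined map marks a superpixel
abnormal when it is below the 1st percentile in at least one analysed
slab and tested when it is in at least one slab's ROI.  Outcome metrics:
proportion abnormal = abnormal/tested; median Euclidean distance of
abnormal cells from the ONH cell in superpixel units (undefined when
nothing is abnormal); surrogate false-positive rate = pooled proportion
of control superpixels below the 1st percentile.

## Phantoms

The phantom emulates the statistical structure the pipeline assumes:
per-region bundle depth extent (raphe 8, temporal macula 10, inferior
nasal 12, central/superior nasal 15, ONH region 21 depth pixels),
hypo-reflective deeper layers, a bright RPE from pixel 42, a raphe gap
(±1.5 superpixels), foveal dip, an ONH disc bright over bundle-bearing
depths only, a smooth eye-level multiplicative texture field **shared
across depth** (a bundle's reflectance varies together over the depths
it spans — this also keeps the combined map's false-positive behaviour
near the single-slab level instead of compounding across seven slabs),
and small independent per-depth Gaussian noise.  Stacks are built in the
aligned frame and mis-aligned by the inverse double shear, so the
alignment stage recovers the constructed geometry exactly; left eyes are
mirrored.

Geometry is parameterised in superpixel-equivalent units and is
therefore resolution independent.  The default cohort — 19 controls and
16 glaucomatous eyes, chosen to match the clinical study design this
package operationalises — uses 256×256 transverse pixels with
superpixel sizes 5–6 px, i.e. a ~1/3.5-scale retina that keeps the full
cohort pipeline under a minute on one CPU; instrument-scale eyes
(superpixel sizes 17–23 px) are obtained by raising `superpixel_px` and
`image_shape` together.  Glaucomatous eyes carry two arcuate defects
(superior and inferior; widths 25–45°, radial extent 2–9 superpixels
from the ONH, attenuation 0.45–0.7) confined by default to depth pixels
14–20 — a deep-defect scenario that shallow single-slab schemes are
geometrically unable to see.

What phantom results do **not** show: the phantom has no speckle, no
vessel shadows, no beam-incidence artefacts, no axial segmentation
error, and its between-eye variability is a single smooth texture field.
Passing the end-to-end tests demonstrates the pipeline's mechanics and
the depth-geometry argument for multi-slab analysis, not clinical
sensitivity or specificity.

## Known limitations

- KDE percentile limits fitted from ~19 controls are anti-conservative
  out of sample: a held-out healthy eye shows more than 1% of
  superpixels below the nominal 1st percentile (the training-control
  surrogate rate is exactly zero, as on clinical data, because the KDE
  limit lies below the training minimum).  Consequently some abnormal
  superpixels in test eyes are diffuse limit noise rather than defect;
  the acceptance script quantifies this as `localization_fraction`
  (~0.75 at the default conditions).  Age or axial-length covariate
  adjustment and multiplicity control across superpixels are out of
  scope, mirroring the method being implemented.
- The ROI visibility floor sits between the phantom's deep-layer and
  bundle reflectance levels; slabs whose cells straddle the floor can
  gain or lose ROI cells between cohorts.
- Region boundaries for the region-dependent comparator schemes are
  declared defaults, not inferred from the original publications.
- Field registration, B-scan segmentation and artefact adjudication are
  inputs, not computations.
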
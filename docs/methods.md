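# Methods

## The measurement problem

A budding-yeast cell's dry-mass density ρ (mg/ml of non-water content) can be
read out optically: the refractive index (RI) of cytoplasm rises linearly with
macromolecule concentration, n_cell = baseline + α·ρ, with refractive
increment α = 0.190 ml/g for proteins and nucleic acids. Quantitative phase
imaging measures, per pixel, the optical path difference (OPD) between light
through the sample and through a reference material:

    OPD(x, y) = (n_sample − n_reference) · d(x, y)

with d the geometric path length. `qpidense` implements the two referencing
modes this experiment needs and the inference built on top of them.

**Plate mode** (single cells in culture medium, reference n_media = 1.336):
cells are segmented from the phase image, each cell's height d_cell is taken
as the in-plane minor-axis length of its mask (prolate-ellipsoid assumption:
the vertical semi-axis equals the in-plane minor semi-axis), its OPD statistic
is the mean of the brightest 5% of in-mask pixels, and

    n_cell = n_media + OPD / d_cell.

**Chamber mode** (cells packed in an elastic PDMS microfluidic chamber,
reference n_PDMS = 1.405): the chamber-average OPD against the surrounding
PDMS is negative because the packed cells are optically rarer than PDMS, and

    n_cell(P) = n_PDMS + OPD(P) / d_chamber(P),

where P is the growth-induced pressure (GIP) the proliferating cells exert,
measured from the lateral wall deformation via k = 8.2 μm/MPa
(P = Δw / k). The pressure-dependent chamber height d_chamber(P) is
calibrated separately: chambers filled with culture medium are inflated with
known hydraulic pressures, each height is d = |OPD| / (n_PDMS − n_media), and
an ordinary-least-squares line d_chamber(P) = h₀ + s·P is fitted.

**Nominal intracellular osmotic pressure.** RI rises linearly with GIP.
Extrapolating the fitted line a + b·P down to the RI of water at 30 °C
(n_water = 1.332) gives the pressure at which the cell would be "empty" of
macromolecules and its osmotic pressure null; the nominal intracellular
osmotic pressure at zero GIP is

    Π_c0 = (a − n_water) / b,

reported with a 95% interval. Because ρ is an affine function of RI, fitting
density instead of RI yields the identical Π_c0 — this invariance is tested
exactly.

## Synthetic scenes as ground truth

The simulator replaces the microscope so every stage has an oracle.

*Plate scenes.* Cells are prolate ellipsoids with semi-axes a ≥ b = c, minor
axis vertical. Each pixel receives (ri − n_media) times the exact analytic
vertical chord through the ellipsoid at the pixel centre (no antialiasing; the
closed form is what makes tight recovery tolerances meaningful). Noise is
additive i.i.d. Gaussian on OPD in nm — a deliberate idealisation; real
quadriwave-interferometry maps carry spatially correlated background
gradients, which are emulated only as an optional low-order polynomial bias
surface (default off). Any stochastic render requires an explicit seed.

*Chamber scenes.* The interior is a uniform effective medium
φ·ri(P) + (1 − φ)·n_media at packing fraction φ, of height h₀ + s·P; the
PDMS frame renders as zero. φ defaults to 1 for P > 0 (chambers under GIP are
confluent by construction) and is configurable below 1 for P = 0 to reproduce
the documented underestimation of RI in loosely packed, unpressurised
chambers; those observations carry an `underestimated` flag and are excluded
from inference by default, with the plate-mode population RI entering the fit
as an ordinary anchor point at P = 0 instead.

*GFP stacks.* A labeled z-stack (0.5 μm step by default) spreads each cell's
total brightness uniformly over its footprint voxels on top of uniform
background and autofluorescence rates; a matched blank stack carries the
rates only. The corrected chamber total (raw sum minus
(background + autofluorescence)·n_pixels·n_z) recovers the brightness exactly
in the noiseless case. Corrected totals are never clipped; negative values
are flagged.

### Default study conditions

The generator's defaults reproduce the experiment's conditions: a plate
population of 91 cells with RI ~ N(1.384, 0.004²) and height (2b) ~
N(3.94, 0.50²) μm (in-plane aspect ratio uniform in [1.05, 1.6], orientation
uniform — values typical of budding yeast); a chamber of unpressurised height
9.2 μm; a 45-observation pressure series (3 unpressurised chambers at packing
fraction 0.8 plus an even spread up to 0.6 MPa) whose ground-truth RI–GIP
line is anchored at a true Π_c0 of 1.55 MPa; OPD noise 10 nm. Two values the
experiment does not pin down are package choices: the chamber-height
compliance, 0.5 μm/MPa (a few-percent height change over the GIP range,
consistent with a modest linear inflation), and the pixel size, 0.1 μm
(well below the ~4 μm cell scale; configurable, as is everything above, via
`RunConfig`).

## Numerical and design choices

*Otsu thresholding* is implemented directly (256 bins spanning the image
min–max; the split maximising the between-class variance ω₀ω₁(μ₀−μ₁)²; ties
break toward the lowest bin) and is verified in tests against an independent
exhaustive search and against scikit-image. Split points falling in an empty
histogram gap tie exactly; tests therefore compare the attained variance, not
the bin index.

*Mask refinement.* On a smooth ellipsoidal OPD profile the Otsu threshold
lands at roughly a third of the peak even without noise, so the raw Otsu mask
clips the cell rim and shrinks the minor axis — and hence inflates RI —
systematically. `segment_cells` therefore uses Otsu for detection and then
grows each detected region to its full connected support above a robust
background floor (background median + 3σ, σ estimated from the MAD of
sub-threshold pixels). Noiselessly the floor is zero and masks are exact;
at 10 nm noise the residual shrinkage is ~1%. Regions under 30 px (config)
are rejected as specks; touching mother/bud pairs are deliberately not split.

*Upper-5% statistic.* "Brightest 5%" is read as the mean of the top-5% pixels
(k = ⌈0.05·n⌉), falling back to the in-mask maximum below 20 px. The mean is
preferred over the 95th percentile for noise robustness. On an exact
ellipsoid profile the statistic is 0.981× the true peak OPD, so recovered RI
carries a known ≈ −9×10⁻⁴ bias, within the 2×10⁻³ recovery tolerance;
under noise the top-5% selection preferentially catches positive noise
excursions, a small upward bias visible in the pipeline's mean OPD statistic.

*Confidence intervals for Π_c0.* The estimate is a ratio of correlated OLS
estimates. Both a first-order delta method (normal interval from the
gradient-propagated covariance) and case-resampling bootstrap (percentile
interval; resamples with non-positive slope or a single distinct pressure are
discarded as uninformative; n_boot = 2000) are implemented; bootstrap is the
default for headline numbers and its seed is recorded in every report. On
well-conditioned synthetic data the two agree within 20% of interval width
(tested). Empirical coverage at the study noise level is ~0.89 over 100
replicates — the familiar mild undercoverage of the percentile bootstrap at
n ≈ 15 — inside the accepted [0.88, 0.99] band.

*Density baseline.* The conversion ρ = (n_cell − baseline)/α defaults to the
culture-medium baseline (1.336), the relation the plate-mode RI is referenced
to. A water baseline (1.332) is selectable (`density_baseline: water`),
because published population densities for these conditions are more
consistent with a water-referenced conversion; the package takes no position
and supports both.

*Units* are fixed in every schema — OPD nm, lengths μm, pressure MPa, density
mg/ml — and converted internally; an SI-vs-working-units audit test requires
agreement to 10⁻¹².

## What the synthetic tests do and do not show

Passing recovery and coverage tests demonstrate the analysis chain is
unbiased and correctly calibrated *under the simulator's assumptions*: exact
ellipsoidal cells, uniform intracellular RI, uncorrelated Gaussian OPD noise,
a perfectly uniform packed chamber, and a truly linear RI–GIP relation. They
do not validate segmentation against diffraction halos, vacuole/organelle RI
heterogeneity (visible in real single-cell OPD profiles), correlated
interferometric background, partial confluence at low positive GIP, or
departures from RI–GIP linearity outside the sampled 0–0.6 MPa range. The
extrapolation to n_water spans ~2.5× the measured pressure range; Π_c0
inherits any nonlinearity of the true relation, which no synthetic test can
exclude.

## Problem sizes

Default analyses use a 1280² px plate field (91 cells), 64² px chamber
frames (45 observations + 6 calibration points), 100 replicates × 15
chambers × 2000 bootstrap resamples for coverage, and 6 GFP stacks of
8 × 96² voxels — sizes chosen so the full suite and the reproduction script
each complete in seconds on one core while keeping discretisation error an
order of magnitude below the tested tolerances.
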
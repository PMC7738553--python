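# Methods

## Optical model

A single iridophore is modelled as a one-dimensional stack of k double
layers — crystalline β-guanine platelet (refractive index 1.83) over
aqueous cytoplasm (1.33) — between semi-infinite ambient media of index
1.0.  Each lossless layer carries the unimodular characteristic matrix

    m_j = [[cos β_j, −(i/η_j) sin β_j],
           [−i η_j sin β_j, cos β_j]],   β_j = (2π/λ) n_j d_j cos θ_j,

and the stack matrix M is the ordered product over the 2k layers.  The
default reflectance convention is the amplitude modulus

    R = |((m11 + m12) − (m21 + m22)) / ((m11 + m12) + (m21 + m22))|,

i.e. |r| with unity ambient/exit admittances at normal incidence.  A
conventional intensity reflectance |r|² sits behind the
`standard_intensity` flag; peak positions — the quantities all
downstream readouts use — are identical under both, so the choice only
rescales curve heights.  At oblique incidence the per-layer angle θ_j
follows Snell's law from the ambient, β_j gains the cos θ_j factor, the
admittances are η_s = n cos θ and η_p = n / cos θ, the ambient/exit
admittance is that of air at the incidence angle, and unpolarized
results average R_s and R_p.  Index dispersion is neglected and
interfaces are treated as parallel; disorder enters the model only
through the thickness distributions, not through platelet tilt.

Monte Carlo: a crystallotype's spectrum is the per-wavelength mean
reflectance of 500 independently sampled stacks.  The sampler draws the
crystal-layer count uniformly from the crystallotype's range and every
thickness from a normal distribution, rejection-resampled below a 5 nm
physical floor.  Rejection shifts the mean upward by 0.02 nm for the
ordered crystal distribution and 2.7 nm (<2%) for the worst case, the
disordered cytoplasm spacing; both bounds are asserted in tests against
the truncated-normal closed form.  Stacks are zero-padded to a common
layer count for vectorisation — a zero-thickness layer is exactly the
identity matrix, so padding is lossless.  In angle scans the same stack
ensemble is reused at every angle (the same cells viewed obliquely), so
the 0° column reproduces the normal-incidence simulation bit-for-bit.

### Parameters

| parameter | ordered (stripe) | disordered (interstripe) |
|---|---|---|
| crystal thickness (nm) | 27 ± 7 | 25 ± 8 |
| cytoplasm spacing (nm) | 131 ± 24 | 186 ± 81 |
| crystal layers | 20–30 (uniform) | 30–40 (uniform) |
| n crystal / cytoplasm | 1.83 / 1.33 | 1.83 / 1.33 |

The cytoplasm index is not a measured quantity; 1.33 (aqueous) is the
standard structural-colour assumption and is configurable.  The
distribution family (normal) is likewise a modelling choice — only the
means, SDs and ranges are measured.  Stacks begin with a crystal layer
and end with a cytoplasm layer, matching the k-double-layer product
j = 1…2k; beginning and ending with crystal would give an odd layer
count incompatible with that product, so the double-layer form is used.

The default wavelength grid is 380–780 nm at 1 nm — the visible portion
of the hyperspectral band.  Angle-dependence analyses extend the grid
down to 300 nm: at 60–70° the ordered Bragg peak physically sits near
330–355 nm, and on the default band its argmax would clip at the 380 nm
edge, turning monotonicity and range comparisons into measurements of
the band edge rather than of the cos θ dependence.

## Spectral readouts

Spectra are smoothed with a centred 3-point running average (shrinking
windows at the edges) before peak extraction, matching the smoothing
convention used for measured hyperspectral reflectance.  Peak ties
break toward the shortest wavelength (fixed, documented).  FWHM is
linear-interpolated at half the peak height; a side that never crosses
half-maximum is truncated at the band edge and flagged.  Because the
smoothed Monte Carlo mean spectrum has a broad, nearly flat plateau
around its Bragg peak, the argmax realisation jitters by a few nm
between seeds (±~5 nm at 500 runs); tests therefore assert stability of
the peak in the mean over seed families rather than per family.

Chromaticity uses the CIE 1931 2° observer represented analytically as
sums of piecewise Gaussians (the Wyman–Sloan–Shirley multi-lobe fit,
accurate to about 1% of peak), with each function area-normalised over
380–780 nm.  Equal areas are a defining property of the true 1931
observer, so the normalisation pins the equal-energy white point at
exactly (1/3, 1/3) while leaving other chromaticities within ~0.01 of
the published tables (verified in tests at a 450 nm band).  The default
illuminant is equal-energy, reporting intrinsic cell reflectance
colour; a "D65" option approximates daylight by a 6504 K Planckian
radiator rather than bundling the CIE daylight-component tables.  The
contrast metric is the Euclidean distance in (x, y) — deliberately
simple; no uniform-colour-space ΔE is attempted.

## Norepinephrine model

The quarter-wave relation λ = 2(n₁d₁ + n₂d₂) gives 447.2 nm at the mean
ordered geometry, consistent with the simulated ~450 nm blue peak.  NE
is modelled as a multiplicative dilation of the cytoplasm spacing mean
(SD scaled proportionally — constant coefficient of variation, the
simplest choice) with crystal thicknesses unchanged.  The post-NE
spacing is not a measured quantity anywhere in this pipeline: the
default factor 1.35 is **calibrated** so the analytic peak moves from
≈447 to ≈570 nm (inverting the relation at 570 nm gives 177.1 nm =
1.351 × 131 nm).  The disordered type's refractoriness is encoded
directly as dilation 1.0 rather than derived from an optical
insensitivity argument.  Only spacing changes are modelled; platelet
tilt or reorientation under NE is not.

## Cell-behaviour statistics

Division-plane angles are axial (mod 180°); they are doubled into
circular space, where the mean direction and resultant length are
computed and the Rayleigh test assesses uniformity (p-value via
`pingouin.circ_rayleigh`), then the mean is halved back to an axis.
The Rayleigh test is not prescribed by any measurement protocol here;
it is the standard choice for axial orientation data, and its type-I
error is calibrated by simulation in the test suite (2,000 uniform-null
replicates, 5 ± 1.5%).  The von Mises concentration estimate uses the
Best–Fisher approximation with the small-sample correction.

Migration bias takes each qualifying cell's net start-to-end
displacement (threshold: one nominal cell diameter, default 20 µm —
configurable, since the diameter is not a fixed constant) and reports
the mean dorsoventral component with a percentile bootstrap CI.  The
convention is x toward posterior, y dorsal; stripe cells moving away
from the first interstripe therefore have negative y displacement.
Proliferation is divisions per cell-hour per class with exact
(Garwood/chi-square) Poisson CIs and a score-method two-sample rate
ratio test (`statsmodels.stats.rates`).

The synthetic track generator emulates a 15 h movie at 5 min frames:
dense interstripe cells are near-static jitter walks (0.3 µm/frame SD)
whose divisions concentrate on the AP axis (doubled-angle von Mises,
κ = 4); loose stripe cells are random walks (1.5 µm/frame SD) with a
ventral drift (−0.3 µm/frame, ≈2.7 cell diameters over the movie) and
uniform division angles; divisions are Poisson-thinned at 0.01 (dense)
and 0.02 (loose) events per cell-hour — a 2× loose excess.  Rates,
drift and κ are plausibility choices (no published per-hour values
exist to copy) sized so that qualifying migrators and division counts
appear at realistic frequencies.  What the generator does *not*
emulate: lineage branching after division (daughters are not tracked as
new cells), cell–cell contact or crowding, the edge class's mixed
behaviour, and measurement noise in position or angle.  Passing
recovery tests therefore show the statistics are unbiased and
calibrated on clean tracks, not that they are robust to segmentation or
tracking artifacts in real imaging data.

## Numerical and design notes

- All randomness flows through `numpy.random.Generator` seeds; the
  pipeline fans a single seed into per-stage child seeds (below 2³¹)
  via `SeedSequence` with fixed stage keys, so stages re-run
  independently yet reproducibly, and every CLI/pipeline run writes a
  manifest with its config snapshot and output checksums.
- Unimodularity of every characteristic matrix (|det − 1| < 1e−9) and
  the closed-form k-pair quarter-wave Bragg reflectance ((ρ−1)/(ρ+1)
  with ρ = (n₁/n₂)²ᵏ, matched to 1e−8) anchor the matrix engine.
- The exact Mann–Whitney null is used for small samples (both n ≤ 20);
  large samples use the normal approximation.
- Degenerate inputs: empty stacks return the identity matrix and a
  zero spectrum; all-zero spectra yield a NaN "no peak" sentinel; zero
  division counts fall back to the exact one-sided Poisson bound.
- Test and acceptance problem sizes (runs per seed, seed counts,
  replicate counts) are chosen to keep the full suite in the
  few-minute range while leaving each stochastic assertion with a wide
  margin; the headline simulations always run at the full 500-run,
  1 nm-grid study conditions.

## Known limitations

- No absorption, birefringence, surface roughness or finite coherence
  length; platelet orientation disorder is not optically modelled.
- Whether the original reflectance convention was |r| or |r|², and its
  exit medium, is not documented; both conventions are provided and
  agree on every peak-based readout.
- The D65 option is a Planckian approximation, adequate for the
  qualitative contrast readouts it serves.
- The NE dilation factor is calibrated, not measured; conclusions that
  depend on the exact post-NE spacing should treat it as a free
  parameter.
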
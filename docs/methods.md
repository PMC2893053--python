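# Methods

## The measurement problem

Very small or dysmorphic ocular lenses (e.g. neonatal mice, cataract
models where the lens fragments on dissection) cannot be weighed
reliably. `lensmorph` instead estimates whole-lens volume, mass, and
shape from a single 2-D image of a mid-sagittal histological section —
the section through the optical axis that captures the maximal
equatorial diameter — under the assumption that the lens is rotationally
symmetric about its optical (anterior–posterior) axis.

## Pipeline

1. **Segmentation** (`image_io`). The input is either a pre-binarized
   mask image (foreground = lens tissue) or a grey/RGB micrograph that is
   globally thresholded (fixed threshold or Otsu; configurable
   foreground polarity, default dark-on-light). Cleanup keeps the
   largest 8-connected component and fills interior holes (4-connected
   background flood), so the subsequent edge filter sees only the outer
   capsule boundary. Interior voids in fixed sections are treated as
   processing artifacts: the capsule is taken as the true lens boundary.
2. **Frame placement** (`geometry`). In the default `vertical` mode the
   optical axis is the foreground-centroid column and the equatorial
   plane is the row of maximal foreground width (ties resolved at the
   midpoint). The `auto` mode first rotates the mask so that the
   principal direction of *smaller* extent — normally the optical axis,
   since lenses are wider at the equator — is vertical; severely
   axially-elongated lenses can invert this assumption, which is why
   `vertical` (trusting the operator's orientation) is the default.
3. **Boundary extraction**. Edge pixels are foreground pixels with at
   least one 8-neighbour in the background. On a binary mask this
   morphological inner boundary is exactly what an edge filter returns,
   with no threshold sensitivity.
4. **Half profiles**. The boundary is split at the axis into left and
   right halves (a pixel exactly on the axis belongs to both, so each
   half closes at the poles). Coordinates are converted to millimetres
   with the per-image pixels-per-mm calibration: x along the axis
   (anterior negative), y ≥ 0 the lateral distance from the axis.
   Each half is resampled to one point per image row, keeping the
   outermost edge pixel, so y(x) is single-valued.
5. **Volume, mass, diameter** (`morphometry`). Each half is integrated
   with the trapezoidal solid-of-revolution rule

       V = (π/2) · Σᵢ (xᵢ₊₁ − xᵢ)(y²ᵢ₊₁ + y²ᵢ),

   the discrete form of π∫y²dx, which tolerates irregular x spacing. The
   whole-lens volume is the mean of the two half volumes; averaging the
   halves cancels first-order errors from axis misplacement and mild
   asymmetry. If one half has fewer than two boundary points the other
   half is used alone and the result is flagged. Mass is volume ×
   density with a default homogeneous density of 1.0 g/ml (1 mm³ ↦
   1 mg); fixed-section estimates track dry weight, roughly 25% below
   fresh weight. Equatorial diameter is the foreground span along the
   equatorial row.
6. **Shape profile** (`shape_profile`). Boundary pixels are binned into
   360 one-degree sectors about the axis/equator intersection, angle
   measured from the anterior pole (0°) through the equator (90°) to the
   posterior pole (180°); the per-sector mean radius is recorded. The
   two lateral halves are additionally folded onto 0–180° (181 bins
   centred on integer degrees), and profiles from lenses of similar age
   and genotype are averaged sector-wise (lenses weighted equally;
   sectors absent in a lens are skipped, never zero-filled). Folding is
   applied per lens before group averaging; for symmetric lenses the
   order is immaterial.
7. **Statistics** (`stats`). Genotype groups within an age bin are
   compared with the heteroscedastic (Welch) two-sample t-test,
   two-sided, α = 0.05, no multiplicity correction by default (an
   optional Bonferroni flag exists). Agreement with an external growth
   reference (age vs dry weight table) is summarised as
   R² = 1 − SS_res/SS_tot of cohort masses about the *interpolated*
   reference curve — the reference is a fixed external curve, not a
   fitted model, so R² may be negative. A zero-variance cohort returns
   1 if it sits exactly on the curve and 0 otherwise.

## Numerical conventions

* **Integration form.** The revolution integral uses the summed-squares
  trapezoid `(y²ᵢ₊₁ + y²ᵢ)`. A difference form `(y²ᵢ₊₁ − y²ᵢ)`
  telescopes and collapses toward zero on closed profiles (exactly zero
  for a constant-radius profile); the test suite demonstrates this
  collapse explicitly.
* **Outer-boundary (pixel-area) convention.** Rasterized boundary pixels
  under-represent the continuous outline by half a pixel on average. All
  radial measures therefore refer to the outer side of the boundary
  pixel: resampled profile radii and polar profile radii add 0.5 px to
  the centre distance, and the diameter is the outer-pixel span + 1 px.
  This removes the systematic ~0.5 px/r bias (≈1.2% in volume for a 1 mm
  lens at 100 px/mm) without any sub-pixel interpolation; axial
  coordinates remain pixel centres. Residual volume error on noise-free
  phantoms is ≈0.03–0.15% at 50–100 px/mm.
* **Ties and degenerate inputs.** Width ties place the equator at the
  tying-row midpoint; a fractional equator row evaluates the diameter on
  both neighbouring rows and keeps the wider span. Masks thinner than
  3 px, empty/full threshold results, single-point halves, sub-2-lens
  samples, and zero-variance sample pairs raise typed errors
  (`DegenerateMaskError`, `InsufficientProfileError`,
  `InsufficientDataError`, `DegenerateVarianceError`).

## Phantom validation (`phantoms`)

Phantoms are rasterized outlines with closed-form ground truth captured
before degradation:

| shape | outline | volume |
|---|---|---|
| sphere | radius r | (4/3)πr³ |
| spheroid | axial a, equatorial b | (4/3)πab² |
| asymmetric | anterior half-ellipse a_ant ∪ posterior half-ellipse a_post, shared b | (2π/3)b²(a_ant + a_post) |

The asymmetric composite reproduces the dysmorphic phenotype signature
(anterior radius < posterior radius < equatorial radius) while keeping
all ground truth analytic. Degradations: per-degree Gaussian boundary
jitter (σ in px), circular interior voids, and a fragmenting cut; all
drawn from a single integer seed. Measured volume error grows
monotonically with jitter σ (≈0.03% at σ=0 to ≈5% at σ=4 px for a 1 mm
sphere at 100 px/mm).

An independent **voxel oracle** recomputes volume by counting voxel
centres inside the swept solid (per-row outermost extent revolved about
the axis, lattice counting at native resolution, two-half average). It
shares no code with the edge/trapezoid path and agrees with it to
≲0.05% on noise-free phantoms. Because the swept solid is axisymmetric,
voxel membership depends only on radial distance, so the angular sweep
is evaluated exactly rather than at a finite number of rotation steps.

Synthetic cohorts (`make_cohort`) sample per-lens semi-axes from normal
distributions around per-group means (default relative SD 6%). The
default study conditions follow murine lens biology: wild-type and
heterozygous groups near-spherical, growing from ≈0.65 mm radius at
6 days (≈1.1–1.2 mg fixed mass) to ≈1.1 mm at 300 days; the
homozygote-like group small (equatorial semi-axis ≈0.56 mm), anteriorly
flattened, and nearly flat with age.

**What the phantoms do and do not show.** Phantoms have perfectly known
geometry, sharp binary boundaries, and exact rotational symmetry about a
vertical axis. Passing the phantom suite demonstrates the correctness of
the geometry, integration, and statistics — it does not validate
segmentation of real stained tissue (staining variation, capsule
detachment, sectioning obliquity, true axial asymmetry), which remain
the user's responsibility via the pre-binarized input path.

## Problem sizes

The test suite and the acceptance script use phantoms at 25–200 px/mm
(lens radii 0.5–1.5 mm, i.e. masks up to ≈440×620 px), cohorts of
n = 10 lenses per group, and 200 re-seeded repetitions for the null
false-positive calibration; the whole validation completes in seconds on
one CPU. These sizes were chosen because the measured discretization
errors (≲0.3% at 25 px/mm) are already far inside the acceptance bands;
higher resolutions only shrink them further.

## Known limitations

* Rotational symmetry is assumed; strongly non-axisymmetric lenses bias
  the volume even after two-half averaging.
* No correction for sectioning obliquity or tissue shrinkage; fixed
  sections track dry weight.
* `auto` axis mode can flip anterior/posterior for lenses longer along
  the optical axis than across the equator; use `vertical` with oriented
  images when the phenotype is axially elongated.
* Global thresholding is a convenience, not a substitute for careful
  manual extraction on difficult histology.
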
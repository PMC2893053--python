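# lensmorph

Morphometry of ocular lenses from mid-sagittal histological section
images: whole-lens **volume**, **mass**, **equatorial diameter**, and
per-degree **radial shape profiles**, with Welch group statistics and a
synthetic-phantom validation suite.

## Why

Lenses from very young animals, or from cataract models in which the
lens is small, dysmorphic, or fragments during dissection, cannot be
weighed accurately. A mid-sagittal section — the slice through the
optical axis capturing the maximal equatorial diameter — contains enough
information to recover whole-lens geometry if the lens is treated as a
solid of revolution about its optical (anterior–posterior) axis.

Given the outer (capsule) boundary of the section, split along the
optical axis into two half-profiles with axial coordinate *x* and radius
*y(x)* (mm), each half yields

    V = (π/2) · Σᵢ (xᵢ₊₁ − xᵢ)(y²ᵢ₊₁ + y²ᵢ)

(the trapezoidal rule for π∫y²dx, tolerant of irregular point spacing),
and the whole-lens volume is the average of the two halves. Mass follows
from an assumed homogeneous density (default 1.0 g/ml, so mm³ ↦ mg;
fixed sections track *dry* weight). Lens shape is summarised as the mean
boundary radius in 360 one-degree sectors about the axis/equator
intersection, folded onto 0° (anterior pole) – 90° (equator) – 180°
(posterior pole). Genotype groups of similar age are compared with the
heteroscedastic (Welch) t-test at p < 0.05.

Because no reference micrographs ship with the package, correctness is
established on rasterized **phantoms** — spheres, spheroids, and
anterior/posterior-asymmetric composites with closed-form volume,
diameter, and polar radius — including noise models (boundary jitter,
interior voids, fragmentation) and an independent voxel-counting volume
oracle. See `docs/methods.md` for the full model description and
conventions.

## Worked example

Render three noisy asymmetric phantoms (anterior semi-axis 0.5 mm,
posterior 1.0 mm, equatorial 1.2 mm, 3% between-lens variation) and
measure them back:

```sh
lensmorph simulate --shape asymmetric --a-ant 0.5 --a-post 1.0 --b 1.2 \
    --px-per-mm 100 --n 3 --rel-sd 0.03 --genotype homozygous --age 6 \
    --seed 17 --out phantoms
lensmorph measure --manifest phantoms/manifest.csv --out results
```

`results/results.csv` then contains (alongside the analytic ground truth
written by `simulate` to `phantoms/ground_truth.csv`):

```
       lens_id  volume_mm3  mass_mg  equatorial_diameter_mm     (measured)
homozygous_000    4.455693 4.455693                    2.37
homozygous_001    4.226117 4.226117                    2.35
homozygous_002    4.448948 4.448948                    2.39

       lens_id  volume_mm3  equatorial_diameter_mm            (ground truth)
homozygous_000    4.456370                2.361122
homozygous_001    4.226566                2.341639
homozygous_002    4.450478                2.396267
```

Measured volumes agree with the closed form `(2π/3)b²(a_ant + a_post)`
to ≈0.02%, diameters to within one pixel (0.01 mm). The shape profile of
the same group,

```sh
lensmorph profile --manifest phantoms/manifest.csv --group-by genotype --out profiles
```

writes `profiles/group_homozygous.csv`, whose mean radius rises from
≈0.50 mm at 0° (the flattened anterior pole) to ≈1.2 mm at 90° (equator)
and ≈1.0 mm at 180° (posterior pole) — the quantitative signature of an
anteriorly flattened, posteriorly enlarged lens. `lensmorph compare
--results results/results.csv --bins 0-17,60-180,270-365` runs the
per-age-bin Welch comparisons between genotypes, optionally reporting R²
against a reference growth table (`--reference ref.csv` with
`age_days,weight_mg` columns).

The same functionality is available as a library:

```python
from lensmorph import PhantomSpec, render_phantom, find_axes, lens_volume

mask, truth = render_phantom(PhantomSpec.sphere(1.0, pixels_per_mm=100))
frame, mask = find_axes(mask)
res = lens_volume(mask, frame)
print(res.volume_mm3)   # 4.1899  (4π/3 ≈ 4.18879)
```

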
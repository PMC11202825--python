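# Methods

## Problem and quantities

Dural ectasia is quantified per vertebral level. For each level ℓ ∈
{L3, L4, L5, S1} the dural sac volume ratio is

    DSVR_ℓ = V_dural,ℓ / V_body,ℓ        (DSVR_S1 = V_dural,S1 / V_body,L5)

where V_dural,ℓ is the dural sac segment volume between the clipping
planes bounding level ℓ and V_body,ℓ the vertebral body volume. The
diameter ratio DSDR_ℓ = d_dural,ℓ / d_body,ℓ uses anteroposterior (AP)
diameters and extends up to L1. S1 scalloping is the mean of the S1
upper/lower endplate AP diameters minus the mid-body AP diameter
(positive = scalloped). BMI = weight/height², BSA (Du Bois) =
0.007184·kg^0.425·cm^0.725; BMI-corrected variables are plain quotients
value/BMI.

## Coordinate and rasterization conventions

Right-handed axes: x left→right, y posterior→anterior, z caudal→cranial;
AP measurements run along +y. Voxel centers sit at `index × spacing`; a
voxel belongs to a structure iff its center lies inside the analytic
surface. This makes voxel-count volumetry convergent: on the test
phantoms the volume error is ≤ 2% at 1 mm spacing and ≤ 0.5% at 0.5 mm.
Phantom structures are positioned at non-integer centers so analytic
boundaries do not coincide with voxel-center lattice planes, which would
otherwise create a one-layer counting degeneracy.

## Phantom geometry

Vertebral bodies are elliptic cylinders (AP semi-axis a along y, lateral
semi-axis b along x, height h) with optional parabolic concavity: the
semi-axes shrink by d·(1−ζ²), ζ = 2(z−c_z)/h, so cross-sections stay
elliptical and the volume has the closed form
π·h/2·[2ab − 4/3·(a·d_b + b·d_a) + 16/15·d_a·d_b]. Lateral concavity
models the waisted body shape; an AP concavity on S1 (default 2.5 mm)
models posterior scalloping, making the scalloping measurement
non-trivial (ground truth 2·d_a = 5 mm on the default phantom).

The dural sac is a tube whose horizontal cross-sections are circles of
radius r(z) centred on a sagittal centerline y(z); both are
piecewise-linear in z. The default profile tapers from 8 mm radius
cranially to ~4.5 mm at the sacrum with a ventrally convex lumbar bow.
Because cross-sections are horizontal circles, the exact volume between
horizontal planes is ∫π r(z)² dz (evaluated adaptively with the profile
breakpoints); for tilted planes a fine-grid oracle at spacing/4 is
provided instead. An ectasia factor f ≥ 1 multiplies r(z) caudal of the
L5/S1 disc, ramping in linearly across the disc gap to keep the surface
continuous.

Intensities are per-structure base signals (dural 1.0, bone 0.45,
background 0.05 in arbitrary units) with Rician noise
√((S+n₁)² + n₂²), n ~ N(0, σ), σ defaulting to 5% of the dural signal —
the magnitude-image noise model of MRI. The bundled threshold segmenter
(band threshold, largest connected components, hole filling) is
deliberately simple plumbing so image-domain stages can run from
intensities; it is not a model of any clinical segmentation algorithm.

`perturb_labels` emulates imperfect segmentation: each structure surface
is displaced along its normal by a smooth zero-mean Gaussian random
field (SD = noise in mm, correlation length 10 mm), implemented by
thresholding the signed Euclidean distance map at the field value;
overlap conflicts go to the structure with the smallest displaced
distance. The field is mean-zero, so perturbation is volume-neutral on
average while the per-seed absolute volume error grows with the noise
amplitude.

## Clipping planes and partition

For each adjacent vertebra pair the clipping plane passes through the
midpoint of the facing endplate centroids (extreme 2 mm voxel slab of
each body along the inter-centroid axis) with the inter-centroid
direction as normal, oriented cranially. Using the centroid axis rather
than a fitted endplate surface is a robustness choice: it is stable on
noisy masks and lands within 1 voxel and well under 2° of the true disc
mid-planes on phantoms. The outer planes sit half a disc gap outside the
outer endplates of L3/S1, the gap being estimated from the three
interior discs. How the clinical planes are oriented (disc-parallel vs
axis-orthogonal) is not standardised; the centroid-axis convention is
this package's choice.

Membership is half-open at voxel centers: a dural voxel at or below
exactly k of the five ordered planes belongs to segment k−1. For ordered
planes this equals "at/below the upper plane, strictly above the lower
plane", but it guarantees pairwise disjointness and exact cover of the
in-range dural voxels even for degenerate (crossing) plane
configurations, so volume conservation holds exactly by construction.

## Measurement conventions

AP diameters are read in the midsagittal slab (±1 voxel of the sagittal
plane through the structure centroid) within a 1-voxel slab of the
reference plane: the body-centroid level for vertebrae, the mid-plane
between the bounding clipping planes for dural segments, and 2 mm end
slabs for the S1 endplates; the diameter is the y-range plus one
spacing (a single voxel reads as one spacing). Diameters are therefore
quantization-limited to ±1 voxel, and scalloping — a difference of
three diameter reads — to ~1.5 voxels; tests assert volumes within 5%
of analytic truth but diameters/scalloping at the quantization floor.
mL↔mm³ uses a fixed factor of 1000; rounding (1 decimal mm/mL,
3 decimals for ratios/AUCs) happens only at report time.

## Cohort simulator

Each group (63 MFS / 81 non-MFS by default) is described by per-variable
(mean, SD) pairs taken from published group statistics for every
per-level dural/vertebral volume, diameter, ratio, the L5 nerve-root
sleeve diameter, S1 scalloping, height and weight. Marginals default to
a moment-matched lognormal (σ² = ln(1+(sd/mean)²), μ = ln(mean)−σ²/2)
for all measured quantities — they are strictly positive and
right-skewed, and the S1 ratios (e.g. DSDR 1.11 ± 0.68 vs 0.50 ± 0.14)
imply strong skew that a normal model cannot carry — and to a normal
truncated at zero for height/weight. Truncation is not re-standardised;
the resulting upward bias is < 2% of the mean whenever mean ≥ 2.5 SD,
which holds for every default variable except the MFS S1 ratios/volume
and scalloping (bias up to ~7%), which is one reason the lognormal is
the default for them. Variables are independent by default because no
inter-variable correlations are published; a Gaussian copula with a
user-supplied PSD correlation matrix is available. All sampling is
driven by one explicit seed; identical (specs, n, seed) give
byte-identical tables.

What the simulator does not model: within-patient consistency between
image-derived and tabular values, age/sex structure, and any real
correlation between levels. Passing diagnostics tests on simulated
cohorts therefore validates the statistical machinery and the published
summary statistics' implications, not the imaging pipeline on real
anatomy — that is what the phantom route is for, and conversely the
phantoms validate geometry, not population statistics.

## Diagnostics

Group comparisons use Welch's t (the group SDs differ several-fold at
S1, so pooled-variance t would be wrong; constant equal groups return
t = 0, p = 1). The empirical AUC is the Mann–Whitney estimator with
ties counted ½, computed via midranks and exactly equal to brute-force
pair counting; its 95% CI is DeLong's, degenerating to a point at
perfect separation or group size < 2. Closed-form AUCs use the binormal
formula, or the same formula after moment-matched log transform for the
lognormal family (exact by rank invariance of the AUC). Youden cut-offs
scan observed scores with "≥ cutoff ⇒ MFS" (all MFS group means exceed
the non-MFS means, so the positivity direction is fixed), breaking ties
toward the lowest cutoff; PPV/NPV use sample prevalence. McNemar
defaults to the exact binomial two-sided p on the discordant counts
(small counts are expected at n = 144); the continuity-corrected χ²
variant is available. The per-level report compares the correctness of
the Youden-dichotomized DSVR and DSDR classifications against the true
group — which specific classifications the clinical comparison used is
not fully standardised, so the report states this pairing. No
multiple-testing correction is applied (α = 0.05, two-sided).

## Problem sizes and numerical choices

The test suite uses a compact phantom (72×72×152 voxels, 20 mm bodies)
for most image-domain checks and a straight-anatomy phantom for the
closed-form tube/cylinder oracles; resolution-convergence tests
rebuild the compact phantom at 0.5 mm. Simulation-based checks use 500
cohorts of 63/81 for AUC recovery, 1000 for DeLong coverage (observed
95.0% against the nominal 95%, asserted at 93–97%), and 200 for the
Welch power check. The cut-off plausibility check evaluates the
specificity of the DSVR ≥ 0.25 rule on 200,000 simulated non-MFS
draws (model value ≈ 0.947); the corresponding sensitivity is
distribution-shape sensitive (lognormal model value ≈ 0.69) and is
reported descriptively, not asserted.

## Known limitations

- Clipping-plane orientation and AP-diameter loci are package
  conventions; real clinical measurements vary by institution.
- The phantom has no vertebral arches, nerve-root sleeves, meningoceles
  or bias fields, and its dural cross-sections are circular.
- The threshold segmenter is not robust to overlapping intensity
  distributions; it exists to close the image-route plumbing.
- Simulated cohorts inherit only first- and second-moment information
  (plus a chosen marginal shape) from the published groups; per-run
  orderings of near-tied AUCs are consequently unstable (see the
  README note on the one intentionally failing test).
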
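# Methods

This note documents the models, conventions and numerical choices behind
`synquant`. Coordinates are 0-based voxel indices in (t, z, y, x) order;
physical quantities are µm and seconds; CSV times are seconds relative to
tight cell coupling (t₀), negative before coupling.

## Synthetic acquisition model

The generator emulates spinning-disk confocal movies of a GFP-expressing
T cell conjugated to a non-fluorescent APC. Defaults follow the
acquisition protocol the pipeline is designed for: 21 z-sections at 1 µm
intervals every 20 s, 16-bit camera. The lateral pixel size is not fixed
by that protocol; the default of 0.25 µm resolves the 1.3 µm neck
criterion with at least five pixels.

Cells are spheres with a flattened contact disc: the T cell (default
radius 4 µm) sits above the APC (4.5 µm) along z, with the contact disc
(default radius 3 µm) in an xy plane — the interface is then sampled at
full lateral resolution and all ground-truth geometry is closed-form.
Couples either form instantly at a programmed contact frame or grow their
contact disc linearly over a few frames ("grow to full width"). Noise is
the standard camera model, `Poisson(scale·I)/scale + N(0, σ)` with
`poisson_scale` = 1 photon per intensity unit and σ = 2 on a cellular
background of 100 over a camera offset of 10. All randomness derives from
explicit seeds; equal specs give bit-identical volumes.

Pattern templates add a component of amplitude `contrast × background`
(contrast 2 by default) inside the T cell mask:

| pattern      | region (relative to interface of radius R, depth d behind it) |
|--------------|----------------------------------------------------------------|
| central      | r < 0.5 R, d ≤ ~1 µm (membrane-proximal focus)                 |
| invagination | r ≤ 1.6 µm tube, d ≤ ~2.4 µm (beyond the 1.5 µm depth rule)    |
| diffuse      | full disc, one plane deep (thin cortical film)                 |
| lamellal     | band of half-width 0.45 R across the disc, d ≤ ~1 µm           |
| peripheral   | annulus r ≥ 0.5 R through the shell depth                      |
| asymmetric   | 120° sector of that annulus                                    |

Template proportions were fixed by closed-form arithmetic so that every
accumulation pattern clears the 35% shell-mean rule at contrast 2: with
the camera offset included in the measured background, a pattern whose
enriched area covers a fraction *f* of the interface shell scores
`E ≈ 2f·B/(B+offset)`, so the rim sector needs ≥ 120° and the
invagination mouth a radius of 1.6 µm ("large, µm-scale") to count as
accumulation by the same rule that the classifier applies. The lamellal
template is a band rather than a full-depth disc because a slab covering
the entire interface at depth is geometrically indistinguishable from
diffuse accumulation.

Shape events reshape the T cell's solid-of-revolution radius profile:
`early_lamella(length L)` inserts a tapering stalk so the profile minimum
sits exactly at depth L (the taper is 25% so it survives voxelization);
`neck(position, width)` clamps the profile locally; and
`off_interface_protrusion(frame, length)` grows a thin lateral finger
from the cell equator from a given frame onward.

What the generator deliberately does not emulate: photobleaching, stage
drift, multi-couple fields, organelle texture, DIC image formation, and
partial-volume effects at cell boundaries (masks are binary before
noise). Passing tests therefore demonstrate correctness of the
measurement logic under the stated acquisition geometry and noise, not
robustness to every artifact of real microscopy.

## Couple tracking and t₀

Segmentation is Otsu thresholding per channel followed by largest
connected component and hole filling; the APC comes from its label
channel (without one the APC cannot be identified and the frame is
flagged). Contact voxels are T cell boundary voxels within one voxel of
the dilated APC (26-connectivity after one voxel of dilation, tolerant to
single-voxel segmentation gaps). The interface normal is the
smallest-variance principal axis of the contact voxels, oriented into the
T cell; the diameter is the largest pairwise distance of contact voxels
projected onto the interface plane (convex hull for speed).

Tight coupling t₀ is the earlier of (a) the first contact frame whose
diameter reaches 90% of the running maximum over the following 120 s and
(b) contact + ⌈40 s / frame interval⌉. The original full-width judgement
was made by eye; the 90%/120 s plateau rule is this package's documented
operationalization — robust to noise, with the window matching the
~2-minute signaling period the analyses focus on. Frames that fail
segmentation are carried by the nearest valid masks for tracking but
excluded from classification counts.

## Enrichment and pattern classification

The interface shell is the contact set dilated one voxel into the T cell.
The scalar enrichment is `E = mean(shell)/mean(background) − 1`, with the
background over T cell voxels excluding the shell and a cylindrical
invagination search region (radius 1.8 µm, depth 3 µm) under the
interface center, so a deep accumulation cannot suppress its own
reference. `E < 0.35` classifies the frame as no accumulation; exactly
0.35 counts as accumulation (the rule is "less than 35%"). Whether the
35% rule should use a shell mean or a peak statistic is a genuinely open
choice; the shell mean is used because it is stable under camera noise.

Above the gate, the enriched set A is all T cell voxels ≥ 1.35 × the
background mean (the same multiplicative cutoff as the scalar rule, for
single-threshold consistency), with connected components smaller than 4
voxels removed as noise. Depth statistics use the k-th deepest voxel
(k = 6) rather than the single deepest, so one stray noise voxel attached
to a large component cannot drag a film into the "slab" depth window.
Decisions run in fixed precedence — depth-based structures first, because
depth is the key discriminator between the central cluster (stays at the
interface) and the invagination (reaches µm deep):

1. **invagination** — the enriched component seeded under the interface
   center (seed radius 1 µm, depth ≤ 1.25 µm) reaches > 1.5 µm behind
   the interface plane;
2. **central** — the mass-weighted mean relative radius of the enriched
   shell mass is < 0.5 ("the centroid projects inside the central
   disc" — the radial mean is used rather than the vector centroid,
   which would be the disc center for any rotationally symmetric
   pattern including a rim annulus);
3. **peripheral** — ≥ 75% of enriched shell mass in the annulus
   (relative radius ≥ 0.5), angular coverage ≥ 180°, and projected
   coverage of the central disc ≤ 0.5 (a diffuse film covers the disc;
   a true ring spares it);
4. **asymmetric** — enriched shell mass spans < 180° of azimuth
   (coverage = 360° minus the largest empty gap over 24 bins of 15°,
   bins counted when holding ≥ 1% of the mass);
5. **lamellal** — the enriched slab's projected footprint covers ≥ 50%
   of the interface disc and its robust maximum depth lies in
   (0.5 µm, 2.5 µm];
6. **diffuse** — projected coverage ≥ 75% of both the central disc and
   the annulus; also the terminal fallback, guaranteeing totality.

Area coverages are measured on the 2D projection of the enriched set onto
the interface plane (cells of one pixel), not on raw shell-voxel counts:
at a 1 µm z-step the shell is two planes deep and a one-plane film could
otherwise never reach 75% coverage. All thresholds above are named
configuration parameters (`ClassifierParams`); they are re-derived
defaults of this package, not published constants, except the 35% rule,
the relative-radius-0.5 disc and the 1.5 µm depth.

Because enrichment is a ratio and every geometric rule operates on the
thresholded set, multiplying a volume by any positive constant changes no
label.

## Half-spheroid standardization

Each cell is rigidly rotated so the interface normal becomes the template
depth axis and the interface center a fixed landmark (single-landmark +
normal alignment; no azimuth reference exists, so azimuth is not
standardized and azimuthally asymmetric patterns land at arbitrary
template azimuth). Resampling is trilinear on an isotropic 0.5 µm grid;
an already-upright isotropic input passes through untouched.

The template is a half spheroid on a 64×64×32 (x, y, depth) grid — large
enough to resolve the relative-0.5 central core well. A template voxel at
relative depth ρ, relative radius and azimuth is sampled from the source
cell at depth ρ × (cell depth extent), at the same fraction of the
cross-section boundary radius at that depth and azimuth (72 azimuth bins
per slice, nearest-filled where a slice has no boundary voxel in a bin).
Before sampling, voxels outside the mask are filled with their nearest
in-mask intensity so that boundary interpolation does not dilute the rim.
Values are clipped at zero and normalized to sum 1: a uniform cell of any
shape maps to a uniform template (the testable null), and two cells that
differ only in scale map to the same distribution.

The interface enrichment region is the top 10% of voxels of the average
map over all cells and timepoints of an analysis batch (pooled across
conditions within the batch; per-condition pooling is a caller choice),
with ties at the cutoff broken by fixed grid order so the region size is
exactly ⌈0.1 N⌉. Enrichment ratio = mean(map | region) / mean(map |
template); central core ratio likewise over the cylinder of relative
radius and depth 0.5. The ratios recomputed through the full procedure
(region rebuilt from the analyzed maps) change by < 2% under rigid
rotation or sub-voxel translation of the input; a ratio against a region
frozen from *other* maps is not rotation-invariant for azimuthally
asymmetric patterns, which is inherent to the method, not an artifact.

## Morphometrics

The midline runs from the interface center to the posterior pole (the
mask voxel of maximal in-mask geodesic distance) as a minimum-cost
geodesic whose cost is low near the medial axis (1/(EDT + 0.5)), then
smoothed over ~1 µm; cell length is its arc length. Every mask voxel is
assigned to its nearest midline sample and each sample's diameter is the
maximal in-plane pairwise extent of its own bin — thin, unbiased
cross-sections (a slab-based measure systematically drags the neck
position toward the interface). Cell width is the profile maximum. A neck
is the narrowest interior profile point that is narrower than both the
interface diameter and the widest part beyond it; the lamella is scorable
only when the neck lies > 1.3 µm behind the interface, and then the
lamellal length is the interface-to-neck arc distance and the shape
factor its ratio to the interface diameter. Note that reliable neck
localization needs sub-µm sampling along the cell axis; on the default
1 µm z-step the profile is quantized to 1 µm along z, so quantitative
neck phantoms are generated at 0.5 µm z-steps or on isotropic grids.

Off-interface lamellae are residuals of a morphological opening of the
cell (ball radius 1 µm built in physical units): a residual counts when
its extent beyond the opened body exceeds 1.3 µm (reusing the lamella
length rule) and its base lies farther than one interface radius from
the interface center, so lamellae at the synapse itself are excluded.
This definition — opening residual, 1.3 µm, one-interface-radius
exclusion — is this package's reconstruction of an otherwise qualitative
notion.

Manual line annotations (CSV with endpoints in µm, up to four lines per
frame: interface diameter, cell width, lamellal length, cell length)
override the automatic measurements; the lamellal-length line doubles as
the neck distance and the > 1.3 µm rule is enforced on it.

## Cohort statistics

Timelines are aligned on a fixed −40 s … +420 s grid in 20 s steps;
couples lacking a timepoint contribute to neither numerator nor
denominator there. Dispersion defaults to the binomial standard error
√(p(1−p)/n); a per-experiment SEM mode (mean over per-experiment
percentages) is available when experiment identifiers are supplied —
which of the two a given published error bar represents is generally not
stated, so both are provided and neither claimed as canonical. The
central/invagination balance is log₂((k_c + ½)/(k_i + ½)) per timepoint
(Haldane–Anscombe continuity constant ½ keeps the curve finite at zero
counts; the constant cancels in the sign at equal n). Cumulative
off-interface curves count couples flagged at any time in (0, t].
Condition comparisons use the two-sided Fisher exact test per pattern per
timepoint — appropriate at cohort sizes of a few dozen couples — with
Holm adjustment within each pattern's time course.

## Problem sizes and determinism

The default test and acceptance workloads use 64×64×21 voxel frames,
cohorts of 50–500 couples for image-level checks and 10⁴ couples for
label-level frequency checks, and 500 replicate cohorts of 60 for
calibration — sizes chosen so the full suite runs in a few minutes on one
CPU while keeping binomial standard errors small against the tested
tolerances. Every stochastic component is driven by explicit seeds
(`numpy.random.SeedSequence`); pipeline CSVs are byte-identical across
reruns of the same configuration and seed.

## Known limitations

* The six-pattern geometric criteria are reconstructions with named
  parameters; absolute frequencies from real data will depend on them.
* Vesicular accumulation is not a class; frames with vesicle-like
  distributions will fall into the nearest geometric class.
* Segmentation is threshold-based and assumes a single bright T cell per
  field; crowded fields need external segmentation.
* The standardization assumes star-convex cross-sections about the
  per-slice centroid; strongly concave cells violate the radial mapping.
* The generator's cells are rotationally symmetric solids; classifier
  recovery on real, irregular cells is expected to be lower than on
  synthetic cohorts.
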
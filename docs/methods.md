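# Methods

## Volumetry model

A serial cryosectioning protocol keeps one section of thickness `t` and
discards `s` of tissue before the next kept section. The necrotic volume is
estimated by treating each kept section as representative of the slab it
heads: every section except the last contributes its necrotic area times
`t + s`, the last contributes area times `t` only,

    volume = Σ_{i=1..N−1} A_i (t + s) + A_N t,      depth = N t + (N − 1) s,

with defaults `t = 0.02 mm`, `s = 0.5 mm` (so `t + s = 0.52 mm` and
`depth(N) = 0.52 N − 0.5`). `N` counts every section whose measured necrotic
area exceeds an inclusion threshold (default 0.01 mm², suppressing speck
noise), contiguous or not — a literal reading of "number of sections
containing necrosis". The thickness-only weight is assigned to the **last**
section in sectioning order, a literal transcription of the formula as
printed; weighting the first section instead would change the volume by
`(A₁ − A_N) × s`, which is zero for symmetric lesions. All areas are pixel
counts times the pixel area; 1 mm³ ≡ 1 µL.

Hemi-cervix endpoints use a per-slice split: the horizontal line through the
area centroid of that slice's tissue mask, with "above" being lower row
indices (row 0 is rendered as the 12 o'clock side). Per-slice centroids are
robust to missing or damaged sections; a global reference-section centroid
would couple all slices to one section's segmentation quality.

## Segmentation

Two color rules, applied in sequence:

1. **Tissue vs background.** A pixel is background when its HSV value is at
   least `background_value_min` (default 0.86) *and* its saturation is at
   most `background_saturation_max` (default 0.16) — near-white and washed
   out. The complement is tissue, after (a) filling interior holes up to
   `max_hole_area_mm2` (default 0.5 mm²; the endocervical canal is far
   larger and is preserved) and (b) removing connected components below
   `min_component_area_mm2` (default 0.05 mm², dropping debris and
   background specks).
2. **Viable vs necrotic.** Within tissue, a pixel is viable when saturation
   ≥ `viable_saturation_min` (default 0.15) and the blue channel exceeds red
   by `blue_over_red_margin` (default 10/255) — the blue of the
   NADH-diaphorase viability stain. Everything else in tissue (gray/white:
   necrosis and polymer deposits) is necrotic. Necrotic components below
   `min_necrosis_component_mm2` (default 0.05 mm²) are reassigned to viable:
   these are resampling boundary pixels and staining noise of the kind the
   original manual workflow removed by hand.

Cleanup sizes are specified in mm² and converted through the calibration, so
behaviour is resolution-independent. The exact thresholds of the original
analysis are unrecorded; these defaults are calibrated against the phantoms
(see limitations). Manual corrections are modelled as declarative polygon
edits (`fill_hole`, `remove_region`, `reassign_to_necrosis`,
`reassign_to_viable`) applied in order, with the tissue = necrosis ∪ viable
partition re-validated after every edit, so a "semi-automated" session is a
replayable, auditable file. Sections whose tissue touches the image border
are kept and flagged in QC output, not clipped.

## Registration

Serial sections land on slides with arbitrary in-plane offset and rotation.
Alignment is rigid and **silhouette-driven**: the estimator maximizes tissue
mask IoU, which is insensitive to staining variation and sufficient for
volumetry (areas are preserved by rigid maps up to resampling). The search
is deterministic: translation initialized from the centroid difference, an
exhaustive rotation sweep over ±20° in 1° steps, local refinement to 0.1°
and a ±1.5 px translation grid at 0.5 px steps. Stacks are aligned by
chaining neighbor-to-neighbor estimates outward from a reference slice
(default: the middle slice), since adjacent sections are the most similar
pair; drift is bounded by the short stacks (~30–50 sections). Masks are
resampled nearest-neighbor (labels stay binary), images bilinearly. Empty
slices pass through with the identity transform and a QC flag.

## 3D reconstruction

Each aligned necrosis mask is extruded along z over the slab it represents
(`t + s`; the last section `t` only), so the occupied-voxel volume is
*identical to the volumetry formula by construction* — the package has one
volume definition, not two. Inter-slice interpolation was deliberately not
used: it would produce a second, slightly different volume with no recorded
procedure to anchor it. The z voxel size defaults to the section thickness
(0.02 mm divides 0.52 mm exactly). The 0.5-occupancy iso-surface is
extracted with marching cubes on the zero-padded grid (hence closed,
watertight meshes for solid lesions); an optional Gaussian pre-filter is for
visualization only, never volumetry. Meshes are in mm, z = 0 at the first
sectioned face, and export to binary PLY (default), STL, or OBJ. The
divergence-theorem volume of the mesh agrees with the formula volume to
well under 5% at the working resolutions and converges as pixels shrink; a
single voxel meshes to its inscribed octahedron (volume `dx·dy·dz/6`), the
expected marching-cubes behaviour at the voxel scale.

## Group comparison

Unpaired two-tailed two-sample t-tests, pooled-variance Student's by default
(the conventional reading of a generic "parametric unpaired t-test") with
Welch's available by flag; both accept raw values or per-group summary
statistics (mean, SD, n). No multiplicity correction is applied, matching
the original analysis. Degenerate inputs (n < 2, zero variance in both
groups) are rejected rather than returning NaN.

## Synthetic phantoms

The generator emulates what the downstream stages consume, not histology
per se: an elliptical cervix silhouette with a central canal hole, a solid
ellipsoidal or cylindrical lesion at a clock position, class-constant colors
(viable blue-dominant, necrosis light gray, background near-white) with
additive per-channel Gaussian noise, small gray background specks, optional
unstained holes inside viable tissue, and per-slice rigid jitter. Ground
truth (masks, areas, transforms, formula-true summary) is defined in the
unjittered frame and rasterized without anti-aliasing, so the truth is an
exact pixel count. Holes and specks are rendered but excluded from true
necrosis — they emulate the artifacts the original workflow removed
manually, and are handled by hole filling, component-size cleanup, and
replayable edits.

Deliberate choices:

- **Elliptical, not circular, silhouette** (default aspect 0.85). Real
  cervical cross-sections are not rotationally symmetric; a circular
  phantom would make rotation recovery ill-posed for silhouette-driven
  registration.
- **Study conditions as defaults.** The well-posed preset uses 30 sections,
  moderate noise (SD 6/255), jitter up to ±20 px and ±10°, and a 12 o'clock
  ellipsoidal lesion lying strictly inside the tissue annulus. Its ~19
  necrosis-bearing sections (~9.4 mm depth, ~85 µL) are a scaled-down
  working size chosen so a full multi-stack recovery suite remains quick on
  a laptop; the formulas are linear in N and areas, so recovery behaviour
  does not depend on lesion scale.
- **Phantom calibration 0.05 mm/px** (whole cross-section in a 320 px
  canvas). The default `StackGeometry` calibration is 0.004 mm/px, a
  placeholder for low-magnification microscopy: the true µm/px of the
  original images is unrecorded, so calibration is always explicit and
  configurable.

What the phantoms do **not** emulate: histological texture, stain gradients
and partial staining, tissue tearing and folding, out-of-plane distortion,
non-elliptical anatomy, and illumination fields. Passing recovery tests
therefore demonstrates correctness of the measurement pipeline under the
stated appearance model, not segmentation robustness on real slides — on
real data the color thresholds and edit files are expected to need tuning.

## Numerical choices and degenerate inputs

- Areas are exact pixel counts; no sub-pixel boundary estimation.
- Rasterization uses pixel-center inclusion; lesion cross-section area
  converges to the analytic value as pixel size shrinks (error at least
  halves per 2× refinement in tests).
- Empty inputs degrade gracefully: blank images give empty masks, empty
  stacks give zero summaries, empty grids give empty meshes; errors are
  reserved for contract violations (negative areas, non-RGB input, empty
  masks passed to registration, out-of-bounds edit polygons).
- Rigid transforms compose and invert in closed form; equality of
  `T⁻¹ ∘ T` with identity is exact to floating point.
- Reporting precision is 0.1 mm / 0.1 µL / 0.1 mm²; internal computation is
  double precision throughout.

## Known limitations

- The thickness-only weight's assignment to the last section and the
  per-slice centroid convention are plausible readings of an under-specified
  procedure; both are isolated behind single functions and configurable
  geometry.
- Registration is rigid only; real sections deform (stretch, tear, fold),
  which rigid IoU cannot model.
- Neighbor-chaining accumulates estimation drift on long stacks; for the
  ~30-section stacks used here the post-alignment tissue IoU against truth
  stays ≥ 0.97.
- The voxel z-resolution must divide both the slab and the thickness, which
  ties mesh resolution to the sectioning geometry.
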
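# necrovol

Quantification of ablation zones in serial histological sections of cervix.

Ablative therapies for cervical dysplasia — ethanol-based injectable ablation
and thermocoagulation among them — are evaluated histologically: the excised
cervix is cryosectioned serially, sections are stained with NADH-diaphorase
(viable tissue turns blue; necrotic tissue and polymer deposits remain
unstained, white or gray), and the necrotic region is measured section by
section. `necrovol` packages that workflow as a tested, scriptable pipeline
for anyone quantifying ablation zones from stained serial sections:

- **segmentation** — color-based separation of tissue from background and of
  necrotic from viable tissue, with hole filling, speck removal, and
  replayable polygon edits standing in for the manual corrections;
- **quantification** — per-slice necrotic/viable areas, necrotic depth and
  volume, hemi-cervix (top-half) variants, and unpaired two-tailed t-tests
  between treatment groups;
- **registration** — rigid (translation + rotation) alignment of serial
  sections by tissue-silhouette overlap;
- **3D reconstruction** — anisotropic voxel extrusion and marching-cubes
  surface meshes exportable to PLY/STL/OBJ;
- **synthetic phantoms** — stained-section image stacks with exact ground
  truth, so every stage is testable without real histology.

## The model

For a stack of `N` sections containing necrosis, cut at thickness `t`
(default 0.02 mm) with spacing `s` (default 0.5 mm) of tissue discarded
between kept sections, with `A_i` the necrotic area (mm²) of the *i*-th such
section:

```
volume = Σ_{i=1..N−1} A_i (t + s) + A_N t        [mm³ ≡ µL]
depth  = N t + (N − 1) s                          [mm]
```

Each section except the last represents a slab of `t + s` (0.52 mm at
defaults); the last represents its own thickness only. At the defaults,
`depth(N) = 0.52 N − 0.5`: a stack with necrosis in 50 sections is 25.5 mm
deep, in 25 sections 12.5 mm. Because a single injection targets the
12 o'clock position, the same endpoints are also computed for the top half of
each section, split at the horizontal line through the tissue centroid.

## Worked example

Run the full pipeline on a synthetic phantom (30 sections, moderate staining
noise, rigid jitter up to 20 px / 10°) and compare against its ground truth:

```python
import necrovol as nv

geom = nv.StackGeometry(pixel_size_mm=0.05)
config = nv.RunConfig(
    out_dir="demo",
    phantom=nv.well_posed_config(seed=42),
    geometry=geom,
)
report = nv.run_pipeline(config)
print("whole cervix :", report.summary)
print("top half     :", report.summary_top_half)
print("mesh volume  :", round(report.mesh_volume_uL, 1), "uL")

_, gt = nv.generate_phantom(nv.well_posed_config(seed=42), geom)
print("ground truth :", nv.ground_truth_summary(gt).rounded())

res = nv.compare_groups_from_stats(626.2, 122.8, 10, 1292.9, 242.3, 10)
print(f"t = {res.t:.3f}, df = {res.df:.0f}, p = {res.p:.2e}")
```

prints

```
whole cervix : NecrosisSummary(n_sections_with_necrosis=19, depth_mm=9.4, volume_uL=83.5)
top half     : NecrosisSummary(n_sections_with_necrosis=19, depth_mm=9.4, volume_uL=83.5)
mesh volume  : 84.7 uL
ground truth : NecrosisSummary(n_sections_with_necrosis=19, depth_mm=9.4, volume_uL=84.9)
t = -7.761, df = 18, p = 3.76e-07
```

The pipeline recovers the section count `N` exactly (hence the depth
exactly), the volume within ~2% despite noise and misregistration, and the
independently extracted surface mesh encloses a volume agreeing with the
slice-area formula. The top-half summary equals the whole-cervix summary here
because the simulated lesion sits entirely at the 12 o'clock position. The
t-test reproduces the headline group comparison of single-injection vs
whole-cervix thermocoagulation necrotic volumes (626.2 ± 122.8 vs
1292.9 ± 242.3 µL, n = 10 each): p < 0.0001.

The same stages are available as a CLI:

```
necrovol simulate --out stack --seed 42
necrovol segment --in stack --out masks
necrovol align --in masks --out aligned
necrovol quantify --masks masks --out quant
necrovol reconstruct --masks masks --out necrosis.ply
necrovol compare --a groupA.csv --b groupB.csv
necrovol run --config run.json
```

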
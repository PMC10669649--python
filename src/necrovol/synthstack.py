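"""Synthetic serial-section phantoms with exact ground truth.

The generator emulates NADH-diaphorase-stained cervical cross-sections:
an elliptical cervix silhouette with a central canal hole, blue-stained
viable stroma, an unstained (gray) necrotic lesion placed at a clock
position, near-white background, small background artifacts, optional
unstained holes inside viable tissue, per-channel Gaussian staining noise,
and per-slice rigid misregistration (jitter).  Every stack comes with exact
per-slice label masks, areas, injected transforms, and a formula-true
necrosis summary, so each downstream stage can be scored against truth.

Ground truth is defined in the unjittered frame; the rendered image is the
jittered one.  The outer silhouette is elliptical rather than circular —
real cervical cross-sections are not rotationally symmetric, and a circular
silhouette would make rotation recovery ill-posed for silhouette-driven
registration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

from .geometry import StackGeometry
from .quantify import NecrosisSummary, summarize
from .register import RigidTransform, apply_rigid
from .segmentation import LabelMasks, SectionImage


class GeometryError(ValueError):
    """Phantom geometry is inconsistent (e.g. lesion outside the canvas)."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LesionSpec:
    """Solid lesion: an ellipsoid or a cylinder in stack coordinates.

    The in-plane center sits ``radial_offset_mm`` from the cervix center in
    the ``clock_hours`` direction (12 = toward row 0, the top of the image).
    For a cylinder the cross-section is constant over slices
    ``z_start <= i < z_stop``; for an ellipsoid the in-plane semi-axes scale
    with distance from ``z_center_slice`` and vanish beyond
    ``semi_axis_z_mm``.  Zero semi-axes give an empty lesion.
    """

    shape: str = "ellipsoid"  # "ellipsoid" | "cylinder"
    semi_axis_x_mm: float = 2.2
    semi_axis_y_mm: float = 1.8
    clock_hours: float = 12.0
    radial_offset_mm: float = 3.5
    # ellipsoid axial extent
    z_center_slice: float = 14.0
    semi_axis_z_mm: float = 5.2
    # cylinder axial extent (slice index range, half-open)
    z_start: int = 0
    z_stop: int = 0

    def __post_init__(self) -> None:
        if self.shape not in ("ellipsoid", "cylinder"):
            raise ValueError(f"lesion shape must be 'ellipsoid' or 'cylinder', got {self.shape!r}")
        if self.semi_axis_x_mm < 0 or self.semi_axis_y_mm < 0 or self.semi_axis_z_mm < 0:
            raise ValueError("lesion semi-axes must be non-negative")

    def center_mm(self) -> tuple[float, float]:
        """In-plane center (x_mm, y_mm) relative to the cervix center."""
        angle = np.deg2rad(self.clock_hours / 12.0 * 360.0)
        return (
            float(self.radial_offset_mm * np.sin(angle)),
            float(-self.radial_offset_mm * np.cos(angle)),
        )

    def inplane_scale(self, slice_index: int, geometry: StackGeometry) -> float:
        """Scale factor for the in-plane semi-axes at a given slice."""
        if self.shape == "cylinder":
            return 1.0 if self.z_start <= slice_index < self.z_stop else 0.0
        if self.semi_axis_z_mm == 0:
            return 0.0
        dz = (slice_index - self.z_center_slice) * geometry.slab_mm
        u = 1.0 - (dz / self.semi_axis_z_mm) ** 2
        return float(np.sqrt(u)) if u > 0 else 0.0


@dataclass(frozen=True)
class StainColorModel:
    """Mean RGB per class plus per-channel Gaussian noise SD (0–255 scale)."""

    viable_rgb: tuple[int, int, int] = (60, 70, 170)
    necrosis_rgb: tuple[int, int, int] = (200, 198, 196)
    background_rgb: tuple[int, int, int] = (247, 247, 247)
    noise_sd: float = 6.0


@dataclass(frozen=True)
class PhantomConfig:
    """Full description of a synthetic stack; same config + seed ⇒ same bytes."""

    canvas_px: tuple[int, int] = (320, 320)  # (height, width)
    n_sections: int = 30
    cervix_outer_radius_mm: float = 6.5     # column semi-axis of the silhouette
    cervix_aspect: float = 0.85             # row semi-axis / column semi-axis
    canal_radius_mm: float = 1.5
    lesion: LesionSpec = field(default_factory=LesionSpec)
    colors: StainColorModel = field(default_factory=StainColorModel)
    artifact_count: int = 3
    artifact_radius_mm: tuple[float, float] = (0.06, 0.11)
    hole_count: int = 0
    hole_radius_mm: tuple[float, float] = (0.1, 0.25)
    jitter_max_shift_px: float = 0.0
    jitter_max_rotation_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sections < 1:
            raise ValueError("n_sections must be >= 1")
        if self.cervix_outer_radius_mm <= 0 or self.canal_radius_mm <= 0:
            raise ValueError("cervix and canal radii must be positive")
        if not self.canal_radius_mm < self.cervix_outer_radius_mm:
            raise GeometryError("canal radius must be smaller than the cervix outer radius")
        if not 0 < self.cervix_aspect <= 1.5:
            raise ValueError("cervix_aspect out of range")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        if "lesion" in d and isinstance(d["lesion"], dict):
            d["lesion"] = LesionSpec(**d["lesion"])
        if "colors" in d and isinstance(d["colors"], dict):
            c = dict(d["colors"])
            for k in ("viable_rgb", "necrosis_rgb", "background_rgb"):
                if k in c:
                    c[k] = tuple(c[k])
            d["colors"] = StainColorModel(**c)
        for k in ("canvas_px", "artifact_radius_mm", "hole_radius_mm"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class PhantomGroundTruth:
    """Exact truth for one synthetic stack, in the unjittered frame."""

    masks: list[LabelMasks]
    necrotic_areas_mm2: list[float]
    viable_areas_mm2: list[float]
    transforms: list[RigidTransform]
    summary: NecrosisSummary
    config: PhantomConfig
    geometry: StackGeometry


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def _grids_mm(canvas_px: tuple[int, int], geometry: StackGeometry):
    """Pixel-center coordinate grids in mm, origin at the canvas center."""
    h, w = canvas_px
    y = (np.arange(h) - (h - 1) / 2.0) * geometry.pixel_size_mm
    x = (np.arange(w) - (w - 1) / 2.0) * geometry.pixel_size_mm
    return np.meshgrid(y, x, indexing="ij")


def _ellipse_mask(yy, xx, cx, cy, ax, ay) -> np.ndarray:
    if ax <= 0 or ay <= 0:
        return np.zeros_like(yy, dtype=bool)
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0


def rasterize_lesion(
    lesion: LesionSpec,
    slice_index: int,
    canvas_px: tuple[int, int],
    geometry: StackGeometry,
) -> np.ndarray:
    """Boolean cross-section of the lesion at one slice (unclipped by tissue)."""
    yy, xx = _grids_mm(canvas_px, geometry)
    s = lesion.inplane_scale(slice_index, geometry)
    cx, cy = lesion.center_mm()
    return _ellipse_mask(yy, xx, cx, cy, lesion.semi_axis_x_mm * s, lesion.semi_axis_y_mm * s)


def _check_lesion_in_canvas(config: PhantomConfig, geometry: StackGeometry) -> None:
    h, w = config.canvas_px
    half_x = (w - 1) / 2.0 * geometry.pixel_size_mm
    half_y = (h - 1) / 2.0 * geometry.pixel_size_mm
    cx, cy = config.lesion.center_mm()
    if (
        abs(cx) + config.lesion.semi_axis_x_mm > half_x
        or abs(cy) + config.lesion.semi_axis_y_mm > half_y
    ):
        raise GeometryError("lesion extends outside the canvas")


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_phantom(
    config: PhantomConfig, geometry: StackGeometry = StackGeometry(pixel_size_mm=0.05)
) -> tuple[list[SectionImage], PhantomGroundTruth]:
    """Render a synthetic stack and its exact ground truth.

    Returns the rendered (jittered, noisy) section images and the
    :class:`PhantomGroundTruth` holding unjittered masks, true areas, the
    injected per-slice transforms, and the formula-true summary.
    """
    _check_lesion_in_canvas(config, geometry)
    rng = np.random.default_rng(config.seed)
    h, w = config.canvas_px
    yy, xx = _grids_mm(config.canvas_px, geometry)
    colors = config.colors

    outer = _ellipse_mask(
        yy, xx, 0.0, 0.0,
        config.cervix_outer_radius_mm,
        config.cervix_outer_radius_mm * config.cervix_aspect,
    )
    canal = _ellipse_mask(yy, xx, 0.0, 0.0, config.canal_radius_mm, config.canal_radius_mm)
    tissue = outer & ~canal

    images: list[SectionImage] = []
    gt_masks: list[LabelMasks] = []
    necrotic_areas: list[float] = []
    viable_areas: list[float] = []
    transforms: list[RigidTransform] = []

    for i in range(config.n_sections):
        lesion_xs = rasterize_lesion(config.lesion, i, config.canvas_px, geometry)
        necrosis = lesion_xs & tissue
        viable = tissue & ~necrosis
        masks = LabelMasks(tissue=tissue.copy(), necrosis=necrosis, viable=viable)
        masks.validate()
        gt_masks.append(masks)
        necrotic_areas.append(geometry.px_to_mm2(int(necrosis.sum())))
        viable_areas.append(geometry.px_to_mm2(int(viable.sum())))

        # clean render in the unjittered frame
        img = np.empty((h, w, 3), dtype=float)
        img[:] = colors.background_rgb
        img[viable] = colors.viable_rgb
        img[necrosis] = colors.necrosis_rgb

        # unstained holes inside viable tissue (not part of true necrosis)
        for _ in range(config.hole_count):
            r = rng.uniform(*config.hole_radius_mm)
            idx = np.nonzero(viable)
            if idx[0].size == 0:
                break
            k = rng.integers(idx[0].size)
            cy_mm, cx_mm = yy[idx[0][k], idx[1][k]], xx[idx[0][k], idx[1][k]]
            hole = _ellipse_mask(yy, xx, cx_mm, cy_mm, r, r) & tissue
            img[hole] = colors.background_rgb

        # small gray specks in the background
        for _ in range(config.artifact_count):
            r = rng.uniform(*config.artifact_radius_mm)
            cx_mm = rng.uniform(xx.min() + r, xx.max() - r)
            cy_mm = rng.uniform(yy.min() + r, yy.max() - r)
            speck = _ellipse_mask(yy, xx, cx_mm, cy_mm, r, r) & ~tissue
            img[speck] = colors.necrosis_rgb

        # rigid jitter of the rendered image (ground truth stays unjittered)
        if config.jitter_max_shift_px > 0 or config.jitter_max_rotation_deg > 0:
            t = RigidTransform(
                dx_px=float(rng.uniform(-config.jitter_max_shift_px, config.jitter_max_shift_px)),
                dy_px=float(rng.uniform(-config.jitter_max_shift_px, config.jitter_max_shift_px)),
                theta_deg=float(
                    rng.uniform(-config.jitter_max_rotation_deg, config.jitter_max_rotation_deg)
                ),
            )
        else:
            t = RigidTransform()
        transforms.append(t)
        # resample relative to the background color so out-of-canvas pixels
        # and canvas-edge blends stay background-colored
        bg = np.asarray(colors.background_rgb, dtype=float)
        img = apply_rigid(img - bg, t, interpolation="linear", cval=0.0) + bg

        if colors.noise_sd > 0:
            img = img + rng.normal(0.0, colors.noise_sd, size=img.shape)
        images.append(
            SectionImage(index=i, pixels=np.clip(img, 0, 255).astype(np.uint8),
                         geometry=geometry)
        )

    gt = PhantomGroundTruth(
        masks=gt_masks,
        necrotic_areas_mm2=necrotic_areas,
        viable_areas_mm2=viable_areas,
        transforms=transforms,
        summary=summarize(necrotic_areas, geometry),
        config=config,
        geometry=geometry,
    )
    return images, gt


def ground_truth_summary(
    gt: PhantomGroundTruth, geometry: StackGeometry | None = None
) -> NecrosisSummary:
    """Formula-true summary from the true per-slice areas (the oracle)."""
    return summarize(gt.necrotic_areas_mm2, geometry or gt.geometry)


def well_posed_config(seed: int = 0, noisy: bool = True, jittered: bool = True) -> PhantomConfig:
    """Preset used throughout testing: 30 sections, ellipsoidal 12 o'clock
    lesion inside the annulus, moderate noise, jitter within ±20 px / ±10°."""
    return PhantomConfig(
        canvas_px=(320, 320),
        n_sections=30,
        cervix_outer_radius_mm=6.5,
        cervix_aspect=0.85,
        canal_radius_mm=1.5,
        lesion=LesionSpec(
            shape="ellipsoid",
            semi_axis_x_mm=2.2,
            semi_axis_y_mm=1.8,
            clock_hours=12.0,
            radial_offset_mm=3.5,
            z_center_slice=14.0,
            semi_axis_z_mm=5.2,
        ),
        colors=StainColorModel(noise_sd=6.0 if noisy else 0.0),
        artifact_count=3 if noisy else 0,
        jitter_max_shift_px=20.0 if jittered else 0.0,
        jitter_max_rotation_deg=10.0 if jittered else 0.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Stack I/O (numbered PNGs + JSON sidecar; label masks as 8-bit PNG)
# ---------------------------------------------------------------------------

LABEL_BACKGROUND, LABEL_VIABLE, LABEL_NECROSIS = 0, 128, 255


def masks_to_label(masks: LabelMasks) -> np.ndarray:
    """Encode a partition as one 8-bit label raster (0/128/255)."""
    label = np.zeros(masks.tissue.shape, dtype=np.uint8)
    label[masks.viable] = LABEL_VIABLE
    label[masks.necrosis] = LABEL_NECROSIS
    return label


def label_to_masks(label: np.ndarray) -> LabelMasks:
    viable = label == LABEL_VIABLE
    necrosis = label == LABEL_NECROSIS
    return LabelMasks(tissue=viable | necrosis, necrosis=necrosis, viable=viable)


def save_stack(
    out_dir,
    images: Sequence[SectionImage],
    ground_truth: PhantomGroundTruth | None = None,
) -> Path:
    """Write numbered section PNGs plus a ``stack.json`` sidecar.

    With ground truth, also writes per-slice true label masks
    (``true_label_###.png``) and records geometry, config, injected
    transforms, and true areas in the sidecar.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for img in images:
        iio.imwrite(out / f"section_{img.index:03d}.png", img.pixels)
    sidecar: dict = {
        "n_sections": len(images),
        "geometry": images[0].geometry.to_dict() if images else {},
    }
    if ground_truth is not None:
        for i, m in enumerate(ground_truth.masks):
            iio.imwrite(out / f"true_label_{i:03d}.png", masks_to_label(m))
        sidecar["config"] = ground_truth.config.to_dict()
        sidecar["transforms"] = [t.to_dict() for t in ground_truth.transforms]
        sidecar["true_necrotic_areas_mm2"] = ground_truth.necrotic_areas_mm2
        sidecar["true_viable_areas_mm2"] = ground_truth.viable_areas_mm2
        sidecar["true_summary"] = ground_truth.summary.to_dict()
    with open(out / "stack.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return out


def load_stack(in_dir) -> tuple[list[SectionImage], StackGeometry]:
    """Read a saved stack (or any directory of numbered RGB sections)."""
    src = Path(in_dir)
    sidecar_path = src / "stack.json"
    geometry = StackGeometry()
    if sidecar_path.exists():
        with open(sidecar_path) as fh:
            sidecar = json.load(fh)
        if sidecar.get("geometry"):
            geometry = StackGeometry.from_dict(sidecar["geometry"])
    paths = sorted(
        p for p in src.iterdir()
        if p.suffix.lower() in (".png", ".tif", ".tiff")
        and not p.name.startswith("true_label")
    )
    images = [
        SectionImage(index=i, pixels=np.asarray(iio.imread(p)), geometry=geometry)
        for i, p in enumerate(paths)
    ]
    if not images:
        raise FileNotFoundError(f"no section images found in {src}")
    return images, geometry
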
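"""Semi-automated segmentation of NADH-diaphorase-stained cervical sections.

The viability stain turns metabolically active (viable) tissue blue, while
necrotic tissue and ethyl-cellulose deposits remain unstained and appear
white or gray.  Segmentation proceeds in two color-based stages:

1. :func:`segment_tissue` — separate tissue from the near-white background,
   fill small holes and drop small connected components (specks, debris);
2. :func:`separate_necrosis` — within the tissue mask, classify pixels as
   viable (blue-dominant, saturated) or necrotic (gray/white, unsaturated).

The manual corrections of the original workflow are reproduced as
declarative, replayable :class:`EditOp` polygons applied by
:func:`apply_edits`, so a "semi-automated" run is fully scriptable and
auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import polygon2mask
from skimage.morphology import remove_small_objects

from .geometry import StackGeometry

EditAction = Literal[
    "fill_hole", "remove_region", "reassign_to_necrosis", "reassign_to_viable"
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SectionImage:
    """One RGB section image with its position in sectioning order."""

    index: int
    pixels: np.ndarray  # (H, W, 3) uint8
    geometry: StackGeometry

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(
                f"SectionImage requires an (H, W, 3) RGB raster, got shape {px.shape}"
            )
        self.pixels = px


@dataclass
class LabelMasks:
    """Binary partition of one section into tissue = necrosis ∪ viable.

    Invariant (checked by :meth:`validate`): ``necrosis`` and ``viable`` are
    disjoint and their union is exactly ``tissue``.
    """

    tissue: np.ndarray
    necrosis: np.ndarray
    viable: np.ndarray

    def validate(self) -> None:
        for name in ("tissue", "necrosis", "viable"):
            m = getattr(self, name)
            if m.dtype != bool:
                raise ValueError(f"mask {name!r} must be boolean, got {m.dtype}")
        if not (self.tissue.shape == self.necrosis.shape == self.viable.shape):
            raise ValueError("masks must share one shape")
        if np.any(self.necrosis & self.viable):
            raise ValueError("necrosis and viable masks overlap")
        if not np.array_equal(self.necrosis | self.viable, self.tissue):
            raise ValueError("necrosis ∪ viable != tissue")

    def copy(self) -> "LabelMasks":
        return LabelMasks(self.tissue.copy(), self.necrosis.copy(), self.viable.copy())


@dataclass(frozen=True)
class EditOp:
    """A replayable manual correction: a polygon plus an action.

    ``region`` is a sequence of (row, col) vertices of a closed polygon in
    pixel coordinates; the polygon interior (inclusive of boundary pixels)
    is the edited region.
    """

    action: EditAction
    region: tuple[tuple[float, float], ...]
    slice_index: int = 0

    def __post_init__(self) -> None:
        if self.action not in (
            "fill_hole", "remove_region", "reassign_to_necrosis", "reassign_to_viable"
        ):
            raise ValueError(f"unknown edit action {self.action!r}")
        if len(self.region) < 3:
            raise ValueError("edit polygon needs at least 3 vertices")

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        verts = np.asarray(self.region, dtype=float)
        if (verts < -0.5).any() or (verts[:, 0] > shape[0] - 0.5).any() or (
            verts[:, 1] > shape[1] - 0.5
        ).any():
            raise ValueError("edit polygon extends outside the image bounds")
        return polygon2mask(shape, verts)

    def to_dict(self) -> dict:
        return {
            "action": self.action,
            "region": [list(v) for v in self.region],
            "slice_index": self.slice_index,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EditOp":
        return cls(
            action=d["action"],
            region=tuple(tuple(v) for v in d["region"]),
            slice_index=int(d.get("slice_index", 0)),
        )


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholds for the two color-based stages.

    Background: a pixel is background when its luminance exceeds
    ``background_value_min`` (scale 0–1) and its HSV saturation is below
    ``background_saturation_max``.  Viable: a tissue pixel is viable when its
    saturation is at least ``viable_saturation_min`` and its blue channel
    exceeds red by ``blue_over_red_margin`` (scale 0–1); otherwise necrotic.

    Hole filling and component removal are specified in mm² so behaviour is
    resolution-independent; they are converted to pixel counts through the
    stack geometry.
    """

    background_value_min: float = 0.86
    background_saturation_max: float = 0.16
    viable_saturation_min: float = 0.15
    blue_over_red_margin: float = 10.0 / 255.0
    max_hole_area_mm2: float = 0.5
    min_component_area_mm2: float = 0.05
    min_necrosis_component_mm2: float = 0.05

    def to_dict(self) -> dict:
        return {
            "background_value_min": self.background_value_min,
            "background_saturation_max": self.background_saturation_max,
            "viable_saturation_min": self.viable_saturation_min,
            "blue_over_red_margin": self.blue_over_red_margin,
            "max_hole_area_mm2": self.max_hole_area_mm2,
            "min_component_area_mm2": self.min_component_area_mm2,
            "min_necrosis_component_mm2": self.min_necrosis_component_mm2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentationParams":
        return cls(**d)


# ---------------------------------------------------------------------------
# Color helpers
# ---------------------------------------------------------------------------

def _rgb_to_value_saturation(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """HSV value and saturation on [0, 1] from a uint8 or float RGB raster."""
    x = np.asarray(rgb, dtype=float)
    if x.max(initial=0.0) > 1.0:
        x = x / 255.0
    cmax = x.max(axis=-1)
    cmin = x.min(axis=-1)
    sat = np.where(cmax > 0, (cmax - cmin) / np.where(cmax > 0, cmax, 1.0), 0.0)
    return cmax, sat


def _fill_small_holes(mask: np.ndarray, max_hole_px: int) -> np.ndarray:
    """Fill interior holes of at most ``max_hole_px`` pixels.

    A hole is a background component not connected to the image border; large
    holes (e.g. the endocervical canal) are preserved.
    """
    if max_hole_px <= 0:
        return mask
    holes, n = ndi.label(~mask)
    if n == 0:
        return mask
    border_labels = np.unique(
        np.concatenate([holes[0, :], holes[-1, :], holes[:, 0], holes[:, -1]])
    )
    counts = np.bincount(holes.ravel(), minlength=n + 1)
    fill = np.ones(n + 1, dtype=bool)
    fill[0] = False
    fill[border_labels] = False
    fill &= counts <= max_hole_px
    return mask | fill[holes]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def segment_tissue(
    image: SectionImage | np.ndarray,
    params: SegmentationParams = SegmentationParams(),
    geometry: StackGeometry | None = None,
) -> np.ndarray:
    """Segment tissue from the near-white background of one section.

    Steps: (1) classify background as bright *and* unsaturated pixels,
    (2) fill interior holes up to ``max_hole_area_mm2``, (3) remove connected
    components smaller than ``min_component_area_mm2``.

    Returns a boolean tissue mask.  A blank (all-background) image yields an
    empty mask rather than an error.
    """
    if isinstance(image, SectionImage):
        geometry = image.geometry
        pixels = image.pixels
    else:
        pixels = np.asarray(image)
        if geometry is None:
            geometry = StackGeometry()
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected an RGB image, got shape {pixels.shape}")

    value, sat = _rgb_to_value_saturation(pixels)
    background = (value >= params.background_value_min) & (
        sat <= params.background_saturation_max
    )
    tissue = ~background

    max_hole_px = int(round(params.max_hole_area_mm2 / geometry.pixel_area_mm2))
    tissue = _fill_small_holes(tissue, max_hole_px)

    min_comp_px = int(round(params.min_component_area_mm2 / geometry.pixel_area_mm2))
    if min_comp_px > 1:
        tissue = remove_small_objects(tissue, max_size=min_comp_px - 1)
    return tissue


def separate_necrosis(
    image: SectionImage | np.ndarray,
    tissue: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
    geometry: StackGeometry | None = None,
) -> LabelMasks:
    """Split a tissue mask into viable (blue-stained) and necrotic pixels.

    Within the tissue mask, a pixel is viable when it is blue-dominant
    (B − R ≥ margin) and sufficiently saturated; everything else in the mask
    is necrotic (unstained white/gray, which includes polymer deposits).
    Necrotic specks below ``min_necrosis_component_mm2`` — boundary pixels
    and staining noise, which the original workflow removed by hand — are
    reassigned to viable.  The partition invariant holds by construction.
    """
    if isinstance(image, SectionImage):
        geometry = image.geometry
        pixels = image.pixels
    else:
        pixels = np.asarray(image)
        if geometry is None:
            geometry = StackGeometry()
    x = pixels.astype(float)
    if x.max(initial=0.0) > 1.0:
        x = x / 255.0
    _, sat = _rgb_to_value_saturation(x)
    blue_dominant = (x[..., 2] - x[..., 0]) >= params.blue_over_red_margin
    viable = tissue & blue_dominant & (sat >= params.viable_saturation_min)
    necrosis = tissue & ~viable
    min_speck_px = int(round(params.min_necrosis_component_mm2 / geometry.pixel_area_mm2))
    if min_speck_px > 1:
        necrosis = remove_small_objects(necrosis, max_size=min_speck_px - 1)
        viable = tissue & ~necrosis
    masks = LabelMasks(tissue=tissue.astype(bool), necrosis=necrosis, viable=viable)
    masks.validate()
    return masks


def apply_edits(masks: LabelMasks, edits: Iterable[EditOp]) -> LabelMasks:
    """Apply manual-correction polygons in order, preserving the partition.

    Semantics per action (``poly`` = rasterized polygon interior):

    - ``fill_hole``: pixels in ``poly`` are added to tissue as viable
      (use a follow-up ``reassign_to_necrosis`` for necrotic fills);
    - ``remove_region``: pixels in ``poly`` are removed from all masks;
    - ``reassign_to_necrosis`` / ``reassign_to_viable``: tissue pixels in
      ``poly`` are moved to the requested class.

    Out-of-bounds polygons raise a ``ValueError`` naming the offending edit.
    """
    out = masks.copy()
    for i, edit in enumerate(edits):
        try:
            poly = edit.rasterize(out.tissue.shape)
        except ValueError as exc:
            raise ValueError(f"edit {i} ({edit.action}): {exc}") from exc
        if edit.action == "fill_hole":
            out.tissue |= poly
            out.viable |= poly & ~out.necrosis
        elif edit.action == "remove_region":
            out.tissue &= ~poly
            out.necrosis &= ~poly
            out.viable &= ~poly
        elif edit.action == "reassign_to_necrosis":
            sel = poly & out.tissue
            out.necrosis |= sel
            out.viable &= ~sel
        elif edit.action == "reassign_to_viable":
            sel = poly & out.tissue
            out.viable |= sel
            out.necrosis &= ~sel
        out.validate()
    return out


def render_labels(
    masks: LabelMasks,
    viable_rgb: Sequence[int] = (60, 70, 170),
    necrosis_rgb: Sequence[int] = (205, 203, 200),
    background_rgb: Sequence[int] = (247, 247, 247),
) -> np.ndarray:
    """Render a label partition back to a noise-free RGB preview image."""
    h, w = masks.tissue.shape
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = np.asarray(background_rgb, dtype=np.uint8)
    img[masks.viable] = np.asarray(viable_rgb, dtype=np.uint8)
    img[masks.necrosis] = np.asarray(necrosis_rgb, dtype=np.uint8)
    return img


def tissue_touches_border(masks: LabelMasks) -> bool:
    """QC flag: tissue touching the image border (section kept, not clipped)."""
    t = masks.tissue
    return bool(t[0, :].any() or t[-1, :].any() or t[:, 0].any() or t[:, -1].any())


# ---------------------------------------------------------------------------
# Edit-log persistence
# ---------------------------------------------------------------------------

def save_edits(edits: Sequence[EditOp], path) -> None:
    with open(path, "w") as fh:
        json.dump([e.to_dict() for e in edits], fh, indent=1)


def load_edits(path) -> list[EditOp]:
    with open(path) as fh:
        return [EditOp.from_dict(d) for d in json.load(fh)]
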
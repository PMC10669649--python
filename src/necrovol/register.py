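"""Rigid serial-section alignment.

Consecutive cryosections land on slides with arbitrary in-plane offset and
rotation, so before 3D reconstruction every section is brought into a common
frame with a rigid transform (translation + rotation; areas and distances
are preserved up to resampling).

Registration here is mask-driven: it maximizes the intersection-over-union
(IoU) of tissue silhouettes, which is robust to staining variation.  The
search is a centroid-difference translation initializer, a coarse exhaustive
rotation sweep, and local refinement of both rotation and translation.
Stacks are aligned by chaining neighbor-to-neighbor estimates outward from a
reference slice, since consecutive sections are the most similar pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi


class RegistrationError(ValueError):
    """Raised when registration is impossible (e.g. empty tissue masks)."""


@dataclass(frozen=True)
class RigidTransform:
    """In-plane rigid transform: rotation about the image center, then shift.

    Maps moving-frame pixel coordinates ``p = (row, col)`` to fixed-frame
    coordinates via ``R(theta) @ (p - c) + c + t`` where ``c`` is the image
    center (supplied at application time) and ``t = (dy_px, dx_px)``.
    Composition and inversion are exact and independent of ``c``.
    """

    dx_px: float = 0.0
    dy_px: float = 0.0
    theta_deg: float = 0.0

    @property
    def _rot(self) -> np.ndarray:
        th = np.deg2rad(self.theta_deg)
        c, s = np.cos(th), np.sin(th)
        return np.array([[c, -s], [s, c]])

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``first`` and then ``self``."""
        t = self._rot @ np.array([first.dy_px, first.dx_px]) + np.array(
            [self.dy_px, self.dx_px]
        )
        return RigidTransform(
            dx_px=float(t[1]), dy_px=float(t[0]),
            theta_deg=self.theta_deg + first.theta_deg,
        )

    def inverse(self) -> "RigidTransform":
        t = -self._rot.T @ np.array([self.dy_px, self.dx_px])
        return RigidTransform(
            dx_px=float(t[1]), dy_px=float(t[0]), theta_deg=-self.theta_deg
        )

    def is_near_identity(self, tol_px: float = 0.5, tol_deg: float = 0.1) -> bool:
        return (
            abs(self.dx_px) < tol_px
            and abs(self.dy_px) < tol_px
            and abs(self.theta_deg) < tol_deg
        )

    def to_dict(self) -> dict:
        return {"dx_px": self.dx_px, "dy_px": self.dy_px, "theta_deg": self.theta_deg}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(**d)


@dataclass(frozen=True)
class SearchParams:
    """Exhaustive-sweep parameters for :func:`estimate_rigid`."""

    theta_range_deg: float = 20.0
    theta_step_deg: float = 1.0
    theta_fine_step_deg: float = 0.1
    translation_refine_px: float = 1.5
    translation_step_px: float = 0.5


@dataclass
class AlignmentResult:
    """Per-slice transforms to the reference frame plus aligned rasters."""

    transforms: list[RigidTransform]
    ious: list[float]
    empty_slices: list[int]
    masks: list[np.ndarray] | None = None
    images: list[np.ndarray] | None = None
    reference: int = 0


def _center(shape: Sequence[int]) -> np.ndarray:
    return (np.asarray(shape[:2], dtype=float) - 1.0) / 2.0


def apply_rigid(
    raster: np.ndarray,
    transform: RigidTransform,
    interpolation: str = "nearest",
    cval: float = 0.0,
) -> np.ndarray:
    """Resample a raster under a rigid transform.

    Masks should use ``"nearest"`` so labels stay binary; RGB images
    ``"linear"``.  Pixels mapped from outside the canvas become ``cval``.
    """
    order = {"nearest": 0, "linear": 1}.get(interpolation)
    if order is None:
        raise ValueError(f"interpolation must be 'nearest' or 'linear', got {interpolation!r}")
    x = np.asarray(raster)
    was_bool = x.dtype == bool
    if was_bool:
        x = x.astype(np.uint8)
    c = _center(x.shape)
    t = np.array([transform.dy_px, transform.dx_px])
    rot_t = transform._rot.T
    offset = c - rot_t @ (c + t)
    if x.ndim == 2:
        out = ndi.affine_transform(x, rot_t, offset=offset, order=order, cval=cval)
    elif x.ndim == 3:
        out = np.stack(
            [
                ndi.affine_transform(x[..., k], rot_t, offset=offset, order=order, cval=cval)
                for k in range(x.shape[2])
            ],
            axis=-1,
        )
    else:
        raise ValueError(f"expected a 2D or 3D raster, got ndim={x.ndim}")
    return out.astype(bool) if was_bool else out


def _iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.count_nonzero(a & b)
    union = np.count_nonzero(a | b)
    return inter / union if union else 0.0


def _centroid(mask: np.ndarray) -> np.ndarray:
    idx = np.nonzero(mask)
    return np.array([idx[0].mean(), idx[1].mean()])


def estimate_rigid(
    fixed: np.ndarray,
    moving: np.ndarray,
    search: SearchParams = SearchParams(),
) -> tuple[RigidTransform, float]:
    """Estimate the rigid transform mapping ``moving`` onto ``fixed``.

    Both inputs are binary tissue masks (or rasters truthy inside tissue) of
    identical shape.  Returns ``(transform, iou)`` where ``iou`` is the
    tissue overlap achieved.  Raises :class:`RegistrationError` if either
    mask is empty.
    """
    f = np.asarray(fixed).astype(bool)
    m = np.asarray(moving).astype(bool)
    if f.shape != m.shape:
        raise RegistrationError(f"shape mismatch: {f.shape} vs {m.shape}")
    if not f.any() or not m.any():
        raise RegistrationError("cannot register empty tissue mask")

    c = _center(f.shape)
    cf, cm = _centroid(f), _centroid(m)

    def centroid_translation(theta_deg: float) -> np.ndarray:
        th = np.deg2rad(theta_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        return cf - c - rot @ (cm - c)

    def score(theta: float, t: np.ndarray) -> float:
        tr = RigidTransform(dx_px=float(t[1]), dy_px=float(t[0]), theta_deg=theta)
        return _iou(apply_rigid(m, tr), f)

    # coarse rotation sweep with centroid-matched translation
    thetas = np.arange(
        -search.theta_range_deg,
        search.theta_range_deg + search.theta_step_deg / 2,
        search.theta_step_deg,
    )
    coarse = [(score(th, centroid_translation(th)), th) for th in thetas]
    best_iou, best_theta = max(coarse, key=lambda x: x[0])

    # fine rotation sweep around the coarse optimum
    lo = best_theta - search.theta_step_deg
    hi = best_theta + search.theta_step_deg
    for th in np.arange(lo, hi + search.theta_fine_step_deg / 2, search.theta_fine_step_deg):
        s = score(th, centroid_translation(th))
        if s > best_iou:
            best_iou, best_theta = s, th

    # local translation refinement around the centroid initializer
    best_t = centroid_translation(best_theta)
    offsets = np.arange(
        -search.translation_refine_px,
        search.translation_refine_px + search.translation_step_px / 2,
        search.translation_step_px,
    )
    for dy in offsets:
        for dx in offsets:
            if dy == 0 and dx == 0:
                continue
            t = best_t + np.array([dy, dx])
            s = score(best_theta, t)
            if s > best_iou:
                best_iou, best_t = s, t

    transform = RigidTransform(
        dx_px=float(best_t[1]), dy_px=float(best_t[0]), theta_deg=float(best_theta)
    )
    return transform, best_iou


def align_stack(
    masks: Sequence[np.ndarray],
    images: Sequence[np.ndarray] | None = None,
    reference: int = 0,
    search: SearchParams = SearchParams(),
    image_cval: float = 255.0,
) -> AlignmentResult:
    """Align every slice of a stack to the reference slice's frame.

    Transforms are estimated between neighboring slices and chained outward
    from the reference; each slice's logged transform maps it directly into
    the reference frame.  A slice with an empty tissue mask is passed through
    with the identity transform and flagged; chaining skips over it.
    """
    n = len(masks)
    if n == 0:
        raise ValueError("empty stack")
    if not 0 <= reference < n:
        raise ValueError(f"reference index {reference} out of range for {n} slices")
    masks = [np.asarray(m).astype(bool) for m in masks]

    transforms: list[RigidTransform] = [RigidTransform() for _ in range(n)]
    ious: list[float] = [1.0] * n
    empty = [i for i in range(n) if not masks[i].any()]
    empty_set = set(empty)
    if reference in empty_set:
        raise RegistrationError(f"reference slice {reference} has empty tissue")

    for direction in (1, -1):
        anchor = reference  # nearest non-empty slice toward the reference
        rng = range(reference + direction, n if direction == 1 else -1, direction)
        for i in rng:
            if i in empty_set:
                continue
            try:
                step, _ = estimate_rigid(masks[anchor], masks[i], search)
            except RegistrationError as exc:
                raise RegistrationError(f"slice {i} vs {anchor}: {exc}") from exc
            transforms[i] = transforms[anchor].compose(step)
            ious[i] = _iou(apply_rigid(masks[i], transforms[i]), masks[reference])
            anchor = i

    aligned_masks = [apply_rigid(m, t) for m, t in zip(masks, transforms)]
    aligned_images = None
    if images is not None:
        aligned_images = [
            apply_rigid(np.asarray(img), t, interpolation="linear", cval=image_cval)
            for img, t in zip(images, transforms)
        ]
    return AlignmentResult(
        transforms=transforms,
        ious=ious,
        empty_slices=empty,
        masks=aligned_masks,
        images=aligned_images,
        reference=reference,
    )
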
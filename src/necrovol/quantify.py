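"""Per-slice areas, necrotic depth and volume, hemi-cervix variants, t-tests.

Volumetry treats each section except the last as representative of a slab of
``thickness + spacing`` (0.52 mm at defaults) and the last of its thickness
only:

    volume = Σ_{i=1..N−1} A_i × (t + s)  +  A_N × t        [mm³ ≡ µL]
    depth  = N × t + (N − 1) × s                            [mm]

where ``A_i`` is the necrotic area (mm²) in the *i*-th section containing
necrosis and ``N`` is the number of such sections.  At the default geometry
depth(N) = 0.52·N − 0.5.

Because a single injection targets the 12 o'clock position, the same
endpoints are also computed for the top half of each section: the tissue-mask
centroid defines a horizontal split line and only necrosis above it counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .geometry import StackGeometry
from .segmentation import LabelMasks

#: measured necrotic area below this is treated as speck noise when counting N
DEFAULT_INCLUSION_THRESHOLD_MM2 = 0.01


@dataclass
class SliceMeasurement:
    """Areas measured on one section (whole and top-half)."""

    slice_index: int
    necrotic_area_mm2: float
    viable_area_mm2: float
    top_half_necrotic_area_mm2: float = float("nan")
    tissue_centroid_row: float = float("nan")

    def __post_init__(self) -> None:
        if self.necrotic_area_mm2 < 0 or self.viable_area_mm2 < 0:
            raise ValueError("areas must be non-negative")


@dataclass(frozen=True)
class NecrosisSummary:
    """N (sections containing necrosis), depth in mm, volume in µL."""

    n_sections_with_necrosis: int
    depth_mm: float
    volume_uL: float

    def rounded(self, decimals: int = 1) -> "NecrosisSummary":
        """Summary at reporting precision (0.1 mm, 0.1 µL)."""
        return NecrosisSummary(
            self.n_sections_with_necrosis,
            round(self.depth_mm, decimals),
            round(self.volume_uL, decimals),
        )

    def to_dict(self) -> dict:
        return {
            "n_sections_with_necrosis": self.n_sections_with_necrosis,
            "depth_mm": self.depth_mm,
            "volume_uL": self.volume_uL,
        }


@dataclass(frozen=True)
class GroupComparison:
    """Unpaired two-tailed two-sample t-test result."""

    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    df: float
    p: float
    variant: str

    def to_dict(self) -> dict:
        return {
            "group_a": {"mean": self.mean_a, "sd": self.sd_a, "n": self.n_a},
            "group_b": {"mean": self.mean_b, "sd": self.sd_b, "n": self.n_b},
            "t": self.t,
            "df": self.df,
            "p": self.p,
            "variant": self.variant,
        }


# ---------------------------------------------------------------------------
# Area measurement
# ---------------------------------------------------------------------------

def slice_areas(
    masks: LabelMasks, geometry: StackGeometry, slice_index: int = 0
) -> SliceMeasurement:
    """Necrotic and viable areas of one section: pixel count × pixel area."""
    if geometry.pixel_size_mm <= 0:
        raise ValueError("pixel size must be positive")
    return SliceMeasurement(
        slice_index=slice_index,
        necrotic_area_mm2=geometry.px_to_mm2(int(masks.necrosis.sum())),
        viable_area_mm2=geometry.px_to_mm2(int(masks.viable.sum())),
    )


def top_half_areas(
    masks: LabelMasks, geometry: StackGeometry
) -> tuple[float, float]:
    """Necrotic area above the horizontal line through the tissue centroid.

    Returns ``(top_half_necrotic_area_mm2, centroid_row)``.  "Above" means
    lower row indices (row 0 is rendered as the 12 o'clock side).  An empty
    tissue mask has no centroid; the area is 0 and the centroid row NaN
    (callers flag this in QC output).
    """
    rows = np.nonzero(masks.tissue)[0]
    if rows.size == 0:
        return 0.0, float("nan")
    centroid_row = float(rows.mean())
    necrosis_rows = np.nonzero(masks.necrosis)[0]
    n_above = int((necrosis_rows < centroid_row).sum())
    return geometry.px_to_mm2(n_above), centroid_row


def measure_slice(
    masks: LabelMasks, geometry: StackGeometry, slice_index: int = 0
) -> SliceMeasurement:
    """Complete per-slice measurement including the hemi-cervix split."""
    m = slice_areas(masks, geometry, slice_index)
    top, centroid = top_half_areas(masks, geometry)
    m.top_half_necrotic_area_mm2 = top
    m.tissue_centroid_row = centroid
    return m


# ---------------------------------------------------------------------------
# Depth and volume formulas
# ---------------------------------------------------------------------------

def necrosis_volume(
    areas: Sequence[float], geometry: StackGeometry = StackGeometry()
) -> float:
    """Necrotic volume in µL from per-section areas in sectioning order.

    ``areas`` must contain only the sections counted as containing necrosis.
    Every section but the last is weighted by thickness + spacing; the last
    by thickness only (the printed constants 0.52 and 0.02 at defaults).
    """
    a = np.asarray(list(areas), dtype=float)
    if a.size == 0:
        return 0.0
    if np.any(a < 0):
        raise ValueError("necrotic areas must be non-negative")
    return float(a[:-1].sum() * geometry.slab_mm + a[-1] * geometry.section_thickness_mm)


def necrosis_depth(n_sections: int, geometry: StackGeometry = StackGeometry()) -> float:
    """Necrotic depth in mm from the count N of sections containing necrosis.

    depth = N × thickness + (N − 1) × spacing for N ≥ 1, and 0 for N = 0.
    """
    if isinstance(n_sections, float) and not float(n_sections).is_integer():
        raise ValueError(f"N must be an integer, got {n_sections!r}")
    n = int(n_sections)
    if n < 0:
        raise ValueError("N must be non-negative")
    if n == 0:
        return 0.0
    return n * geometry.section_thickness_mm + (n - 1) * geometry.section_spacing_mm


def summarize(
    areas: Sequence[float],
    geometry: StackGeometry = StackGeometry(),
    inclusion_threshold_mm2: float = DEFAULT_INCLUSION_THRESHOLD_MM2,
) -> NecrosisSummary:
    """N, depth and volume from per-slice necrotic areas (whole stack).

    A section counts toward N when its necrotic area exceeds the inclusion
    threshold (default 0.01 mm², suppressing speck noise); included sections
    need not be contiguous.  Only included areas enter the volume sum, in
    sectioning order.
    """
    a = np.asarray(list(areas), dtype=float)
    included = a[a > inclusion_threshold_mm2]
    n = int(included.size)
    return NecrosisSummary(
        n_sections_with_necrosis=n,
        depth_mm=necrosis_depth(n, geometry),
        volume_uL=necrosis_volume(included, geometry),
    )


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    variant: str = "pooled",
) -> GroupComparison:
    """Unpaired two-tailed t-test between two groups of raw values.

    ``variant`` is ``"pooled"`` (Student's, equal variances assumed; the
    default) or ``"welch"``.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    return compare_groups_from_stats(
        float(a.mean()), float(a.std(ddof=1)), a.size,
        float(b.mean()), float(b.std(ddof=1)), b.size,
        variant=variant,
    )


def compare_groups_from_stats(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    variant: str = "pooled",
) -> GroupComparison:
    """Unpaired two-tailed t-test from per-group summary statistics."""
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sd_a == 0 and sd_b == 0:
        raise ValueError("zero variance in both groups: t-test undefined")
    equal_var = {"pooled": True, "welch": False}.get(variant)
    if equal_var is None:
        raise ValueError(f"variant must be 'pooled' or 'welch', got {variant!r}")
    res = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=equal_var
    )
    if equal_var:
        df = float(n_a + n_b - 2)
    else:
        va, vb = sd_a**2 / n_a, sd_b**2 / n_b
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    return GroupComparison(
        mean_a=mean_a, sd_a=sd_a, n_a=n_a,
        mean_b=mean_b, sd_b=sd_b, n_b=n_b,
        t=float(res.statistic), df=df, p=float(res.pvalue), variant=variant,
    )
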
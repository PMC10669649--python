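"""Physical calibration of a serial-section stack.

All downstream conversions between pixels and physical units (mm², mm, µL)
pass through :class:`StackGeometry`.  The defaults describe cryosectioning at
20 µm section thickness with 500 µm discarded between consecutive kept
sections, imaged at a nominal 4 µm/pixel calibration.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class StackGeometry:
    """Stack calibration: section thickness, inter-section spacing, pixel size.

    Parameters
    ----------
    section_thickness_mm : float
        Physical thickness of each kept section (default 0.02 mm = 20 µm).
    section_spacing_mm : float
        Tissue discarded between consecutive kept sections
        (default 0.5 mm = 500 µm).
    pixel_size_mm : float
        In-plane edge length of one pixel (default 0.004 mm).

    Notes
    -----
    With the default thickness and spacing, each section except the last
    represents a 0.52 mm slab of tissue, which is the per-slice weight used
    in the volumetry formula.
    """

    section_thickness_mm: float = 0.02
    section_spacing_mm: float = 0.5
    pixel_size_mm: float = 0.004

    def __post_init__(self) -> None:
        for name in ("section_thickness_mm", "section_spacing_mm", "pixel_size_mm"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")

    @property
    def slab_mm(self) -> float:
        """Axial extent represented by one section: thickness + spacing."""
        return self.section_thickness_mm + self.section_spacing_mm

    @property
    def pixel_area_mm2(self) -> float:
        """Area of one pixel in mm²."""
        return self.pixel_size_mm**2

    def px_to_mm2(self, n_pixels: int | float) -> float:
        """Convert a pixel count to an area in mm²."""
        return float(n_pixels) * self.pixel_area_mm2

    def to_dict(self) -> dict:
        return {
            "section_thickness_mm": self.section_thickness_mm,
            "section_spacing_mm": self.section_spacing_mm,
            "pixel_size_mm": self.pixel_size_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StackGeometry":
        return cls(**{k: d[k] for k in (
            "section_thickness_mm", "section_spacing_mm", "pixel_size_mm") if k in d})
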
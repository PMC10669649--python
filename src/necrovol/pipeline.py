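"""End-to-end orchestration: simulate/load → segment → edit → align →
quantify → reconstruct, with every stage's artifacts persisted so each
number in the final report is recomputable from files on disk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import __version__
from .geometry import StackGeometry
from .quantify import (
    DEFAULT_INCLUSION_THRESHOLD_MM2,
    NecrosisSummary,
    measure_slice,
    summarize,
)
from .reconstruct3d import build_volume, export_mesh, extract_mesh
from .register import align_stack
from .segmentation import (
    LabelMasks,
    SegmentationParams,
    apply_edits,
    load_edits,
    segment_tissue,
    separate_necrosis,
    tissue_touches_border,
)
from .synthstack import (
    PhantomConfig,
    generate_phantom,
    label_to_masks,
    load_stack,
    masks_to_label,
    save_stack,
)

log = logging.getLogger("necrovol")


@dataclass
class RunConfig:
    """One document describing a full run.

    Exactly one of ``phantom`` (synthesize the input stack) or ``input_dir``
    (read numbered section images) must be set.
    """

    out_dir: str | Path
    phantom: PhantomConfig | None = None
    input_dir: str | Path | None = None
    geometry: StackGeometry = field(default_factory=StackGeometry)
    seg_params: SegmentationParams = field(default_factory=SegmentationParams)
    edits_path: str | Path | None = None
    align: bool = True
    reference: int | None = None  # None → middle slice
    make_mesh: bool = True
    inclusion_threshold_mm2: float = DEFAULT_INCLUSION_THRESHOLD_MM2
    seed: int | None = None  # overrides phantom.seed when set
    report_decimals: int = 1
    force: bool = False

    def __post_init__(self) -> None:
        if (self.phantom is None) == (self.input_dir is None):
            raise ValueError("exactly one of 'phantom' and 'input_dir' must be set")
        if self.input_dir is not None and not Path(self.input_dir).is_dir():
            raise FileNotFoundError(f"input directory not found: {self.input_dir}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        if "phantom" in d and d["phantom"] is not None:
            d["phantom"] = PhantomConfig.from_dict(d["phantom"])
        if "geometry" in d:
            d["geometry"] = StackGeometry.from_dict(d["geometry"])
        if "seg_params" in d:
            d["seg_params"] = SegmentationParams.from_dict(d["seg_params"])
        return cls(**d)


@dataclass
class RunReport:
    """Machine-readable result of one run; everything is also on disk."""

    per_slice_csv: str
    summary: NecrosisSummary
    summary_top_half: NecrosisSummary
    transform_log: str | None
    mesh_path: str | None
    mesh_volume_uL: float | None
    qc_flags: list[str]
    config_echo: dict
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "per_slice_csv": self.per_slice_csv,
            "summary": self.summary.to_dict(),
            "summary_top_half": self.summary_top_half.to_dict(),
            "transform_log": self.transform_log,
            "mesh_path": self.mesh_path,
            "mesh_volume_uL": self.mesh_volume_uL,
            "qc_flags": self.qc_flags,
            "config_echo": self.config_echo,
            "version": self.version,
        }


def _stage_done(stage_dir: Path) -> bool:
    return (stage_dir / ".done").exists()


def _mark_done(stage_dir: Path) -> None:
    (stage_dir / ".done").touch()


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages; stage outputs are reused on re-run unless ``force``.

    The reported summaries equal the volumetry formulas applied to the
    persisted per-slice CSV, and the run is deterministic given the seed.
    Any stage failure propagates with the stage name in the message; partial
    outputs are retained for debugging.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    qc_flags: list[str] = []
    geometry = config.geometry

    # --- stage: input -----------------------------------------------------
    input_dir = out / "input"
    if config.phantom is not None:
        phantom_cfg = config.phantom
        if config.seed is not None:
            phantom_cfg = PhantomConfig.from_dict(
                {**phantom_cfg.to_dict(), "seed": int(config.seed)}
            )
        if config.force or not _stage_done(input_dir):
            images, _gt = generate_phantom(phantom_cfg, geometry)
            save_stack(input_dir, images, _gt)
            _mark_done(input_dir)
        images, geometry = load_stack(input_dir)
    else:
        images, geometry = load_stack(config.input_dir)
    n = len(images)
    log.info("input: %d sections", n)

    # --- stage: segmentation (+ edits) ------------------------------------
    seg_dir = out / "segmented"
    seg_dir.mkdir(exist_ok=True)
    edits = load_edits(config.edits_path) if config.edits_path else []
    masks_list: list[LabelMasks] = []
    if config.force or not _stage_done(seg_dir):
        for img in images:
            try:
                tissue = segment_tissue(img, config.seg_params)
                masks = separate_necrosis(img, tissue, config.seg_params)
                slice_edits = [e for e in edits if e.slice_index == img.index]
                if slice_edits:
                    masks = apply_edits(masks, slice_edits)
            except Exception as exc:
                raise RuntimeError(f"segmentation failed at slice {img.index}: {exc}") from exc
            if tissue_touches_border(masks):
                qc_flags.append(f"slice {img.index}: tissue touches image border")
            if not masks.tissue.any():
                qc_flags.append(f"slice {img.index}: empty tissue mask")
            iio.imwrite(seg_dir / f"label_{img.index:03d}.png", masks_to_label(masks))
            masks_list.append(masks)
            log.info(
                "segment: slice %d necrosis_px=%d viable_px=%d",
                img.index, int(masks.necrosis.sum()), int(masks.viable.sum()),
            )
        _mark_done(seg_dir)
    else:
        for i in range(n):
            label = np.asarray(iio.imread(seg_dir / f"label_{i:03d}.png"))
            masks_list.append(label_to_masks(label))

    # --- stage: alignment --------------------------------------------------
    transform_log_path: str | None = None
    if config.align and n > 1:
        reference = config.reference if config.reference is not None else n // 2
        try:
            result = align_stack(
                [m.tissue for m in masks_list],
                images=None,
                reference=reference,
            )
        except Exception as exc:
            raise RuntimeError(f"alignment failed: {exc}") from exc
        aligned: list[LabelMasks] = []
        for m, t in zip(masks_list, result.transforms):
            from .register import apply_rigid

            am = LabelMasks(
                tissue=apply_rigid(m.tissue, t),
                necrosis=apply_rigid(m.necrosis, t),
                viable=apply_rigid(m.viable, t),
            )
            # nearest resampling can disagree at class boundaries; repair
            am.viable = am.tissue & ~am.necrosis
            am.necrosis = am.tissue & am.necrosis
            am.validate()
            aligned.append(am)
        masks_list = aligned
        for i in result.empty_slices:
            qc_flags.append(f"slice {i}: empty tissue, passed through unaligned")
        tlog = {
            "reference": result.reference,
            "transforms": [
                {**t.to_dict(), "iou": iou}
                for t, iou in zip(result.transforms, result.ious)
            ],
        }
        transform_log_path = str(out / "transforms.json")
        with open(transform_log_path, "w") as fh:
            json.dump(tlog, fh, indent=1)
        for i, (t, iou) in enumerate(zip(result.transforms, result.ious)):
            log.info("align: slice %d dx=%.2f dy=%.2f theta=%.2f iou=%.4f",
                     i, t.dx_px, t.dy_px, t.theta_deg, iou)

    # --- stage: quantification ---------------------------------------------
    rows = []
    for i, m in enumerate(masks_list):
        meas = measure_slice(m, geometry, slice_index=i)
        if np.isnan(meas.tissue_centroid_row):
            qc_flags.append(f"slice {i}: no tissue, centroid undefined")
        rows.append(
            {
                "slice_index": meas.slice_index,
                "necrotic_area_mm2": meas.necrotic_area_mm2,
                "viable_area_mm2": meas.viable_area_mm2,
                "top_half_necrotic_area_mm2": meas.top_half_necrotic_area_mm2,
                "centroid_row": meas.tissue_centroid_row,
            }
        )
    df = pd.DataFrame(rows)
    csv_path = out / "slices.csv"
    df.to_csv(csv_path, index=False)
    summary = summarize(
        df["necrotic_area_mm2"], geometry, config.inclusion_threshold_mm2
    )
    summary_top = summarize(
        df["top_half_necrotic_area_mm2"].fillna(0.0),
        geometry,
        config.inclusion_threshold_mm2,
    )

    # --- stage: reconstruction ---------------------------------------------
    mesh_path: str | None = None
    mesh_volume: float | None = None
    if config.make_mesh:
        try:
            grid = build_volume([m.necrosis for m in masks_list], geometry)
            mesh = extract_mesh(grid)
            mesh_path = str(out / "necrosis.ply")
            export_mesh(mesh, mesh_path)
            mesh_volume = mesh.enclosed_volume_uL()
        except Exception as exc:
            raise RuntimeError(f"reconstruction failed: {exc}") from exc

    report = RunReport(
        per_slice_csv=str(csv_path),
        summary=summary.rounded(config.report_decimals),
        summary_top_half=summary_top.rounded(config.report_decimals),
        transform_log=transform_log_path,
        mesh_path=mesh_path,
        mesh_volume_uL=mesh_volume,
        qc_flags=qc_flags,
        config_echo={
            "geometry": geometry.to_dict(),
            "seg_params": config.seg_params.to_dict(),
            "align": config.align,
            "inclusion_threshold_mm2": config.inclusion_threshold_mm2,
            "seed": config.seed,
        },
    )
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)
    return report
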
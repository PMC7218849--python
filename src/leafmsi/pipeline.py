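"""End-to-end processing of one scene: calibrate → segment → spatial
calibration → rotate → petiole removal → features → sections → venation.

Undistortion is applied to the segmented stack (calibration, then
segmentation, then spatial calibration), with bilinear resampling for the
intensity bands and nearest-neighbour for the mask.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as msio
from .calibrate import CalibrationBundle, spectral_calibrate, undistort
from .features import (
    PREVIEW_SIZE,
    ColorFeatures,
    MorphFeatures,
    color_features,
    morphological_features,
    ndvi_preview,
)
from .sections import SectioningParams, section_leaf
from .segment import (
    SegmentationParams,
    SegmentedLeaf,
    compute_ndvi,
    remove_petiole,
    rotate_to_horizontal,
    threshold_segment,
)
from .stack import CalibratedStack, MultispectralStack
from .venation import (
    VenationParams,
    extract_vein_mask,
    graph_to_json,
    skeleton_graph,
    venation_features,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Stage parameters; defaults are the device's published settings."""

    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    sectioning: SectioningParams = field(default_factory=SectioningParams)
    venation: VenationParams = field(default_factory=VenationParams)
    run_venation: bool = True


@dataclass
class LeafResult:
    """Everything the pipeline computed for one leaf."""

    leaf: SegmentedLeaf
    ndvi: np.ndarray
    ndvi_valid: np.ndarray
    color: ColorFeatures
    morphology: MorphFeatures
    section_labels: np.ndarray
    section_ndvi: np.ndarray
    preview: np.ndarray
    vein_mask: np.ndarray | None = None
    vein_graph: object | None = None
    venation: object | None = None
    timings: dict[str, float] = field(default_factory=dict)

    def record(self, leaf_id: str) -> dict:
        rec = {
            "leaf_id": leaf_id,
            "mean_405": self.color.mean_by_wavelength.get(405),
            "mean_560": self.color.mean_by_wavelength.get(560),
            "mean_660": self.color.mean_by_wavelength.get(660),
            "mean_880": self.color.mean_by_wavelength.get(880),
            "mean_ndvi": self.color.mean_ndvi,
            "area_mm2": self.morphology.area_mm2,
            "perimeter_mm": self.morphology.perimeter_mm,
            "major_mm": self.morphology.major_axis_mm,
            "minor_mm": self.morphology.minor_axis_mm,
            "roundness": self.morphology.roundness,
            "theta_deg": self.leaf.theta_deg,
            "cut_col": self.leaf.cut_col,
        }
        for i, v in enumerate(self.section_ndvi, start=1):
            rec[f"ndvi_s{i}"] = v
        if self.venation is not None:
            v = self.venation
            rec.update(
                n_junctions=v.n_junctions,
                n_endpoints=v.n_endpoints,
                n_cycles=v.n_cycles,
                vein_total_length_px=v.total_length_px,
                vein_network_area_px=v.network_area_px,
                vein_hull_area_px=v.convex_hull_area_px,
                vein_avg_edge_length_px=v.avg_edge_length_px,
                vein_avg_edge_width_px=v.avg_edge_width_px,
            )
        return rec


def process_stack(
    raw: MultispectralStack,
    bundle: CalibrationBundle,
    config: PipelineConfig | None = None,
) -> LeafResult:
    """Run the full pipeline on a raw stack.

    Raises :class:`leafmsi.segment.NoLeafError` if segmentation finds
    nothing above the NDVI threshold.
    """
    config = config or PipelineConfig()
    timings: dict[str, float] = {}

    def timed(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                timings[name] = time.perf_counter() - self.t0

        return _T()

    with timed("calibrate"):
        cal = spectral_calibrate(raw, bundle)
    with timed("segment"):
        ndvi = compute_ndvi(cal)
        seg = threshold_segment(cal, ndvi, config.segmentation)
    with timed("undistort"):
        if np.any(bundle.distortion_coeffs):
            bands = np.stack([undistort(b, bundle) for b in seg.stack.data])
            mask = undistort(seg.mask.astype(float), bundle, interpolation="nearest") > 0.5
            valid = undistort(seg.stack.valid.astype(float), bundle, interpolation="nearest") > 0.5
            bands[:, ~mask] = 0.0
            seg = SegmentedLeaf(
                CalibratedStack(bands, list(seg.stack.manifest), valid), mask
            )
    with timed("rotate"):
        seg = rotate_to_horizontal(seg)
    with timed("petiole"):
        seg = remove_petiole(seg, config.segmentation)

    with timed("features"):
        ndvi_rot = compute_ndvi(seg.stack)
        color = color_features(seg.stack, ndvi_rot, seg.mask)
        morph = morphological_features(seg.mask, bundle)
        preview = ndvi_preview(np.where(seg.mask, ndvi_rot.values, 0.0), PREVIEW_SIZE)
    with timed("sections"):
        labels, means = section_leaf(
            seg.mask, ndvi_rot.values, config.sectioning, ndvi_rot.valid
        )

    result = LeafResult(
        leaf=seg,
        ndvi=ndvi_rot.values,
        ndvi_valid=ndvi_rot.valid,
        color=color,
        morphology=morph,
        section_labels=labels,
        section_ndvi=means,
        preview=preview,
        timings=timings,
    )
    if config.run_venation:
        with timed("venation"):
            vein_mask = extract_vein_mask(ndvi_rot.values, seg.mask, config.venation)
            vg = skeleton_graph(vein_mask)
            result.vein_mask = vein_mask
            result.vein_graph = vg
            result.venation = venation_features(vg, vein_mask)
    log.info("pipeline timings: %s", {k: f"{v:.3f}s" for k, v in timings.items()})
    return result


def save_scene(params, scene_dir: str | Path) -> Path:
    """Simulate a scene and write it as a processable directory.

    Writes ``raw.tif``, ``white_ref.tif``, ``dark_ref.tif`` + manifests, a
    zero-distortion ``bundle.json`` at the scene's scale, ground-truth masks
    as PNG and the ground-truth vein graph as JSON.
    """
    from .simulate import generate_scene  # local import: keeps layering one-way
    from .venation import graph_to_json as _gj

    scene_dir = Path(scene_dir)
    scene_dir.mkdir(parents=True, exist_ok=True)
    raw, white, dark, gt = generate_scene(params)
    meta = {"seed": params.seed, "mm_per_px": params.mm_per_px}
    msio.write_stack(raw, scene_dir / "raw.tif", extra_meta=meta)
    msio.write_stack(white, scene_dir / "white_ref.tif", extra_meta=meta)
    msio.write_stack(dark, scene_dir / "dark_ref.tif", extra_meta=meta)
    h, w = params.image_size
    K = [[1000.0, 0.0, (w - 1) / 2.0], [0.0, 1000.0, (h - 1) / 2.0], [0.0, 0.0, 1.0]]
    bundle_meta = {
        "intrinsic_matrix": K,
        "distortion_coeffs": [0.0, 0.0, 0.0, 0.0, 0.0],
        "mm_per_px": params.mm_per_px,
        "platform_distance_mm": 1000.0 * params.mm_per_px,
    }
    import json as _json

    (scene_dir / "bundle.json").write_text(_json.dumps(bundle_meta, indent=2))
    msio.write_mask(gt.leaf_mask, scene_dir / "gt_leaf_mask.png")
    msio.write_mask(gt.petiole_mask, scene_dir / "gt_petiole_mask.png")
    msio.write_mask(gt.vein_mask, scene_dir / "gt_vein_mask.png")
    msio.write_graph(_gj(gt.vein_graph), scene_dir / "graph.json")
    (scene_dir / "truth.json").write_text(
        _json.dumps(
            {
                "theta_deg": gt.theta_deg,
                "area_mm2": gt.true_features.area_mm2,
                "perimeter_mm": gt.true_features.perimeter_mm,
                "major_axis_mm": gt.true_features.major_axis_mm,
                "minor_axis_mm": gt.true_features.minor_axis_mm,
                "roundness": gt.true_features.roundness,
            },
            indent=2,
        )
    )
    return scene_dir


def process_scene_dir(
    scene_dir: str | Path,
    bundle: CalibrationBundle | None = None,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    leaf_id: str | None = None,
) -> LeafResult:
    """Process a scene directory written by the simulator or device.

    Expects ``raw.tif``; if ``bundle`` is None, ``white_ref.tif`` /
    ``dark_ref.tif`` + ``bundle.json`` in the same directory are used.
    When ``out_dir`` is given, every stage's output is saved there.
    """
    scene_dir = Path(scene_dir)
    raw = msio.read_stack(scene_dir / "raw.tif")
    if bundle is None:
        bundle = msio.read_calibration(scene_dir)
    result = process_stack(raw, bundle, config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        lid = leaf_id or scene_dir.name
        msio.write_mask(result.leaf.mask, out / "leaf_mask.png")
        msio.write_label_map(result.section_labels, out / "sections.png")
        np.save(out / "ndvi.npy", result.ndvi)
        np.save(out / "preview.npy", result.preview)
        if result.vein_mask is not None:
            msio.write_mask(result.vein_mask, out / "vein_mask.png")
            msio.write_graph(graph_to_json(result.vein_graph), out / "graph.json")
        msio.write_features([result.record(lid)], out / "features.csv",
                            metadata={"scene": str(scene_dir), "timings_s": result.timings})
    return result
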
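"""End-to-end pipeline: align, segment, crop, trace, detect."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from xraypipe import align as align_mod
from xraypipe import bone_graph, entropy_seg, fracture, roi
from xraypipe.config import PipelineConfig
from xraypipe.errors import StageError

__all__ = ["PipelineResult", "run_pipeline"]

log = logging.getLogger("xraypipe")


@dataclass
class PipelineResult:
    report: fracture.FractureReport
    orientation: align_mod.OrientationResult | None
    roi_box: roi.ROIBox
    bone_lines: list[bone_graph.BoneLine]  # in coordinates of the analysed image
    noise_score: entropy_seg.NoiseScore
    intermediates: dict[str, np.ndarray] = field(default_factory=dict)


def run_pipeline(
    img: np.ndarray,
    config: PipelineConfig | None = None,
    do_align: bool = True,
    keep_intermediates: bool = False,
) -> PipelineResult:
    """Run every stage in order on one 8-bit grayscale image.

    ``do_align=False`` skips the orientation stage (useful when the input is
    known upright and ground-truth coordinates must be preserved).  Bone lines
    and detections are reported in the coordinate frame of the analysed
    (aligned or raw) image.
    """
    cfg = config or PipelineConfig()
    inter: dict[str, np.ndarray] = {}

    def _stage(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:  # surface the failed stage by name
            raise StageError(name, str(exc)) from exc
        log.info("stage %-8s %.3fs", name, time.perf_counter() - t0)
        return out

    orientation = None
    work = np.asarray(img)
    if do_align:
        work, orientation = _stage(
            "align", align_mod.align_image, work, cfg.pad, cfg.closing_kernel
        )
        log.info("alignment rotation applied: %.2f deg", orientation.rotation_applied)

    win = entropy_seg.EntropyWindow(cfg.entropy_window, cfg.log_base)
    emap = _stage("entropy", entropy_seg.local_entropy_map, work, win)
    norm = entropy_seg.normalise_rows(emap)
    log.info("entropy map mean %.3f", float(emap.mean()))
    edges = _stage(
        "segment", entropy_seg.line_edge_image, norm, cfg.peak_threshold, 2, True
    )
    score = _stage("score", entropy_seg.global_entropy_score, edges, cfg.metric_window)

    cropped, box = _stage(
        "roi",
        roi.extract_roi,
        edges,
        norm,
        cfg.roi_band,
        cfg.peak_retention,
        cfg.width_expansion,
    )

    def _trace():
        roots = bone_graph.select_roots(cropped)
        graph = bone_graph.build_graph(cropped, roots, cfg.search_up, cfg.search_side)
        paths = bone_graph.filter_paths(graph, cropped.shape[0], cfg.min_path_frac)
        log.info("trace: %d roots, %d paths kept", len(roots), len(paths))
        return bone_graph.merge_contours(paths, cfg.merge_window)

    lines_local = _stage("trace", _trace)
    lines = [
        bone_graph.BoneLine(rows=l.rows + box.top_row, cols=l.cols + box.left_col)
        for l in lines_local
    ]

    fit_cfg = fracture.FitConfig(
        ideal_degree=cfg.ideal_degree,
        top_frac=cfg.curvature_top_frac,
        tolerance=cfg.tolerance,
        min_run=cfg.min_run,
    )
    report = _stage("detect", fracture.detect_fracture, lines, fit_cfg)

    if keep_intermediates:
        inter = {"aligned": work, "entropy": emap, "edges": edges, "roi": cropped}
    return PipelineResult(
        report=report,
        orientation=orientation,
        roi_box=box,
        bone_lines=lines,
        noise_score=score,
        intermediates=inter,
    )
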
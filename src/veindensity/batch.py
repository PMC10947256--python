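"""Batch pipeline driver, deferred manual review, and estimate comparison.

``run_batch`` processes every image in a directory unattended — one bad
image is logged and skipped, never aborting the batch — writing a results
CSV, per-image overlay PNGs (the vein trace thickened over the greyscale
original) and a run-metadata JSON. The operator then reviews the overlays
at leisure and feeds a rejection list to ``apply_review``, which marks the
rejected rows excluded without deleting them. ``compare_estimates``
summarizes agreement between two density tables (e.g. automated vs manual
tracing) with Pearson's r, a least-squares line and the mean absolute
relative difference.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import preprocess, skeleton as sk
from .config import (IMAGE_EXTENSIONS, ImageReadError, PipelineConfig,
                     read_image, write_overlay, write_results_table)
from .density import DensityResult, measure_density

logger = logging.getLogger("veindensity")

__all__ = ["BatchReport", "run_batch", "process_image", "apply_review",
           "compare_estimates", "list_images"]


@dataclass
class BatchReport:
    """Outcome of one batch run."""

    n_images: int
    n_processed: int
    n_flagged: int
    results: list[DensityResult]
    rejected_ids: list[str] = field(default_factory=list)
    failed_ids: list[str] = field(default_factory=list)
    results_path: Path | None = None


def list_images(directory: Path) -> list[Path]:
    """Image files in ``directory``, sorted by name for determinism."""
    return sorted(p for p in Path(directory).iterdir()
                  if p.suffix.lower() in IMAGE_EXTENSIONS and p.is_file())


def process_image(raster: np.ndarray, config: PipelineConfig, *,
                  image_id: str = "") -> tuple[DensityResult, np.ndarray, np.ndarray]:
    """Run the full measurement chain on one raster.

    Chain: preprocess to a veins-as-foreground mask, skeletonize, build the
    skeleton graph, resolve the effective trim factor (automatic when spur
    pixels dominate), trim spurs, optionally remove commissural veins
    (monocot mode), and measure density.

    Returns ``(result, final_skeleton, greyscale_image)``.
    """
    grey = preprocess.to_greyscale(raster)
    flagged = grey.shape != (config.y_pixels, config.x_pixels)
    if flagged:
        logger.warning("%s: dimensions %s differ from configured (%d, %d)",
                       image_id, grey.shape, config.y_pixels, config.x_pixels)
    mask = preprocess.preprocess_image(
        raster,
        blur_w=config.blur_w,
        clahe_clip_limit=config.clahe_clip_limit,
        clahe_tile_grid=config.clahe_tile_grid,
        threshold_override=config.threshold_override,
        invert_foreground=config.invert_foreground,
    )
    if not mask.any() or mask.all():
        # zero-variance binarization (blank or constant input): nothing to
        # measure, but the batch carries on with the row flagged
        logger.warning("%s: degenerate binarization (uniform mask)", image_id)
        flagged = True
    skel = sk.skeletonize(mask)
    graph = sk.build_graph(skel)
    effective = sk.auto_trim_factor(graph, config.auto_trim_trigger_fraction,
                                    config.trim_factor,
                                    border_margin=2 * config.blur_w + 1)
    auto_used = effective != config.trim_factor
    trimmed = sk.trim_spurs(graph, effective)
    if config.mode == "monocot" and config.monocot_branch_length_to_keep > 0:
        trimmed = sk.remove_commissural(sk.build_graph(trimmed),
                                        config.monocot_branch_length_to_keep)
    result = measure_density(trimmed, config, image_id=image_id,
                             auto_trim_used=auto_used,
                             effective_trim_factor=effective, flagged=flagged)
    return result, trimmed, grey


def run_batch(config: PipelineConfig) -> BatchReport:
    """Process every image under ``config.input_path`` unattended.

    Writes ``results.csv``, ``run_metadata.json`` and
    ``overlays/<image>.png`` under ``config.output_dir``. Unreadable images
    are logged and skipped. Output is deterministic: the pipeline has no
    random state and images are processed in sorted order.
    """
    input_path = Path(config.input_path)
    if input_path.is_dir():
        paths = list_images(input_path)
        if not paths:
            raise FileNotFoundError(f"no readable images in {input_path}")
    elif input_path.is_file():
        paths = [input_path]
    else:
        raise FileNotFoundError(f"input path does not exist: {input_path}")

    out_dir = Path(config.output_dir)
    overlay_dir = out_dir / "overlays"
    try:
        overlay_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory not writable: {out_dir}: {exc}") from exc

    results: list[DensityResult] = []
    failed: list[str] = []
    t_start = time.monotonic()
    for path in paths:
        image_id = path.name
        t0 = time.monotonic()
        try:
            raster = read_image(path)
        except (ImageReadError, ValueError) as exc:
            logger.error("%s: %s — skipped", image_id, exc)
            failed.append(image_id)
            continue
        result, skel, grey = process_image(raster, config, image_id=image_id)
        write_overlay(grey, skel, overlay_dir / f"{path.stem}_overlay.png")
        results.append(result)
        logger.info("%s: density %.1f um/mm^2 (%.2f s)%s", image_id,
                    result.vein_density_um_per_mm2, time.monotonic() - t0,
                    " [flagged]" if result.flagged else "")

    results_path = None
    if results:
        results_path = write_results_table(results, out_dir / "results.csv")
    meta = {
        "config": config.to_mapping(),
        "n_images": len(paths),
        "n_processed": len(results),
        "failed_ids": failed,
        "elapsed_s": round(time.monotonic() - t_start, 3),
        "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out_dir / "run_metadata.json").write_text(json.dumps(meta, indent=2))

    return BatchReport(
        n_images=len(paths),
        n_processed=len(results),
        n_flagged=sum(r.flagged for r in results),
        results=results,
        failed_ids=failed,
        results_path=results_path,
    )


def apply_review(report: BatchReport, rejections: list[str],
                 revised_path: Path | str | None = None) -> BatchReport:
    """Mark reviewed-and-rejected images excluded, keeping their rows.

    Every id in ``rejections`` must name a processed image; unknown ids
    raise ``KeyError``. A revised CSV (all rows, with ``excluded`` and
    ``review_timestamp`` columns) is written next to the original results
    unless ``revised_path`` overrides the location.
    """
    known = {r.image_id for r in report.results}
    unknown = [r for r in rejections if r not in known]
    if unknown:
        raise KeyError(f"unknown image ids in rejection list: {unknown}")
    if len(rejections) == len(report.results) and report.results:
        logger.warning("review rejected every image in the batch")

    stamp = time.strftime("%Y-%m-%dT%H:%M:%S")
    rows = []
    for r in report.results:
        d = dataclasses.asdict(r)
        d["excluded"] = r.image_id in rejections
        d["review_timestamp"] = stamp
        rows.append(d)
    if revised_path is None and report.results_path is not None:
        revised_path = Path(report.results_path).with_name("results_reviewed.csv")
    if revised_path is not None and rows:
        write_results_table(rows, revised_path)
    return dataclasses.replace(report, rejected_ids=list(rejections),
                               results_path=Path(revised_path) if revised_path else None)


def compare_estimates(table_a: pd.DataFrame | str | Path,
                      table_b: pd.DataFrame | str | Path,
                      value_column: str = "vein_density_um_per_mm2") -> dict:
    """Agreement summary between two density tables sharing image ids.

    Returns Pearson's r, the least-squares slope/intercept of b on a, the
    mean absolute relative difference, and the number of shared images.
    At least three shared ids are required.
    """
    a = pd.read_csv(table_a) if not isinstance(table_a, pd.DataFrame) else table_a
    b = pd.read_csv(table_b) if not isinstance(table_b, pd.DataFrame) else table_b
    merged = a.merge(b, on="image_id", suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise ValueError(f"only {len(merged)} shared image ids; need >= 3")
    x = merged[f"{value_column}_a"].to_numpy(dtype=float)
    y = merged[f"{value_column}_b"].to_numpy(dtype=float)
    r, _ = stats.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(y - x) / np.abs(x)
    mard = float(np.nanmean(rel[np.isfinite(rel)]))
    return {
        "n_shared": int(len(merged)),
        "pearson_r": float(r),
        "slope": float(slope),
        "intercept": float(intercept),
        "mean_abs_rel_diff": mard,
    }
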
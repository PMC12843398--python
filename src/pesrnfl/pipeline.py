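"""End-to-end orchestration of the four segmentation stages, the visual
field mapping and the cohort statistics.

Per image: preprocess -> vessel suppression -> pointwise extraction ->
landmarks -> alignment into the canonical frame -> window filtering ->
linking -> Bezier fitting -> entrance angles. Images whose fovea or ONH
cannot be located are excluded with a logged reason and the batch
continues. All per-image processing is deterministic and independent, so
any execution order yields identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import bundles as bundles_mod
from . import extraction as extraction_mod
from . import landmarks as landmarks_mod
from . import refmaps as refmaps_mod
from . import stats as stats_mod
from . import vessels as vessels_mod
from . import vfmap as vfmap_mod
from .preprocess import load_fundus, preprocess as preprocess_image
from .config import RunConfig
from .geometry import EyeAlignment
from .landmarks import OcularParameters, OnhGeometry
from .preprocess import FundusImage

log = logging.getLogger("pesrnfl")


@dataclass
class PipelineContext:
    """Per-run shared state: the reference map and region windows are built
    once and reused for every image."""

    config: RunConfig
    refmap: refmaps_mod.ReferenceMap
    windows: refmaps_mod.RegionWindows

    @classmethod
    def build(cls, config: Optional[RunConfig] = None) -> "PipelineContext":
        config = config or RunConfig()
        rc = config.reference
        refmap = refmaps_mod.build_reference_map(
            dphi0=rc.dphi0_deg, px_per_deg=rc.map_px_per_deg, r_max=rc.r_max_deg)
        windows = refmaps_mod.region_windows(
            refmap, margin=rc.window_margin_deg,
            raphe_full_circle=rc.raphe_full_circle)
        return cls(config=config, refmap=refmap, windows=windows)


@dataclass
class SegmentResult:
    """Everything the mapping and statistics stages need from one image."""

    source: str
    onh_eye: OnhGeometry  # fitted ellipse, eye frame (fovea at origin)
    onh_canonical: OnhGeometry
    fovea_px: tuple
    alignment: EyeAlignment
    params: OcularParameters
    extractions: List[extraction_mod.PointwiseExtraction]  # eye frame
    kept_canonical: List[extraction_mod.PointwiseExtraction]
    bundles: List[bundles_mod.Bundle]  # canonical frame
    effective_pct: float

    def to_json_dict(self) -> dict:
        return dict(
            source=self.source,
            ocular_parameters=dataclasses.asdict(self.params),
            onh=dict(center_deg=list(self.onh_eye.center_deg),
                     radius_major=self.onh_eye.radius_major,
                     radius_minor=self.onh_eye.radius_minor,
                     orientation=self.onh_eye.orientation),
            n_extractions=len(self.extractions),
            n_kept=len(self.kept_canonical),
            effective_pct=self.effective_pct,
            bundles=[dict(entrance_angle=b.entrance_angle,
                          n_markers=int(len(b.markers)),
                          control_points=b.control_points.tolist(),
                          region_trace=b.region_trace)
                     for b in self.bundles],
        )


def segment_image(img: FundusImage, ctx: PipelineContext,
                  fovea_override_px: Optional[tuple] = None,
                  onh_center_override_px: Optional[tuple] = None) -> SegmentResult:
    """Run the full segmentation on one loaded fundus image."""
    cfg = ctx.config
    t0 = time.perf_counter()
    pre = preprocess_image(img, cfg.preprocess)

    # landmarks (overrides are returned verbatim when supplied)
    contour, _sharp = landmarks_mod.detect_onh(pre)
    onh_center_px = (tuple(onh_center_override_px) if onh_center_override_px
                     else tuple(contour.mean(axis=0)))
    fovea_px = (tuple(fovea_override_px) if fovea_override_px
                else landmarks_mod.detect_fovea(pre, onh_center_px=onh_center_px))
    pre.fovea_px = fovea_px
    img.fovea_px = fovea_px

    cx, cy = pre.px_to_deg(contour[:, 0], contour[:, 1])
    pts5 = landmarks_mod.boundary_points(np.column_stack([cx, cy]), k=5)
    onh_eye = landmarks_mod.fit_ellipse_lsq(pts5)
    params = landmarks_mod.ocular_parameters(onh_eye)
    alignment = vfmap_mod.align_normalize(onh_eye)
    onh_canon = vfmap_mod.align_onh_geometry(onh_eye, alignment)

    # vessel suppression
    enhanced = vessels_mod.clahe(pre, cfg.vessels.clahe_clip_limit,
                                 cfg.vessels.clahe_tiles)
    vmap = vessels_mod.frangi_vesselness(enhanced, beta=cfg.vessels.beta,
                                         c=cfg.vessels.c)
    vmask = vessels_mod.vessel_mask(vmap, method=cfg.vessels.mask_method,
                                    threshold=cfg.vessels.mask_threshold,
                                    px_per_deg=pre.px_per_deg)

    # pointwise extraction
    from .config import BASE_PX_PER_DEG

    win = int(round(cfg.extraction.mm_window * pre.px_per_deg / BASE_PX_PER_DEG))
    win = max(win + (win % 2 == 0), 3)
    mm = extraction_mod.mm_modulate(enhanced, win)
    rnf_binary = extraction_mod.binarize_rnf(mm)
    onh_px = pre.deg_to_px(onh_eye.center_deg[0], onh_eye.center_deg[1])
    extractions = extraction_mod.extract_segments(
        rnf_binary, vmask, cfg.extraction.min_segment_size, onh_px)
    for e in extractions:
        x, y = pre.px_to_deg(e.centroid_px[0], e.centroid_px[1])
        e.centroid_deg = (float(x), float(y))

    # canonical frame: positions, thetas, regions
    canon: List[extraction_mod.PointwiseExtraction] = []
    for e in extractions:
        xc, yc = alignment.apply_points(e.centroid_deg[0], e.centroid_deg[1])
        rid = int(ctx.windows.partition.assign(np.array(xc), np.array(yc)))
        e.region_id = rid
        canon.append(extraction_mod.PointwiseExtraction(
            centroid_px=e.centroid_px,
            theta=float(alignment.apply_theta(e.theta)),
            n_pixels=e.n_pixels, region_id=rid,
            centroid_deg=(float(xc), float(yc))))

    kept = bundles_mod.filter_extractions(canon, ctx.windows)
    eff = (stats_mod.effective_percentage(canon, ctx.windows)
           if canon else float("nan"))
    bundles = bundles_mod.assemble_bundles(kept, onh_canon, cfg.bundles)
    log.info("segmented %s: %d extractions, %d kept (%.1f%%), %d bundles "
             "in %.1fs", img.source_path or "<array>", len(extractions),
             len(kept), eff, len(bundles), time.perf_counter() - t0)
    return SegmentResult(source=img.source_path, onh_eye=onh_eye,
                         onh_canonical=onh_canon, fovea_px=fovea_px,
                         alignment=alignment, params=params,
                         extractions=extractions, kept_canonical=kept,
                         bundles=bundles, effective_pct=eff)


def run_segment(images: Sequence, ctx: Optional[PipelineContext] = None,
                out_dir: Optional[str] = None) -> List[SegmentResult]:
    """Segment a batch; failed images are excluded with a logged reason.

    ``images`` may be file paths or (FundusImage, label) pairs.
    """
    ctx = ctx or PipelineContext.build()
    results = []
    for item in images:
        if isinstance(item, (str, Path)):
            label = str(item)
            try:
                img = load_fundus(item, config=ctx.config.preprocess)
            except Exception as exc:  # noqa: BLE001 - exclusion, not crash
                log.warning("excluded %s: %s", label, exc)
                continue
        else:
            img, label = item
        try:
            results.append(segment_image(img, ctx))
        except (landmarks_mod.DetectionError, landmarks_mod.FitError,
                landmarks_mod.GeometryError) as exc:
            log.warning("excluded %s (landmarks): %s", label, exc)
        except Exception as exc:  # noqa: BLE001
            log.warning("excluded %s: %s", label, exc)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ctx.config.save(out / "config_resolved.yaml")
        rows = []
        for i, r in enumerate(results):
            with open(out / f"bundles_{i:04d}.json", "w") as fh:
                json.dump(r.to_json_dict(), fh, indent=1)
            rows.append(dict(source=r.source, n_extractions=len(r.extractions),
                             n_kept=len(r.kept_canonical),
                             n_bundles=len(r.bundles),
                             effective_pct=r.effective_pct))
        pd.DataFrame(rows).to_csv(out / "segment_summary.csv", index=False)
        _write_manifest(out, n_images=len(results))
    return results


@dataclass
class EyeMapping:
    """Per-eye mapping tables for both analytical paths."""

    source: str
    pointwise: pd.DataFrame
    entrance: pd.DataFrame
    pointwise_sets: list
    entrance_sets: list


def map_eye(result: SegmentResult, ctx: PipelineContext,
            resolution: Optional[tuple] = None) -> EyeMapping:
    """Visual-field mapping of one segmented eye (both modes).

    Rasterize the canonical-frame geometry, dilate, intersect with the 24-2
    grid, swap superior/inferior assignments, apply the wraparound rule and
    summarize.
    """
    mc = ctx.config.mapping
    res = tuple(resolution or mc.resolution)
    grid = vfmap_mod.vf_grid_242()
    kept = result.kept_canonical
    if kept:
        pts = np.array([e.centroid_deg for e in kept])
        angles = np.array([e.theta for e in kept])
    else:
        pts = np.empty((0, 2))
        angles = np.empty(0)
    raster_p = vfmap_mod.rasterize_dilate(points_xy=pts, angles=angles,
                                          resolution=res,
                                          extent_x_deg=mc.extent_x_deg,
                                          selem_radius=mc.dilate_px)
    sets_p = vfmap_mod.intersect_vf(raster_p, grid, mc.radius_deg)
    sets_p = vfmap_mod.wrap_adjust_sets(vfmap_mod.mirror_assign(sets_p, grid))

    raster_b = vfmap_mod.rasterize_dilate(bundles=result.bundles, resolution=res,
                                          extent_x_deg=mc.extent_x_deg,
                                          selem_radius=mc.dilate_px)
    sets_b = vfmap_mod.intersect_vf(raster_b, grid, mc.radius_deg)
    sets_b = vfmap_mod.wrap_adjust_sets(vfmap_mod.mirror_assign(sets_b, grid))
    return EyeMapping(source=result.source,
                      pointwise=vfmap_mod.summarize(sets_p),
                      entrance=vfmap_mod.summarize(sets_b),
                      pointwise_sets=sets_p, entrance_sets=sets_b)


def run_map(results: Sequence[SegmentResult], ctx: Optional[PipelineContext] = None,
            out_dir: Optional[str] = None,
            resolution: Optional[tuple] = None) -> List[EyeMapping]:
    ctx = ctx or PipelineContext.build()
    mappings = [map_eye(r, ctx, resolution=resolution) for r in results]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, m in enumerate(mappings):
            m.pointwise.to_csv(out / f"map_pointwise_{i:04d}.csv", index=False)
            m.entrance.to_csv(out / f"map_entrance_{i:04d}.csv", index=False)
        _write_manifest(out, n_eyes=len(mappings))
    return mappings


def run_stats(results: Sequence[SegmentResult], mappings: Sequence[EyeMapping],
              ctx: Optional[PipelineContext] = None,
              baseline_entrance: Optional[pd.DataFrame] = None,
              out_dir: Optional[str] = None) -> dict:
    """Cohort statistics over segmented + mapped eyes.

    Test 1: per-location AIC forward stepwise of the mean pointwise angle on
    the five ocular covariates. Test 2: comparison of per-location mean
    entrance angles against a user-supplied baseline table (columns
    vf_index, mean_deg); skipped with a warning when absent. Test 3:
    pointwise angles against the implemented trajectory reference map.
    """
    ctx = ctx or PipelineContext.build()
    sc = ctx.config.stats
    if len(results) < sc.min_eyes:
        raise stats_mod.InsufficientDataError(
            f"need >= {sc.min_eyes} eyes, got {len(results)}")
    X = pd.DataFrame([dict(zip(landmarks_mod.COVARIATE_ORDER,
                               r.params.as_tuple())) for r in results])

    # per-eye mean pointwise angle per location
    per_loc: Dict[int, np.ndarray] = {}
    for li, m in enumerate(mappings):
        for _, row in m.pointwise.iterrows():
            per_loc.setdefault(int(row.vf_index), np.full(len(mappings), np.nan))[li] = row.mean_deg
    stepwise = []
    for vf_index in sorted(per_loc):
        y = per_loc[vf_index]
        if np.isfinite(y).sum() < sc.min_eyes:
            continue
        stepwise.append(stats_mod.aic_forward_stepwise(
            X, y, vf_index=vf_index, p_threshold=sc.p_threshold,
            min_n=sc.min_eyes, aicc=sc.use_aicc))

    pooled = pd.concat([m.pointwise for m in mappings], ignore_index=True) \
        if mappings else pd.DataFrame()
    pooled_summary = (pooled.groupby("vf_index")
                      .agg(mean_deg=("mean_deg", "mean"),
                           sd_deg=("mean_deg", "std"), n=("mean_deg", "size"))
                      .reset_index()) if len(pooled) else pd.DataFrame()
    if len(pooled_summary):
        pooled_summary["sd_deg"] = pooled_summary["sd_deg"].fillna(0.0)
        pooled_summary["limit95_deg"] = 2.0 * pooled_summary["sd_deg"]
    table2, table3 = stats_mod.variability_report(
        stepwise, pooled_summary if len(pooled_summary) else None,
        p_threshold=sc.p_threshold)

    # test 2: entrance angles vs a baseline map
    entrance_cmp = None
    ent = pd.concat([m.entrance for m in mappings], ignore_index=True) \
        if mappings else pd.DataFrame()
    if baseline_entrance is None:
        log.warning("no baseline entrance-angle table supplied; test 2 skipped")
    elif len(ent):
        ours = (ent.groupby("vf_index").mean_deg.mean().rename("ours")
                .reset_index())
        merged = ours.merge(baseline_entrance, on="vf_index")
        if len(merged):
            entrance_cmp = stats_mod.circular_rmse(
                merged["ours"].to_numpy() % 360.0,
                merged["mean_deg"].to_numpy() % 360.0)

    # test 3: pointwise angles vs the reference map
    ref_pairs_a, ref_pairs_b = [], []
    for r in results:
        for e in r.kept_canonical:
            ref = ctx.refmap.sample(np.array(e.centroid_deg[0]),
                                    np.array(e.centroid_deg[1]))
            if np.isfinite(ref):
                ref_pairs_a.append(e.theta)
                ref_pairs_b.append(float(ref))
    reference_cmp = (stats_mod.circular_rmse(ref_pairs_a, ref_pairs_b)
                     if ref_pairs_a else None)

    out = dict(stepwise=stepwise, per_location=table2, incidence=table3,
               entrance_comparison=entrance_cmp,
               reference_comparison=reference_cmp)
    if out_dir is not None:
        p = Path(out_dir)
        p.mkdir(parents=True, exist_ok=True)
        table2.to_csv(p / "variability_per_location.csv", index=False)
        table3.to_csv(p / "predictor_incidence.csv", index=False)
        with open(p / "stepwise_traces.json", "w") as fh:
            json.dump([dataclasses.asdict(s) for s in stepwise], fh, indent=1,
                      default=lambda o: list(o) if isinstance(o, tuple) else o)
        _write_manifest(p, n_eyes=len(results))
    return out


def _write_manifest(out: Path, **extra) -> None:
    from . import __version__

    with open(out / "manifest.json", "w") as fh:
        json.dump(dict(package="pesrnfl", version=__version__, **extra), fh)
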
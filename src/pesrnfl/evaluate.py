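"""Scoring of pipeline output against phantom ground truth.

Used by the test suite and the reproduction script: phantoms carry their
true tangent-angle map, trajectory set and landmark geometry, so the
pipeline's pointwise orientations, bundle entrance angles and detected
landmarks can be scored directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .geometry import circ_abs_diff, wrap360
from .phantom import PhantomTruth
from .pipeline import SegmentResult


@dataclass
class PhantomScores:
    """Per-phantom agreement between pipeline output and ground truth."""

    effective_pct: float
    pointwise_mae_deg: float  # extraction theta vs true tangent at centroid
    pointwise_n: int
    entrance_mae_deg: Optional[float]  # bundle entrance vs matched trajectory
    n_bundles: int
    onh_error_deg: float
    fovea_error_deg: float


def pointwise_angle_error(result: SegmentResult, truth: PhantomTruth):
    """Circular differences between each extraction's directed orientation
    (eye frame) and the true tangent at its centroid; extractions landing
    outside the truth map's striation support are skipped."""
    errs = []
    for e in result.extractions:
        r = int(round(e.centroid_px[0]))
        c = int(round(e.centroid_px[1]))
        if (0 <= r < truth.angle_map.shape[0] and 0 <= c < truth.angle_map.shape[1]
                and truth.angle_valid[r, c]):
            errs.append(float(circ_abs_diff(e.theta, truth.angle_map[r, c])))
    return np.asarray(errs)


def entrance_angle_error(result: SegmentResult, truth: PhantomTruth):
    """Circular differences between each entering bundle's canonical-frame
    entrance angle and that of the nearest ground-truth trajectory.

    Bundles are matched to trajectories by majority vote of the nearest
    trajectory sample over the bundle's markers (canonical frame).
    """
    pts = np.concatenate([t.xy for t in truth.trajectories])
    owner = np.concatenate([np.full(len(t.xy), i)
                            for i, t in enumerate(truth.trajectories)])
    tree = cKDTree(pts)
    true_entrance = np.array([wrap360(-t.phi0) for t in truth.trajectories])
    errs = []
    for b in result.bundles:
        if b.entrance_angle is None:
            continue
        _, idx = tree.query(b.markers)
        votes = owner[idx]
        match = int(np.bincount(votes).argmax())
        errs.append(float(circ_abs_diff(b.entrance_angle, true_entrance[match])))
    return np.asarray(errs)


def score_phantom(result: SegmentResult, truth: PhantomTruth) -> PhantomScores:
    pw = pointwise_angle_error(result, truth)
    ent = entrance_angle_error(result, truth)
    onh_err = float(np.hypot(result.onh_eye.center_deg[0] - truth.onh.center_deg[0],
                             result.onh_eye.center_deg[1] - truth.onh.center_deg[1]))
    # fovea error: truth fovea is the degree-frame origin by construction,
    # so the detected fovea's pixel offset converts directly
    ppd = truth.angle_map.shape[1] / 45.0
    fov_err = float(np.hypot(result.fovea_px[0] - truth.fovea_px[0],
                             result.fovea_px[1] - truth.fovea_px[1]) / ppd)
    return PhantomScores(
        effective_pct=result.effective_pct,
        pointwise_mae_deg=float(pw.mean()) if pw.size else float("nan"),
        pointwise_n=int(pw.size),
        entrance_mae_deg=float(ent.mean()) if ent.size else None,
        n_bundles=len(result.bundles),
        onh_error_deg=onh_err,
        fovea_error_deg=fov_err)
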
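"""Structure-function mapping: the 24-2 perimetry grid, eye normalization
into the canonical frame, rasterization with dilation, intersection of grid
points with pointwise-angle maps or bundle traces, superior/inferior
mirroring, and the 0/360 wraparound rule.

Two mapping modes mirror the two analytical paths of the method: in
``pointwise`` mode each grid point collects the directed tangent angles of
nearby fiber extractions; in ``entrance`` mode it collects the ONH entrance
angles of bundles passing nearby. The acceptance radius is 0.86 deg, twice
the diameter of the Goldmann size III stimulus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .config import MappingConfig
from .geometry import CANONICAL_ONH, CANONICAL_ONH_DIST, EyeAlignment
from .landmarks import GeometryError, OnhGeometry
from .bundles import Bundle, bezier_eval
from .preprocess import InputError


@dataclass(frozen=True)
class VFPoint:
    """One 24-2 visual-field test location in retinal degree coordinates."""

    index: int  # 1..54, row-major from the superior-nasal corner
    x_deg: float
    y_deg: float
    blind_spot: bool
    hemifield: str  # superior | inferior (of the retina-aligned grid)


def vf_grid_242() -> List[VFPoint]:
    """The canonical right-eye 24-2 layout: 54 points 6 deg apart at odd
    multiples of 3 deg, rows y = +-3 extended one step nasally, and the two
    blind-spot points straddling the ONH center flagged."""
    rows = {
        21: [9, 3, -3, -9],
        15: [15, 9, 3, -3, -9, -15],
        9: [21, 15, 9, 3, -3, -9, -15, -21],
        3: [27, 21, 15, 9, 3, -3, -9, -15, -21],
        -3: [27, 21, 15, 9, 3, -3, -9, -15, -21],
        -9: [21, 15, 9, 3, -3, -9, -15, -21],
        -15: [15, 9, 3, -3, -9, -15],
        -21: [9, 3, -3, -9],
    }
    points: List[VFPoint] = []
    idx = 1
    for y in sorted(rows, reverse=True):
        for x in rows[y]:
            points.append(VFPoint(
                index=idx, x_deg=float(x), y_deg=float(y),
                blind_spot=(x == 15 and abs(y) == 3),
                hemifield="superior" if y > 0 else "inferior"))
            idx += 1
    return points


def align_normalize(onh: OnhGeometry, fovea_deg: tuple = (0.0, 0.0)) -> EyeAlignment:
    """Similarity transform of a fovea-centered eye into the canonical frame.

    Rotates by -disc_fovea_angle + atan(2/15) and scales by
    sqrt(15^2 + 2^2) / |fovea -> ONH| so that the ONH center lands exactly
    at (15, 2). Coordinates must already be fovea-centered.
    """
    cx = onh.center_deg[0] - fovea_deg[0]
    cy = onh.center_deg[1] - fovea_deg[1]
    d = math.hypot(cx, cy)
    if cx <= 0 or d <= 0:
        raise GeometryError("degenerate geometry: ONH must lie nasal of the fovea")
    gamma = math.degrees(math.atan2(cy, cx))
    target = math.degrees(math.atan2(CANONICAL_ONH[1], CANONICAL_ONH[0]))
    return EyeAlignment(rotation_deg=target - gamma, scale=CANONICAL_ONH_DIST / d)


def align_onh_geometry(onh: OnhGeometry, alignment: EyeAlignment,
                       fovea_deg: tuple = (0.0, 0.0)) -> OnhGeometry:
    """The ONH ellipse expressed in the canonical frame (isotropic scaling
    keeps it an ellipse; the center lands at (15, 2) by construction)."""
    cx, cy = alignment.apply_points(onh.center_deg[0] - fovea_deg[0],
                                    onh.center_deg[1] - fovea_deg[1])
    return OnhGeometry(
        center_deg=(float(cx), float(cy)),
        radius_major=onh.radius_major * alignment.scale,
        radius_minor=onh.radius_minor * alignment.scale,
        orientation=(onh.orientation + alignment.rotation_deg) % 180.0,
    )


# ---------------------------------------------------------------------------
# rasterization


@dataclass
class MappedRaster:
    """Angle-valued raster over the canonical frame."""

    values: np.ndarray  # degrees; undefined where ~mask
    mask: np.ndarray
    px_per_deg: float
    extent_x: float  # x spans [-extent_x, extent_x]

    @property
    def extent_y(self) -> float:
        return self.values.shape[0] / (2.0 * self.px_per_deg)

    def to_px(self, x, y):
        row = self.values.shape[0] / 2.0 - np.asarray(y, float) * self.px_per_deg
        col = self.values.shape[1] / 2.0 + np.asarray(x, float) * self.px_per_deg
        return row, col


def _paint(raster: MappedRaster, xs, ys, vals) -> None:
    row, col = raster.to_px(xs, ys)
    r = np.round(row).astype(int)
    c = np.round(col).astype(int)
    h, w = raster.values.shape
    ok = (r >= 0) & (r < h) & (c >= 0) & (c < w)
    raster.values[r[ok], c[ok]] = np.asarray(vals, float)[ok]
    raster.mask[r[ok], c[ok]] = True


def rasterize_dilate(points_xy: Optional[np.ndarray] = None,
                     angles: Optional[np.ndarray] = None,
                     bundles: Optional[Sequence[Bundle]] = None,
                     resolution: tuple = MappingConfig.resolution,
                     extent_x_deg: float = MappingConfig.extent_x_deg,
                     selem_radius: int = 1) -> MappedRaster:
    """Rasterize an angle-valued geometry and dilate it to mitigate pixel
    spacing.

    Exactly one of (``points_xy`` with ``angles``) or ``bundles`` must be
    given. Bundles are painted as densely evaluated Bezier polylines
    carrying their entrance angle (non-entering bundles are skipped).
    Dilation is morphological with a disk of ``selem_radius`` pixels; each
    dilated pixel carries the angle of its nearest source pixel.
    """
    rows, cols = int(resolution[0]), int(resolution[1])
    if rows <= 0 or cols <= 0:
        raise InputError("resolution must be positive")
    ppd = cols / (2.0 * extent_x_deg)
    raster = MappedRaster(values=np.zeros((rows, cols)),
                          mask=np.zeros((rows, cols), dtype=bool),
                          px_per_deg=ppd, extent_x=extent_x_deg)
    if (points_xy is None) == (bundles is None):
        raise InputError("provide either points_xy+angles or bundles")
    if points_xy is not None:
        pts = np.asarray(points_xy, float)
        if len(pts):
            _paint(raster, pts[:, 0], pts[:, 1], np.asarray(angles, float))
    else:
        for b in bundles:
            if b.entrance_angle is None:
                continue
            # sample finely enough that consecutive samples stay adjacent
            span = np.hypot(*(b.markers.max(0) - b.markers.min(0))) + 1e-9
            n = max(int(span * ppd * 2), 64)
            xy = bezier_eval(b.control_points, np.linspace(0.0, 1.0, n))
            _paint(raster, xy[:, 0], xy[:, 1],
                   np.full(len(xy), b.entrance_angle))
    if selem_radius > 0 and raster.mask.any():
        dist, (ir, ic) = ndi.distance_transform_edt(~raster.mask,
                                                    return_indices=True)
        grow = dist <= selem_radius
        raster.values[grow] = raster.values[ir[grow], ic[grow]]
        raster.mask |= grow
    return raster


# ---------------------------------------------------------------------------
# intersections and summaries


@dataclass
class IntersectionSet:
    """Angles collected at one 24-2 location."""

    vf_index: int
    angles: np.ndarray
    adjusted: bool = False
    irreducible: bool = False

    @property
    def n(self) -> int:
        return int(len(self.angles))


def intersect_vf(raster: MappedRaster, grid: Sequence[VFPoint],
                 radius_deg: float = 0.86) -> List[IntersectionSet]:
    """Collect raster angle values within ``radius_deg`` of each analyzable
    (non-blind-spot) grid point; empty collections are allowed."""
    h, w = raster.values.shape
    rpx = radius_deg * raster.px_per_deg
    out: List[IntersectionSet] = []
    for p in grid:
        if p.blind_spot:
            continue
        row, col = raster.to_px(p.x_deg, p.y_deg)
        r0, r1 = int(np.floor(row - rpx)), int(np.ceil(row + rpx)) + 1
        c0, c1 = int(np.floor(col - rpx)), int(np.ceil(col + rpx)) + 1
        r0c, c0c = max(r0, 0), max(c0, 0)
        sub_m = raster.mask[r0c:min(r1, h), c0c:min(c1, w)]
        if sub_m.size == 0 or not sub_m.any():
            out.append(IntersectionSet(p.index, np.empty(0)))
            continue
        rr, cc = np.nonzero(sub_m)
        rr = rr + r0c
        cc = cc + c0c
        keep = (rr - row) ** 2 + (cc - col) ** 2 <= rpx * rpx
        out.append(IntersectionSet(
            p.index, raster.values[rr[keep], cc[keep]].copy()))
    return out


def mirror_assign(sets: Sequence[IntersectionSet],
                  grid: Sequence[VFPoint]) -> List[IntersectionSet]:
    """Swap each location's angle set with that of its reflection across the
    horizontal meridian (the retina-to-field inversion); an involution."""
    by_coord = {(p.x_deg, p.y_deg): p for p in grid}
    by_index = {p.index: p for p in grid}
    mirror_index: Dict[int, int] = {}
    for p in grid:
        q = by_coord.get((p.x_deg, -p.y_deg))
        if q is None:
            raise InputError(f"grid point {p.index} has no mirror partner")
        mirror_index[p.index] = q.index
    sets_by_index = {s.vf_index: s for s in sets}
    out = []
    for s in sets:
        src = sets_by_index.get(mirror_index[s.vf_index])
        angles = src.angles.copy() if src is not None else np.empty(0)
        out.append(IntersectionSet(s.vf_index, angles,
                                   adjusted=s.adjusted if src is None else src.adjusted,
                                   irreducible=s.irreducible if src is None else src.irreducible))
    return out


def wrap_adjust(angles) -> tuple:
    """Apply the 0/360 continuity rule to a set of angles in [0, 360).

    If max - min exceeds 180 deg, 360 is subtracted from every angle of at
    least 180; if the spread still exceeds 180 the set is flagged
    irreducible. Returns (adjusted_angles, adjusted_flag, irreducible_flag).
    """
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        return a, False, False
    if a.max() - a.min() <= 180.0:
        return a, False, False
    a = np.where(a >= 180.0, a - 360.0, a)
    return a, True, bool(a.max() - a.min() > 180.0)


def wrap_adjust_sets(sets: Sequence[IntersectionSet]) -> List[IntersectionSet]:
    out = []
    for s in sets:
        a, adj, irr = wrap_adjust(s.angles)
        out.append(IntersectionSet(s.vf_index, a, adjusted=adj, irreducible=irr))
    return out


def summarize(sets: Sequence[IntersectionSet]) -> pd.DataFrame:
    """Per-location mean, SD and 95% limit (2 SD) of the wrap-adjusted
    angle sets; locations with empty sets are reported absent."""
    rows = []
    for s in sets:
        if s.n == 0:
            continue
        sd = float(np.std(s.angles, ddof=1)) if s.n > 1 else 0.0
        rows.append(dict(vf_index=s.vf_index, n=s.n,
                         mean_deg=float(np.mean(s.angles)), sd_deg=sd,
                         limit95_deg=2.0 * sd, adjusted=bool(s.adjusted),
                         irreducible=bool(s.irreducible)))
    return pd.DataFrame(rows, columns=["vf_index", "n", "mean_deg", "sd_deg",
                                       "limit95_deg", "adjusted", "irreducible"])
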
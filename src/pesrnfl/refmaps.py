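"""Nerve-fiber trajectory model, the directional-angle reference map, the
10-region field partition with angular windows, and ONH circumference
sectors.

The trajectory model describes fiber paths in a modified polar frame
(r, phi) centered on the ONH: phi(r) = phi0 + b (r - r0)^c with r0 = 4 deg,
where phi0 is the angular position at the r0 circle (phi = 0 nasal,
positive toward superior retina) and the shape coefficients depend on phi0
and hemifield:

  superior (60 < phi0 < 180):  b =  exp(-1.9 + 3.9 tanh(-(phi0 - 121)/14)),
                               c = 1.9 + 1.4 tanh((phi0 - 121)/14)
  inferior (-180 < phi0 < -60): b = -exp(0.7 + 1.5 tanh(-(-phi0 - 90)/25)),
                               c = 1.0 + 0.5 tanh((-phi0 - 90)/25)
  nasal (|phi0| <= 60):        straight radial course (b = 0).

Trajectories are clipped where they would cross the horizontal raphe
(|phi| > 180). All Cartesian output is in the canonical aligned frame
(fovea at origin, ONH center at (15, 2) deg).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi

from .geometry import CANONICAL_ONH, AngleWindow, theta_from_vec, wrap360
from .preprocess import ParameterError

R0 = 4.0  # deg; trajectory starting circle around the ONH center


class WindowingError(ValueError):
    """A region of the partition contains no valid reference angles."""


class ConfigError(ValueError):
    """Sector or partition configuration is inconsistent."""


def _coefficients(phi0: float) -> Tuple[float, float]:
    """Shape coefficients (b, c) for starting position phi0 (degrees)."""
    if abs(phi0) <= 60.0:
        return 0.0, 1.0
    if phi0 > 0:  # superior hemifield
        b = math.exp(-1.9 + 3.9 * math.tanh(-(phi0 - 121.0) / 14.0))
        c = 1.9 + 1.4 * math.tanh((phi0 - 121.0) / 14.0)
    else:  # inferior hemifield
        b = -math.exp(0.7 + 1.5 * math.tanh(-(-phi0 - 90.0) / 25.0))
        c = 1.0 + 0.5 * math.tanh((-phi0 - 90.0) / 25.0)
    return b, c


@dataclass
class Trajectory:
    """One traced fiber path in the canonical frame."""

    phi0: float
    b: float
    c: float
    hemifield: str  # superior | inferior | nasal
    samples: np.ndarray  # (N, 2) of (r, phi), r strictly increasing from R0
    xy: np.ndarray  # (N, 2) fovea-centered Cartesian degrees

    @property
    def entrance_angle(self) -> float:
        """Angular position at the ONH, nasal-origin clockwise convention."""
        return float(wrap360(-self.phi0))

    def tangent_theta(self) -> np.ndarray:
        """Directed tangent orientation (toward the ONH) at every sample."""
        if len(self.xy) < 2:  # clipped to a single sample: radial course
            pr = math.radians(self.phi0)
            return np.atleast_1d(theta_from_vec(-math.cos(pr), -math.sin(pr)))
        d = np.gradient(self.xy, axis=0)  # d(x,y)/d(sample) ~ increasing r
        return theta_from_vec(-d[:, 0], -d[:, 1])


def trajectory(phi0: float, r_max: float = 45.0, dr: float = 1.0) -> Trajectory:
    """Trace one trajectory from the r0 = 4 deg circle outward.

    Samples stop at ``r_max`` or where the path would cross the horizontal
    raphe. phi0 must lie in (-180, 180]; dr must be positive.
    """
    if not -180.0 < phi0 <= 180.0:
        raise ParameterError(f"phi0 = {phi0} outside the model domain (-180, 180]")
    if dr <= 0:
        raise ParameterError("dr must be > 0")
    b, c = _coefficients(phi0)
    hemifield = "nasal" if abs(phi0) <= 60.0 else ("superior" if phi0 > 0 else "inferior")
    r = np.arange(R0, r_max + 0.5 * dr, dr)
    phi = phi0 + b * np.power(r - R0, c)
    # clip where the path crosses the raphe (phi leaving (-180, 180])
    crossed = (np.abs(phi) > 180.0) & (r > R0)
    if crossed.any():
        stop = int(np.argmax(crossed))
        r, phi = r[:stop], phi[:stop]
        if r.size == 0:  # degenerate; keep the starting sample
            r = np.array([R0])
            phi = np.array([phi0])
    pr = np.radians(phi)
    xy = np.column_stack([CANONICAL_ONH[0] + r * np.cos(pr),
                          CANONICAL_ONH[1] + r * np.sin(pr)])
    return Trajectory(phi0=float(phi0), b=b, c=c, hemifield=hemifield,
                      samples=np.column_stack([r, phi]), xy=xy)


# ---------------------------------------------------------------------------
# field partition


@dataclass(frozen=True)
class RegionPartition:
    """Partition of the canonical field of view into 10 labeled regions.

    Default geometry: regions 1-4 are peri-ONH quadrants (within
    ``onh_radius`` of the ONH center), 9 is the macular disk, 10 the
    temporal-raphe strip, and 5-8 the remaining peripheral quadrants split
    at the fovea-ONH midline. A custom partition can be supplied as labeled
    polygons (see ``from_polygon_file``).
    """

    onh_radius: float = 8.0
    macula_radius: float = 4.0
    raphe_x_max: float = -4.0
    raphe_half_height: float = 3.0
    polygons: Optional[tuple] = None  # ((region_id, vertices), ...)

    N_REGIONS = 10

    def assign(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.polygons is not None:
            return self._assign_polygons(x, y)
        out = np.zeros(x.shape, dtype=int)
        dx = x - CANONICAL_ONH[0]
        dy = y - CANONICAL_ONH[1]
        peri = np.hypot(dx, dy) <= self.onh_radius
        out[peri & (dx < 0) & (dy >= 0)] = 1   # peri-ONH superotemporal
        out[peri & (dx >= 0) & (dy >= 0)] = 2  # peri-ONH superonasal
        out[peri & (dx >= 0) & (dy < 0)] = 3   # peri-ONH inferonasal
        out[peri & (dx < 0) & (dy < 0)] = 4    # peri-ONH inferotemporal
        free = out == 0
        macula = free & (np.hypot(x, y) <= self.macula_radius)
        out[macula] = 9
        free = out == 0
        raphe = free & (x <= self.raphe_x_max) & (np.abs(y) <= self.raphe_half_height)
        out[raphe] = 10
        free = out == 0
        mid = CANONICAL_ONH[0] / 2.0
        out[free & (x < mid) & (y >= 0)] = 5   # peripheral superotemporal
        out[free & (x >= mid) & (y >= 0)] = 6  # peripheral superonasal
        out[free & (x >= mid) & (y < 0)] = 7   # peripheral inferonasal
        out[free & (x < mid) & (y < 0)] = 8    # peripheral inferotemporal
        return out

    def _assign_polygons(self, x, y) -> np.ndarray:
        from matplotlib.path import Path

        pts = np.column_stack([x.ravel(), y.ravel()])
        out = np.zeros(pts.shape[0], dtype=int)
        for region_id, verts in self.polygons:
            inside = Path(np.asarray(verts, float)).contains_points(pts)
            out[inside & (out == 0)] = int(region_id)
        return out.reshape(x.shape)

    @classmethod
    def from_polygon_file(cls, path) -> "RegionPartition":
        with open(path) as fh:
            data = json.load(fh)
        polys = tuple((int(p["region_id"]), tuple(map(tuple, p["vertices"])))
                      for p in data["regions"])
        ids = sorted(pid for pid, _ in polys)
        if ids != list(range(1, cls.N_REGIONS + 1)):
            raise ConfigError(f"polygon file must define regions 1..10, got {ids}")
        return cls(polygons=polys)


# ---------------------------------------------------------------------------
# reference map


@dataclass
class ReferenceMap:
    """Per-pixel directed tangent-angle map in the canonical frame."""

    angle: np.ndarray  # degrees in [0, 360); undefined where ~valid
    valid: np.ndarray
    px_per_deg: float
    extent: float  # coordinates span [-extent, extent] in x and y
    trajectories: List[Trajectory] = field(default_factory=list)

    def to_px(self, x, y):
        half = self.angle.shape[0] / 2.0
        row = half - np.asarray(y, float) * self.px_per_deg
        col = half + np.asarray(x, float) * self.px_per_deg
        return row, col

    def to_deg(self, row, col):
        half = self.angle.shape[0] / 2.0
        x = (np.asarray(col, float) - half) / self.px_per_deg
        y = (half - np.asarray(row, float)) / self.px_per_deg
        return x, y

    def sample(self, x, y):
        """Nearest-pixel angle lookup; NaN where invalid or out of bounds."""
        row, col = self.to_px(x, y)
        r = np.round(row).astype(int)
        c = np.round(col).astype(int)
        n = self.angle.shape[0]
        ok = (r >= 0) & (r < n) & (c >= 0) & (c < n)
        out = np.full(np.shape(x), np.nan, dtype=float)
        rr, cc = np.clip(r, 0, n - 1), np.clip(c, 0, n - 1)
        good = ok & self.valid[rr, cc]
        out[good] = self.angle[rr[good], cc[good]]
        return out


def build_reference_map(dphi0: float = 1.0, fov: float = 45.0,
                        px_per_deg: float = 3.0, r_max: Optional[float] = None,
                        dilate_px: int = 1) -> ReferenceMap:
    """Rasterize the full trajectory fan into a directed tangent-angle map.

    Trajectories are traced every ``dphi0`` degrees of starting position and
    extended inward from r0 to near the disc margin as radial stubs. Each
    covered pixel stores the directed tangent orientation (toward the ONH)
    in the nasal-origin clockwise convention; a ``dilate_px`` nearest-source
    dilation closes the gaps between adjacent traces. Deterministic: no
    randomness, fixed iteration order.
    """
    if px_per_deg <= 0 or dphi0 <= 0:
        raise ParameterError("px_per_deg and dphi0 must be > 0")
    extent = fov / 2.0 + 5.0  # margin so off-field trajectory parts still paint
    n = int(round(2 * extent * px_per_deg))
    if r_max is None:
        r_max = fov  # generous: trajectories leave the frame on their own
    angle = np.zeros((n, n))
    valid = np.zeros((n, n), dtype=bool)
    ref = ReferenceMap(angle=angle, valid=valid, px_per_deg=px_per_deg,
                       extent=extent)

    dr = 0.25 / px_per_deg  # sub-pixel stepping keeps traces 8-connected
    phi0s = np.arange(-180.0 + dphi0, 180.0 + 0.5 * dphi0, dphi0)
    trajs: List[Trajectory] = []
    for phi0 in phi0s:
        tr = trajectory(float(phi0), r_max=r_max, dr=dr)
        trajs.append(tr)
        theta = tr.tangent_theta()
        # inner radial stub from near the disc margin to r0
        r_in = np.arange(2.0, R0, dr)
        pr = math.radians(tr.phi0)
        xin = CANONICAL_ONH[0] + r_in * math.cos(pr)
        yin = CANONICAL_ONH[1] + r_in * math.sin(pr)
        tin = np.full(r_in.shape, theta_from_vec(-math.cos(pr), -math.sin(pr)))
        xs = np.concatenate([xin, tr.xy[:, 0]])
        ys = np.concatenate([yin, tr.xy[:, 1]])
        ts = np.concatenate([tin, theta])
        row, col = ref.to_px(xs, ys)
        r_i = np.round(row).astype(int)
        c_i = np.round(col).astype(int)
        ok = (r_i >= 0) & (r_i < n) & (c_i >= 0) & (c_i < n)
        angle[r_i[ok], c_i[ok]] = ts[ok]
        valid[r_i[ok], c_i[ok]] = True

    if dilate_px > 0:
        dist, (ir, ic) = ndi.distance_transform_edt(~valid, return_indices=True)
        grow = dist <= dilate_px
        angle[grow] = angle[ir[grow], ic[grow]]
        valid |= grow
    ref.trajectories = trajs
    return ref


def reference_coverage(ref: ReferenceMap, fov: float = 45.0,
                       onh_exclusion_r: float = 2.0) -> float:
    """Fraction of retina pixels (field-of-view circle minus the ONH
    interior) carrying a valid reference angle."""
    n = ref.angle.shape[0]
    rows, cols = np.mgrid[0:n, 0:n]
    x, y = ref.to_deg(rows, cols)
    roi = np.hypot(x, y) <= fov / 2.0
    roi &= np.hypot(x - CANONICAL_ONH[0], y - CANONICAL_ONH[1]) > onh_exclusion_r
    return float(ref.valid[roi].mean())


# ---------------------------------------------------------------------------
# angular windows per region


@dataclass
class RegionWindows:
    """Admissible directed-orientation window for each of the 10 regions."""

    partition: RegionPartition
    windows: Dict[int, AngleWindow]
    margin: float

    def window_of(self, region_id: int) -> AngleWindow:
        return self.windows[int(region_id)]

    def mean_width(self) -> float:
        return float(np.mean([w.width for w in self.windows.values()]))


def region_windows(ref: ReferenceMap, partition: Optional[RegionPartition] = None,
                   margin: float = 0.0,
                   raphe_full_circle: bool = False) -> RegionWindows:
    """Per-region [min, max] windows of reference angles, widened by
    ``margin`` on each side (wraparound-aware)."""
    partition = partition or RegionPartition()
    n = ref.angle.shape[0]
    rows, cols = np.mgrid[0:n, 0:n]
    x, y = ref.to_deg(rows, cols)
    region = partition.assign(x, y)
    windows: Dict[int, AngleWindow] = {}
    for rid in range(1, RegionPartition.N_REGIONS + 1):
        sel = (region == rid) & ref.valid
        if not sel.any():
            raise WindowingError(f"region {rid} contains no valid reference pixels")
        if rid == 10 and raphe_full_circle:
            windows[rid] = AngleWindow(0.0, 360.0)
        else:
            windows[rid] = AngleWindow.from_angles(ref.angle[sel], margin=margin)
    return RegionWindows(partition=partition, windows=windows, margin=margin)


# ---------------------------------------------------------------------------
# ONH circumference sectors


#: Default ONH sectors in the nasal-origin clockwise convention
#: (name, lower boundary deg, width deg); half-open [lo, lo + width).
DEFAULT_SECTORS = (
    ("inferonasal", 51.0, 40.0),
    ("inferotemporal", 91.0, 40.0),
    ("temporal", 131.0, 90.0),
    ("superotemporal", 221.0, 40.0),
    ("superonasal", 261.0, 40.0),
    ("nasal", 301.0, 110.0),
)


@dataclass(frozen=True)
class OnhSectors:
    """Partition of the ONH circumference into labeled angular sectors."""

    sectors: tuple  # ((name, lo, width), ...)

    def __post_init__(self):
        widths = [w for _, _, w in self.sectors]
        if not math.isclose(sum(widths), 360.0, abs_tol=1e-9):
            raise ConfigError(f"sector widths sum to {sum(widths)}, need 360")
        los = sorted(wrap360(lo) for _, lo, _ in self.sectors)
        ends = sorted(wrap360(lo + w) for _, lo, w in self.sectors)
        if not np.allclose(los, ends):
            raise ConfigError("sectors overlap or fail to cover the circle")

    def sector_of(self, angle_deg: float) -> str:
        a = wrap360(angle_deg)
        for name, lo, width in self.sectors:
            if (a - lo) % 360.0 < width:
                return name
        raise ConfigError(f"angle {angle_deg} not covered by any sector")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([dict(name=n, lo=lo, width=w) for n, lo, w in self.sectors],
                      fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "OnhSectors":
        with open(path) as fh:
            data = json.load(fh)
        return cls(tuple((d["name"], float(d["lo"]), float(d["width"]))
                         for d in data))


def garway_heath_sectors(sectors: Optional[Sequence] = None) -> OnhSectors:
    """Six labeled angular sectors of the ONH circumference (defaults from
    the classical fundus structure-function sector map, expressed in the
    nasal-origin clockwise convention)."""
    return OnhSectors(tuple(sectors) if sectors is not None else DEFAULT_SECTORS)
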
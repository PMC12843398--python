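"""Optic nerve head and fovea localization, least-squares ellipse fitting,
and the five per-eye ocular covariates.

The ONH is modeled as an ellipse fitted (direct conic least squares with
ellipse constraint) to points sampled along the sharpest of two
independently detected boundary contours; the fovea is the center of the
darkest macular region, again taken from the sharper of two detections.
The five covariates are the horizontal and vertical fovea-ONH separations
(ONH_x, ONH_y, degrees), the disc-fovea angle atan(ONH_y/ONH_x), the
ellipticity ratio (minor/major radius) and the ONH area (pi * a * b, deg^2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .preprocess import FundusImage, InputError

log = logging.getLogger("pesrnfl")


class DetectionError(ValueError):
    """A landmark (ONH or fovea) could not be located."""


class FitError(ValueError):
    """Ellipse fitting failed (degenerate or non-elliptical input)."""


class GeometryError(ValueError):
    """Ocular geometry violates a structural requirement."""


#: Population distribution of the five ocular covariates
#: (per-column mean / SD / min / max).
TABLE1 = {
    "onh_x": dict(mean=16.54, sd=1.03, min=11.57, max=21.11),
    "onh_y": dict(mean=2.07, sd=1.02, min=0.04, max=6.01),
    "onh_fo_angle": dict(mean=7.07, sd=3.64, min=-2.60, max=19.76),
    "ellipticity": dict(mean=0.88, sd=0.07, min=0.48, max=0.99),
    "onh_area": dict(mean=38.45, sd=6.35, min=22.03, max=58.96),
}

COVARIATE_ORDER = ("onh_x", "onh_y", "onh_fo_angle", "ellipticity", "onh_area")


@dataclass(frozen=True)
class OnhGeometry:
    """Fitted ONH ellipse in retinal degree coordinates."""

    center_deg: tuple
    radius_major: float
    radius_minor: float
    orientation: float  # major-axis angle, deg CCW from +x, in [0, 180)

    def __post_init__(self):
        if not self.radius_major >= self.radius_minor > 0:
            raise FitError("need radius_major >= radius_minor > 0")

    @property
    def area_deg2(self) -> float:
        return math.pi * self.radius_major * self.radius_minor

    @property
    def ellipticity(self) -> float:
        return self.radius_minor / self.radius_major

    def implicit(self, x, y):
        """Signed implicit value: < 0 inside, 0 on the boundary, > 0 outside."""
        dx = np.asarray(x, float) - self.center_deg[0]
        dy = np.asarray(y, float) - self.center_deg[1]
        t = math.radians(self.orientation)
        u = dx * math.cos(t) + dy * math.sin(t)
        v = -dx * math.sin(t) + dy * math.cos(t)
        return (u / self.radius_major) ** 2 + (v / self.radius_minor) ** 2 - 1.0

    def boundary_point(self, alpha_deg: float) -> Tuple[float, float]:
        """Boundary point at angular position ``alpha_deg`` (nasal-origin,
        clockwise) around the center."""
        a = math.radians(alpha_deg)
        d = np.array([math.cos(a), -math.sin(a)])  # clockwise convention
        # scale the ray until it meets the ellipse
        t = math.radians(self.orientation)
        u = d[0] * math.cos(t) + d[1] * math.sin(t)
        v = -d[0] * math.sin(t) + d[1] * math.cos(t)
        r = 1.0 / math.sqrt((u / self.radius_major) ** 2 + (v / self.radius_minor) ** 2)
        return (self.center_deg[0] + r * d[0], self.center_deg[1] + r * d[1])


@dataclass(frozen=True)
class OcularParameters:
    """The five per-eye covariates used in the variability analysis."""

    onh_x: float
    onh_y: float  # signed, positive when the ONH center is superior
    onh_fo_angle: float
    ellipticity: float
    onh_area: float

    def as_tuple(self) -> tuple:
        return tuple(getattr(self, k) for k in COVARIATE_ORDER)


# ---------------------------------------------------------------------------
# contour detection


def _contour_sharpness(contour: np.ndarray, grad_mag: np.ndarray) -> float:
    """Mean gradient magnitude along a (row, col) contour (nearest-pixel)."""
    r = np.clip(np.round(contour[:, 0]).astype(int), 0, grad_mag.shape[0] - 1)
    c = np.clip(np.round(contour[:, 1]).astype(int), 0, grad_mag.shape[1] - 1)
    return float(grad_mag[r, c].mean())


def _closed_contour_at(smoothed: np.ndarray, level: float,
                       near_px: tuple) -> Optional[np.ndarray]:
    """The closed iso-contour at ``level`` whose centroid is nearest
    ``near_px``; None if no closed contour exists."""
    best, best_d = None, np.inf
    for cont in measure.find_contours(smoothed, level):
        if not np.allclose(cont[0], cont[-1]):
            continue
        cen = cont.mean(axis=0)
        d = float(np.hypot(cen[0] - near_px[0], cen[1] - near_px[1]))
        if d < best_d:
            best, best_d = cont, d
    return best


def detect_onh(img: FundusImage) -> Tuple[np.ndarray, float]:
    """ONH boundary contour (row, col) and its sharpness score.

    Two independent detections are run: (A) brightness-based - threshold the
    top percentile of a smoothed intensity image and take the largest
    component's boundary; (B) edge-based - the closed iso-contour at the
    half-maximum level enclosing the brightest region. The contour with the
    larger mean gradient magnitude wins; ties go to method A.
    """
    sigma = 0.25 * img.px_per_deg
    smoothed = ndi.gaussian_filter(img.pixels, sigma)
    inside = smoothed[img.roi_mask]
    if float(inside.max()) - float(np.median(inside)) < 0.02:
        raise DetectionError("no bright ONH candidate inside the ROI")
    gr, gc = np.gradient(smoothed)
    grad_mag = np.hypot(gr, gc)

    # method A: top-percentile brightness region
    t_a = np.percentile(inside, 99.0)
    mask = (smoothed >= t_a) & img.roi_mask
    labels, n = ndi.label(mask)
    contour_a = None
    if n > 0:
        sizes = ndi.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
        comp = labels == (1 + int(np.argmax(sizes)))
        conts = measure.find_contours(comp.astype(float), 0.5)
        if conts:
            contour_a = max(conts, key=len)

    # method B: half-maximum closed contour around the global brightest pixel
    masked = np.where(img.roi_mask, smoothed, -np.inf)
    peak = np.unravel_index(int(np.argmax(masked)), smoothed.shape)
    bg = float(np.median(inside))
    level = bg + 0.5 * (float(smoothed[peak]) - bg)
    contour_b = _closed_contour_at(smoothed, level, peak)

    candidates = []
    if contour_a is not None and len(contour_a) >= 5:
        candidates.append(("A", contour_a, _contour_sharpness(contour_a, grad_mag)))
    if contour_b is not None and len(contour_b) >= 5:
        candidates.append(("B", contour_b, _contour_sharpness(contour_b, grad_mag)))
    if not candidates:
        raise DetectionError("no bright ONH candidate inside the ROI")
    # sharper contour wins; ties (and near-ties at float precision) go to A
    candidates.sort(key=lambda t: (-t[2], t[0]))
    return candidates[0][1], candidates[0][2]


def detect_fovea(img: FundusImage,
                 onh_center_px: Optional[tuple] = None) -> Tuple[float, float]:
    """Fovea center (row, col) from the darker macular region.

    Method A is intensity-minimum based (darkest heavily smoothed pixel in
    the admissible region); method B is ring/edge based (centroid of the
    closed iso-contour at the half-depth level around that minimum). The
    detection whose contour is sharper wins; ties go to A. When
    ``onh_center_px`` is given, the search is restricted to the region
    temporal to the ONH.
    """
    ppd = img.px_per_deg
    if onh_center_px is None:
        # the admissible region is defined relative to the ONH (the macula
        # lies temporal to it); locate the disc first when not supplied
        contour, _ = detect_onh(img)
        onh_center_px = tuple(contour.mean(axis=0))
    # background-flattened view: a narrow minus a wide Gaussian leaves the
    # foveal dip but removes vignetting and other slow illumination trends
    narrow = ndi.gaussian_filter(img.pixels, 0.5 * ppd)
    wide = ndi.gaussian_filter(img.pixels, 3.0 * ppd)
    smoothed = narrow - wide
    search = ndi.binary_erosion(img.roi_mask,
                                iterations=max(int(1.0 * ppd), 1))
    if onh_center_px is not None:
        rows_g, cols_g = np.mgrid[0:img.shape[0], 0:img.shape[1]]
        d_onh = np.hypot(rows_g - onh_center_px[0], cols_g - onh_center_px[1])
        # plausible macular eccentricity, temporal side of the ONH
        search = search & (d_onh > 8.0 * ppd) & (d_onh < 24.0 * ppd)
        search = search & (cols_g < onh_center_px[1] - 4.0 * ppd)
    if not search.any():
        raise DetectionError("no admissible macular search region")
    inside = smoothed[search]
    med = float(np.median(inside))
    masked = np.where(search, smoothed, np.inf)
    argmin = np.unravel_index(int(np.argmin(masked)), smoothed.shape)
    depth = med - float(smoothed[argmin])
    if depth < 0.02:  # no dip below the macular background worth the name
        raise DetectionError("no dark macular region found")

    gr, gc = np.gradient(smoothed)
    grad_mag = np.hypot(gr, gc)
    vmin = float(smoothed[argmin])

    # method A: intensity minimum; its score comes from the tight iso-ring
    # close to the minimum. method B: centroid of the wider half-depth ring.
    candidates = []
    contour_a = _closed_contour_at(smoothed, vmin + 0.25 * depth, argmin)
    point_a = (float(argmin[0]), float(argmin[1]))
    if contour_a is not None and len(contour_a) >= 5:
        candidates.append(("A", point_a, _contour_sharpness(contour_a, grad_mag)))
    else:
        candidates.append(("A", point_a, 0.0))
    contour_b = _closed_contour_at(smoothed, vmin + 0.5 * depth, argmin)
    if contour_b is not None and len(contour_b) >= 5:
        cen = contour_b.mean(axis=0)
        if np.hypot(cen[0] - argmin[0], cen[1] - argmin[1]) < 2.0 * img.px_per_deg:
            candidates.append(("B", (float(cen[0]), float(cen[1])),
                               _contour_sharpness(contour_b, grad_mag)))
    candidates.sort(key=lambda t: (-t[2], t[0]))  # sharper wins, ties to A
    return candidates[0][1]


# ---------------------------------------------------------------------------
# ellipse fitting


def boundary_points(contour: np.ndarray, k: int = 5) -> np.ndarray:
    """``k`` points sampled at equal arc length along a closed contour."""
    contour = np.asarray(contour, dtype=float)
    if len(contour) < k:
        raise InputError(f"contour has {len(contour)} points, need >= {k}")
    closed = contour if np.allclose(contour[0], contour[-1]) \
        else np.vstack([contour, contour[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise InputError("contour has zero length")
    targets = np.arange(k) * total / k
    out = np.empty((k, 2))
    for d in range(2):
        out[:, d] = np.interp(targets, s, closed[:, d])
    return out


def fit_ellipse_lsq(points: np.ndarray) -> OnhGeometry:
    """Direct least-squares conic fit constrained to an ellipse.

    Uses the numerically stable partitioned formulation of the
    ellipse-specific direct fit (constraint 4ac - b^2 = 1). Points are
    (x, y) pairs in degrees; raises FitError for degenerate inputs or when
    no elliptical solution exists.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise FitError("need at least 5 (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    # normalize for conditioning
    mx, my = x.mean(), y.mean()
    sc = max(np.abs(x - mx).max(), np.abs(y - my).max(), 1e-12)
    xn, yn = (x - mx) / sc, (y - my) / sc

    d1 = np.column_stack([xn * xn, xn * yn, yn * yn])
    d2 = np.column_stack([xn, yn, np.ones_like(xn)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError as exc:
        raise FitError("degenerate point configuration") from exc
    m = s1 + s2 @ t
    c1inv = np.array([[0.0, 0.0, 0.5], [0.0, -1.0, 0.0], [0.5, 0.0, 0.0]])
    try:
        evals, evecs = np.linalg.eig(c1inv @ m)
    except np.linalg.LinAlgError as exc:
        raise FitError("eigendecomposition failed") from exc
    cond = 4.0 * evecs[0] * evecs[2] - evecs[1] ** 2
    ok = np.isreal(evals) & (cond > 0)
    if not ok.any():
        raise FitError("no elliptical solution (degenerate or hyperbolic fit)")
    a1 = np.real(evecs[:, np.argmax(ok)])
    coeffs = np.concatenate([a1, t @ a1])  # A, B, C, D, E, F in normalized frame

    A, B, C, D, E, F = coeffs
    den = B * B - 4.0 * A * C
    if den >= 0:
        raise FitError("fit is not an ellipse")
    x0 = (2.0 * C * D - B * E) / den
    y0 = (2.0 * A * E - B * D) / den
    f0 = A * x0 * x0 + B * x0 * y0 + C * y0 * y0 + D * x0 + E * y0 + F
    mat = np.array([[A, B / 2.0], [B / 2.0, C]])
    w, v = np.linalg.eigh(mat)
    axes2 = -f0 / w
    if np.any(axes2 <= 0):
        raise FitError("fit is not a real ellipse")
    axes = np.sqrt(axes2)
    major = int(np.argmax(axes))
    orientation = math.degrees(math.atan2(v[1, major], v[0, major])) % 180.0
    return OnhGeometry(
        center_deg=(float(x0 * sc + mx), float(y0 * sc + my)),
        radius_major=float(axes[major] * sc),
        radius_minor=float(axes[1 - major] * sc),
        orientation=float(orientation),
    )


def ocular_parameters(onh: OnhGeometry, fovea_deg: tuple = (0.0, 0.0),
                      warn_outside_table1: bool = True) -> OcularParameters:
    """The five covariates from fitted geometry.

    ONH_x is the absolute horizontal fovea-ONH separation; ONH_y is the
    vertical separation of the ONH center from the horizontal meridian
    through the fovea, signed positive superior; the disc-fovea angle is
    atan(ONH_y / ONH_x) in degrees.
    """
    dx = abs(onh.center_deg[0] - fovea_deg[0])
    dy = onh.center_deg[1] - fovea_deg[1]
    if dx == 0:
        raise GeometryError("ONH_x is zero: ONH and fovea vertically aligned")
    params = OcularParameters(
        onh_x=float(dx),
        onh_y=float(dy),
        onh_fo_angle=float(math.degrees(math.atan(dy / dx))),
        ellipticity=float(onh.ellipticity),
        onh_area=float(onh.area_deg2),
    )
    if warn_outside_table1:
        for name in COVARIATE_ORDER:
            v = getattr(params, name)
            rng = TABLE1[name]
            if not rng["min"] <= v <= rng["max"]:
                log.warning("%s = %.3f outside the population range [%g, %g]",
                            name, v, rng["min"], rng["max"])
    return params
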
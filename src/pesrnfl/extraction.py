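"""Pointwise retinal nerve fiber extraction: local max-min contrast
modulation, Otsu binarization, vessel subtraction and per-segment directed
orientations.

A "pointwise RNF extraction" is one connected component of the cleaned
binary fiber map: its centroid, size and directed orientation (principal
axis of the component, with the sense chosen to point along the fiber
toward the optic nerve head, expressed in the nasal-origin clockwise
convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional

import numpy as np
from scipy import ndimage as ndi

from .config import BASE_PX_PER_DEG, ExtractionConfig
from .preprocess import FundusImage, InputError, ParameterError


class DegenerateInputError(ValueError):
    """Input has no usable intensity structure (e.g. a constant image)."""


@dataclass
class PointwiseExtraction:
    """One detected fiber segment."""

    centroid_px: tuple  # (row, col)
    theta: float  # directed orientation, deg in [0, 360), toward the ONH
    n_pixels: int
    region_id: int = 0  # 1..10 once assigned from the FOV partition; 0 before
    centroid_deg: Optional[tuple] = None  # (x, y) retinal degrees


def mm_modulate(img: FundusImage, window: Optional[int] = None) -> FundusImage:
    """Maximum-minimum modulation: sliding-window min-max normalization.

    v' = (v - min_W) / (max_W - min_W) over the window W centered at each
    pixel, restricted to ROI members; flat windows map to 0. Invariant under
    affine rescaling of the input, which is what makes faint striations as
    prominent as high-contrast structure.
    """
    if window is None:
        scale = img.px_per_deg / BASE_PX_PER_DEG
        window = int(round(ExtractionConfig().mm_window * scale))
        window = max(window + (window % 2 == 0), 3)
    if window % 2 == 0 or window < 3:
        raise ParameterError(f"MM window must be odd and >= 3, got {window}")
    p = img.pixels
    hi_src = np.where(img.roi_mask, p, -np.inf)
    lo_src = np.where(img.roi_mask, p, np.inf)
    mx = ndi.maximum_filter(hi_src, size=window, mode="constant", cval=-np.inf)
    mn = ndi.minimum_filter(lo_src, size=window, mode="constant", cval=np.inf)
    rng = mx - mn
    with np.errstate(invalid="ignore"):
        out = np.where(np.isfinite(rng) & (rng > 0), (p - mn) / np.where(rng > 0, rng, 1.0), 0.0)
    out = np.where(img.roi_mask, np.clip(out, 0.0, 1.0), 0.0)
    return replace(img, pixels=out)


def otsu_from_values(values: np.ndarray) -> float:
    """Otsu threshold of a 1D sample over a 256-bin histogram on [0, 1].

    Maximizes between-class variance; ties break toward the lowest
    qualifying bin. Returns the upper edge of the chosen bin so that
    ``pixels > t`` selects the upper class.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0 or np.ptp(v) == 0:
        raise DegenerateInputError("Otsu requires at least two distinct values")
    nbins = 256
    hist, edges = np.histogram(v, bins=nbins, range=(0.0, 1.0))
    p = hist.astype(float) / hist.sum()
    omega = np.cumsum(p)
    mu = np.cumsum(p * np.arange(nbins))
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    k = int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximizer
    return float(edges[k + 1])


def otsu_threshold(img: FundusImage) -> float:
    """Otsu threshold of the ROI pixels of an image (see otsu_from_values)."""
    return otsu_from_values(img.pixels[img.roi_mask])


def binarize_rnf(img: FundusImage) -> np.ndarray:
    """Otsu-binarized fiber candidate map restricted to the ROI."""
    t = otsu_threshold(img)
    return (img.pixels > t) & img.roi_mask


#: minimum elongation (major/minor axis ratio of the pixel covariance) for a
#: component's principal-axis orientation to be considered defined; round
#: noise blobs fall below it, fiber streaks sit well above
MIN_ELONGATION = 2.0


def _principal_axis(rows: np.ndarray, cols: np.ndarray,
                    min_elongation: float = MIN_ELONGATION) -> Optional[float]:
    """Undirected principal-axis orientation of component pixels.

    Returned as an angle in [0, 180) in the clockwise (image) convention
    computed from second central moments; None for (near-)isotropic
    components, whose orientation is numerically undefined.
    """
    r = rows - rows.mean()
    c = cols - cols.mean()
    mcc = float((c * c).mean())
    mrr = float((r * r).mean())
    mrc = float((r * c).mean())
    # eigenvalues of the pixel covariance: elongation = sqrt(l_max / l_min)
    tr_half = (mcc + mrr) / 2.0
    disc = math.sqrt(((mcc - mrr) / 2.0) ** 2 + mrc * mrc)
    l_min = tr_half - disc
    if l_min <= 1e-12:
        l_min = 1e-12  # single-pixel-wide component: perfectly elongated
    if math.sqrt((tr_half + disc) / l_min) < min_elongation:
        return None
    # direction of largest variance in (x, y) = (col, -row) coordinates
    # cov([x, y]) = [[mcc, -mrc], [-mrc, mrr]]
    ang = 0.5 * math.degrees(math.atan2(2.0 * (-mrc), mcc - mrr))
    # ang is CCW in (x, y); clockwise convention negates it
    return (-ang) % 180.0


def extract_segments(rnf_binary: np.ndarray, vessel_mask: np.ndarray,
                     min_size: int, onh_center_px: tuple) -> List[PointwiseExtraction]:
    """Connected components of the cleaned fiber map as pointwise extractions.

    The clean map is ``rnf_binary AND NOT vessel_mask``; 8-connected
    components of at least ``min_size`` pixels are kept. Each component's
    undirected principal axis is directed by choosing the sense that heads
    toward ``onh_center_px`` (row, col); components that are isotropic or
    exactly perpendicular to the ONH direction are dropped as
    orientation-undefined.
    """
    rnf_binary = np.asarray(rnf_binary, bool)
    vessel_mask = np.asarray(vessel_mask, bool)
    if rnf_binary.shape != vessel_mask.shape:
        raise InputError("fiber map and vessel mask shapes differ")
    clean = rnf_binary & ~vessel_mask
    labels, n = ndi.label(clean, structure=np.ones((3, 3), int))
    if n == 0:
        return []
    out: List[PointwiseExtraction] = []
    onh_r, onh_c = float(onh_center_px[0]), float(onh_center_px[1])
    objects = ndi.find_objects(labels)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        sub = labels[sl] == lab
        size = int(sub.sum())
        if size < min_size:
            continue
        rr, cc = np.nonzero(sub)
        rows = rr + sl[0].start
        cols = cc + sl[1].start
        axis = _principal_axis(rows.astype(float), cols.astype(float))
        if axis is None:
            continue
        cr, cc_ = float(rows.mean()), float(cols.mean())
        # two candidate senses; pick the one that reduces distance to the ONH
        to_onh = np.array([onh_c - cc_, -(onh_r - cr)])  # (dx, dy), y = -row
        t = math.radians(axis)
        u = np.array([math.cos(t), -math.sin(t)])
        dot = float(u @ to_onh)
        if abs(dot) < 1e-9:
            continue  # perpendicular: heading toward the ONH is undefined
        theta = axis if dot > 0 else (axis + 180.0) % 360.0
        out.append(PointwiseExtraction(centroid_px=(cr, cc_), theta=float(theta),
                                       n_pixels=size))
    return out


def extractions_to_table(extractions: List[PointwiseExtraction]):
    """Extraction list as a pandas DataFrame (CSV-exportable)."""
    import pandas as pd

    rows = []
    for e in extractions:
        x, y = e.centroid_deg if e.centroid_deg is not None else (np.nan, np.nan)
        rows.append(dict(row=e.centroid_px[0], col=e.centroid_px[1], x_deg=x,
                         y_deg=y, theta_deg=e.theta, region_id=e.region_id,
                         n_pixels=e.n_pixels))
    return pd.DataFrame(rows, columns=["row", "col", "x_deg", "y_deg",
                                       "theta_deg", "region_id", "n_pixels"])
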
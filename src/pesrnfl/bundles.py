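"""Bundle assembly: orientation-window filtering of pointwise extractions,
greedy neighbor linking into marker chains, Bezier curve fitting, and ONH
entrance angles.

Chains are grown greedily from the extraction farthest from the ONH: the
next member is the nearest unused extraction within the link radius whose
orientation agrees with the current member (individual tolerance), with the
chain's running circular mean (group tolerance) and with the bearing from
the current member (so chains follow fibers instead of hopping sideways
between parallel ones). A chain becomes a bundle when it has at least
order_n + 1 markers, the minimum for a degree-order_n Bezier fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import comb

from .config import BundleConfig
from .extraction import PointwiseExtraction
from .geometry import circ_abs_diff, theta_from_vec, wrap360
from .landmarks import OnhGeometry
from .refmaps import RegionWindows


class FitError(ValueError):
    """Curve fitting failed (too few markers or a degenerate system)."""


@dataclass
class Bundle:
    """One assembled fiber bundle."""

    markers: np.ndarray  # (M, 2) ordered centroids, degrees
    order_n: int
    control_points: np.ndarray  # (order_n + 1, 2)
    entrance_angle: Optional[float]  # deg in [0, 360), None if non-entering
    region_trace: List[int]


def filter_extractions(extractions: Sequence[PointwiseExtraction],
                       windows: RegionWindows) -> List[PointwiseExtraction]:
    """Keep extractions whose theta lies inside their region's closed,
    wraparound-aware angular window (false-positive suppression)."""
    kept = []
    for e in extractions:
        w = windows.window_of(e.region_id)
        if bool(w.contains(e.theta)):
            kept.append(e)
    return kept


def link_extractions(kept: Sequence[PointwiseExtraction], link_radius: float,
                     tol_individual: float, tol_group: float,
                     onh_center: tuple) -> List[List[PointwiseExtraction]]:
    """Greedy chain growth over the kept extractions (degree coordinates).

    Seeds are taken farthest-from-ONH first; each extraction joins at most
    one chain. Unlinkable extractions remain singleton chains (discarded
    later by the minimum-marker rule).
    """
    if len(kept) == 0:
        return []
    pts = np.array([e.centroid_deg for e in kept], dtype=float)
    thetas = np.array([e.theta for e in kept], dtype=float)
    d_onh = np.hypot(pts[:, 0] - onh_center[0], pts[:, 1] - onh_center[1])
    tree = cKDTree(pts)
    used = np.zeros(len(kept), dtype=bool)
    chains: List[List[int]] = []
    for seed in np.argsort(-d_onh, kind="stable"):
        if used[seed]:
            continue
        chain = [int(seed)]
        used[seed] = True
        mean_vec = np.array([math.cos(math.radians(thetas[seed])),
                             -math.sin(math.radians(thetas[seed]))])
        cur = int(seed)
        while True:
            cand = [i for i in tree.query_ball_point(pts[cur], link_radius)
                    if not used[i]]
            if not cand:
                break
            cand = np.array(cand)
            mean_theta = theta_from_vec(mean_vec[0], mean_vec[1])
            bearing = theta_from_vec(pts[cand, 0] - pts[cur, 0],
                                     pts[cand, 1] - pts[cur, 1])
            ok = (circ_abs_diff(thetas[cand], thetas[cur]) <= tol_individual)
            ok &= circ_abs_diff(thetas[cand], mean_theta) <= tol_group
            ok &= circ_abs_diff(bearing, thetas[cur]) <= tol_individual
            ok &= circ_abs_diff(bearing, thetas[cand]) <= tol_individual
            cand = cand[ok]
            if cand.size == 0:
                break
            dist = np.hypot(pts[cand, 0] - pts[cur, 0], pts[cand, 1] - pts[cur, 1])
            nxt = int(cand[np.argmin(dist)])
            chain.append(nxt)
            used[nxt] = True
            t = math.radians(thetas[nxt])
            mean_vec = mean_vec + np.array([math.cos(t), -math.sin(t)])
            cur = nxt
        chains.append(chain)
    # chains come out ordered by decreasing seed distance to the ONH
    return [[kept[i] for i in chain] for chain in chains]


def bernstein_matrix(t: np.ndarray, order_n: int) -> np.ndarray:
    """Bernstein basis matrix B[i, k] = C(n, k) t_i^k (1 - t_i)^(n - k)."""
    t = np.asarray(t, dtype=float)[:, None]
    k = np.arange(order_n + 1)[None, :]
    return comb(order_n, k) * t ** k * (1.0 - t) ** (order_n - k)


def bezier_eval(control_points: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Evaluate a Bezier curve at parameter values t in [0, 1]."""
    cp = np.asarray(control_points, dtype=float)
    return bernstein_matrix(t, cp.shape[0] - 1) @ cp


def chord_length_params(markers: np.ndarray) -> np.ndarray:
    """Normalized cumulative chord-length parameter values for the markers."""
    markers = np.asarray(markers, dtype=float)
    seg = np.hypot(*np.diff(markers, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        return np.linspace(0.0, 1.0, len(markers))
    return s / s[-1]


def fit_bezier(markers: np.ndarray, order_n: int = 10,
               params: Optional[np.ndarray] = None) -> np.ndarray:
    """Least-squares degree-``order_n`` Bezier fit to ordered markers.

    Markers are assigned parameter values by normalized chord length unless
    ``params`` is given explicitly. With exactly order_n + 1 markers the
    system is square and the curve interpolates them.
    """
    markers = np.asarray(markers, dtype=float)
    if markers.ndim != 2 or markers.shape[1] != 2:
        raise FitError("markers must be an (M, 2) array")
    if markers.shape[0] < order_n + 1:
        raise FitError(f"need at least {order_n + 1} markers, got {markers.shape[0]}")
    t = chord_length_params(markers) if params is None else np.asarray(params, float)
    basis = bernstein_matrix(t, order_n)
    cp, *_ = np.linalg.lstsq(basis, markers, rcond=None)
    return cp


def entrance_angle(control_points: np.ndarray, onh: OnhGeometry,
                   n_samples: int = 2000) -> Optional[float]:
    """Angular position where the curve first crosses into the ONH ellipse.

    The Bezier is evaluated densely; the first parameter interval whose
    endpoints straddle the boundary (outside -> inside) is refined by
    bisection, and the crossing point's angular position around the ONH
    center (nasal-origin, clockwise) is returned. None when the curve never
    enters the ellipse.
    """
    t = np.linspace(0.0, 1.0, n_samples)
    xy = bezier_eval(control_points, t)
    f = onh.implicit(xy[:, 0], xy[:, 1])
    crossing = np.nonzero((f[:-1] > 0) & (f[1:] <= 0))[0]
    if crossing.size == 0:
        return None
    i = int(crossing[0])
    lo, hi = t[i], t[i + 1]
    for _ in range(60):  # bisection far below the 0.01 deg requirement
        mid = 0.5 * (lo + hi)
        p = bezier_eval(control_points, np.array([mid]))[0]
        if onh.implicit(p[0], p[1]) > 0:
            lo = mid
        else:
            hi = mid
    p = bezier_eval(control_points, np.array([0.5 * (lo + hi)]))[0]
    return float(wrap360(theta_from_vec(p[0] - onh.center_deg[0],
                                        p[1] - onh.center_deg[1])))


def assemble_bundles(kept: Sequence[PointwiseExtraction], onh: OnhGeometry,
                     config: Optional[BundleConfig] = None) -> List[Bundle]:
    """Link kept extractions, fit Bezier curves and compute entrance angles.

    Chains shorter than order_n + 1 markers are discarded. Markers are
    sorted by decreasing distance to the ONH center before fitting (the
    deterministic tie-break for the chord-length parameterization), so the
    fitted curve runs outward-in and its first ellipse crossing is the
    bundle's entrance.
    """
    cfg = config or BundleConfig()
    chains = link_extractions(kept, cfg.link_radius_deg, cfg.tol_individual_deg,
                              cfg.tol_group_deg, onh.center_deg)
    bundles = []
    for chain in chains:
        if len(chain) < cfg.order_n + 1:
            continue
        markers = np.array([e.centroid_deg for e in chain], dtype=float)
        d = np.hypot(markers[:, 0] - onh.center_deg[0],
                     markers[:, 1] - onh.center_deg[1])
        order = np.argsort(-d, kind="stable")
        markers = markers[order]
        cp = fit_bezier(markers, cfg.order_n)
        ang = entrance_angle(cp, onh)
        trace = []
        for e in (chain[i] for i in order):
            if not trace or trace[-1] != e.region_id:
                trace.append(e.region_id)
        bundles.append(Bundle(markers=markers, order_n=cfg.order_n,
                              control_points=cp, entrance_angle=ang,
                              region_trace=trace))
    return bundles
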
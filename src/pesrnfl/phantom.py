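"""Synthetic fundus phantoms with known ground truth.

A phantom emulates the features of a macula-centered 45-deg fundus
photograph that the segmentation pipeline relies on: faint nerve-fiber
striations following the trajectory model (rendered as short interrupted
streaks, the way real striations present), darker tubular blood vessels
along the arcades, a bright elliptical ONH, a dark fovea, radial
vignetting and Gaussian sensor noise. Ocular geometry is sampled from the
study-population distributions (truncated normals within the published
min/max), and the ground truth (trajectories, tangent-angle map, landmark
geometry) is recorded before noise, so every pipeline stage can be scored
against a known answer.

A separate cohort generator produces covariate/response tables for the
variability analysis without rendering images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats as sps

from .geometry import CANONICAL_ONH, EyeAlignment, theta_from_vec, wrap360
from .landmarks import COVARIATE_ORDER, TABLE1, OcularParameters, OnhGeometry
from .preprocess import FundusImage, ParameterError
from .refmaps import Trajectory, trajectory
from .vfmap import align_normalize


def sample_ocular_params(n: int, seed: int = 0) -> List[OcularParameters]:
    """Draw ``n`` eyes from the population distributions.

    Each covariate is a truncated normal with the published mean/SD,
    truncated at the published min/max. The disc-fovea angle is recomputed
    as atan(onh_y / onh_x) for internal geometric consistency (the directly
    sampled angle is discarded); area and ellipticity are sampled
    independently.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    draws = {}
    for name in COVARIATE_ORDER:
        t = TABLE1[name]
        a = (t["min"] - t["mean"]) / t["sd"]
        b = (t["max"] - t["mean"]) / t["sd"]
        draws[name] = sps.truncnorm.rvs(a, b, loc=t["mean"], scale=t["sd"],
                                        size=n, random_state=rng)
    out = []
    for i in range(n):
        x, y = float(draws["onh_x"][i]), float(draws["onh_y"][i])
        out.append(OcularParameters(
            onh_x=x, onh_y=y,
            onh_fo_angle=math.degrees(math.atan(y / x)),
            ellipticity=float(draws["ellipticity"][i]),
            onh_area=float(draws["onh_area"][i])))
    return out


@dataclass
class PhantomSpec:
    """Full description of one phantom; the seed determines every pixel."""

    resolution: tuple = (960, 1440)  # rows, cols
    fov_deg: float = 45.0
    params: Optional[OcularParameters] = None  # None: sampled from the population
    n_trajectories: int = 72  # evenly spaced starting positions on the r0 circle
    striation_width_deg: float = 0.12
    striation_contrast: float = 0.05
    dash_len_deg: float = 0.6
    gap_len_deg: float = 0.25
    vessel_count: int = 4
    vessel_width_deg: float = 0.35
    vessel_contrast: float = 0.15
    onh_contrast: float = 0.25
    fovea_depth: float = 0.12
    background: float = 0.55
    vignetting: float = 0.3
    noise_sd: float = 0.01
    raphe_gaps: bool = False
    seed: int = 0


@dataclass
class PhantomTruth:
    """Ground truth recorded while rendering (before noise)."""

    params: OcularParameters
    onh: OnhGeometry  # eye frame, degrees, fovea at origin
    fovea_px: tuple
    alignment: EyeAlignment  # true eye -> canonical transform
    trajectories: List[Trajectory]  # canonical-frame model curves
    traj_xy_eye: List[np.ndarray]  # the same curves in the eye frame
    traj_theta_eye: List[np.ndarray]  # directed tangents, eye frame
    entrance_eye: np.ndarray  # per-trajectory ONH entrance angle, eye frame
    angle_map: np.ndarray  # per-pixel true tangent angle (deg), eye image
    angle_valid: np.ndarray
    vessel_centerlines_px: List[np.ndarray]


def _true_onh_geometry(params: OcularParameters) -> OnhGeometry:
    a = math.sqrt(params.onh_area / (math.pi * params.ellipticity))
    return OnhGeometry(center_deg=(params.onh_x, params.onh_y),
                       radius_major=a, radius_minor=params.ellipticity * a,
                       orientation=90.0)  # discs are typically taller than wide


def _deposit_lines(canvas: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> None:
    """Mark nearest pixels of subpixel-sampled centerlines (max deposit 1)."""
    h, w = canvas.shape
    r = np.round(rows).astype(int)
    c = np.round(cols).astype(int)
    ok = (r >= 0) & (r < h) & (c >= 0) & (c < w)
    canvas[r[ok], c[ok]] = 1.0


def render_phantom(spec: PhantomSpec) -> Tuple[FundusImage, PhantomTruth]:
    """Render one phantom and its ground truth."""
    h, w = spec.resolution
    if h < 480 or w < 640:
        raise ParameterError(f"resolution {spec.resolution} below 480x640")
    rng = np.random.default_rng(spec.seed)
    params = spec.params or sample_ocular_params(1, seed=spec.seed)[0]
    ppd = w / spec.fov_deg
    fovea_px = (h / 2.0, w / 2.0)

    def deg_to_px(x, y):
        return fovea_px[0] - np.asarray(y, float) * ppd, \
            fovea_px[1] + np.asarray(x, float) * ppd

    onh = _true_onh_geometry(params)
    alignment = align_normalize(onh)  # true eye -> canonical transform
    inv = alignment.inverse()

    rows_i, cols_i = np.mgrid[0:h, 0:w]
    xg = (cols_i - fovea_px[1]) / ppd
    yg = (fovea_px[0] - rows_i) / ppd
    r_fov = spec.fov_deg / 2.0
    d2 = xg * xg + yg * yg
    roi = d2 <= (0.99 * r_fov) ** 2

    # background with radial vignetting
    img = spec.background * (1.0 - spec.vignetting * d2 / (r_fov * r_fov))
    # bright elliptical ONH with a soft sigmoid edge
    from scipy.special import expit

    f_onh = onh.implicit(xg, yg)
    img += spec.onh_contrast * expit(-f_onh / 0.08)
    # dark fovea
    img -= spec.fovea_depth * np.exp(-d2 / (2.0 * 0.7 ** 2))

    # --- striations along model trajectories, as interrupted streaks -------
    dphi0 = 360.0 / spec.n_trajectories
    phi0s = np.round(np.arange(-180.0 + dphi0, 180.0 + 0.5 * dphi0, dphi0), 9)
    trajs, xy_eyes, theta_eyes, entr = [], [], [], []
    centerline = np.zeros((h, w))
    angle_map = np.zeros((h, w))
    angle_valid = np.zeros((h, w), dtype=bool)
    period = spec.dash_len_deg + spec.gap_len_deg
    r_disc = 0.5 * onh.radius_minor * alignment.scale  # canonical units
    for phi0 in phi0s:
        tr = trajectory(float(phi0), r_max=1.5 * r_fov, dr=0.1 / ppd * 4.0)
        if len(tr.xy) < 4:
            continue
        # fibers converge to the disc margin: prepend a radial stub r < r0
        pr = math.radians(tr.phi0)
        r_in = np.arange(r_disc, 4.0, 0.4 / ppd)
        xin = CANONICAL_ONH[0] + r_in * np.cos(pr)
        yin = CANONICAL_ONH[1] + r_in * np.sin(pr)
        xy_can = np.vstack([np.column_stack([xin, yin]), tr.xy])
        th_can = np.concatenate([
            np.full(r_in.shape, theta_from_vec(-math.cos(pr), -math.sin(pr))),
            tr.tangent_theta()])
        xe, ye = inv.apply_points(xy_can[:, 0], xy_can[:, 1])
        th_e = inv.apply_theta(th_can)
        trajs.append(tr)
        xy_eyes.append(np.column_stack([xe, ye]))
        theta_eyes.append(th_e)
        entr.append(wrap360(-tr.phi0 + alignment.rotation_deg))

        seg = np.hypot(np.diff(xe), np.diff(ye))
        s = np.concatenate([[0.0], np.cumsum(seg)])
        phase = rng.uniform(0.0, period)
        on = ((s + phase) % period) < spec.dash_len_deg
        on &= roi[np.clip(np.round(deg_to_px(xe, ye)[0]).astype(int), 0, h - 1),
                  np.clip(np.round(deg_to_px(xe, ye)[1]).astype(int), 0, w - 1)]
        if spec.raphe_gaps:
            near_raphe = (xy_can[:, 0] < -4.0) & (np.abs(xy_can[:, 1] - 2.0) < 2.0)
            on &= ~near_raphe
        rr, cc = deg_to_px(xe[on], ye[on])
        _deposit_lines(centerline, rr, cc)
        ri = np.clip(np.round(rr).astype(int), 0, h - 1)
        ci = np.clip(np.round(cc).astype(int), 0, w - 1)
        angle_map[ri, ci] = th_e[on]
        angle_valid[ri, ci] = True

    sigma_w = max(spec.striation_width_deg * ppd / 2.355, 0.6)  # width = FWHM
    striations = ndi.gaussian_filter(centerline, sigma_w)
    striations *= spec.striation_contrast * math.sqrt(2.0 * math.pi) * sigma_w
    img += np.where(roi, striations, 0.0)

    # grow the truth map out to the striation width (nearest centerline angle)
    if angle_valid.any():
        dist, (ir, ic) = ndi.distance_transform_edt(~angle_valid,
                                                    return_indices=True)
        grow = dist <= max(3.0 * sigma_w, 2.0)
        angle_map[grow] = angle_map[ir[grow], ic[grow]]
        angle_valid |= grow

    # --- vessels: smooth dark tubes along arcade-like courses --------------
    arcade_phi0 = [112.0, -112.0, 140.0, -140.0, 75.0, -75.0]
    vessel_canvas = np.zeros((h, w))
    vessel_lines = []
    for phi0 in arcade_phi0[:spec.vessel_count]:
        tr = trajectory(phi0, r_max=1.5 * r_fov, dr=0.1 / ppd * 4.0)
        xe, ye = inv.apply_points(tr.xy[:, 0], tr.xy[:, 1])
        rr, cc = deg_to_px(xe, ye)
        _deposit_lines(vessel_canvas, rr, cc)
        vessel_lines.append(np.column_stack([rr, cc]))
    sigma_v = max(spec.vessel_width_deg * ppd / 2.0, 0.8)
    vessels = ndi.gaussian_filter(vessel_canvas, sigma_v)
    vessels *= spec.vessel_contrast * math.sqrt(2.0 * math.pi) * sigma_v
    img -= np.where(roi, vessels, 0.0)

    if spec.noise_sd > 0:
        img = img + spec.noise_sd * rng.standard_normal((h, w))
    img = np.where(roi, np.clip(img, 0.0, 1.0), 0.0)

    fundus = FundusImage(pixels=img, roi_mask=roi, fov_deg=spec.fov_deg,
                         eye="right", source_path=f"phantom(seed={spec.seed})")
    fundus.fovea_px = fovea_px
    truth = PhantomTruth(params=params, onh=onh, fovea_px=fovea_px,
                         alignment=alignment, trajectories=trajs,
                         traj_xy_eye=xy_eyes, traj_theta_eye=theta_eyes,
                         entrance_eye=np.array(entr), angle_map=angle_map,
                         angle_valid=angle_valid,
                         vessel_centerlines_px=vessel_lines)
    return fundus, truth


def phantom_to_rgb(img: FundusImage) -> np.ndarray:
    """8-bit RGB rendering with a fundus-like tint (signal on green)."""
    g = img.pixels
    r = np.clip(0.45 + 0.55 * g, 0.0, 1.0)
    b = 0.25 * g
    rgb = np.stack([r, g, b], axis=-1)
    rgb = np.where(img.roi_mask[..., None], rgb, 0.0)
    return (rgb * 255.0 + 0.5).astype(np.uint8)


# ---------------------------------------------------------------------------
# cohort generator for the variability analysis

#: effect model: vf_index -> (intercept_deg, {covariate: deg per unit})
EffectModel = Dict[int, Tuple[float, Dict[str, float]]]

DEFAULT_EFFECTS: EffectModel = {
    # a handful of locations driven by ONH position and disc-fovea angle,
    # the dominant predictors in the population analysis
    22: (150.0, {"onh_x": 1.5, "onh_fo_angle": 2.0}),
    30: (210.0, {"onh_x": 1.5, "onh_fo_angle": 2.0}),
    38: (200.0, {"onh_x": 1.5, "onh_fo_angle": 2.0}),
}


def synthetic_cohort(n_eyes: int, effect_model: Optional[EffectModel] = None,
                     noise_sd: float = 2.0, seed: int = 0):
    """Covariate and per-location response tables for a synthetic cohort.

    Covariates come from ``sample_ocular_params``; the response at each
    location is the effect model's linear predictor plus Gaussian noise of
    ``noise_sd`` degrees. Returns (covariates DataFrame, responses
    DataFrame indexed like the covariates with one column per vf location,
    truth dict vf_index -> tuple of true predictor names).
    """
    effect_model = DEFAULT_EFFECTS if effect_model is None else effect_model
    rng = np.random.default_rng(seed)
    params = sample_ocular_params(n_eyes, seed=int(rng.integers(2 ** 31)))
    cov = pd.DataFrame([dict(zip(COVARIATE_ORDER, p.as_tuple())) for p in params])
    responses = {}
    truth = {}
    for vf_index, (intercept, effects) in effect_model.items():
        y = np.full(n_eyes, float(intercept))
        for name, coef in effects.items():
            y = y + coef * cov[name].to_numpy()
        if noise_sd > 0:
            y = y + noise_sd * rng.standard_normal(n_eyes)
        responses[vf_index] = y
        truth[vf_index] = tuple(k for k in COVARIATE_ORDER if k in effects)
    return cov, pd.DataFrame(responses), truth
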
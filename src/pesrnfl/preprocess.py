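"""Stages 1-2 of the segmentation pipeline: load a fundus photograph, isolate
the circular field-of-view region, denoise and correct illumination.

The working intensity grid is the green channel of the RGB photograph, which
carries the best nerve-fiber and vessel contrast in fundus photography. All
geometry downstream assumes right-eye orientation; left eyes are mirrored
horizontally at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage as ndi

from .config import PreprocessConfig


class InputError(ValueError):
    """Unreadable or structurally invalid input."""


class RoiDetectionError(ValueError):
    """The circular fundus region could not be isolated."""


class ParameterError(ValueError):
    """An operation parameter violates its precondition."""


@dataclass
class FundusImage:
    """Normalized fundus intensity grid with its region-of-interest mask.

    pixels are in [0, 1]; roi_mask has the same shape; px_per_deg is the
    width of the frame divided by the field of view (default 45 deg). After
    construction the data are in right-eye orientation.
    """

    pixels: np.ndarray
    roi_mask: np.ndarray
    fov_deg: float = 45.0
    eye: str = "right"
    rgb: Optional[np.ndarray] = None
    source_path: str = ""
    fovea_px: Optional[tuple] = None  # (row, col), set once landmarks are known

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
        if self.pixels.ndim != 2:
            raise InputError("pixels must be a 2D grid")
        if self.roi_mask.shape != self.pixels.shape:
            raise InputError("roi_mask shape must equal pixels shape")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise InputError(f"intensities must lie in [0,1], got [{lo}, {hi}]")
        if self.px_per_deg <= 0:
            raise InputError("px_per_deg must be positive")

    @property
    def shape(self):
        return self.pixels.shape

    @property
    def px_per_deg(self) -> float:
        return self.pixels.shape[1] / self.fov_deg

    # -- retinal degree frame (fovea at origin, +x nasal, +y superior) ------
    def px_to_deg(self, row, col):
        if self.fovea_px is None:
            raise ValueError("fovea_px not set; run landmark detection first")
        fr, fc = self.fovea_px
        ppd = self.px_per_deg
        return (np.asarray(col, float) - fc) / ppd, (fr - np.asarray(row, float)) / ppd

    def deg_to_px(self, x, y):
        if self.fovea_px is None:
            raise ValueError("fovea_px not set; run landmark detection first")
        fr, fc = self.fovea_px
        ppd = self.px_per_deg
        return fr - np.asarray(y, float) * ppd, fc + np.asarray(x, float) * ppd


def detect_roi(intensity: np.ndarray, threshold: float = 0.05) -> np.ndarray:
    """Circular field-of-view mask: threshold the luminance image at a small
    fixed intensity, keep the largest connected component, fill holes.

    Burned-in text and frame annotations are discarded by the
    largest-component selection; dark speckle inside the field is recovered
    by hole filling. The construction is exactly idempotent: re-running it
    on the masked image returns the same mask. Raises RoiDetectionError when
    the candidate region covers less than 10% of the frame.
    """
    mask = np.asarray(intensity, float) > threshold
    if not mask.any():
        raise RoiDetectionError("no pixels above the ROI threshold")
    labels, n = ndi.label(mask)
    if n > 1:
        sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    mask = ndi.binary_fill_holes(mask)
    frac = mask.mean()
    if frac < 0.10:
        raise RoiDetectionError(f"ROI covers only {100 * frac:.1f}% of the frame")
    return mask


def load_fundus(path, eye: str = "right", fov_deg: float = 45.0,
                config: Optional[PreprocessConfig] = None) -> FundusImage:
    """Load an 8-bit RGB fundus photograph and isolate its circular ROI.

    Left eyes are mirrored about the vertical axis so that downstream
    geometry can use the right-eye convention throughout.
    """
    import imageio.v3 as iio

    if eye not in ("left", "right"):
        raise ParameterError(f"eye must be 'left' or 'right', got {eye!r}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - normalize into the package error
        raise InputError(f"cannot read image {path!r}: {exc}") from exc
    return fundus_from_array(arr, eye=eye, fov_deg=fov_deg, config=config,
                             source_path=str(path))


def fundus_from_array(arr: np.ndarray, eye: str = "right", fov_deg: float = 45.0,
                      config: Optional[PreprocessConfig] = None,
                      source_path: str = "") -> FundusImage:
    """Build a FundusImage from an in-memory uint8/float RGB (or gray) array."""
    cfg = config or PreprocessConfig()
    arr = np.asarray(arr)
    if arr.ndim == 3:
        rgb = arr[..., :3].astype(float)
        green = rgb[..., 1]
    elif arr.ndim == 2:
        rgb = None
        green = arr.astype(float)
    else:
        raise InputError(f"expected a 2D or 3D raster, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        green = green / 255.0
        rgb = None if rgb is None else rgb / 255.0
    lo, hi = green.min(), green.max()
    green = (green - lo) / (hi - lo) if hi > lo else np.zeros_like(green)
    if eye == "left":
        green = green[:, ::-1]
        rgb = None if rgb is None else rgb[:, ::-1]
    roi = detect_roi(green if rgb is None else rgb.mean(axis=-1),
                     threshold=cfg.roi_threshold)
    return FundusImage(pixels=green, roi_mask=roi, fov_deg=fov_deg, eye=eye,
                       rgb=rgb, source_path=source_path)


def _masked_median_band(pixels, roi, kernel):
    """Exact ROI-restricted median on the band of ROI pixels whose window
    touches non-ROI pixels (the fast full-window filter is wrong only there)."""
    k = kernel // 2
    touching = ndi.binary_dilation(~roi, structure=np.ones((kernel, kernel), bool))
    # image borders truncate the window exactly like out-of-ROI pixels do
    touching[:k, :] = touching[-k:, :] = True
    touching[:, :k] = touching[:, -k:] = True
    band = touching & roi
    if not band.any():
        return None, band
    padded = np.pad(np.where(roi, pixels, np.nan), k, constant_values=np.nan)
    rows, cols = np.nonzero(band)
    windows = np.empty((rows.size, kernel * kernel))
    idx = 0
    for dr in range(kernel):
        for dc in range(kernel):
            windows[:, idx] = padded[rows + dr, cols + dc]
            idx += 1
    return np.nanmedian(windows, axis=1), band


def median_denoise(img: FundusImage, kernel: Optional[int] = None) -> FundusImage:
    """ROI-restricted median filter.

    Window members outside the ROI are ignored; the default kernel is 3 for
    frames up to 1500 px wide and 5 above that.
    """
    if kernel is None:
        kernel = 3 if img.shape[1] <= 1500 else 5
    if kernel % 2 == 0 or kernel < 3:
        raise ParameterError(f"median kernel must be odd and >= 3, got {kernel}")
    out = ndi.median_filter(img.pixels, size=kernel, mode="nearest")
    fixed, band = _masked_median_band(img.pixels, img.roi_mask, kernel)
    if fixed is not None:
        out[band] = fixed
    out = np.where(img.roi_mask, out, img.pixels)
    return replace(img, pixels=np.clip(out, 0.0, 1.0))


def sigmoid_illumination(img: FundusImage, gain: float = 10.0,
                         cutoff: float = 0.5) -> FundusImage:
    """Sigmoid intensity remapping v -> 1/(1+exp(-gain (v - cutoff))),
    then min-max rescaled to [0, 1] within the ROI.

    The pre-rescale mapping is strictly monotone, so pixel ordering is
    preserved; outside-ROI pixels are left untouched.
    """
    if gain <= 0:
        raise ParameterError(f"sigmoid gain must be > 0, got {gain}")
    mapped = 1.0 / (1.0 + np.exp(-gain * (img.pixels - cutoff)))
    inside = mapped[img.roi_mask]
    lo, hi = inside.min(), inside.max()
    if hi > lo:
        mapped = (mapped - lo) / (hi - lo)
    else:
        mapped = np.zeros_like(mapped)
    out = np.where(img.roi_mask, np.clip(mapped, 0.0, 1.0), img.pixels)
    return replace(img, pixels=out)


def sigmoid_map(v, gain: float, cutoff: float):
    """The raw (pre-rescale) sigmoid mapping, exposed for verification."""
    return 1.0 / (1.0 + np.exp(-gain * (np.asarray(v, float) - cutoff)))


def preprocess(img: FundusImage, config: Optional[PreprocessConfig] = None) -> FundusImage:
    """median_denoise followed by sigmoid_illumination with config defaults."""
    cfg = config or PreprocessConfig()
    out = median_denoise(img, cfg.median_kernel)
    return sigmoid_illumination(out, cfg.sigmoid_gain, cfg.sigmoid_cutoff)
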
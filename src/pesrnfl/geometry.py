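"""Angle conventions, circular arithmetic and the canonical eye alignment.

Every directed angle in this package lives in the fundus convention used for
structure-function mapping: 0 deg at the nasal margin (3 o'clock of a right
eye), increasing clockwise when the image is viewed with superior retina up.
Retinal degree coordinates put the fovea at the origin, +x toward the optic
nerve head (nasal, right eye) and +y toward superior retina, so a direction
``theta`` corresponds to the unit vector ``(cos theta, -sin theta)``.

The canonical aligned frame places the ONH center at 15 deg eccentricity,
2 deg above the horizontal meridian; cohorts are compared after every eye is
translated (fovea to origin), rotated and isotropically scaled into it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Canonical ONH center in the aligned frame, degrees (x nasal, y superior).
CANONICAL_ONH = (15.0, 2.0)

#: Disc-fovea angle of the canonical frame, degrees (atan(2/15)).
CANONICAL_ONH_ANGLE = math.degrees(math.atan2(CANONICAL_ONH[1], CANONICAL_ONH[0]))

#: Canonical fovea-ONH distance, degrees.
CANONICAL_ONH_DIST = math.hypot(*CANONICAL_ONH)


def wrap360(angle):
    """Wrap angle(s) in degrees to [0, 360)."""
    a = np.mod(angle, 360.0)
    # float rounding can land exactly on 360.0 (e.g. fmod of -1e-17)
    return np.where(a >= 360.0, 0.0, a) if np.ndim(a) else (0.0 if a >= 360.0 else a)


def circ_diff(a, b):
    """Minimal signed circular difference a - b, in (-180, 180] degrees."""
    d = np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float), 360.0)
    return np.where(d > 180.0, d - 360.0, d)


def circ_abs_diff(a, b):
    """Minimal absolute circular difference in [0, 180] degrees."""
    return np.abs(circ_diff(a, b))


def circular_mean(angles_deg) -> float:
    """Circular mean of angles in degrees, wrapped to [0, 360)."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValueError("circular mean of empty set")
    return float(wrap360(math.degrees(math.atan2(np.sin(a).mean(), np.cos(a).mean()))))


def theta_from_vec(dx, dy):
    """Directed angle of retinal-degree vector(s) (dx, dy) in [0, 360).

    0 deg = +x (nasal), clockwise positive (90 deg = inferior, -y).
    """
    return wrap360(np.degrees(np.arctan2(-np.asarray(dy, float), np.asarray(dx, float))))


def vec_from_theta(theta_deg):
    """Unit vector (dx, dy) in retinal degrees for directed angle(s) theta."""
    t = np.radians(np.asarray(theta_deg, dtype=float))
    return np.cos(t), -np.sin(t)


def angular_position(x, y, center) -> np.ndarray:
    """Angular position of point(s) around ``center`` in the nasal-origin,
    clockwise convention, degrees in [0, 360)."""
    return theta_from_vec(np.asarray(x, float) - center[0], np.asarray(y, float) - center[1])


@dataclass(frozen=True)
class AngleWindow:
    """Wraparound-aware closed angular interval [lo, lo + width] (degrees).

    ``width`` saturates at 360 (full circle). Membership is closed at both
    ends, matching the boundary rule used when filtering extractions.
    """

    lo: float
    width: float

    def __post_init__(self):
        if not 0.0 <= self.width <= 360.0:
            raise ValueError(f"window width must be in [0, 360], got {self.width}")

    @property
    def hi(self) -> float:
        return wrap360(self.lo + self.width) if self.width < 360.0 else float(wrap360(self.lo))

    def contains(self, theta) -> np.ndarray:
        if self.width >= 360.0:
            return np.ones(np.shape(theta), dtype=bool) if np.ndim(theta) else np.bool_(True)
        rel = np.mod(np.asarray(theta, float) - self.lo, 360.0)
        # tiny epsilon so that theta == hi (up to float noise) stays inside
        return rel <= self.width + 1e-9

    def widened(self, margin: float) -> "AngleWindow":
        if margin < 0:
            raise ValueError("margin must be >= 0")
        w = self.width + 2.0 * margin
        if w >= 360.0:
            return AngleWindow(0.0, 360.0)
        return AngleWindow(float(wrap360(self.lo - margin)), float(w))

    @staticmethod
    def from_angles(angles_deg, margin: float = 0.0) -> "AngleWindow":
        """Smallest closed arc containing all angles, widened by ``margin``.

        Found by sorting and excising the largest angular gap; if the largest
        gap is zero-length (angles span the circle) the full circle is used.
        """
        a = np.sort(wrap360(np.asarray(angles_deg, dtype=float)))
        if a.size == 0:
            raise ValueError("cannot build a window from no angles")
        if a.size == 1:
            return AngleWindow(float(a[0]), 0.0).widened(margin)
        gaps = np.diff(np.concatenate([a, [a[0] + 360.0]]))
        i = int(np.argmax(gaps))
        if gaps[i] <= 0.0:
            return AngleWindow(0.0, 360.0)
        lo = a[(i + 1) % a.size]
        width = min(max(360.0 - gaps[i], 0.0), 360.0)  # clamp float residue
        return AngleWindow(float(lo), float(width)).widened(margin)


@dataclass(frozen=True)
class EyeAlignment:
    """Similarity transform taking one eye's fovea-centered degree frame into
    the canonical frame (ONH at (15, 2)).

    rotation_deg is counterclockwise in the (x nasal, y superior) frame;
    directed angles (clockwise convention) therefore transform as
    theta -> theta - rotation_deg.
    """

    rotation_deg: float
    scale: float

    def apply_points(self, x, y):
        r = math.radians(self.rotation_deg)
        cr, sr = math.cos(r), math.sin(r)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return self.scale * (cr * x - sr * y), self.scale * (sr * x + cr * y)

    def apply_theta(self, theta_deg):
        return wrap360(np.asarray(theta_deg, dtype=float) - self.rotation_deg)

    def inverse(self) -> "EyeAlignment":
        return EyeAlignment(-self.rotation_deg, 1.0 / self.scale)
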
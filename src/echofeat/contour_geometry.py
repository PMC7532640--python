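"""Shape features from mask and boundary alone.

Three descriptors: circularity C^2/S, the height-to-width ratio of the
axis-aligned circumscribed rectangle, and the angle between the lesion long
axis and the skin line (ALS), obtained from a direct least-squares ellipse
fit to the boundary and folded into [0, 90] degrees.  The skin is assumed
parallel to the top image edge (standard linear-probe geometry), so the
"horizontal direction" is the image column axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.measure import EllipseModel

from .exceptions import FitError, ValidationError
from .roi_io import Contour, LesionROI

#: aspect ratio below which the fitted orientation is ill-defined
LOW_CONFIDENCE_ASPECT = 1.05


@dataclass(frozen=True)
class EllipseFit:
    """Least-squares ellipse through the boundary pixels.

    ``theta_raw`` is the angle of the long axis measured from the +col
    (horizontal) axis toward +row, normalized to [0, 2*pi).
    """

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    theta_raw: float

    @property
    def aspect_ratio(self) -> float:
        return self.semi_major / self.semi_minor

    @property
    def low_confidence(self) -> bool:
        """Orientation is poorly determined for near-circular boundaries."""
        return self.aspect_ratio < LOW_CONFIDENCE_ASPECT


def circularity(roi: LesionROI) -> float:
    """C^2 / S — similarity of the lesion to a circle.

    C is the Freeman chain length of the traced boundary and S the
    foreground pixel count, so the continuous limit for a disc is 4*pi and
    every other shape scores higher.
    """
    s = roi.area_px
    if s == 0:
        raise ValidationError("empty mask")
    return roi.perimeter_px ** 2 / s


def height_width_ratio(roi: LesionROI) -> float:
    """H/W of the axis-aligned circumscribed rectangle of the boundary.

    Extents are inclusive pixel counts (max - min + 1), consistent with the
    pixel-count semantics of C and S.
    """
    v = roi.boundary.vertices
    h = v[:, 0].max() - v[:, 0].min() + 1.0
    w = v[:, 1].max() - v[:, 1].min() + 1.0
    if h <= 0 or w <= 0:
        raise ValidationError("degenerate boundary extent")
    return float(h / w)


def fit_ellipse(boundary: Contour) -> EllipseFit:
    """Direct least-squares (algebraic) ellipse fit to boundary points."""
    v = boundary.vertices
    if v.shape[0] < 8:
        raise FitError("need at least 8 boundary points")
    xy = np.stack([v[:, 1], v[:, 0]], axis=1)  # (x=col, y=row)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = EllipseModel.from_estimate(xy)
    if not model:
        raise FitError("ellipse fit failed (collinear or degenerate points)")
    xc, yc = model.center
    a, b = model.axis_lengths
    theta = float(model.theta)
    if b > a:
        a, b = b, a
        theta += np.pi / 2
    if a <= 0 or b <= 0 or not np.isfinite(theta):
        raise FitError("degenerate ellipse fit")
    theta = float(np.mod(theta, 2 * np.pi))
    return EllipseFit(center=(float(yc), float(xc)), semi_major=float(a),
                      semi_minor=float(b), theta_raw=theta)


def fold_angle(theta_raw: float) -> float:
    """Fold a raw axis angle in [0, 2*pi] into [0, pi/2].

    Piecewise: theta on [0, pi/2]; pi - theta on [pi/2, pi];
    theta - pi on [pi, 3*pi/2]; 2*pi - theta on [3*pi/2, 2*pi].
    An axis has no direction, so the map is pi-periodic and idempotent on
    [0, pi/2].
    """
    th = float(theta_raw)
    if th < 0 or th > 2 * np.pi:
        raise ValidationError(f"angle {th} outside [0, 2*pi]")
    if th <= np.pi / 2:
        return th
    if th <= np.pi:
        return np.pi - th
    if th <= 3 * np.pi / 2:
        return th - np.pi
    return 2 * np.pi - th


def als_degrees(roi: LesionROI) -> float:
    """Angle between the lesion long axis and the skin line, in [0, 90] deg."""
    fit = fit_ellipse(roi.boundary)
    return float(np.degrees(fold_angle(fit.theta_raw)))
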
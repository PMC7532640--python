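"""Margin descriptors: spicules, coarseness, indistinctness, lobulation.

The first three operate on the radial boundary sequence (r_i, theta_i) and
the local Sobel gradient; lobulation counts undulations of a smoothed
radial profile.

Spicules (MS) is the ratio of low-frequency to high-frequency magnitude in
the one-sided spectrum of the radii, with the split at angular frequency
pi/4 per boundary sample; the DC term is included in the numerator, so MS
scales with lesion radius and diverges for a perfectly smooth boundary.
That degenerate case returns ``SPICULES_OVERFLOW`` (infinity) rather than
raising, because smooth lesions are legitimate inputs.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .exceptions import ValidationError
from .roi_io import LesionROI, RadialSequence, boundary_pixel_set

#: sentinel for a spicule ratio with (near-)zero high-frequency energy
SPICULES_OVERFLOW = math.inf

_SOBEL_MODE = "nearest"  # replicate padding at the image border


def sobel_magnitude(pixels: np.ndarray) -> np.ndarray:
    """3x3 Sobel gradient magnitude sqrt(dx^2 + dy^2) of the full image."""
    img = np.asarray(pixels, dtype=float)
    dx = ndimage.sobel(img, axis=1, mode=_SOBEL_MODE)
    dy = ndimage.sobel(img, axis=0, mode=_SOBEL_MODE)
    return np.hypot(dx, dy)


def margin_spicules(seq: RadialSequence) -> float:
    """Low/high frequency ratio of the radial spectrum (dimensionless).

    Splits the one-sided DFT magnitude spectrum at omega = pi/4 (bin
    k = N/8): numerator sums bins with 2*pi*k/N <= pi/4 (DC included),
    denominator the bins up to the Nyquist frequency pi.  Sharper, denser
    margin spicules raise the high-frequency content and lower the value.
    """
    r = seq.r
    n = r.size
    if n < 8:
        raise ValidationError("radial sequence shorter than 8 samples")
    mags = np.abs(np.fft.rfft(r))
    k = np.arange(mags.size)
    low = 8 * k <= n          # omega_k = 2*pi*k/N <= pi/4
    num = float(mags[low].sum())
    den = float(mags[~low].sum())
    if den < 1e-9 * num:
        return SPICULES_OVERFLOW
    return num / den


def resample_radial(seq: RadialSequence, n: int) -> RadialSequence:
    """Resample radii onto n angles uniform in theta (linear, periodic)."""
    if n < 8:
        raise ValidationError("need at least 8 resampled points")
    order = np.argsort(seq.theta)
    grid = np.arange(n) * 2 * np.pi / n
    r = np.interp(grid, seq.theta[order], seq.r[order], period=2 * np.pi)
    return RadialSequence(r, grid, clockwise=True)


def margin_coarseness(seq: RadialSequence) -> float:
    """Mean absolute cyclic difference of consecutive radii (pixel units)."""
    r = seq.r
    if r.size < 2:
        raise ValidationError("need at least 2 radii")
    return float(np.mean(np.abs(np.diff(r, append=r[:1]))))


def margin_indistinctness(roi: LesionROI, band_width: int = 5) -> float:
    """Summed Sobel gradient magnitude over the boundary band.

    The band is the boundary pixel set dilated by a disc of radius
    ``band_width`` (covering tissue just inside and outside the margin).  A
    blurred, ill-defined margin has weak gradients and a low value.  The
    raw sum is returned; feature tables report it divided by 1e6.
    """
    if band_width < 1:
        raise ValidationError("band_width must be >= 1")
    bnd = boundary_pixel_set(roi.mask)
    band = ndimage.binary_dilation(bnd, structure=disk(band_width).astype(bool))
    if not band.any():
        raise ValidationError("empty boundary band")
    grad = sobel_magnitude(roi.image.pixels)
    return float(grad[band].sum())


def _merge_plateau_runs(values: np.ndarray, tol: float) -> np.ndarray:
    """Compress cyclically consecutive near-equal values into single runs."""
    out = [values[0]]
    for v in values[1:]:
        if abs(v - out[-1]) > tol:
            out.append(v)
    if len(out) > 1 and abs(out[0] - out[-1]) <= tol:
        out.pop()
    return np.asarray(out)


def count_cyclic_extrema(values: np.ndarray, tol: float = 0.0) -> int:
    """Strict local maxima + minima on a cyclic grid, plateaus merged."""
    vals = _merge_plateau_runs(np.asarray(values, dtype=float), tol)
    m = vals.size
    if m < 3:
        return 0
    prev = np.roll(vals, 1)
    nxt = np.roll(vals, -1)
    return int(np.sum((vals > prev) & (vals > nxt)) +
               np.sum((vals < prev) & (vals < nxt)))


def smooth_radial_profile(seq: RadialSequence, median_frame: int = 21,
                          degree: int = 20) -> np.ndarray:
    """Median-filter then fit a periodic smoother; return fitted values.

    The radii are first passed through a cyclic median filter of the given
    frame size.  The smoother is a least-squares trigonometric polynomial
    in the normalized position t = i/N with harmonics 1..degree/2 (20
    coefficients beyond the constant at the default degree): the boundary
    is closed, so a periodic basis avoids the seam artefacts an algebraic
    polynomial produces at t = 0.
    """
    r = seq.r
    n = r.size
    if n < 2 * median_frame:
        raise ValidationError(
            f"need N >= {2 * median_frame} boundary samples, got {n}")
    rf = ndimage.median_filter(r, size=median_frame, mode="wrap")
    order = max(1, degree // 2)
    t = np.arange(n) / n
    cols = [np.ones(n)]
    for h in range(1, order + 1):
        w = 2 * np.pi * h * t
        cols.append(np.cos(w))
        cols.append(np.sin(w))
    basis = np.stack(cols, axis=1)
    coef, *_ = np.linalg.lstsq(basis, rf, rcond=None)
    return basis @ coef


def margin_lobulation(seq: RadialSequence, median_frame: int = 21,
                      degree: int = 20, min_prominence: float = 0.5) -> int:
    """Number of undulations of the smoothed radial profile.

    Counts strict local maxima plus minima of the smoothed profile over the
    cyclic sample grid (a planted k-fold harmonic yields 2k).  Variations
    below ``min_prominence`` (pixels) are treated as plateaus: rasterizing
    a smooth boundary leaves a sub-half-pixel staircase ripple in the
    radii (measured < 0.4 px on discs of radius 30-80 after smoothing), so
    the default half-pixel floor makes a clean disc count zero while real
    lobes, at least a pixel deep, are unaffected.
    """
    fitted = smooth_radial_profile(seq, median_frame=median_frame, degree=degree)
    tol = max(float(min_prominence), 1e-9 * max(1.0, float(np.max(np.abs(fitted)))))
    return count_cyclic_extrema(fitted, tol=tol)
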
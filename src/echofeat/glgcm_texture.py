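"""Grey level gradient co-occurrence matrix (GLGCM) texture features.

The GLGCM is the joint histogram H(i, j) of quantized pixel intensity
(level i of L_s) and quantized Sobel gradient magnitude (level j of L_g)
over the lesion interior, normalized to P(i, j).  Three descriptors are
computed from it:

* energy       E   = sum_ij P(i, j)^2
* entropy      Ent = -sum_i q_i ln q_i,  q_i = sum_j P(i, j)
* grey mean    GM  = sum_i g_i q_i,      g_i = (i - 1) / (L_s - 1)

Entropy is the entropy of the grey-level marginal, with the natural
logarithm, so it is bounded by ln L_s.  The grey mean uses normalized level
values g_i in [0, 1]; the raw level index is available via
``gm_scale="levels"``.  Gradients are normalized per lesion to their own
interior maximum, because absolute gradient scales depend on instrument
gain and are not comparable across machines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .margin_features import sobel_magnitude
from .roi_io import LesionROI

MIN_INTERIOR_PX = 16


@dataclass(frozen=True)
class GLGCM:
    """Joint grey/gradient histogram H and its normalization P."""

    H: np.ndarray
    P: np.ndarray
    L_s: int
    L_g: int

    @property
    def grey_values(self) -> np.ndarray:
        """Representative normalized grey value g_i in [0, 1] per level."""
        if self.L_s == 1:
            return np.zeros(1)
        return np.arange(self.L_s) / (self.L_s - 1)

    @property
    def grey_marginal(self) -> np.ndarray:
        """q_i = sum_j P(i, j)."""
        return self.P.sum(axis=1)


def _quantize(values: np.ndarray, upper: float, levels: int) -> np.ndarray:
    """Map [0, upper] linearly onto integer levels 1..levels."""
    if upper <= 0:
        return np.ones(values.shape, dtype=int)
    lvl = np.floor(values / upper * levels).astype(int) + 1
    return np.clip(lvl, 1, levels)


def build_glgcm(roi: LesionROI, L_s: int = 16, L_g: int = 16,
                quantization: str = "fixed") -> GLGCM:
    """Accumulate the GLGCM over the lesion interior.

    Grey levels are mapped linearly from the fixed range [0, 255] (or the
    interior min-max range with ``quantization="minmax"``) to 1..L_s;
    gradient magnitudes from [0, interior max] to 1..L_g, an all-zero
    gradient field mapping to level 1.
    """
    if L_s < 2 or L_g < 2:
        raise ValidationError("L_s and L_g must be >= 2")
    if quantization not in ("fixed", "minmax"):
        raise ValidationError("quantization must be 'fixed' or 'minmax'")
    mask = roi.mask
    if int(mask.sum()) < MIN_INTERIOR_PX:
        raise ValidationError(f"interior smaller than {MIN_INTERIOR_PX} pixels")

    grey = roi.image.pixels[mask].astype(float)
    if quantization == "fixed":
        grey_lvl = np.floor(grey / 256.0 * L_s).astype(int) + 1
        grey_lvl = np.clip(grey_lvl, 1, L_s)
    else:
        lo, hi = grey.min(), grey.max()
        grey_lvl = (_quantize(grey - lo, hi - lo, L_s) if hi > lo
                    else np.ones(grey.shape, dtype=int))

    grad = sobel_magnitude(roi.image.pixels)[mask]
    grad_lvl = _quantize(grad, float(grad.max()), L_g)

    flat = (grey_lvl - 1) * L_g + (grad_lvl - 1)
    H = np.bincount(flat, minlength=L_s * L_g).reshape(L_s, L_g)
    P = H / H.sum()
    return GLGCM(H=H, P=P, L_s=L_s, L_g=L_g)


def glgcm_energy(g: GLGCM) -> float:
    """Sum of squared joint probabilities; 1 iff a single nonzero cell."""
    return float(np.sum(g.P ** 2))


def glgcm_entropy(g: GLGCM) -> float:
    """Natural-log entropy of the grey-level marginal, in [0, ln L_s]."""
    q = g.grey_marginal
    q = q[q > 0]
    return float(max(0.0, -np.sum(q * np.log(q))))


def glgcm_grey_mean(g: GLGCM, gm_scale: str = "normalized") -> float:
    """Marginal-weighted mean grey level.

    ``normalized`` (default) weights by g_i = (i-1)/(L_s-1) in [0, 1];
    ``levels`` weights by the raw level index i in 1..L_s.
    """
    q = g.grey_marginal
    if gm_scale == "normalized":
        return float(np.dot(g.grey_values, q))
    if gm_scale == "levels":
        return float(np.dot(np.arange(1, g.L_s + 1), q))
    raise ValidationError("gm_scale must be 'normalized' or 'levels'")
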
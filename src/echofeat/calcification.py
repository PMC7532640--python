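"""Internal calcification counting.

Calcifications appear as small bright (hyperechoic) foci inside the lesion.
They are counted by zeroing everything outside the mask, thresholding the
interior between its mean and maximum grey value, cleaning the binary image
morphologically, and counting connected components above a minimum size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .exceptions import ValidationError
from .roi_io import LesionROI


@dataclass(frozen=True)
class CalcificationParams:
    """Knobs of the calcification detector.

    ``threshold_alpha`` places the binarization threshold between the
    interior mean and maximum: T = mu + alpha * (max - mu).  ``morph_order``
    selects the cleaning step: "close" (dilate then erode, the literal word
    order of the procedure) or "open" (the conventional speck remover).
    """

    threshold_alpha: float = 0.5
    struct_radius: int = 1
    min_blob_px: int = 4
    connectivity: int = 8
    morph_order: str = "close"

    def __post_init__(self) -> None:
        if not 0 < self.threshold_alpha < 1:
            raise ValidationError("threshold_alpha must be in (0, 1)")
        if self.struct_radius < 1 or self.min_blob_px < 1:
            raise ValidationError("struct_radius and min_blob_px must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValidationError("connectivity must be 4 or 8")
        if self.morph_order not in ("close", "open"):
            raise ValidationError("morph_order must be 'close' or 'open'")


def calcification_binary(roi: LesionROI,
                         params: CalcificationParams | None = None) -> np.ndarray:
    """Thresholded and morphologically cleaned bright-spot binary image.

    Pixels outside the mask are zeroed, the interior is binarized at
    T = mu + alpha * (max - mu) over interior statistics, and the result is
    cleaned with a disc structuring element (restricted back to the mask so
    dilation cannot leak outside the lesion).
    """
    params = params or CalcificationParams()
    mask = roi.mask
    interior = roi.image.pixels[mask].astype(float)
    if interior.size == 0:
        raise ValidationError("empty lesion interior")
    mu, mx = interior.mean(), interior.max()
    if mx <= mu:  # constant interior: nothing can exceed the threshold
        return np.zeros_like(mask)
    thresh = mu + params.threshold_alpha * (mx - mu)
    binary = (roi.image.pixels > thresh) & mask

    selem = disk(params.struct_radius).astype(bool)
    if params.morph_order == "close":
        binary = ndimage.binary_erosion(
            ndimage.binary_dilation(binary, structure=selem), structure=selem)
    else:
        binary = ndimage.binary_dilation(
            ndimage.binary_erosion(binary, structure=selem), structure=selem)
    return binary & mask


def count_calcifications(roi: LesionROI,
                         params: CalcificationParams | None = None) -> int:
    """Number of bright connected blobs inside the lesion."""
    params = params or CalcificationParams()
    binary = calcification_binary(roi, params)
    structure = (np.ones((3, 3), dtype=int) if params.connectivity == 8
                 else ndimage.generate_binary_structure(2, 1))
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return 0
    sizes = np.bincount(labels.ravel())[1:]
    return int(np.sum(sizes >= params.min_blob_px))
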